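# n15quant

Identification and quantification of ¹⁵N metabolic-labeling LC-MS
proteomics data by high-precision extracted-ion-chromatogram (XIC)
pairing.

## The problem

In ¹⁵N metabolic labeling, one of two biological conditions is grown on a
¹⁵N nitrogen source so that every peptide from that condition is heavier
by `N × 0.99703489341` Da, where `N` is the peptide's nitrogen count.
Unlike SILAC, the mass offset between the light and heavy form of a
peptide is *sequence-dependent*, so light/heavy pairs cannot be found
with a single fixed shift. Worse, incompletely labeled peptides produce
satellite peaks *below* the fully labeled monoisotopic peak, spaced by
the ¹⁵N shift, which an isotope-envelope reader can mistake for ¹³C
isotope peaks.

`n15quant` implements an integrated solution:

1. **XIC detection** over all MS1 scans (greedy, most-intense-first
   seeding; charge from ¹³C spacing).
2. **Monoisotopic classification** using instrument precision: the
   per-unit ¹³C shift (1.00335483781 Da) and ¹⁵N shift (0.99703489341 Da)
   differ by `d = 0.0063199444` Da, so at precision `p` ppm the two are
   distinguishable up to m/z `(d / p) × 10⁶ / z` — 6319 for z = 1 and
   1579 for z = 4 at 1 ppm. An XIC is monoisotopic if it has a
   co-eluting ¹³C neighbour above but none below.
3. **Pairing** of monoisotopic XICs through two peptide-mass databases
   (unlabeled and labeled, with nitrogen counts) built by in-silico
   tryptic digestion: each database hit with nitrogen count `N`
   nominates one candidate position at `mz ± 0.99703489341 × N / z`;
   exactly one occupied candidate makes an unambiguous pair, which fixes
   each member's label and the peptide's nitrogen count.
4. **Label-aware MS/MS search**: each fragmentation spectrum is searched
   against the database matching its XIC's label, with candidates of the
   wrong nitrogen count filtered out before scoring. PSMs are scored
   `(M/L) Σ log₂(I_m)` over matched b/y ladder peaks and filtered at a
   peptide-level q-value threshold estimated from concatenated reverse
   decoys.
5. **Quantification**: log₂ ratios of paired XIC areas, collated to
   peptide medians and rolled up to protein medians, with split-half
   consistency and label-swap replicate correlation as evaluation
   statistics.

A first-class synthetic-data generator (`n15quant.synthetic`) emulates
Gaussian elution, natural ¹³C envelopes, binomial incomplete-labeling
envelopes, ppm-scale mass error and data-dependent MS2 selection, with a
full ground-truth manifest, so every stage is testable without any
external data.

## Worked example

```python
import numpy as np
from n15quant import SimConfig, simulate_run, build_databases, run_pipeline
from n15quant.synthetic import random_proteome
from n15quant.evaluation import pairing_metrics, protein_ratio_recovery
from n15quant.quant import split_half_consistency

cfg = SimConfig(seed=7)                      # 50 proteins x 6 peptides, e = 0.98
run, peptide_truth, species_truth = simulate_run(cfg)
proteome = random_proteome(cfg, np.random.default_rng(cfg.seed))
db_light, db_heavy = build_databases(proteome)
result = run_pipeline(run, db_light, db_heavy)

c = result.counters
print(f"XICs: {c['n_xics']}  monoisotopic: {c['n_monoisotopic']}  "
      f"pairs: {c['n_pairs']}  multiply coupled: {c['n_multiply_coupled']}")
pm = pairing_metrics(result, peptide_truth, species_truth)
rec = protein_ratio_recovery(result, peptide_truth)
rho, _ = split_half_consistency(result.protein_quants, seed=17)
```

Output:

```
XICs: 7466  monoisotopic: 1586  pairs: 295  multiply coupled: 4
PSMs: 1004  accepted at 1% FDR: 587
pair sensitivity: 0.983  N accuracy: 1.000
protein ratios: Spearman 0.999, median |error| 0.018 log2 (50 proteins)
split-half consistency: rho = 0.998
   protein  n_distinct_peptides  median_log2_ratio  cv_percent
SIMPROT000                    6           1.909125    4.264061
SIMPROT001                    6          -2.533381    7.474560
SIMPROT002                    6          -0.582659    3.542528
```

Of the 300 simulated peptides (two channels each), 295 light/heavy pairs
are recovered, every formed pair carries the correct nitrogen count and
label orientation, and the recovered protein log₂ ratios track the
configured truth to ~0.02 log₂ units.

## Command line

```bash
n15quant simulate --config sim.yaml --seed 1 --out run.mzML --truth truth.tsv
n15quant digest   --fasta proteome.fasta --out db.tsv
n15quant detect   --in run.mzML --tol-ppm 4 --out xics.tsv
n15quant run      --in run.mzML --fasta proteome.fasta --out-dir results/
n15quant eval split-half --run-dir results/ --seed 17
n15quant eval replicates --table-a A/proteins.tsv --table-b B/proteins.tsv --swap
```

`run` writes `pairs.tsv`, `psms.tsv`, `peptides.tsv`, `proteins.tsv`,
plus per-stage counters.

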