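"""Self-contained benchmark simulations for the statistical machinery.

Two studies that need no LC dimension:

* :func:`fdr_calibration` -- does the decoy-estimated q-value cutoff
  deliver the promised false-discovery proportion when the decoy score
  distribution matches the incorrect-target score distribution?
* :func:`nitrogen_constraint_benchmark` -- does filtering candidates by
  the pair-derived nitrogen count increase identifications at a fixed FDR
  when near-isobaric wrong-nitrogen peptides are present?  Distractors are
  Asn->Asp substitutions: the substitution adds 0.98402 Da and removes one
  nitrogen, so above ~1302 Da neutral mass the *labeled* masses of the
  original and the variant collide within 10 ppm while their nitrogen
  counts differ by one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import DELTA_15N, PROTON_MASS
from .msms_search import (
    PSM,
    SearchParams,
    best_psm_per_spectrum,
    estimate_qvalues,
    fdr_filter,
    search_spectrum,
    theoretical_fragments,
)
from .peptide_db import LABELED, DigestParams, build_databases, monoisotopic_mass, nitrogen_count
from .spectra_io import MS2Spectrum
from .synthetic import SimConfig, random_proteome


@dataclass(frozen=True)
class CalibrationResult:
    n_accepted: int
    n_false: int
    fdp: float
    q_threshold: float


def fdr_calibration(
    n_spectra: int = 2000,
    true_fraction: float = 0.5,
    effect: float = 3.0,
    q_threshold: float = 0.05,
    seed: int = 0,
) -> CalibrationResult:
    """Spectrum-level target/decoy competition under a known ground truth.

    Each simulated spectrum yields one best PSM.  A *true* spectrum's
    target score is drawn from a shifted normal; a *null* spectrum draws
    both a target and a decoy score from the same null normal and keeps
    the larger (the concatenated-database competition).  The realised
    false-discovery proportion among targets accepted at ``q_threshold``
    is returned alongside the counts.
    """
    rng = np.random.default_rng(seed)
    psms: list[PSM] = []
    is_false: dict[int, bool] = {}
    for i in range(n_spectra):
        if rng.random() < true_fraction:
            score = float(rng.normal(effect, 1.0))
            psms.append(_null_psm(i, score, decoy=False))
            is_false[i] = False
        else:
            t = float(rng.normal(0.0, 1.0))
            d = float(rng.normal(0.0, 1.0))
            if t >= d:
                psms.append(_null_psm(i, t, decoy=False))
                is_false[i] = True
            else:
                psms.append(_null_psm(i, d, decoy=True))
    psms = estimate_qvalues(psms)
    accepted = [p for p in psms if not p.is_decoy and p.q_value <= q_threshold]
    n_false = sum(1 for p in accepted if is_false[p.ms2_id])
    fdp = n_false / len(accepted) if accepted else 0.0
    return CalibrationResult(len(accepted), n_false, fdp, q_threshold)


def _null_psm(i: int, score: float, decoy: bool) -> PSM:
    return PSM(
        ms2_id=i, sequence=f"seq{i}", label_state="unlabeled", charge=2,
        score=score, nitrogen_count=1, is_decoy=decoy,
    )


@dataclass(frozen=True)
class ConstraintBenchmarkResult:
    n_spectra: int
    accepted_with_constraint: int
    accepted_without_constraint: int


def _distractor_entries(db) -> list:
    """Decoy entries that are Asn->Asp variants of heavy target peptides.

    Under 15N labeling the variant is a true doppelganger: its labeled
    precursor mass differs by 0.013 Da (inside a 10 ppm window above
    ~1302 Da) and every labeled fragment by the same 0.013 Da (inside any
    ion-trap fragment tolerance), so only the nitrogen count -- one fewer
    -- can tell them apart.  Injecting them as decoys makes each
    undecidable match visible to the FDR estimate.
    """
    from dataclasses import replace as _replace

    out = []
    for e in db:
        if e.is_decoy or "N" not in e.sequence or e.mass_unlabeled < 1302.0:
            continue
        variant = e.sequence.replace("N", "D")
        mu = monoisotopic_mass(variant, labeled=False)
        n = nitrogen_count(variant)
        out.append(
            _replace(
                e, sequence=variant, mass_unlabeled=mu,
                mass_labeled=mu + n * DELTA_15N, nitrogen_count=n,
                proteins=frozenset({"distractor_" + next(iter(e.proteins))}),
                is_decoy=True,
            )
        )
    return out


def nitrogen_constraint_benchmark(
    seed: int,
    n_proteins: int = 24,
    n_spectra: int = 150,
    fdr_threshold: float = 0.01,
    fragment_keep: float = 0.7,
    noise_peaks: int = 15,
) -> ConstraintBenchmarkResult:
    """Accepted peptide identifications at a fixed FDR, with and without
    the nitrogen-count constraint, on heavy-channel spectra whose search
    space contains near-isobaric wrong-nitrogen distractors."""
    rng = np.random.default_rng(seed)
    base_cfg = SimConfig(
        seed=seed, n_proteins=n_proteins, peptides_per_protein=6,
        peptide_len=(10, 14), max_peptide_mass=1800.0,
    )
    proteome = random_proteome(base_cfg, rng)
    params = DigestParams(max_missed=0)
    from .peptide_db import LABELED as _L, UNLABELED as _U, PeptideDatabase

    db_u0, _ = build_databases(proteome, params)
    entries = list(db_u0) + _distractor_entries(db_u0)
    db_pair = (
        PeptideDatabase(entries, _U, params),
        PeptideDatabase(entries, _L, params),
    )
    search_params = SearchParams(fdr_threshold=fdr_threshold)

    # candidate true peptides: Asn-containing, heavy enough for the
    # labeled-mass collision to fall inside the precursor window
    eligible = [
        e
        for e in db_pair[0]
        if not e.is_decoy and "N" in e.sequence and e.mass_unlabeled >= 1302.0
    ]
    if not eligible:
        raise ValueError("no eligible Asn-containing peptides; enlarge the proteome")

    spectra: list[tuple[MS2Spectrum, int]] = []
    for i in range(n_spectra):
        e = eligible[int(rng.integers(len(eligible)))]
        z = 2
        frags = theoretical_fragments(e.sequence, LABELED, z)
        keep = rng.random(len(frags)) < fragment_keep
        if keep.sum() < 2:
            keep[:2] = True
        frags = frags[keep]
        f_int = rng.uniform(50.0, 1000.0, size=len(frags))
        noise_mz = rng.uniform(150.0, 1500.0, size=noise_peaks)
        noise_int = rng.uniform(2.0, 400.0, size=noise_peaks)
        pmz = e.mass_labeled / z + PROTON_MASS
        spectra.append(
            (
                MS2Spectrum(
                    scan_id=i, retention_time=float(i),
                    precursor_mz=pmz * (1.0 + rng.normal(0, 1.0) * 1e-6),
                    precursor_charge=z,
                    mz=np.concatenate([frags, noise_mz]),
                    intensity=np.concatenate([f_int, noise_int]),
                ),
                e.nitrogen_count,
            )
        )

    def accepted_count(use_constraint: bool) -> int:
        psms: list[PSM] = []
        for spectrum, n_true in spectra:
            hits = search_spectrum(
                spectrum, LABELED, n_true if use_constraint else None,
                db_pair, search_params,
            )
            if hits:
                psms.append(hits[0])
        if not psms:
            return 0
        psms = estimate_qvalues(best_psm_per_spectrum(psms))
        return len(fdr_filter(psms, fdr_threshold))

    return ConstraintBenchmarkResult(
        n_spectra=n_spectra,
        accepted_with_constraint=accepted_count(True),
        accepted_without_constraint=accepted_count(False),
    )


@dataclass(frozen=True)
class LabelSwapResult:
    protein_rho: float
    peptide_rho: float
    n_shared_proteins: int


def label_swap_study(seed: int, config: SimConfig | None = None) -> LabelSwapResult:
    """Forward and label-swap replicates of the same ground truth.

    Two runs share one proteome and one set of true protein ratios; the
    swap run reverses which condition is 15N-labeled (true log2 ratios
    negate) and uses independent noise.  Both are processed end to end and
    their ratio tables correlated after negating the swap run.
    """
    from .pipeline import run_pipeline
    from .quant import replicate_correlation

    cfg = config or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    proteome = random_proteome(cfg, rng)
    ratios = {acc: float(rng.normal(0.0, cfg.ratio_log2_sd)) for acc, _ in proteome}
    fwd_cfg = replace(cfg, proteome=proteome, true_log2_ratios=ratios)
    swap_cfg = replace(
        cfg, seed=seed + 10_000, proteome=proteome, true_log2_ratios=ratios,
        swap_labels=True,
    )
    db_u, db_l = build_databases(proteome)
    from .synthetic import simulate_run

    run_f, _, _ = simulate_run(fwd_cfg)
    run_s, _, _ = simulate_run(swap_cfg)
    res_f = run_pipeline(run_f, db_u, db_l)
    res_s = run_pipeline(run_s, db_u, db_l)
    prot_rho = replicate_correlation(
        res_f.protein_table, res_s.protein_table, level="protein", swap=True
    )
    pep_rho = replicate_correlation(
        res_f.peptide_table, res_s.peptide_table, level="peptide", swap=True
    )
    shared = len(
        set(res_f.protein_table["protein"]) & set(res_s.protein_table["protein"])
    )
    return LabelSwapResult(prot_rho, pep_rho, shared)
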