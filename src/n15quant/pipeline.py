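"""End-to-end orchestration: run -> XICs -> pairs -> PSMs -> ratio tables."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from . import quant
from .msms_search import (
    PSM,
    SearchParams,
    best_psm_per_spectrum,
    estimate_qvalues,
    fdr_filter,
    search_spectrum,
    search_unpaired,
)
from .pairing import PairingResult, pair_xics
from .peptide_db import PeptideDatabase, peptide_to_protein_map
from .spectra_io import Run
from .xic import (
    MONOISOTOPIC,
    XIC,
    PrecisionModel,
    attach_ms2,
    annotate_xics,
    extract_xics,
    transfer_ms2_to_monoisotopic,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tolerance and threshold of the pipeline in one place."""

    xic_tol_ppm: float = 4.0
    min_scans: int = 3
    max_gap_scans: int = 1
    charge_range: tuple[int, ...] = (1, 2, 3, 4)
    precursor_tol_ppm: float = 10.0
    pairing_tol_ppm: float = 3.0
    fragment_tol: float = 0.5
    fdr_threshold: float = 0.01
    orientation: str = quant.NUMERATOR_LABELED
    shared_peptides: str = "exclude"

    @property
    def precision(self) -> PrecisionModel:
        return PrecisionModel(self.xic_tol_ppm, self.charge_range)

    @property
    def search_params(self) -> SearchParams:
        return SearchParams(
            self.precursor_tol_ppm, self.fragment_tol, self.fdr_threshold
        )


@dataclass
class PipelineResult:
    xics: list[XIC]
    pairing: PairingResult
    psms: list[PSM]  # all scored best-per-spectrum PSMs with q-values
    accepted: list[PSM]  # FDR-filtered, target, peptide-level
    peptide_quants: list
    protein_quants: list
    counters: dict = field(default_factory=dict)

    @property
    def peptide_table(self) -> pd.DataFrame:
        return quant.peptide_table(self.peptide_quants)

    @property
    def protein_table(self) -> pd.DataFrame:
        return quant.protein_table(self.protein_quants)

    @property
    def pairs_table(self) -> pd.DataFrame:
        rows = []
        for p in self.pairing.pairs:
            ratio = quant.pair_ratio(p, self.counters.get("orientation", "labeled"))
            rows.append(
                {
                    "light_mz": p.light_mz, "heavy_mz": p.heavy_mz,
                    "charge": p.charge, "nitrogen_count": p.nitrogen_count,
                    "rt_start": p.rt_start, "rt_end": p.rt_end,
                    "light_area": p.light_area, "heavy_area": p.heavy_area,
                    "log2_ratio": ratio,
                }
            )
        return pd.DataFrame(rows)

    @property
    def psms_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scan": [p.ms2_id for p in self.psms],
                "sequence": [p.sequence for p in self.psms],
                "label": [p.label_state for p in self.psms],
                "charge": [p.charge for p in self.psms],
                "score": [p.score for p in self.psms],
                "q_value": [p.q_value for p in self.psms],
                "decoy": [p.is_decoy for p in self.psms],
            }
        )


def run_pipeline(
    run: Run,
    db_unlabeled: PeptideDatabase,
    db_labeled: PeptideDatabase,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the full identification + quantification pipeline."""
    cfg = config or PipelineConfig()
    db_pair = (db_unlabeled, db_labeled)

    xics = extract_xics(run, cfg.xic_tol_ppm, cfg.min_scans, cfg.max_gap_scans)
    annotate_xics(xics, cfg.precision)
    orphans = attach_ms2(run, xics, cfg.precursor_tol_ppm)

    mono = [x for x in xics if x.isotope_class == MONOISOTOPIC]
    pairing = pair_xics(mono, db_unlabeled, db_labeled, cfg.pairing_tol_ppm)
    n_transferred = transfer_ms2_to_monoisotopic(xics, cfg.precision)

    pair_by_xic = {}
    for p in pairing.pairs:
        pair_by_xic[p.light] = p
        pair_by_xic[p.heavy] = p

    spectra_by_id = {s.scan_id: s for s in run.ms2}
    all_psms: list[PSM] = []
    for x in xics:
        scan_ids = list(dict.fromkeys(x.ms2_ids + x.transferred_ms2_ids))
        if not scan_ids:
            continue
        pair = pair_by_xic.get(x.id)
        for sid in scan_ids:
            spectrum = spectra_by_id[sid]
            if pair is not None:
                label = pairing.label_of[x.id]
                hits = search_spectrum(
                    spectrum, label, pair.nitrogen_count, db_pair, cfg.search_params
                )
                if hits:
                    all_psms.append(replace(hits[0], xic_id=x.id))
            elif x.isotope_class == MONOISOTOPIC:
                hit = search_unpaired(spectrum, db_pair, cfg.search_params)
                if hit is not None:
                    all_psms.append(replace(hit, xic_id=x.id))

    psms = best_psm_per_spectrum(all_psms)
    if psms:
        psms = estimate_qvalues(psms)
        accepted = fdr_filter(psms, cfg.fdr_threshold)
    else:
        accepted = []

    # Quantify every pair-linked PSM whose peptide passed the peptide-level
    # FDR, so one peptide can contribute measurements from several pairs
    # (charge states) even though acceptance is peptide-level.
    accepted_seqs = {p.sequence for p in accepted}
    quant_psms = [p for p in psms if not p.is_decoy and p.sequence in accepted_seqs]
    peptide_quants = quant.collate_peptides(quant_psms, pair_by_xic, cfg.orientation)
    pep2prot = peptide_to_protein_map(db_unlabeled)
    protein_quants = quant.rollup_proteins(
        peptide_quants, pep2prot, cfg.shared_peptides
    )

    counters = {
        "n_ms1": len(run.ms1),
        "n_ms2": len(run.ms2),
        "n_xics": len(xics),
        "n_monoisotopic": len(mono),
        "n_pairs": len(pairing.pairs),
        "n_multiply_coupled": len(pairing.multiply_coupled),
        "n_unpaired": len(pairing.unpaired),
        "n_orphan_ms2": len(orphans),
        "n_transferred_ms2": n_transferred,
        "n_psms": len(psms),
        "n_accepted": len(accepted),
        "n_quantified_peptides": len(peptide_quants),
        "n_quantified_proteins": len(protein_quants),
        "orientation": cfg.orientation,
    }
    return PipelineResult(
        xics=xics,
        pairing=pairing,
        psms=psms,
        accepted=accepted,
        peptide_quants=peptide_quants,
        protein_quants=protein_quants,
        counters=counters,
    )
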