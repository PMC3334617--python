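"""Scoring pipeline output against a simulator's ground-truth manifest.

Detected XICs are attributed to the emitted species that dominates them
(largest emitted area among truth species within tolerance and retention
overlap): two species closer than the instrument precision inevitably
merge into one chimeric XIC, and such an XIC is judged as its dominant
contributor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import PipelineResult
from .xic import MONOISOTOPIC, XIC, distinguishability_limit


def attribute_xics(
    xics: list[XIC],
    species_truth: pd.DataFrame,
    tol_ppm: float = 5.0,
    rt_slack: float = 0.05,
) -> dict[int, int]:
    """Map XIC id -> index of the dominant truth species (or nothing).

    A species is a candidate for an XIC when its theoretical m/z lies
    within ``tol_ppm`` and its elution centre within the XIC's retention
    span (plus slack); the candidate with the largest emitted area wins.
    """
    st = species_truth.reset_index(drop=True)
    order = np.argsort(st["mz"].to_numpy())
    mz_sorted = st["mz"].to_numpy()[order]
    out: dict[int, int] = {}
    for x in xics:
        tol = x.mz * tol_ppm * 1e-6
        lo = int(np.searchsorted(mz_sorted, x.mz - tol, "left"))
        hi = int(np.searchsorted(mz_sorted, x.mz + tol, "right"))
        best, best_area = None, 0.0
        for j in order[lo:hi]:
            row = st.iloc[j]
            if not (x.rt_start - rt_slack <= row["rt_center"] <= x.rt_end + rt_slack):
                continue
            if row["area"] > best_area:
                best, best_area = int(j), float(row["area"])
        if best is not None:
            out[x.id] = best
    return out


@dataclass(frozen=True)
class ClassificationMetrics:
    n_light_mono: int
    n_light_mono_correct: int
    n_plus_one: int
    n_plus_one_called_mono: int

    @property
    def light_mono_sensitivity(self) -> float:
        return self.n_light_mono_correct / self.n_light_mono

    @property
    def plus_one_false_mono_rate(self) -> float:
        return self.n_plus_one_called_mono / self.n_plus_one


def classification_metrics(
    xics: list[XIC],
    species_truth: pd.DataFrame,
    tol_ppm: float = 4.0,
) -> ClassificationMetrics:
    """Monoisotopic-classification quality against ground truth.

    Counts XICs whose dominant species is a light monoisotopic peak below
    the distinguishability limit for its charge, and XICs dominated by a
    first 13C satellite (either channel).
    """
    st = species_truth.reset_index(drop=True)
    attribution = attribute_xics(xics, st)
    # principal XIC per species: a trace occasionally splits at a dropout,
    # and the species is judged by its dominant (most intense) trace
    principal: dict[int, XIC] = {}
    for x in xics:
        j = attribution.get(x.id)
        if j is None:
            continue
        cur = principal.get(j)
        if cur is None or x.max_intensity > cur.max_intensity:
            principal[j] = x
    n_lm = n_lm_ok = n_p1 = n_p1_mono = 0
    for j, x in principal.items():
        row = st.iloc[j]
        is_light_mono = row["channel"] == "light" and bool(row["is_mono"])
        below = row["mz"] < distinguishability_limit(tol_ppm, int(row["charge"]))
        if is_light_mono and below:
            n_lm += 1
            n_lm_ok += x.isotope_class == MONOISOTOPIC
        if row["n_c13"] == 1 and row["n_unlabeled"] == 0:
            n_p1 += 1
            n_p1_mono += x.isotope_class == MONOISOTOPIC
    return ClassificationMetrics(n_lm, n_lm_ok, n_p1, n_p1_mono)


@dataclass(frozen=True)
class PairingMetrics:
    n_true_peptides: int
    n_pairs: int
    n_correct_pairs: int
    n_correct_nitrogen: int
    n_correct_labels: int

    @property
    def sensitivity(self) -> float:
        return self.n_correct_pairs / self.n_true_peptides

    @property
    def nitrogen_accuracy(self) -> float:
        return self.n_correct_nitrogen / self.n_pairs if self.n_pairs else 0.0

    @property
    def label_accuracy(self) -> float:
        return self.n_correct_labels / self.n_pairs if self.n_pairs else 0.0


def pairing_metrics(
    result: PipelineResult,
    peptide_truth: pd.DataFrame,
    species_truth: pd.DataFrame,
) -> PairingMetrics:
    """Pair recovery against ground truth.

    A pair is correct when its light and heavy members are dominated by
    the light and heavy monoisotopic species of the same peptide; its
    nitrogen count (and, through orientation, label assignment) is then
    checked against that peptide.
    """
    st = species_truth.reset_index(drop=True)
    attribution = attribute_xics(result.xics, st)
    truth_n = dict(zip(peptide_truth["peptide"], peptide_truth["nitrogen_count"]))
    xic_by_id = {x.id: x for x in result.xics}
    n_correct = n_nitrogen = n_labels = 0
    paired_peptides: set[str] = set()
    for p in result.pairing.pairs:
        jl = attribution.get(p.light)
        jh = attribution.get(p.heavy)
        if jl is None or jh is None:
            continue
        rl, rh = st.iloc[jl], st.iloc[jh]
        same_peptide = rl["peptide"] == rh["peptide"]
        monos = bool(rl["is_mono"]) and bool(rh["is_mono"])
        channels_ok = rl["channel"] == "light" and rh["channel"] == "heavy"
        if same_peptide and monos:
            n_correct += 1
            paired_peptides.add(str(rl["peptide"]))
            if channels_ok:
                n_labels += 1
            if p.nitrogen_count == truth_n.get(rl["peptide"]):
                n_nitrogen += 1
    return PairingMetrics(
        n_true_peptides=len(peptide_truth),
        n_pairs=len(result.pairing.pairs),
        n_correct_pairs=len(paired_peptides),
        n_correct_nitrogen=n_nitrogen,
        n_correct_labels=n_labels,
    )


@dataclass(frozen=True)
class RecoveryMetrics:
    n_proteins: int
    spearman_rho: float
    median_abs_error: float


def protein_ratio_recovery(
    result: PipelineResult, peptide_truth: pd.DataFrame
) -> RecoveryMetrics:
    """Recovered protein log2 ratios vs the simulator's configured truth."""
    truth = peptide_truth.groupby("protein")["true_log2_ratio"].first()
    est = result.protein_table.set_index("protein")["median_log2_ratio"]
    shared = truth.index.intersection(est.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 quantified proteins with known truth")
    err = (est.loc[shared] - truth.loc[shared]).abs()
    rho = stats.spearmanr(est.loc[shared], truth.loc[shared]).statistic
    return RecoveryMetrics(len(shared), float(rho), float(err.median()))
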