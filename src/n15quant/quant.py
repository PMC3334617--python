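"""Peptide/protein ratio tables and the consistency evaluation statistics.

Each accepted identification linked to an XIC pair contributes one log2
area ratio.  Measurements of one peptide (across charge states and
fractions) are collated to a median; protein ratios are medians of the
per-peptide medians.  Split-half consistency and label-swap replicate
correlation use Spearman rank correlation with average-rank ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .msms_search import PSM
from .pairing import XICPair


@dataclass(frozen=True)
class Measurement:
    sequence: str
    charge: int
    fraction: str
    log2_ratio: float


@dataclass
class PeptideQuant:
    sequence: str
    measurements: list[Measurement] = field(default_factory=list)

    @property
    def charges(self) -> tuple[int, ...]:
        return tuple(sorted({m.charge for m in self.measurements}))

    @property
    def median_log2_ratio(self) -> float:
        return float(np.median([m.log2_ratio for m in self.measurements]))

    @property
    def cv_percent(self) -> float:
        """CV of the linear-scale ratios (sample sd / mean * 100); NaN with
        fewer than two measurements."""
        if len(self.measurements) < 2:
            return float("nan")
        linear = 2.0 ** np.array([m.log2_ratio for m in self.measurements])
        return float(np.std(linear, ddof=1) / np.mean(linear) * 100.0)


@dataclass
class ProteinQuant:
    protein: str
    peptides: list[PeptideQuant]

    @property
    def n_distinct(self) -> int:
        return len({p.sequence for p in self.peptides})

    @property
    def median_log2_ratio(self) -> float:
        return float(np.median([p.median_log2_ratio for p in self.peptides]))

    @property
    def cv_percent(self) -> float:
        if self.n_distinct < 2:
            return float("nan")
        linear = 2.0 ** np.array([p.median_log2_ratio for p in self.peptides])
        return float(np.std(linear, ddof=1) / np.mean(linear) * 100.0)


NUMERATOR_LABELED = "labeled"
NUMERATOR_UNLABELED = "unlabeled"


def pair_ratio(pair: XICPair, orientation: str = NUMERATOR_LABELED) -> float | None:
    """log2 area ratio of a pair in the configured orientation; pairs with
    a non-positive area are dropped with a warning."""
    if pair.light_area <= 0 or pair.heavy_area <= 0:
        warnings.warn(
            f"pair ({pair.light}, {pair.heavy}) has a non-positive area; dropped"
        )
        return None
    if orientation == NUMERATOR_LABELED:
        return float(np.log2(pair.heavy_area / pair.light_area))
    return float(np.log2(pair.light_area / pair.heavy_area))


def collate_peptides(
    psms: list[PSM],
    pair_by_xic: dict[int, XICPair],
    orientation: str = NUMERATOR_LABELED,
    fraction: str = "1",
) -> list[PeptideQuant]:
    """Group the ratio measurements of FDR-accepted PSMs by sequence.

    A PSM contributes one measurement when its XIC belongs to a pair; the
    same (sequence, pair) is counted once even if both members carry
    identifying spectra.
    """
    by_seq: dict[str, dict[tuple, Measurement]] = {}
    for p in psms:
        if p.xic_id is None:
            continue
        pair = pair_by_xic.get(p.xic_id)
        if pair is None:
            continue
        ratio = pair_ratio(pair, orientation)
        if ratio is None:
            continue
        key = (pair.light, pair.heavy, fraction)
        by_seq.setdefault(p.sequence, {})[key] = Measurement(
            sequence=p.sequence, charge=pair.charge, fraction=fraction,
            log2_ratio=ratio,
        )
    return [
        PeptideQuant(sequence=s, measurements=list(meas.values()))
        for s, meas in sorted(by_seq.items())
    ]


def merge_peptide_quants(groups: list[list[PeptideQuant]]) -> list[PeptideQuant]:
    """Pool measurements of the same sequence across fractions/runs."""
    by_seq: dict[str, list[Measurement]] = {}
    for group in groups:
        for pq in group:
            by_seq.setdefault(pq.sequence, []).extend(pq.measurements)
    return [PeptideQuant(s, m) for s, m in sorted(by_seq.items())]


def rollup_proteins(
    peptide_quants: list[PeptideQuant],
    peptide_to_protein: dict[str, frozenset[str]],
    shared_peptides: str = "exclude",
) -> list[ProteinQuant]:
    """Aggregate peptide medians to proteins (median of medians).

    Peptides mapping to more than one protein are excluded by default
    (``shared_peptides="count_in_all"`` assigns them to every parent).
    """
    by_protein: dict[str, list[PeptideQuant]] = {}
    for pq in peptide_quants:
        proteins = peptide_to_protein.get(pq.sequence)
        if not proteins:
            continue
        if len(proteins) > 1 and shared_peptides == "exclude":
            continue
        for prot in proteins:
            by_protein.setdefault(prot, []).append(pq)
    return [ProteinQuant(p, peps) for p, peps in sorted(by_protein.items())]


def peptide_table(peptide_quants: list[PeptideQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence": [p.sequence for p in peptide_quants],
            "charges": [";".join(map(str, p.charges)) for p in peptide_quants],
            "median_log2_ratio": [p.median_log2_ratio for p in peptide_quants],
            "n_measurements": [len(p.measurements) for p in peptide_quants],
            "cv_percent": [p.cv_percent for p in peptide_quants],
        }
    )


def protein_table(protein_quants: list[ProteinQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [p.protein for p in protein_quants],
            "n_distinct_peptides": [p.n_distinct for p in protein_quants],
            "median_log2_ratio": [p.median_log2_ratio for p in protein_quants],
            "cv_percent": [p.cv_percent for p in protein_quants],
        }
    )


def split_half_consistency(
    protein_quants: list[ProteinQuant], seed: int
) -> tuple[float, pd.DataFrame]:
    """Seeded random split of each protein's peptides into two groups;
    Spearman correlation of the two group-median log2 ratios across
    proteins with >= 2 distinct peptides."""
    rng = np.random.default_rng(seed)
    rows = []
    for pq in protein_quants:
        if pq.n_distinct < 2:
            continue
        peptides = sorted(pq.peptides, key=lambda p: p.sequence)
        perm = rng.permutation(len(peptides))
        half = len(peptides) // 2
        g1 = [peptides[i].median_log2_ratio for i in perm[:half]]
        g2 = [peptides[i].median_log2_ratio for i in perm[half:]]
        rows.append((pq.protein, float(np.median(g1)), float(np.median(g2))))
    if len(rows) < 3:
        raise ValueError("need >= 3 proteins with >= 2 distinct peptides")
    df = pd.DataFrame(rows, columns=["protein", "group1_median", "group2_median"])
    rho = stats.spearmanr(df["group1_median"], df["group2_median"]).statistic
    return float(rho), df


def replicate_correlation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    level: str = "protein",
    swap: bool = False,
) -> float:
    """Spearman correlation of median log2 ratios across the keys shared
    by two result tables; ``swap`` negates table_b's ratios first (label
    swap reverses true ratios in log space)."""
    key = "protein" if level == "protein" else "sequence"
    a = table_a.set_index(key)["median_log2_ratio"]
    b = table_b.set_index(key)["median_log2_ratio"]
    if swap:
        b = -b
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared keys for a rank correlation")
    return float(stats.spearmanr(a.loc[shared], b.loc[shared]).statistic)
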