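"""Label-aware, nitrogen-constrained fragmentation-spectrum search.

Candidates come from the label-appropriate peptide database at the
precursor neutral mass; when an XIC pair supplies a nitrogen count,
same-mass candidates with a different count are filtered before scoring.
PSMs are scored ``(M/L) * sum(log2(I_m))`` over matched b/y ladder peaks
and filtered by q-values estimated from the concatenated reverse decoys.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import DELTA_15N, PROTON_MASS, RESIDUE_MASS, RESIDUE_NITROGENS, WATER_MASS
from .peptide_db import DEFAULT_FIXED_MODS, LABELED, UNLABELED, PeptideDatabase
from .spectra_io import MS2Spectrum


@dataclass(frozen=True)
class SearchParams:
    precursor_tol_ppm: float = 10.0
    fragment_tol: float = 0.5  # Da, ion-trap MS2
    fdr_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class PSM:
    ms2_id: int
    sequence: str
    label_state: str
    charge: int
    score: float
    nitrogen_count: int
    is_decoy: bool
    missed_cleavages: int = 0
    q_value: float = 1.0
    constraint_used: bool = False
    ambiguous_label: bool = False
    xic_id: int | None = None


def theoretical_fragments(
    sequence: str,
    label_state: str = UNLABELED,
    precursor_charge: int = 2,
    fixed_mods: dict[str, float] | None = None,
) -> np.ndarray:
    """Singly-protonated b/y ladders (plus doubly-charged ladders for
    precursors of charge >= 3), sorted ascending.

    For labeled peptides every fragment is shifted by the nitrogen count of
    its own residues times the per-unit 15N shift.
    """
    if len(sequence) < 2:
        raise ValueError("need at least 2 residues to fragment")
    if precursor_charge < 1:
        raise ValueError("precursor charge must be >= 1")
    mods = DEFAULT_FIXED_MODS if fixed_mods is None else fixed_mods
    res = np.array([RESIDUE_MASS[aa] + mods.get(aa, 0.0) for aa in sequence])
    if label_state == LABELED:
        res = res + np.array([RESIDUE_NITROGENS[aa] for aa in sequence]) * DELTA_15N
    prefix = np.cumsum(res)  # prefix[i] = mass of residues [0..i]
    total = prefix[-1]
    b = prefix[:-1] + PROTON_MASS
    y = (total - prefix[:-1]) + WATER_MASS + PROTON_MASS
    frags = np.concatenate([b, y])
    if precursor_charge >= 3:
        frags = np.concatenate([frags, (frags + PROTON_MASS) / 2.0])
    return np.sort(frags)


def score_psm(
    spectrum: MS2Spectrum, fragments: np.ndarray, fragment_tol: float
) -> tuple[float, int, int]:
    """``(M/L) * sum(log2(I_m))`` intensity-weighted match score.

    M counts theoretical peaks with an observed peak within the tolerance
    (nearest observed peak, each observed peak used at most once); matched
    intensities below 2 contribute log2 = 0 but still count toward M.
    """
    if len(fragments) == 0:
        raise ValueError("empty theoretical spectrum")
    L = len(fragments)
    obs_mz = spectrum.mz
    obs_int = spectrum.intensity
    used = np.zeros(len(obs_mz), dtype=bool)
    M = 0
    logsum = 0.0
    for f in np.sort(fragments):
        lo = int(np.searchsorted(obs_mz, f - fragment_tol, side="left"))
        hi = int(np.searchsorted(obs_mz, f + fragment_tol, side="right"))
        best, best_d = -1, None
        for i in range(lo, hi):
            if used[i]:
                continue
            d = abs(obs_mz[i] - f)
            if best < 0 or d < best_d:
                best, best_d = i, d
        if best >= 0:
            used[best] = True
            M += 1
            if obs_int[best] >= 2:
                logsum += float(np.log2(obs_int[best]))
    return (M / L) * logsum, M, L


def _rank_key(psm: PSM) -> tuple:
    # exact score ties resolve to fewer missed cleavages, then
    # conservatively to the decoy (an ambiguous best match must show up as
    # estimated contamination, not as a free identification), then
    # lexicographically
    return (-psm.score, psm.missed_cleavages, not psm.is_decoy, psm.sequence)


def search_spectrum(
    spectrum: MS2Spectrum,
    label_state: str,
    nitrogen_constraint: int | None,
    db_pair: tuple[PeptideDatabase, PeptideDatabase],
    params: SearchParams,
) -> list[PSM]:
    """Ranked PSMs from the label-appropriate database.

    Unknown precursor charge tries 2 and 3 and keeps every scored
    candidate in one ranking.  With a nitrogen constraint, candidates with
    a different nitrogen count are removed before scoring.
    """
    db_unlabeled, db_labeled = db_pair
    db = db_labeled if label_state == LABELED else db_unlabeled
    charges = (
        (spectrum.precursor_charge,) if spectrum.precursor_charge else (2, 3)
    )
    psms: list[PSM] = []
    for z in charges:
        mass = (spectrum.precursor_mz - PROTON_MASS) * z
        if mass <= 0:
            continue
        candidates = db.query_mass(mass, params.precursor_tol_ppm)
        if nitrogen_constraint is not None:
            candidates = [
                e for e in candidates if e.nitrogen_count == nitrogen_constraint
            ]
        for e in candidates:
            frags = theoretical_fragments(
                e.sequence, label_state, z, db.digest_params.fixed_mods
            )
            score, _, _ = score_psm(spectrum, frags, params.fragment_tol)
            psms.append(
                PSM(
                    ms2_id=spectrum.scan_id,
                    sequence=e.sequence,
                    label_state=label_state,
                    charge=z,
                    score=score,
                    nitrogen_count=e.nitrogen_count,
                    is_decoy=e.is_decoy,
                    missed_cleavages=e.missed_cleavages,
                    constraint_used=nitrogen_constraint is not None,
                )
            )
    return sorted(psms, key=_rank_key)


def search_unpaired(
    spectrum: MS2Spectrum,
    db_pair: tuple[PeptideDatabase, PeptideDatabase],
    params: SearchParams,
) -> PSM | None:
    """Fallback for spectra on unpaired XICs: search both databases without
    the nitrogen constraint; the best score sets sequence and label.  An
    exact cross-database tie prefers unlabeled and is flagged ambiguous."""
    best_u = search_spectrum(spectrum, UNLABELED, None, db_pair, params)
    best_l = search_spectrum(spectrum, LABELED, None, db_pair, params)
    top_u = best_u[0] if best_u else None
    top_l = best_l[0] if best_l else None
    if top_u is None:
        return top_l
    if top_l is None:
        return top_u
    if top_l.score > top_u.score:
        return top_l
    if top_l.score == top_u.score:
        return replace(top_u, ambiguous_label=True)
    return top_u


def best_psm_per_spectrum(psms: list[PSM]) -> list[PSM]:
    by_scan: dict[int, PSM] = {}
    for p in psms:
        cur = by_scan.get(p.ms2_id)
        if cur is None or _rank_key(p) < _rank_key(cur):
            by_scan[p.ms2_id] = p
    return [by_scan[k] for k in sorted(by_scan)]


def estimate_qvalues(psms: list[PSM]) -> list[PSM]:
    """Concatenated-decoy q-values with the FDR estimator D/T.

    At each score threshold s, FDR(s) = (#decoys >= s) / (#targets >= s)
    (1 when no target clears s); a PSM's q-value is the minimum FDR over
    all thresholds at or below its score, hence monotone non-increasing in
    score.  Score ties place decoys first (conservative).
    """
    if not psms:
        raise ValueError("no PSMs: q-values undefined")
    order = sorted(range(len(psms)), key=lambda i: (-psms[i].score, not psms[i].is_decoy))
    n = len(order)
    n_t = 0
    n_d = 0
    fdr = np.empty(n)
    group_start = 0
    for rank, i in enumerate(order):
        if psms[i].is_decoy:
            n_d += 1
        else:
            n_t += 1
        last_of_group = (
            rank == n - 1 or psms[order[rank + 1]].score != psms[i].score
        )
        if last_of_group:
            # tied scores share one threshold: the counts at the end of
            # the tie group apply to every member
            fdr[group_start : rank + 1] = (n_d / n_t) if n_t else 1.0
            group_start = rank + 1
    q = np.minimum.accumulate(np.minimum(fdr, 1.0)[::-1])[::-1]
    out = list(psms)
    for rank, i in enumerate(order):
        out[i] = replace(psms[i], q_value=float(q[rank]))
    return out


def fdr_filter(psms: list[PSM], threshold: float) -> list[PSM]:
    """Peptide-level acceptance: keep the best PSM per (sequence, label),
    then return target PSMs with q-value <= threshold.  Decoys are never
    reported."""
    best: dict[tuple[str, str], PSM] = {}
    for p in psms:
        key = (p.sequence, p.label_state)
        cur = best.get(key)
        if cur is None or _rank_key(p) < _rank_key(cur):
            best[key] = p
    return [
        p
        for key, p in sorted(best.items())
        if not p.is_decoy and p.q_value <= threshold
    ]
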