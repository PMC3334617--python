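"""Light/heavy XIC pairing through nitrogen-count database lookup.

For each monoisotopic XIC (visited in order of decreasing intensity) the
neutral mass implied by (m/z, z) is searched in both peptide databases; each
returned nitrogen count N nominates one partner position at
``mz +/- delta_15N * N / z`` (up for an unlabeled-database hit, down for a
labeled-database hit).  Exactly one candidate XIC across all nominations
makes an unambiguous pair; two or more mark the XIC multiply coupled.
Passes repeat until no further pair forms, so an XIC that was ambiguous can
pair later once a competing candidate has been consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DELTA_15N, PROTON_MASS
from .peptide_db import LABELED, UNLABELED, PeptideDatabase
from .xic import XIC, XICIndex


@dataclass(frozen=True)
class XICPair:
    """An unambiguously matched light/heavy couple."""

    light: int  # XIC id
    heavy: int
    charge: int
    nitrogen_count: int
    shift_observed: float  # Th, heavy.mz - light.mz
    shift_theoretical: float  # Th, delta_15N * N / z
    ppm_error: float
    light_mz: float
    heavy_mz: float
    light_area: float
    heavy_area: float
    rt_start: float
    rt_end: float


@dataclass
class PairingResult:
    pairs: list[XICPair] = field(default_factory=list)
    multiply_coupled: set[int] = field(default_factory=set)
    unpaired: set[int] = field(default_factory=set)
    label_of: dict[int, str] = field(default_factory=dict)

    def pair_of(self, xic_id: int) -> XICPair | None:
        for p in self.pairs:
            if xic_id in (p.light, p.heavy):
                return p
        return None


def neutral_mass(mz: float, z: int) -> float:
    return (mz - PROTON_MASS) * z


def _candidate_partners(
    x: XIC,
    index: XICIndex,
    consumed: set[int],
    db_unlabeled: PeptideDatabase,
    db_labeled: PeptideDatabase,
    tol_ppm: float,
) -> list[tuple[XIC, int, int]]:
    """Distinct candidate XICs as (partner, N, direction) nominations.

    direction +1 means the partner sits above (x would be the light
    member); -1 below.  Candidate multiplicity is counted over distinct
    XICs, not database entries.
    """
    z = x.charge
    mass = neutral_mass(x.mz, z)
    nominations: dict[int, tuple[XIC, int, int]] = {}
    for db, direction in ((db_unlabeled, +1), (db_labeled, -1)):
        ns = sorted({e.nitrogen_count for e in db.query_mass(mass, tol_ppm)})
        for n in ns:
            target = x.mz + direction * DELTA_15N * n / z
            for c in index.coeluting(x, target, tol_ppm):
                if c.id in consumed or c.id == x.id or c.charge != z:
                    continue
                if c.id not in nominations:
                    nominations[c.id] = (c, n, direction)
    return [nominations[i] for i in sorted(nominations)]


def pair_xics(
    monoisotopic_xics: list[XIC],
    db_unlabeled: PeptideDatabase,
    db_labeled: PeptideDatabase,
    tol_ppm: float = 3.0,
) -> PairingResult:
    """Pair monoisotopic XICs into light/heavy couples (see module doc)."""
    pool = [x for x in monoisotopic_xics if x.charge]
    order = sorted(pool, key=lambda x: (-x.max_intensity, x.id))
    index = XICIndex(pool)
    consumed: set[int] = set()
    result = PairingResult()
    flagged_ambiguous: set[int] = set()

    made_pair = True
    while made_pair:
        made_pair = False
        flagged_ambiguous = set()
        for x in order:
            if x.id in consumed:
                continue
            cands = _candidate_partners(
                x, index, consumed, db_unlabeled, db_labeled, tol_ppm
            )
            if len(cands) == 1:
                partner, n, direction = cands[0]
                light, heavy = (x, partner) if direction > 0 else (partner, x)
                shift_obs = heavy.mz - light.mz
                shift_theo = DELTA_15N * n / x.charge
                result.pairs.append(
                    XICPair(
                        light=light.id,
                        heavy=heavy.id,
                        charge=x.charge,
                        nitrogen_count=n,
                        shift_observed=shift_obs,
                        shift_theoretical=shift_theo,
                        ppm_error=(shift_obs - shift_theo) / light.mz * 1e6,
                        light_mz=light.mz,
                        heavy_mz=heavy.mz,
                        light_area=light.area,
                        heavy_area=heavy.area,
                        rt_start=min(light.rt_start, heavy.rt_start),
                        rt_end=max(light.rt_end, heavy.rt_end),
                    )
                )
                result.label_of[light.id] = UNLABELED
                result.label_of[heavy.id] = LABELED
                consumed.update((light.id, heavy.id))
                made_pair = True
            elif len(cands) >= 2:
                flagged_ambiguous.add(x.id)

    for x in pool:
        if x.id in consumed:
            continue
        if x.id in flagged_ambiguous:
            result.multiply_coupled.add(x.id)
        else:
            result.unpaired.add(x.id)
        result.label_of[x.id] = "unknown"
    return result


def pair_precision_stats(
    pairs: list[XICPair], bins: int = 40
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """Mean, sample sd, and histogram of per-pair ppm errors between the
    observed and theoretical 15N shifts."""
    if not pairs:
        raise ValueError("no pairs: precision statistics undefined")
    errs = np.array([p.ppm_error for p in pairs])
    sd = float(np.std(errs, ddof=1)) if len(errs) > 1 else 0.0
    hist = np.histogram(errs, bins=bins)
    return float(np.mean(errs)), sd, hist
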