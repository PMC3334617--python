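"""XIC detection, charge assignment, and isotope-status classification.

The classifier exploits the 0.0063199444 Da difference between the per-unit
13C and 15N spacings: below ``distinguishability_limit(p, z)`` an instrument
of precision ``p`` ppm can tell whether the neighbour one unit below an XIC
sits at the carbon or at the nitrogen spacing, which is what separates true
monoisotopic peaks from the satellites of incompletely labeled peptides.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DELTA_13C, DELTA_15N, D_SHIFT
from .spectra_io import Run

MONOISOTOPIC = "monoisotopic"
ISOTOPE_PEAK = "isotope_peak"
FIFTEEN_N_OR_UNDETERMINED = "fifteenN_or_undetermined"


@dataclass
class XIC:
    """A charge-assigned chromatographic trace of one isotopic species."""

    id: int
    mz: float  # intensity-weighted mean over member peaks
    rts: np.ndarray  # minutes, strictly increasing
    intensities: np.ndarray
    charge: int | None = None
    isotope_class: str = FIFTEEN_N_OR_UNDETERMINED
    ms2_ids: list[int] = field(default_factory=list)
    transferred_ms2_ids: list[int] = field(default_factory=list)

    @property
    def rt_start(self) -> float:
        return float(self.rts[0])

    @property
    def rt_end(self) -> float:
        return float(self.rts[-1])

    @property
    def rt_apex(self) -> float:
        return float(self.rts[int(np.argmax(self.intensities))])

    @property
    def max_intensity(self) -> float:
        return float(self.intensities.max())

    @property
    def area(self) -> float:
        return xic_area(self)

    @property
    def n_scans(self) -> int:
        return len(self.rts)


@dataclass(frozen=True)
class PrecisionModel:
    """Matching tolerance and the charge states examined for isotope shifts."""

    tol_ppm: float = 4.0
    charge_range: tuple[int, ...] = (1, 2, 3, 4)
    #: A negative-13C-shift neighbour is only believed when its apex
    #: intensity is at least this fraction of the query's.  A genuine +1
    #: satellite is smaller than its parent whenever the peptide has fewer
    #: than ~93 carbons (natural 13C abundance 0.0107), i.e. everywhere in
    #: tryptic bottom-up m/z ranges, so an intense XIC cannot be the
    #: satellite of a faint one; the gate rejects chance interferences.
    parent_intensity_ratio: float = 0.5
    #: A 13C neighbour used for *charge assignment* must reach this
    #: fraction of the query's apex intensity.  The +1 satellite of a
    #: tryptic peptide carries >~25% of the parent (n_C x 0.0107 for
    #: n_C >= 25), so a genuine spacing partner is never fainter than a
    #: tenth of the query; chance co-elutions usually are.
    satellite_intensity_ratio: float = 0.1

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if not self.charge_range or min(self.charge_range) < 1:
            raise ValueError("charge_range must be non-empty positive integers")


def distinguishability_limit(p_ppm: float, z: int = 1) -> int:
    """Maximum m/z (integer-truncated) at which a one-unit 15N shift can be
    told apart from a one-unit 13C shift at precision ``p_ppm``."""
    if p_ppm <= 0:
        raise ValueError("precision must be positive")
    if z < 1:
        raise ValueError("charge must be >= 1")
    return math.floor((D_SHIFT / p_ppm) * 1e6 / z)


def xic_area(x: XIC) -> float:
    """Trapezoidal integral of intensity over retention time (units*min)."""
    if len(x.rts) < 2:
        return 0.0
    return float(np.trapezoid(x.intensities, x.rts))


# ---------------------------------------------------------------------------
# Extraction

def extract_xics(
    run: Run,
    tol_ppm: float = 4.0,
    min_scans: int = 3,
    max_gap_scans: int = 1,
) -> list[XIC]:
    """Greedy seeded XIC extraction over the MS1 scans of a run.

    Repeatedly seeds from the most intense unclaimed peak (ties broken by
    lower m/z, then earlier scan), extends across adjacent scans collecting
    the nearest unclaimed peak within ``tol_ppm`` of the running
    intensity-weighted mean m/z, tolerates up to ``max_gap_scans``
    consecutive scans without a match, and claims all member peaks.  XICs
    spanning fewer than ``min_scans`` member scans are discarded but their
    peaks stay claimed, keeping the peak partition disjoint.
    """
    n_scans = len(run.ms1)
    if n_scans < min_scans:
        return []
    scan_mz = [s.mz for s in run.ms1]
    scan_int = [s.intensity for s in run.ms1]
    scan_rt = np.array([s.retention_time for s in run.ms1])
    claimed = [np.zeros(len(m), dtype=bool) for m in scan_mz]

    seeds = [
        (-scan_int[s][i], scan_mz[s][i], s, i)
        for s in range(n_scans)
        for i in range(len(scan_mz[s]))
    ]
    seeds.sort()

    def nearest_unclaimed(s: int, target: float) -> int | None:
        mzs = scan_mz[s]
        if len(mzs) == 0:
            return None
        tol = target * tol_ppm * 1e-6
        lo = int(np.searchsorted(mzs, target - tol, side="left"))
        hi = int(np.searchsorted(mzs, target + tol, side="right"))
        best, best_d = None, None
        for i in range(lo, hi):
            if claimed[s][i]:
                continue
            d = abs(mzs[i] - target)
            if best is None or d < best_d:
                best, best_d = i, d
        return best

    xics: list[XIC] = []
    next_id = 0
    for negint, seed_mz, seed_scan, seed_idx in seeds:
        if claimed[seed_scan][seed_idx]:
            continue
        members: list[tuple[int, int]] = [(seed_scan, seed_idx)]
        wsum = scan_int[seed_scan][seed_idx]
        mzsum = seed_mz * wsum

        for direction in (1, -1):
            gap = 0
            s = seed_scan + direction
            while 0 <= s < n_scans and gap <= max_gap_scans:
                i = nearest_unclaimed(s, mzsum / wsum)
                if i is None:
                    gap += 1
                else:
                    gap = 0
                    members.append((s, i))
                    w = scan_int[s][i]
                    wsum += w
                    mzsum += scan_mz[s][i] * w
                s += direction

        for s, i in members:
            claimed[s][i] = True
        if len(members) < min_scans:
            continue
        members.sort()
        rts = scan_rt[[s for s, _ in members]]
        ints = np.array([scan_int[s][i] for s, i in members])
        xics.append(XIC(id=next_id, mz=mzsum / wsum, rts=rts, intensities=ints))
        next_id += 1
    return xics


# ---------------------------------------------------------------------------
# Neighbour index

class XICIndex:
    """m/z-sorted index over XICs for tolerance + co-elution queries."""

    def __init__(self, xics: list[XIC]):
        self.xics = sorted(xics, key=lambda x: x.mz)
        self._mzs = [x.mz for x in self.xics]

    def query(self, target_mz: float, tol_ppm: float) -> list[XIC]:
        tol = target_mz * tol_ppm * 1e-6
        lo = bisect.bisect_left(self._mzs, target_mz - tol)
        hi = bisect.bisect_right(self._mzs, target_mz + tol)
        return self.xics[lo:hi]

    def coeluting(self, x: XIC, target_mz: float, tol_ppm: float,
                  mode: str = "apex_in_span") -> list[XIC]:
        """Neighbours near ``target_mz`` that co-elute with ``x``.

        ``apex_in_span``: the candidate's RT apex falls inside x's RT span
        (the pairing-rule convention).  ``overlap``: the RT spans intersect.
        """
        out = []
        for c in self.query(target_mz, tol_ppm):
            if c.id == x.id:
                continue
            if mode == "apex_in_span":
                ok = x.rt_start <= c.rt_apex <= x.rt_end
            else:
                ok = c.rt_start <= x.rt_end and x.rt_start <= c.rt_end
            if ok:
                out.append(c)
        return out


# ---------------------------------------------------------------------------
# Charge and isotope classification

def assign_charge(x: XIC, index: XICIndex, precision: PrecisionModel) -> int | None:
    """Charge from 13C spacing: the largest z in the charge range with a
    co-eluting neighbour at ``mz + delta_13C / z``.

    Larger z wins outright because isotope spacings alias downward, never
    upward: every true charge-z envelope also shows a peak at the charge
    z/2 (and z/4, ...) spacing -- the second (fourth, ...) 13C satellite
    lands there exactly -- so a smaller-z match is expected for a high-z
    species, while a true low-z species has no peak at any tighter
    spacing.  Among several neighbours at the winning z the smallest ppm
    error is taken.
    """
    floor = precision.satellite_intensity_ratio * x.max_intensity
    for z in sorted(precision.charge_range, reverse=True):
        target = x.mz + DELTA_13C / z
        for c in index.coeluting(x, target, precision.tol_ppm, mode="overlap"):
            if c.max_intensity >= floor:
                return z
    return None


def _has_c13_neighbor(
    x: XIC, index: XICIndex, precision: PrecisionModel, z: int, sign: int
) -> bool:
    """Is there a co-eluting neighbour at ``sign * delta_13C / z``?

    Above the distinguishability limit the 13C and 15N spacings cannot be
    told apart, so a neighbour at either spacing conservatively counts as a
    13C neighbour.
    """
    min_intensity = (
        precision.parent_intensity_ratio * x.max_intensity if sign < 0 else 0.0
    )
    target = x.mz + sign * DELTA_13C / z
    for c in index.coeluting(x, target, precision.tol_ppm):
        if c.max_intensity >= min_intensity:
            return True
    if x.mz >= distinguishability_limit(precision.tol_ppm, z):
        target_n = x.mz + sign * DELTA_15N / z
        for c in index.coeluting(x, target_n, precision.tol_ppm):
            if c.max_intensity >= min_intensity:
                return True
    return False


def classify_isotope_status(
    x: XIC, index: XICIndex, precision: PrecisionModel
) -> str:
    """Monoisotopic / isotope-peak / 15N-or-undetermined classification.

    Tested charges are the assigned charge when known, else the whole
    charge range.  A negative-13C neighbour at any tested z demotes the XIC
    to an isotope peak; otherwise a positive-13C neighbour at some z makes
    it monoisotopic; with neither it is 15N-or-undetermined.
    """
    zs = (x.charge,) if x.charge else precision.charge_range
    positive_found = False
    for z in zs:
        if _has_c13_neighbor(x, index, precision, z, -1):
            return ISOTOPE_PEAK
        if not positive_found and _has_c13_neighbor(x, index, precision, z, +1):
            positive_found = True
    return MONOISOTOPIC if positive_found else FIFTEEN_N_OR_UNDETERMINED


def annotate_xics(xics: list[XIC], precision: PrecisionModel) -> list[XIC]:
    """Assign charges then isotope classes, in place."""
    index = XICIndex(xics)
    for x in xics:
        x.charge = assign_charge(x, index, precision)
    for x in xics:
        x.isotope_class = classify_isotope_status(x, index, precision)
    return xics


# ---------------------------------------------------------------------------
# MS2 association

def attach_ms2(run: Run, xics: list[XIC], precursor_tol_ppm: float = 10.0) -> list[int]:
    """Attach each MS2 to the XIC matching its precursor m/z within
    tolerance whose RT span contains the MS2 time; nearest m/z wins.
    Returns the scan ids of unassigned (orphan) MS2 spectra."""
    index = XICIndex(xics)
    orphans: list[int] = []
    for s in run.ms2:
        best: XIC | None = None
        best_d = None
        for c in index.query(s.precursor_mz, precursor_tol_ppm):
            if not (c.rt_start <= s.retention_time <= c.rt_end):
                continue
            d = abs(c.mz - s.precursor_mz)
            if best is None or d < best_d:
                best, best_d = c, d
        if best is None:
            orphans.append(s.scan_id)
        else:
            best.ms2_ids.append(s.scan_id)
    return orphans


def transfer_ms2_to_monoisotopic(xics: list[XIC], precision: PrecisionModel) -> int:
    """Give MS2 scans on 15N/undetermined or isotope-peak XICs a secondary
    attachment to the nearest co-eluting monoisotopic XIC at a positive
    ``k * delta_15N / z`` shift (k >= 1); the original stays.  Returns the
    number of transferred spectra."""
    index = XICIndex(xics)
    n_transferred = 0
    for x in xics:
        if x.isotope_class == MONOISOTOPIC or not x.ms2_ids:
            continue
        zs = (x.charge,) if x.charge else precision.charge_range
        best: XIC | None = None
        best_key = None
        for z in zs:
            for k in range(1, 6):
                target = x.mz + k * DELTA_15N / z
                for c in index.coeluting(x, target, precision.tol_ppm):
                    if c.isotope_class != MONOISOTOPIC:
                        continue
                    key = (abs(c.rt_apex - x.rt_apex), abs(c.mz - target))
                    if best is None or key < best_key:
                        best, best_key = c, key
        if best is not None:
            best.transferred_ms2_ids.extend(x.ms2_ids)
            n_transferred += len(x.ms2_ids)
    return n_transferred
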