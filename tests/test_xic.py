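import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from n15quant.constants import DELTA_13C, DELTA_15N
from n15quant.spectra_io import MS1Spectrum, MS2Spectrum, Run
from n15quant.xic import (
    FIFTEEN_N_OR_UNDETERMINED,
    ISOTOPE_PEAK,
    MONOISOTOPIC,
    XIC,
    PrecisionModel,
    XICIndex,
    assign_charge,
    attach_ms2,
    classify_isotope_status,
    distinguishability_limit,
    extract_xics,
    transfer_ms2_to_monoisotopic,
    xic_area,
)


def make_run(traces, n_scans=10, interval=0.1):
    """Build an MS1-only run from (mz, intensity, scan_indices) traces."""
    scans = []
    for s in range(n_scans):
        mzs, ints = [], []
        for mz, intensity, idx in traces:
            if s in idx:
                mzs.append(mz)
                ints.append(intensity)
        scans.append(
            MS1Spectrum(s + 1, s * interval, np.array(mzs), np.array(ints))
        )
    return Run(ms1=scans)


def make_xic(id, mz, apex_intensity, rt_center=1.0, width=0.3, n=7):
    rts = np.linspace(rt_center - width, rt_center + width, n)
    shape = np.exp(-0.5 * ((rts - rt_center) / (width / 2)) ** 2)
    return XIC(id=id, mz=mz, rts=rts, intensities=apex_intensity * shape)


class TestArea:
    @pytest.mark.parametrize(
        "intensities,rts,expected",
        [
            ([0, 2, 0], [0, 1, 2], 2.0),  # triangle
            ([5.0], [1.0], 0.0),  # single point
            ([1, 1, 1], [0, 1, 2], 2.0),  # rectangle
        ],
    )
    def test_trapezoidal_area(self, intensities, rts, expected):
        x = XIC(0, 500.0, np.array(rts, float), np.array(intensities, float))
        assert xic_area(x) == pytest.approx(expected)


class TestDistinguishabilityLimit:
    def test_one_ppm_limits(self):
        assert distinguishability_limit(1.0, 1) == 6319
        assert distinguishability_limit(1.0, 4) == 1579

    def test_two_ppm_limit(self):
        assert distinguishability_limit(2.0, 1) == 3159

    def test_invalid_precision_rejected(self):
        with pytest.raises(ValueError):
            distinguishability_limit(0.0, 1)
        with pytest.raises(ValueError):
            distinguishability_limit(-1.0, 2)

    @given(
        st.floats(min_value=0.1, max_value=10.0),
        st.integers(min_value=1, max_value=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_charge_scaling(self, p, z):
        assert distinguishability_limit(p, z) >= distinguishability_limit(p * 1.5, z)
        assert distinguishability_limit(p, z) >= distinguishability_limit(p, z + 1)
        base = distinguishability_limit(p, 1)
        assert abs(distinguishability_limit(p, z) - base // z) <= 1


class TestExtraction:
    def test_single_trace_single_xic(self):
        run = make_run([(500.0, 100.0, set(range(1, 9)))])
        xics = extract_xics(run, 4.0, 3, 1)
        assert len(xics) == 1
        assert xics[0].n_scans == 8
        assert xics[0].mz == pytest.approx(500.0)

    def test_species_fifty_ppm_apart_stay_separate(self):
        run = make_run(
            [(500.0, 100.0, set(range(10))), (500.025, 80.0, set(range(10)))]
        )
        xics = extract_xics(run, 4.0, 3, 1)
        assert len(xics) == 2
        assert {round(x.mz, 3) for x in xics} == {500.0, 500.025}
        assert sum(x.n_scans for x in xics) == 20  # disjoint peak claims

    def test_gap_tolerance(self):
        idx = {0, 1, 2, 3, 5, 6, 7, 8}  # one-scan dropout at scan 4
        run = make_run([(500.0, 100.0, idx)])
        assert len(extract_xics(run, 4.0, 3, max_gap_scans=1)) == 1
        assert len(extract_xics(run, 4.0, 3, max_gap_scans=0)) == 2

    def test_short_traces_are_dropped(self):
        run = make_run([(500.0, 100.0, {0, 1})])
        assert extract_xics(run, 4.0, 3, 1) == []

    def test_matches_exhaustive_grouping_oracle(self):
        # well-separated species: the oracle partition groups every peak
        # within tolerance of the species m/z
        rng = np.random.default_rng(2)
        species = [400.0, 400.8, 612.3, 900.0, 1203.7]
        traces = []
        for mz in species:
            for s in range(10):
                traces.append((mz * (1 + rng.normal(0, 1e-6)), rng.uniform(10, 100), {s}))
        run = make_run(traces)
        xics = extract_xics(run, 4.0, 3, 1)
        assert len(xics) == len(species)
        total_peaks = sum(len(s.mz) for s in run.ms1)
        assert sum(x.n_scans for x in xics) == total_peaks
        for x in xics:
            ref = min(species, key=lambda m: abs(m - x.mz))
            assert abs(x.mz - ref) / ref * 1e6 < 4.0


class TestChargeAssignment:
    def test_charge_two_envelope(self):
        mono = make_xic(0, 500.0, 1000.0)
        sat1 = make_xic(1, 500.0 + DELTA_13C / 2, 400.0)
        sat2 = make_xic(2, 500.0 + DELTA_13C, 100.0)
        index = XICIndex([mono, sat1, sat2])
        assert assign_charge(mono, index, PrecisionModel()) == 2

    def test_isolated_xic_has_unknown_charge(self):
        x = make_xic(0, 500.0, 1000.0)
        assert assign_charge(x, XICIndex([x]), PrecisionModel()) is None

    def test_downward_alias_resolves_to_larger_charge(self):
        # a z=2 envelope always shows its second satellite at the z=1
        # spacing; the tighter spacing must win
        mono = make_xic(0, 500.0, 1000.0)
        sat1 = make_xic(1, 500.0 + DELTA_13C / 2, 400.0)
        sat2 = make_xic(2, 500.0 + DELTA_13C, 120.0)
        index = XICIndex([mono, sat1, sat2])
        assert assign_charge(mono, index, PrecisionModel(charge_range=(1, 2))) == 2

    def test_faint_interference_cannot_set_the_charge(self):
        mono = make_xic(0, 500.0, 1000.0)
        ghost = make_xic(1, 500.0 + DELTA_13C / 4, 5.0)  # 0.5% of the apex
        sat1 = make_xic(2, 500.0 + DELTA_13C / 2, 400.0)
        index = XICIndex([mono, ghost, sat1])
        assert assign_charge(mono, index, PrecisionModel()) == 2


class TestClassification:
    def make_envelope(self, z=2, base_mz=500.0):
        mono = make_xic(0, base_mz, 1000.0)
        mono.charge = z
        sat1 = make_xic(1, base_mz + DELTA_13C / z, 400.0)
        sat1.charge = z
        sat2 = make_xic(2, base_mz + 2 * DELTA_13C / z, 90.0)
        sat2.charge = z
        return [mono, sat1, sat2]

    def test_envelope_classes(self):
        xics = self.make_envelope()
        index = XICIndex(xics)
        pm = PrecisionModel()
        assert classify_isotope_status(xics[0], index, pm) == MONOISOTOPIC
        assert classify_isotope_status(xics[1], index, pm) == ISOTOPE_PEAK

    def test_isolated_xic_is_undetermined(self):
        x = make_xic(0, 500.0, 100.0)
        x.charge = 2
        assert (
            classify_isotope_status(x, XICIndex([x]), PrecisionModel())
            == FIFTEEN_N_OR_UNDETERMINED
        )

    def test_nitrogen_spacing_neighbour_does_not_demote_below_limit(self):
        # incompletely labeled satellite one 15N below a fully labeled
        # monoisotopic peak: at m/z 500 and 4 ppm the 15N spacing is
        # distinguishable from the 13C spacing, so the fully labeled peak
        # keeps its positive-13C classification
        z = 2
        heavy = make_xic(0, 500.0, 1000.0)
        heavy.charge = z
        c13 = make_xic(1, 500.0 + DELTA_13C / z, 350.0)
        c13.charge = z
        deficit = make_xic(2, 500.0 - DELTA_15N / z, 300.0)
        deficit.charge = z
        index = XICIndex([heavy, c13, deficit])
        assert classify_isotope_status(heavy, index, PrecisionModel()) == MONOISOTOPIC

    def test_above_limit_either_spacing_demotes(self):
        z = 1
        pm = PrecisionModel(tol_ppm=4.0)
        base = float(distinguishability_limit(4.0, z) + 500)
        x = make_xic(0, base, 1000.0)
        x.charge = z
        below_n = make_xic(1, base - DELTA_15N / z, 2000.0)
        below_n.charge = z
        above = make_xic(2, base + DELTA_13C / z, 400.0)
        above.charge = z
        index = XICIndex([x, below_n, above])
        assert classify_isotope_status(x, index, pm) == ISOTOPE_PEAK


class TestMs2Attachment:
    def base_run_and_xics(self):
        xa = make_xic(0, 500.0, 1000.0, rt_center=1.0)
        xb = make_xic(1, 500.003, 800.0, rt_center=1.0)
        ms2 = [
            MS2Spectrum(100, 1.0, 500.0005, 2, np.array([200.0]), np.array([5.0])),
            MS2Spectrum(101, 1.0, 480.0, 2, np.array([200.0]), np.array([5.0])),
        ]
        run = Run(
            ms1=[MS1Spectrum(1, 0.5, np.array([500.0]), np.array([1.0])),
                 MS1Spectrum(2, 1.5, np.array([500.0]), np.array([1.0]))],
            ms2=ms2,
        )
        return run, [xa, xb]

    def test_nearest_mz_wins_and_orphans_recorded(self):
        run, xics = self.base_run_and_xics()
        orphans = attach_ms2(run, xics, precursor_tol_ppm=10.0)
        assert xics[0].ms2_ids == [100]
        assert xics[1].ms2_ids == []
        assert orphans == [101]

    def test_rt_span_containment_required(self):
        run, xics = self.base_run_and_xics()
        run.ms2[0].retention_time = 5.0
        orphans = attach_ms2(run, xics, precursor_tol_ppm=10.0)
        assert orphans == [100, 101]


class TestMs2Transfer:
    def test_satellite_spectrum_transfers_to_monoisotopic(self):
        z = 2
        mono = make_xic(0, 600.0, 1000.0)
        mono.charge = z
        mono.isotope_class = MONOISOTOPIC
        sat = make_xic(1, 600.0 - DELTA_15N / z, 200.0)
        sat.charge = z
        sat.isotope_class = FIFTEEN_N_OR_UNDETERMINED
        sat.ms2_ids = [42]
        n = transfer_ms2_to_monoisotopic([mono, sat], PrecisionModel())
        assert n == 1
        assert mono.transferred_ms2_ids == [42]
        assert sat.ms2_ids == [42]  # original attachment retained

    def test_no_candidate_no_transfer(self):
        sat = make_xic(0, 600.0, 200.0)
        sat.charge = 2
        sat.isotope_class = FIFTEEN_N_OR_UNDETERMINED
        sat.ms2_ids = [42]
        assert transfer_ms2_to_monoisotopic([sat], PrecisionModel()) == 0

    def test_closer_apex_wins_between_candidates(self):
        z = 2
        sat = make_xic(0, 600.0, 200.0, rt_center=1.0, width=0.5)
        sat.charge = z
        sat.isotope_class = FIFTEEN_N_OR_UNDETERMINED
        sat.ms2_ids = [42]
        near = make_xic(1, 600.0 + DELTA_15N / z, 900.0, rt_center=1.05)
        far = make_xic(2, 600.0 + 2 * DELTA_15N / z, 900.0, rt_center=1.4)
        for c in (near, far):
            c.charge = z
            c.isotope_class = MONOISOTOPIC
        transfer_ms2_to_monoisotopic([sat, near, far], PrecisionModel())
        assert near.transferred_ms2_ids == [42]
        assert far.transferred_ms2_ids == []
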