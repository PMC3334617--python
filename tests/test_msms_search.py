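from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from n15quant.constants import DELTA_15N, PROTON_MASS
from n15quant.msms_search import (
    PSM,
    SearchParams,
    best_psm_per_spectrum,
    estimate_qvalues,
    fdr_filter,
    score_psm,
    search_spectrum,
    search_unpaired,
    theoretical_fragments,
)
from n15quant.peptide_db import (
    LABELED,
    UNLABELED,
    DigestParams,
    PeptideDatabase,
    build_databases,
)
from n15quant.spectra_io import MS2Spectrum


def spectrum(mz, intensity, scan_id=1, precursor_mz=500.0, charge=2, rt=1.0):
    return MS2Spectrum(scan_id, rt, precursor_mz, charge,
                       np.asarray(mz, float), np.asarray(intensity, float))


class TestFragments:
    def test_gk_ladder(self):
        frags = theoretical_fragments("GK", UNLABELED, 2, fixed_mods={})
        assert frags == pytest.approx([58.0287, 147.1128], abs=1e-3)

    def test_label_shift_carries_fragment_nitrogens(self):
        u = theoretical_fragments("GK", UNLABELED, 2, fixed_mods={})
        l = theoretical_fragments("GK", LABELED, 2, fixed_mods={})
        # y1 is the K fragment: two nitrogens
        assert max(l) - max(u) == pytest.approx(2 * 0.99703489341, abs=1e-9)

    def test_doubly_charged_ladders_only_for_high_charge_precursors(self):
        assert len(theoretical_fragments("GK", UNLABELED, 2)) == 2
        assert len(theoretical_fragments("GK", UNLABELED, 3)) == 4

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            theoretical_fragments("G", UNLABELED, 2)


class TestScoring:
    def test_full_match_at_intensity_two(self):
        frags = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        s = spectrum(frags, [2.0] * 5)
        score, M, L = score_psm(s, frags, 0.5)
        assert (score, M, L) == (pytest.approx(5.0), 5, 5)

    def test_no_match_scores_zero(self):
        s = spectrum([1000.0], [50.0])
        score, M, L = score_psm(s, np.array([100.0, 200.0]), 0.5)
        assert (score, M) == (0.0, 0)

    def test_partial_match_hand_example(self):
        frags = np.array([100.0, 200.0, 300.0, 400.0])
        s = spectrum([100.1, 200.2], [4.0, 8.0])
        score, M, L = score_psm(s, frags, 0.5)
        assert M == 2 and L == 4
        assert score == pytest.approx((2 / 4) * (2 + 3))

    def test_sub_threshold_intensity_counts_as_match_with_zero_log(self):
        frags = np.array([100.0, 200.0])
        s = spectrum([100.0, 200.0], [1.5, 4.0])
        score, M, L = score_psm(s, frags, 0.5)
        assert M == 2
        assert score == pytest.approx((2 / 2) * 2.0)

    def test_each_observed_peak_used_once(self):
        frags = np.array([100.0, 100.3])
        s = spectrum([100.1], [4.0])
        _, M, _ = score_psm(s, frags, 0.5)
        assert M == 1

    def test_invariant_to_peak_order_and_unmatched_intensities(self):
        frags = np.array([100.0, 300.0])
        s1 = spectrum([100.0, 300.0, 800.0], [4.0, 16.0, 9.0])
        s2 = spectrum([300.0, 800.0, 100.0], [16.0, 999.0, 4.0])
        assert score_psm(s1, frags, 0.5)[0] == score_psm(s2, frags, 0.5)[0]


@pytest.fixture(scope="module")
def db_pair():
    return build_databases(
        [("p1", "LGFFETVDTDTQRVVDLESKMNWDERAAGHIK")],
        DigestParams(max_missed=0),
    )


def true_spectrum(seq, label, charge, db, scan_id=1):
    entry = next(e for e in db if e.sequence == seq)
    mass = entry.mass_labeled if label == LABELED else entry.mass_unlabeled
    frags = theoretical_fragments(seq, label, charge)
    return spectrum(
        frags, np.full(len(frags), 256.0), scan_id=scan_id,
        precursor_mz=mass / charge + PROTON_MASS, charge=charge,
    )


class TestSearch:
    def test_true_peptide_tops_the_ranking(self, db_pair):
        db_u, _ = db_pair
        s = true_spectrum("LGFFETVDTDTQR", UNLABELED, 2, db_u)
        hits = search_spectrum(s, UNLABELED, None, db_pair, SearchParams())
        assert hits[0].sequence == "LGFFETVDTDTQR"
        assert not hits[0].is_decoy

    def test_nitrogen_constraint_excludes_wrong_count_candidates(self, db_pair):
        db_u, db_l = db_pair
        base = next(e for e in db_u if e.sequence == "LGFFETVDTDTQR")
        # near-isobar in labeled space with one fewer nitrogen
        n2 = base.nitrogen_count - 1
        iso = replace(
            base, sequence="LGFFETVDTDTQK",
            mass_unlabeled=base.mass_labeled - n2 * DELTA_15N,
            mass_labeled=base.mass_labeled, nitrogen_count=n2,
        )
        dbs = (
            PeptideDatabase(list(db_u) + [iso], UNLABELED),
            PeptideDatabase(list(db_l) + [iso], LABELED),
        )
        s = true_spectrum("LGFFETVDTDTQR", LABELED, 2, db_u)
        params = SearchParams()
        with_constraint = search_spectrum(s, LABELED, base.nitrogen_count, dbs, params)
        without = search_spectrum(s, LABELED, None, dbs, params)
        assert {h.sequence for h in with_constraint} == {"LGFFETVDTDTQR"}
        assert "LGFFETVDTDTQK" in {h.sequence for h in without}

    def test_empty_candidate_window(self, db_pair):
        s = spectrum([100.0], [10.0], precursor_mz=4321.0, charge=2)
        assert search_spectrum(s, UNLABELED, None, db_pair, SearchParams()) == []

    def test_unknown_charge_tries_two_and_three(self, db_pair):
        db_u, _ = db_pair
        s = true_spectrum("LGFFETVDTDTQR", UNLABELED, 3, db_u)
        s.precursor_charge = None
        hits = search_spectrum(s, UNLABELED, None, db_pair, SearchParams())
        assert hits[0].sequence == "LGFFETVDTDTQR"
        assert hits[0].charge == 3

    def test_unpaired_fallback_infers_label(self, db_pair):
        db_u, _ = db_pair
        heavy = true_spectrum("MNWDER", LABELED, 2, db_u)
        light = true_spectrum("MNWDER", UNLABELED, 2, db_u, scan_id=2)
        assert search_unpaired(heavy, db_pair, SearchParams()).label_state == LABELED
        assert search_unpaired(light, db_pair, SearchParams()).label_state == UNLABELED


def make_psms(target_scores, decoy_scores):
    out = []
    for i, s in enumerate(target_scores):
        out.append(PSM(i, f"T{i}", UNLABELED, 2, float(s), 5, False))
    for j, s in enumerate(decoy_scores):
        out.append(PSM(1000 + j, f"D{j}", UNLABELED, 2, float(s), 5, True))
    return out


def qvalues_bruteforce(psms):
    """O(n^2) reference: q = min over thresholds <= own score of D/T."""
    out = []
    for p in psms:
        qs = []
        for t in psms:
            if t.score > p.score:
                continue
            d = sum(1 for x in psms if x.is_decoy and x.score >= t.score)
            n = sum(1 for x in psms if not x.is_decoy and x.score >= t.score)
            qs.append(d / n if n else 1.0)
        out.append(min(min(qs), 1.0) if qs else 1.0)
    return out


class TestQValues:
    def test_textbook_example(self):
        psms = estimate_qvalues(make_psms([10, 9, 8], [7]))
        assert [p.q_value for p in psms if not p.is_decoy] == [0.0, 0.0, 0.0]

    def test_target_below_decoy_pays_for_it(self):
        psms = estimate_qvalues(make_psms([10, 9, 8, 6], [7]))
        by_seq = {p.sequence: p.q_value for p in psms}
        assert by_seq["T3"] == pytest.approx(1 / 4)

    def test_no_decoys_all_zero(self):
        psms = estimate_qvalues(make_psms([3, 2, 1], []))
        assert all(p.q_value == 0.0 for p in psms)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_qvalues([])

    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=60),
        st.lists(st.floats(min_value=0, max_value=100), min_size=0, max_size=60),
    )
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_bruteforce_and_is_monotone(self, targets, decoys):
        psms = make_psms(targets, decoys)
        est = estimate_qvalues(psms)
        expected = qvalues_bruteforce(psms)
        for p, q in zip(est, expected):
            assert p.q_value == pytest.approx(q, abs=1e-12)
        ranked = sorted(est, key=lambda p: -p.score)
        for a, b in zip(ranked, ranked[1:]):
            if a.score > b.score:
                assert a.q_value <= b.q_value + 1e-12

    def test_complete_null_rarely_reaches_low_q(self):
        # with targets and decoys drawn from one distribution the running
        # decoy/target ratio hovers near 1, so almost no target can reach
        # q <= 0.05; the brute-force oracle on a subsample confirms the
        # estimator, and the full-size fraction stays near zero
        rng = np.random.default_rng(0)
        psms = make_psms(rng.normal(0, 1, 2000), rng.normal(0, 1, 2000))
        est = estimate_qvalues(psms)
        frac = np.mean([p.q_value <= 0.05 for p in est if not p.is_decoy])
        assert frac < 0.01
        sub = make_psms(rng.normal(0, 1, 100), rng.normal(0, 1, 100))
        assert [p.q_value for p in estimate_qvalues(sub)] == pytest.approx(
            qvalues_bruteforce(sub)
        )


class TestFdrFilter:
    def test_all_zero_q_pass_and_decoys_never_reported(self):
        psms = estimate_qvalues(make_psms([10, 9], [1]))
        accepted = fdr_filter(psms, 0.01)
        assert {p.sequence for p in accepted} == {"T0", "T1"}
        assert all(not p.is_decoy for p in accepted)

    def test_threshold_zero_requires_outscoring_every_decoy(self):
        psms = estimate_qvalues(make_psms([10, 9, 8, 6], [7]))
        accepted = fdr_filter(psms, 0.0)
        assert {p.sequence for p in accepted} == {"T0", "T1", "T2"}

    def test_peptide_level_collapse_keeps_best(self):
        a = PSM(1, "PEP", UNLABELED, 2, 10.0, 5, False, q_value=0.0)
        b = PSM(2, "PEP", UNLABELED, 3, 4.0, 5, False, q_value=0.5)
        accepted = fdr_filter([a, b], 0.01)
        assert len(accepted) == 1 and accepted[0].ms2_id == 1

    def test_best_psm_per_spectrum(self):
        a = PSM(1, "A", UNLABELED, 2, 10.0, 5, False)
        b = PSM(1, "B", UNLABELED, 2, 12.0, 5, False)
        c = PSM(2, "C", UNLABELED, 2, 1.0, 5, False)
        best = best_psm_per_spectrum([a, b, c])
        assert [(p.ms2_id, p.sequence) for p in best] == [(1, "B"), (2, "C")]
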