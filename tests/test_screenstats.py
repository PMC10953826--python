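"""Plate statistics: well summaries, Welch test, Z', criteria, full screen."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admscreen import (
    apply_selection_criteria,
    run_screen,
    summarize_well,
    welch_test,
    z_prime,
)
from admscreen.screenstats import WellSummary

floats_pct = st.floats(0.0, 100.0, allow_nan=False)


def objects_frame(n_live_ducts=0, n_live_clusters=0, n_dead_ducts=0,
                  n_dead_clusters=0):
    rows = ([("duct", True)] * n_live_ducts
            + [("cluster", True)] * n_live_clusters
            + [("duct", False)] * n_dead_ducts
            + [("cluster", False)] * n_dead_clusters)
    return pd.DataFrame(rows, columns=["organoid_class", "live"])


def make_summary(pct_live_clusters, viability=1.0, n=50,
                 pct_total_clusters=None):
    pct_total = (pct_live_clusters if pct_total_clusters is None
                 else pct_total_clusters)
    return WellSummary(None, n, int(round(n * viability)),
                       100.0 - pct_live_clusters, pct_live_clusters,
                       pct_total, viability, valid=True)


class TestSummarizeWell:
    def test_all_live_ducts(self):
        s = summarize_well(objects_frame(n_live_ducts=10))
        assert s.pct_live_ducts == 100.0
        assert s.viability_frac == 1.0

    def test_mixed_counting(self):
        s = summarize_well(objects_frame(n_live_ducts=20, n_live_clusters=20,
                                         n_dead_ducts=10))
        assert s.pct_live_clusters == 50.0
        assert s.viability_frac == pytest.approx(0.8)
        assert s.pct_total_clusters == pytest.approx(40.0)

    def test_percentages_sum_to_100_over_live(self):
        s = summarize_well(objects_frame(7, 13, 4, 6))
        assert s.pct_live_ducts + s.pct_live_clusters == pytest.approx(100.0)

    def test_empty_and_dead_wells_flagged(self):
        assert not summarize_well(objects_frame()).valid
        dead = summarize_well(objects_frame(n_dead_ducts=5))
        assert not dead.valid and math.isnan(dead.pct_live_clusters)


class TestWelch:
    def test_textbook_example(self):
        t, df, p = welch_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert t == pytest.approx(-1.0954, abs=1e-4)
        assert df == pytest.approx(6.0)
        assert p == pytest.approx(0.3153, abs=5e-4)

    def test_identical_samples(self):
        t, _, p = welch_test([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_convention(self):
        t, _, p = welch_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        t, _, p = welch_test([3.0, 3.0], [2.0, 2.0])
        assert t == math.inf and p == 0.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])

    @settings(derandomize=True, max_examples=30)
    @given(a=st.lists(floats_pct, min_size=2, max_size=8),
           b=st.lists(floats_pct, min_size=2, max_size=8))
    def test_antisymmetry(self, a, b):
        ta, _, pa = welch_test(a, b)
        tb, _, pb = welch_test(b, a)
        assert ta == pytest.approx(-tb, rel=1e-9, abs=1e-12)
        assert pa == pytest.approx(pb, rel=1e-9, abs=1e-12)


class TestZPrime:
    def test_hand_computed_example(self):
        # means 10/90 exactly, sds 4/3 exactly (n = 2 pairs)
        d_pos, d_neg = 4.0 / math.sqrt(2), 3.0 / math.sqrt(2)
        qc = z_prime(pos=[10 - d_pos, 10 + d_pos],
                     neg=[90 - d_neg, 90 + d_neg])
        assert qc.z_prime == pytest.approx(0.7375, abs=1e-9)
        assert (qc.mu_pos, qc.mu_neg) == (10.0, 90.0)

    def test_perfect_separation(self):
        qc = z_prime([10.0, 10.0], [90.0, 90.0])
        assert qc.z_prime == 1.0

    def test_equal_means_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            z_prime([50.0, 51.0], [51.0, 50.0])

    @settings(derandomize=True, max_examples=30)
    @given(c=st.floats(0.1, 10.0),
           pos=st.lists(st.floats(0.0, 40.0), min_size=3, max_size=6),
           neg=st.lists(st.floats(60.0, 100.0), min_size=3, max_size=6))
    def test_scale_invariance(self, c, pos, neg):
        a = z_prime(pos, neg).z_prime
        b = z_prime([c * x for x in pos], [c * x for x in neg]).z_prime
        assert b == pytest.approx(a, rel=1e-6, abs=1e-9)

    def test_inflating_sd_decreases_z_prime(self):
        base = z_prime([8.0, 12.0, 10.0], [88.0, 92.0, 90.0]).z_prime
        wider = z_prime([4.0, 16.0, 10.0], [88.0, 92.0, 90.0]).z_prime
        assert wider < base


class TestSelectionCriteria:
    VEHICLE = [make_summary(10.0), make_summary(12.0), make_summary(9.0),
               make_summary(11.0)]

    def test_null_compound_is_not_a_hit(self):
        hits = apply_selection_criteria({"X": self.VEHICLE}, self.VEHICLE,
                                        mode="inhibition")
        assert len(hits) == 1 and not hits[0].pass_i and not hits[0].is_hit

    def test_cytotoxic_compound_fails_criterion_iii_only(self):
        wells = [make_summary(70.0, viability=0.4),
                 make_summary(75.0, viability=0.38),
                 make_summary(72.0, viability=0.42),
                 make_summary(68.0, viability=0.41)]
        [hit] = apply_selection_criteria({"X": wells}, self.VEHICLE,
                                         mode="inhibition")
        assert hit.pass_i and hit.pass_ii and not hit.pass_iii
        assert not hit.is_hit
        assert hit.viability_vs_vehicle < 0.5

    def test_strong_clean_compound_is_a_hit(self):
        wells = [make_summary(70.0, viability=0.95),
                 make_summary(75.0, viability=0.94),
                 make_summary(72.0, viability=0.96),
                 make_summary(68.0, viability=0.95)]
        [hit] = apply_selection_criteria({"X": wells}, self.VEHICLE,
                                         mode="inhibition")
        assert hit.is_hit and hit.pass_i and hit.pass_ii and hit.pass_iii

    def test_significant_decrease_is_gated_out(self):
        # direction gating: lower cluster % with tiny p is not "significant"
        wells = [make_summary(1.0), make_summary(2.0), make_summary(1.5),
                 make_summary(2.5)]
        [hit] = apply_selection_criteria({"X": wells}, self.VEHICLE,
                                         mode="inhibition")
        assert hit.p_live_clusters < 0.05 and not hit.pass_i

    def test_missing_vehicle_rejected(self):
        with pytest.raises(ValueError):
            apply_selection_criteria({"X": self.VEHICLE}, [],
                                     mode="inhibition")


DESIGNED_SIX = {"chaetocin", "apicidin", "IBET151", "OTX015",
                "3-deazaneplanocin A", "B32B3"}


class TestRunScreen:
    @pytest.fixture(scope="class")
    def inhibition(self, library):
        return run_screen(library, mode="inhibition", seed=1)

    def test_designed_six_all_significant(self, inhibition, library_by_name):
        ids = {library_by_name[n].compound_id for n in DESIGNED_SIX}
        sig = {h.compound_id for h in inhibition.hits if h.pass_i}
        assert ids <= sig

    def test_four_designed_excluded_by_viability(self, inhibition,
                                                 library_by_name):
        ids = {library_by_name[n].compound_id for n in DESIGNED_SIX}
        excluded = {h.compound_id for h in inhibition.hits
                    if h.compound_id in ids and not h.pass_iii}
        assert len(excluded) == 4

    def test_designed_hits_are_apicidin_and_chaetocin(self, inhibition,
                                                      library, library_by_name):
        designed_ids = {r.compound_id for r in library
                        if r.cluster_shift_inh > 0}
        hits = inhibition.hit_ids() & designed_ids
        expected = {library_by_name["apicidin"].compound_id,
                    library_by_name["chaetocin"].compound_id}
        assert hits == expected

    def test_reversal_hits_and_tubastatin_near_miss(self, library,
                                                    library_by_name):
        result = run_screen(library, mode="reversal", seed=1)
        designed_ids = {r.compound_id for r in library
                        if r.cluster_shift_rev > 0}
        expected = {library_by_name["apicidin"].compound_id,
                    library_by_name["chaetocin"].compound_id}
        assert result.hit_ids() & designed_ids == expected
        tub = next(h for h in result.hits if h.compound_id ==
                   library_by_name["tubastatin A"].compound_id)
        assert tub.pass_i and tub.pass_ii and not tub.pass_iii

    def test_qc_exceeds_screen_quality_bar(self, inhibition):
        assert inhibition.qc.z_prime > 0.5

    def test_determinism_and_replicate_extension(self, library):
        small = library[:8]
        a = run_screen(small, mode="inhibition", seed=5)
        b = run_screen(small, mode="inhibition", seed=5)
        assert [s.pct_live_clusters for s in a.well_summaries] == \
               [s.pct_live_clusters for s in b.well_summaries]
        # adding replicate wells never perturbs existing wells' draws
        c = run_screen(small, mode="inhibition", seed=5, replicates=5)
        key = lambda s: (s.spec.compound_id, s.spec.replicate_index)
        c_map = {key(s): s.pct_live_clusters for s in c.well_summaries}
        for s in a.well_summaries:
            assert c_map[key(s)] == s.pct_live_clusters


class TestErrorControlAndPower:
    def test_false_positive_rate_of_null_compounds(self, library):
        # zero-effect compounds pass criterion i at the direction-gated
        # two-tailed rate (~2.5%); bound at 5%
        nulls = [r for r in library if r.cluster_shift_inh == 0
                 and r.cytotox_frac <= 0.2][:20]
        trials = passes = 0
        for seed in range(100):
            result = run_screen(nulls, mode="inhibition", seed=seed)
            trials += len(result.hits)
            passes += sum(h.pass_i for h in result.hits)
        assert trials == 2000
        assert passes / trials <= 0.05

    def test_power_on_designed_effects(self, library):
        designed = [r for r in library if r.cluster_shift_inh > 0]
        trials = passes = 0
        for seed in range(100):
            result = run_screen(designed, mode="inhibition", seed=seed)
            trials += len(result.hits)
            passes += sum(h.pass_i for h in result.hits)
        assert trials == 600
        assert passes / trials >= 0.99
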