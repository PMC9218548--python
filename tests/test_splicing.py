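"""PSI computation, census filters, DS testing and DSG summarization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from wingnet.splicing import (
    DiffSpliceResult,
    SpliceEvent,
    census_filter,
    compute_psi,
    diff_splicing,
    ds_test,
    event_census,
    events_to_frame,
    frame_to_events,
    psi_per_sample,
    summarize_dsg,
    welch_t,
)

WS = [f"w{i}" for i in range(4)]
DS = [f"d{i}" for i in range(4)]


def make_event(eid="e1", gene="g1", etype="SE", li=1, ls=1, inc=None, skp=None):
    return SpliceEvent(eid, gene, etype, li, ls, inc or {}, skp or {})


class TestComputePsi:
    def test_boundaries(self):
        assert compute_psi(5, 0, 1, 1) == 1.0
        assert compute_psi(0, 7, 1, 1) == 0.0

    def test_length_weighting(self):
        assert compute_psi(10, 10, 2, 1) == pytest.approx(1 / 3)

    def test_undefined_for_no_counts(self):
        with pytest.raises(ValueError):
            compute_psi(0, 0, 1, 1)

    @given(st.integers(0, 500), st.integers(0, 500),
           st.integers(1, 5), st.integers(1, 5))
    def test_always_in_unit_interval(self, i, s, li, ls):
        if i + s == 0:
            return
        assert 0.0 <= compute_psi(i, s, li, ls) <= 1.0


class TestCensusFilter:
    def test_total_support_below_20_excluded(self):
        ev = make_event(inc={s: 2 for s in WS}, skp={s: 2 for s in WS[:3]})
        # 8 + 6 = 14 < 20
        assert census_filter([ev], WS) == []
        ev2 = make_event(inc={s: 3 for s in WS}, skp={s: 2 for s in WS})
        assert census_filter([ev2], WS) == [ev2]  # 12 + 8 = 20, PSI 0.6

    def test_sum_nineteen_excluded(self):
        ev = make_event(inc={WS[0]: 10}, skp={WS[0]: 9})
        assert census_filter([ev], WS) == []

    def test_extreme_mean_psi_excluded(self):
        high = make_event(inc={s: 19 for s in WS}, skp={s: 1 for s in WS})
        assert census_filter([high], WS) == []  # mean PSI 0.95

    def test_boundary_psi_point_one_excluded(self):
        ev = make_event(inc={s: 2 for s in WS}, skp={s: 18 for s in WS})
        assert census_filter([ev], WS) == []  # mean PSI exactly 0.1
        ev2 = make_event(inc={s: 3 for s in WS}, skp={s: 17 for s in WS})
        assert census_filter([ev2], WS) == [ev2]

    def test_each_mode_requires_both_junctions(self):
        ev = make_event(inc={s: 10 for s in WS}, skp={s: 2 for s in WS})
        assert census_filter([ev], WS, mode="sum", psi_band=None) == [ev]
        assert census_filter([ev], WS, mode="each", psi_band=None) == []


class TestDsTest:
    def test_identical_psi_null(self):
        inc = {s: 10 for s in WS + DS}
        skp = {s: 10 for s in WS + DS}
        r = ds_test(make_event(inc=inc, skp=skp), WS, DS)
        assert r.dpsi == 0.0
        assert r.p == 1.0

    def test_dpsi_is_ds_minus_ws(self):
        inc = {**{s: 1 for s in WS}, **{s: 9 for s in DS}}
        skp = {**{s: 9 for s in WS}, **{s: 1 for s in DS}}
        r = ds_test(make_event(inc=inc, skp=skp), WS, DS)
        assert r.dpsi == pytest.approx(0.8)

    def test_form_swap_negates_dpsi_exactly(self):
        rng = np.random.default_rng(0)
        inc = {s: int(v) for s, v in zip(WS + DS, rng.integers(1, 40, 8))}
        skp = {s: int(v) for s, v in zip(WS + DS, rng.integers(1, 40, 8))}
        ev = make_event(inc=inc, skp=skp)
        a = ds_test(ev, WS, DS)
        b = ds_test(ev, DS, WS)
        assert a.dpsi == -b.dpsi
        assert a.p == b.p

    def test_welch_matches_reference(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            x = rng.normal(size=rng.integers(2, 9))
            y = rng.normal(loc=0.3, size=rng.integers(2, 9))
            t, _, p = welch_t(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_unequal_means_uses_exact_test(self):
        inc = {**{s: 0 for s in WS}, **{s: 20 for s in DS}}
        skp = {**{s: 20 for s in WS}, **{s: 0 for s in DS}}
        r = ds_test(make_event(inc=inc, skp=skp), WS, DS)
        ref = stats.fisher_exact([[0, 80], [80, 0]])[1]
        assert r.dpsi == pytest.approx(1.0)
        assert r.p == pytest.approx(ref)

    def test_insufficient_samples_skipped(self):
        ev = make_event(inc={WS[0]: 10, DS[0]: 10, DS[1]: 10},
                        skp={WS[0]: 10, DS[0]: 1, DS[1]: 2})
        with pytest.raises(ValueError):
            ds_test(ev, WS, DS)
        assert diff_splicing([ev], WS, DS) == []


class TestSummarizeDsg:
    def _res(self, eid, gene, dpsi, p, fdr):
        return DiffSpliceResult(eid, gene, "Wr60", dpsi, p, fdr)

    def test_max_abs_dpsi_represents_gene(self):
        res = [self._res("e1", "g1", 0.2, 0.01, 0.02),
               self._res("e2", "g1", -0.5, 0.02, 0.03)]
        df = summarize_dsg(res)
        assert df.loc[0, "dpsi"] == -0.5
        assert df.loc[0, "event"] == "e2"

    def test_ties_broken_by_p_then_event_id(self):
        res = [self._res("e2", "g1", 0.5, 0.02, 0.03),
               self._res("e1", "g1", -0.5, 0.02, 0.03),
               self._res("e0", "g1", 0.5, 0.04, 0.04)]
        df = summarize_dsg(res)
        assert df.loc[0, "event"] == "e1"

    def test_no_significant_event_no_dsg(self):
        res = [self._res("e1", "g1", 0.9, 0.2, 0.4)]
        assert summarize_dsg(res).empty


class TestEventCensus:
    def test_empty(self):
        census = event_census([], WS)
        assert census["n_events"] == 0
        assert all(v == 0 for v in census["by_type"].values())

    def test_hand_tally_on_ten_event_fixture(self):
        """10 hand-built events; 6 survive the census filters; type
        breakdown matches the hand tally."""
        passing = [
            make_event(f"p{i}", f"g{i}", t, 1, 1,
                       inc={s: 10 for s in WS}, skp={s: 10 for s in WS})
            for i, t in enumerate(["SE", "SE", "MXE", "A5SS", "A3SS", "RI"])
        ]
        low_support = [
            make_event(f"l{i}", "gx", "SE", 1, 1,
                       inc={WS[0]: 5}, skp={WS[0]: 5})
            for i in range(2)
        ]
        extreme_psi = [
            make_event(f"x{i}", "gy", "MXE", 1, 1,
                       inc={s: 24 for s in WS}, skp={s: 1 for s in WS})
            for i in range(2)
        ]
        surviving = census_filter(passing + low_support + extreme_psi, WS)
        assert {e.event_id for e in surviving} == {e.event_id for e in passing}
        census = event_census(surviving, WS)
        assert census["n_events"] == 6
        assert census["by_type"] == {"SE": 2, "MXE": 1, "A5SS": 1, "A3SS": 1, "RI": 1}
        assert census["n_genes_with_events"] == 6

    def test_single_gene(self):
        evs = [make_event(f"e{i}", "g1", "SE", 1, 1,
                          inc={s: 10 for s in WS}, skp={s: 10 for s in WS})
               for i in range(3)]
        assert event_census(evs, WS)["n_genes_with_events"] == 1

    def test_expressed_gene_fraction(self):
        ev = make_event("e1", "g1", "SE", 1, 1,
                        inc={s: 10 for s in WS}, skp={s: 10 for s in WS})
        census = event_census([ev], WS, gene_norm_means={"g1": 5.0, "g2": 3.0,
                                                         "g3": 0.05})
        assert census["n_expressed_genes"] == 2
        assert census["fraction_expressed_genes_with_event"] == 0.5


def test_junction_frame_round_trip(small_dataset):
    events = small_dataset["events"]
    samples = small_dataset["genes"].samples
    df = events_to_frame(events, samples)
    back = frame_to_events(df)
    assert back == sorted(events, key=lambda e: e.event_id)


def test_null_calibration_seeded():
    """Equal true PSI in both forms: rejection rate near nominal."""
    rng = np.random.default_rng(2)
    events = []
    for k in range(800):
        psi = rng.uniform(0.2, 0.8)
        q = psi * 2 / (psi * 2 + (1 - psi))
        inc, skp = {}, {}
        for s in WS + DS:
            t = rng.poisson(200)
            i = rng.binomial(t, q)
            inc[s], skp[s] = int(i), int(t - i)
        events.append(make_event(f"e{k}", "g", "SE", 2, 1, inc, skp))
    res = diff_splicing(events, WS, DS)
    frac = np.mean([r.p < 0.05 for r in res])
    assert 0.02 <= frac <= 0.08
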