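"""Time-course assembly and progressive DMP calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methdyn import (
    ConfigError,
    TimeCourseDesign,
    ValidationError,
    build_timecourse,
    call_dmps,
    dmp_row_indices,
    platform_concordance,
    split_by_direction,
    zscore_trajectories,
)
from .conftest import make_timecourse
from .oracles import brute_is_dmp


def _calls(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
    df["strand"] = "."
    df["fraction"] = df["meth"] / (df["meth"] + df["unmeth"])
    return df


LABELS = ("0h", "1h", "24h", "96h")


class TestBuildTimecourse:
    def test_inner_join_drops_sites_missing_a_time_point(self):
        base = [("chr1", 100, 10, 10), ("chr1", 200, 10, 10)]
        tables = {l: _calls(base) for l in LABELS}
        tables["96h"] = _calls(base[:1])  # site 200 absent at 96h
        tc = build_timecourse(tables, TimeCourseDesign(min_coverage=1))
        assert list(tc.sites["pos"]) == [100]

    @pytest.mark.parametrize("covs,kept", [((20, 20, 20, 19), 0), ((20, 20, 20, 20), 1)])
    def test_per_timepoint_coverage_gate(self, covs, kept):
        tables = {l: _calls([("chr1", 100, c // 2, c - c // 2)]) for l, c in zip(LABELS, covs)}
        tc = build_timecourse(tables, TimeCourseDesign(min_coverage=20))
        assert len(tc) == kept

    def test_missing_table_is_configuration_error(self):
        tables = {l: _calls([("chr1", 100, 10, 10)]) for l in LABELS[:3]}
        with pytest.raises(ConfigError):
            build_timecourse(tables, TimeCourseDesign())

    def test_replicates_pooled_by_count_summation(self):
        rep = _calls([("chr1", 100, 5, 5)])
        tables = {l: _calls([("chr1", 100, 10, 10)]) for l in LABELS}
        tables["0h"] = [rep, rep, rep]
        tc = build_timecourse(tables, TimeCourseDesign(min_coverage=15))
        assert tc.sites.loc[0, "total_0h"] == 30 and tc.sites.loc[0, "meth_0h"] == 15

    def test_design_validation(self):
        with pytest.raises(ConfigError):
            TimeCourseDesign(labels=("0h", "1h"))
        with pytest.raises(ConfigError):
            TimeCourseDesign(labels=("a", "a", "b"))
        with pytest.raises(ConfigError):
            TimeCourseDesign(min_coverage=0)


class TestCallDmps:
    @pytest.mark.parametrize(
        "fractions,expected",
        [
            ((0.10, 0.20, 0.35, 0.50), "hyper"),   # strictly increasing, |d|>0.2
            ((0.10, 0.20, 0.15, 0.50), None),       # non-monotone
            ((0.10, 0.15, 0.20, 0.28), None),       # |d| = 0.18 fails the gate
            ((0.90, 0.70, 0.50, 0.30), "hypo"),     # strictly decreasing
            ((0.10, 0.10, 0.20, 0.40), None),       # tie breaks strict chain
        ],
    )
    def test_printed_examples(self, fractions, expected):
        total = np.full((1, 4), 100)
        meth = (np.array(fractions)[None, :] * 100).round().astype(int)
        tc = make_timecourse(meth, total)
        dmps = call_dmps(tc, min_delta=0.20, strict=True)
        if expected is None:
            assert len(dmps) == 0
        else:
            assert len(dmps) == 1 and dmps.loc[0, "direction"] == expected

    def test_delta_is_signed_last_minus_first(self):
        tc = make_timecourse([[90, 70, 50, 30]], np.full((1, 4), 100))
        dmps = call_dmps(tc)
        assert dmps.loc[0, "delta"] == pytest.approx(-0.60)

    def test_boundary_delta_exactly_020_excluded(self):
        # 0.20 overall change is NOT "> 20%": counts chosen to land exactly
        tc = make_timecourse([[20, 25, 30, 40]], np.full((1, 4), 100))
        assert len(call_dmps(tc, min_delta=0.20)) == 0

    def test_non_strict_accepts_intermediate_ties(self):
        tc = make_timecourse([[10, 10, 20, 40]], np.full((1, 4), 100))
        assert len(call_dmps(tc, strict=True)) == 0
        relaxed = call_dmps(tc, strict=False)
        assert len(relaxed) == 1 and relaxed.loc[0, "direction"] == "hyper"

    def test_exact_arithmetic_no_float_ties(self):
        # 1/3 vs 33/99 are equal as ratios: must not count as strict increase
        tc = make_timecourse([[1, 33, 50, 90], [100, 100, 100, 100]],
                             [[3, 99, 100, 100], [100, 100, 100, 100]])
        assert len(call_dmps(tc, strict=True)) == 0

    def test_fewer_than_three_timepoints_rejected(self):
        with pytest.raises(ConfigError):
            TimeCourseDesign(labels=("0h", "96h"))

    def test_partition_hyper_hypo(self):
        rng = np.random.default_rng(3)
        total = rng.integers(20, 80, size=(300, 4))
        meth = rng.binomial(total, rng.random((300, 1)))
        tc = make_timecourse(meth, total)
        dmps = call_dmps(tc)
        hyper, hypo = split_by_direction(dmps)
        assert len(hyper) + len(hypo) == len(dmps)
        assert set(hyper["pos"]).isdisjoint(set(hypo["pos"]))

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_oracle_equivalence_random_counts(self, data):
        n = data.draw(st.integers(1, 40))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        total = rng.integers(1, 60, size=(n, 4))
        meth = rng.binomial(total, rng.random((n, 4)))
        strict = data.draw(st.booleans())
        tc = make_timecourse(meth, total)
        dmps = call_dmps(tc, strict=strict)
        called = dict(zip(dmps["pos"], dmps["direction"]))
        for i in range(n):
            expect = brute_is_dmp(meth[i], total[i], strict=strict)
            assert called.get(i * 10) == expect

    def test_row_order_permutation_invariance(self):
        rng = np.random.default_rng(9)
        total = rng.integers(20, 60, size=(200, 4))
        meth = rng.binomial(total, rng.random((200, 4)))
        tc = make_timecourse(meth, total)
        perm = rng.permutation(200)
        tc_shuf = make_timecourse(meth[perm], total[perm])
        tc_shuf.sites["pos"] = np.array([p * 10 for p in perm])
        a = call_dmps(tc).sort_values("pos").reset_index(drop=True)
        b = call_dmps(tc_shuf).sort_values("pos").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        total = rng.integers(20, 60, size=(400, 4))
        meth = rng.binomial(total, np.linspace(0.1, 0.9, 4)[None, :].repeat(400, 0))
        tc = make_timecourse(meth, total)
        sets = [set(call_dmps(tc, min_delta=d)["pos"]) for d in (0.1, 0.2, 0.4, 0.6)]
        for smaller, larger in zip(sets[1:], sets[:-1]):
            assert smaller <= larger

    def test_degenerate_min_delta_one_yields_nothing(self):
        rng = np.random.default_rng(6)
        total = rng.integers(20, 60, size=(100, 4))
        meth = np.clip(rng.binomial(total, rng.random((100, 4))), 1, None)  # fractions > 0
        tc = make_timecourse(meth, total)
        assert len(call_dmps(tc, min_delta=1.0)) == 0


class TestZscore:
    def test_affine_normalisation(self):
        tc = make_timecourse([[10, 20, 30, 40]], np.full((1, 4), 100))
        z = zscore_trajectories(tc, {"g": np.array([0])})
        row = z.loc["g"].to_numpy()
        assert row.mean() == pytest.approx(0, abs=1e-12)
        assert np.std(row, ddof=1) == pytest.approx(1, abs=1e-12)
        assert (np.diff(row) > 0).all()

    def test_constant_site_gets_zero_z(self):
        tc = make_timecourse([[50, 50, 50, 50]], np.full((1, 4), 100))
        z = zscore_trajectories(tc, {"g": np.array([0])})
        assert (z.loc["g"] == 0).all()

    def test_hyper_group_mean_z_is_monotone_increasing(self, small_timecourse):
        dmps = call_dmps(small_timecourse)
        hyper = dmps.loc[dmps["direction"] == "hyper"]
        idx = dmp_row_indices(small_timecourse, hyper)
        z = zscore_trajectories(small_timecourse, {"hyper": idx})
        assert (np.diff(z.loc["hyper"].to_numpy()) > 0).all()

    def test_empty_group_rejected(self):
        tc = make_timecourse([[10, 20, 30, 40]], np.full((1, 4), 100))
        with pytest.raises(ValidationError):
            zscore_trajectories(tc, {"g": np.array([], dtype=int)})


class TestPlatformConcordance:
    def test_identical_platforms_give_r_one(self):
        a = _calls([("chr1", p, p % 7 + 1, 10) for p in range(30)])
        n, r = platform_concordance(a, a, 5, 5)
        assert n == 30 and r == pytest.approx(1.0)

    def test_coverage_threshold_excludes_low_sites(self):
        a = _calls([("chr1", 1, 5, 5), ("chr1", 2, 8, 8), ("chr1", 3, 2, 2)])
        b = _calls([("chr1", 1, 5, 4), ("chr1", 2, 8, 8), ("chr1", 3, 9, 9)])
        n, _ = platform_concordance(a, b, 1, 10)
        assert n == 2  # site 1 has coverage 9 < 10 on platform b

    def test_perfect_anticorrelation(self):
        a = _calls([("chr1", 1, 0, 10), ("chr1", 2, 5, 5), ("chr1", 3, 10, 0)])
        b = _calls([("chr1", 1, 10, 0), ("chr1", 2, 5, 5), ("chr1", 3, 0, 10)])
        _, r = platform_concordance(a, b, 1, 1)
        assert r == pytest.approx(-1.0, abs=1e-6)

    def test_too_few_shared_sites_rejected(self):
        a = _calls([("chr1", 1, 5, 5)])
        b = _calls([("chr2", 9, 5, 5)])
        with pytest.raises(ValidationError):
            platform_concordance(a, b, 1, 1)
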