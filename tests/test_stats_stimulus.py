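import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cionaswim import stats_stimulus as stx
from cionaswim.io_model import StimulusProtocol


# ---------------------------------------------------------------------------
# exact small-n null enumeration oracles
# ---------------------------------------------------------------------------


def exact_mannwhitney(a, b, alternative="two-sided"):
    """Enumerate all rank configurations of the pooled sample (no ties)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(n1 + n2), n1):
        r = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.asarray(us)
    if alternative == "greater":
        p = np.mean(us >= u_obs)
    elif alternative == "less":
        p = np.mean(us <= u_obs)
    else:
        p = min(1.0, 2 * min(np.mean(us >= u_obs), np.mean(us <= u_obs)))
    return u_obs, p


def exact_signed_rank(a, b, alternative="two-sided"):
    """Enumerate all 2^n sign patterns of the nonzero differences."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(ranks[np.array(signs, bool)].sum())
    ws = np.asarray(ws)
    if alternative == "greater":
        p = np.mean(ws >= w_obs)
    elif alternative == "less":
        p = np.mean(ws <= w_obs)
    else:
        p = min(1.0, 2 * min(np.mean(ws >= w_obs), np.mean(ws <= w_obs)))
    return w_obs, p


class TestSMD:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=100)
        assert stx.smd(x, x) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=30), r.normal(loc=1, size=25)
        assert stx.smd(a, b) == pytest.approx(-stx.smd(b, a), abs=1e-12)

    def test_worked_example_formula(self):
        # medians 10 and 8, both MAD-based scales exactly 2 -> SMD = 1.0
        spread = 2.0 / 1.4826
        a = np.array([10 - spread, 10.0, 10 + spread])
        b = np.array([8 - spread, 8.0, 8 + spread])
        assert stx.smd(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_classical_scale_variant(self, rng):
        a = rng.normal(loc=2, size=2000)
        b = rng.normal(size=2000)
        robust = stx.smd(a, b, robust=True)
        classical = stx.smd(a, b, robust=False)
        assert robust == pytest.approx(2.0, abs=0.15)
        assert classical == pytest.approx(2.0, abs=0.15)

    def test_zero_scale_flagged(self):
        assert np.isnan(stx.smd([1.0, 1.0], [2.0, 2.0]))
        assert stx.smd([1.0, 1.0], [1.0, 1.0]) == 0.0


class TestNormality:
    def test_reference_vector(self):
        # 11-point reference sample; W and p frozen from an independent R run
        x = [148, 154, 158, 160, 161, 162, 166, 170, 182, 195, 236]
        res = stx.normality(x)
        assert res["statistic"] == pytest.approx(0.7888146949, abs=1e-8)
        assert res["p"] == pytest.approx(0.0067038141, abs=1e-8)
        assert res["reject_normality"]

    def test_uniform_rejected_at_large_n(self, rng):
        res = stx.normality(rng.uniform(size=2000))
        assert res["reject_normality"]

    def test_large_sample_subsampled(self, rng):
        res = stx.normality(rng.normal(size=10_000))
        assert res["subsampled"] and res["n"] == stx.SHAPIRO_MAX_N

    def test_tiny_sample_error(self):
        with pytest.raises(ValueError):
            stx.normality([1.0, 2.0])


class TestPairedSegmentTest:
    def test_identical_pairs_degenerate(self):
        res = stx.paired_segment_test({"N": np.ones(10), "TB": np.ones(10)})
        assert res[0].degenerate and not res[0].significant

    def test_matches_exact_enumeration(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        res = stx.paired_segment_test({"A": a, "B": b})[0]
        _, p_exact = exact_signed_rank(a, b)
        assert res.p_two_sided == pytest.approx(p_exact, abs=1e-10)
        _, p_g = exact_signed_rank(a, b, "greater")
        assert res.p_greater == pytest.approx(p_g, abs=1e-10)

    def test_one_sided_swap_antisymmetry(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        r_ab = stx.paired_segment_test({"A": a, "B": b})[0]
        r_ba = stx.paired_segment_test({"B": b, "A": a})[0]
        assert r_ab.p_greater == pytest.approx(r_ba.p_less, abs=1e-12)

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            stx.paired_segment_test({"A": np.ones(5), "B": np.ones(6)})


class TestDrugVsControl:
    def test_bonferroni_alpha_is_0_002(self, rng):
        res = stx.drug_vs_control_test(rng.normal(size=20), rng.normal(size=20))
        assert res.alpha == pytest.approx(0.002)
        assert res.alpha == pytest.approx(0.05 / 25)

    def test_identical_distributions_effect_half(self, rng):
        a = rng.normal(size=4000)
        b = rng.normal(size=4000)
        res = stx.drug_vs_control_test(a, b)
        assert res.effect_size == pytest.approx(0.5, abs=0.03)

    def test_matches_exact_enumeration(self, rng):
        a = rng.normal(size=7)
        b = rng.normal(size=8)
        res = stx.drug_vs_control_test(a, b)
        u_exact, p_exact = exact_mannwhitney(a, b)
        assert res.statistic == pytest.approx(u_exact)
        assert res.p_two_sided == pytest.approx(p_exact, abs=1e-10)
        _, p_less = exact_mannwhitney(a, b, "less")
        assert res.p_less == pytest.approx(p_less, abs=1e-10)

    def test_order_invariance(self, rng):
        a, b = rng.normal(size=40), rng.normal(size=35)
        r1 = stx.drug_vs_control_test(a, b)
        r2 = stx.drug_vs_control_test(np.flip(a), rng.permutation(b))
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)


class TestUsageComparison:
    def test_identical_distributions_nonsignificant(self, rng):
        x = rng.uniform(0, 100, size=30)
        res = stx.usage_comparison(x, x + 0.0)
        assert not res.significant or res.p_two_sided > 0.9

    def test_doubled_usage_detected_at_n30(self, rng):
        control = rng.normal(10, 2, size=30).clip(0)
        drug = rng.normal(20, 2, size=30).clip(0)
        res = stx.usage_comparison(drug, control)
        assert res.significant

    def test_too_few_videos(self):
        with pytest.raises(ValueError):
            stx.usage_comparison([1.0], [2.0, 3.0])


class TestEventWindows:
    def test_standard_protocol_frames(self):
        win = stx.event_windows(StimulusProtocol(color="white"))
        assert win.before_on == (600, 900)
        assert win.after_on == (915, 990)

    def test_off_windows(self):
        win = stx.event_windows(StimulusProtocol(color="red"))
        assert win.before_off == (2400, 2700)
        assert win.after_off == (2715, 2790)

    @pytest.mark.parametrize("onset", [30.0, 45.0, 60.0])
    def test_after_window_always_75_frames(self, onset):
        win = stx.event_windows(StimulusProtocol(color="blue", onset_s=onset))
        assert win.after_on[1] - win.after_on[0] == 75
        assert win.after_off[1] - win.after_off[0] == 75

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            stx.event_windows(StimulusProtocol(color="white"), n_frames=1000)


class TestEventResponse:
    def _panel(self, speeds):
        T = len(speeds)
        data = {c: np.random.default_rng(0).normal(size=T) for c in stx.PANEL_COLUMNS}
        for c in ("sN", "sTB", "sTprM", "sTM", "sTpoM", "sTT"):
            data[c] = speeds
        return pd.DataFrame(data)

    def test_no_change_near_zero(self, rng):
        panel = self._panel(rng.normal(10, 1, size=3000))
        win = stx.event_windows(StimulusProtocol(color="white"))
        resp = stx.event_response(panel, win)
        assert abs(resp.loc["sN", "on"]) < 0.5

    def test_planted_speed_drop_negative_at_on(self, rng):
        speeds = rng.normal(10, 1, size=3000)
        speeds[900:2700] *= 0.5  # stimulus window
        win = stx.event_windows(StimulusProtocol(color="white"))
        resp = stx.event_response(self._panel(speeds), win)
        for c in ("sN", "sTB", "sTT"):
            assert resp.loc[c, "on"] < -1.0
            assert resp.loc[c, "off"] > 1.0

    def test_window_swap_antisymmetry(self, rng):
        panel = self._panel(rng.normal(10, 3, size=3000))
        win = stx.event_windows(StimulusProtocol(color="white"))
        swapped = stx.EventWindows(
            before_on=win.after_on,
            after_on=win.before_on,
            before_off=win.after_off,
            after_off=win.before_off,
        )
        r1 = stx.event_response(panel, win)
        r2 = stx.event_response(panel, swapped)
        np.testing.assert_allclose(r1["on"], -r2["on"], atol=1e-12)
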