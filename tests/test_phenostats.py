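"""Stratified statistics: CMH, Breslow-Day, chunking, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spherotype.phenostats import (StratTable, adjust_bonferroni,
                                   area_summary, bin_chunks, breslow_day,
                                   build_strat_table, cmh_test,
                                   mantel_haenszel_or, summarize)


def _random_tables(rng, k, lo=1, hi=30):
    t = rng.integers(lo, hi, size=(k, 2, 2)).astype(float)
    return StratTable(a=t[:, 0, 0], b=t[:, 0, 1], c=t[:, 1, 0],
                      d=t[:, 1, 1]), t


class TestCMH:
    def test_single_stratum_equals_scaled_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            st, t = _random_tables(rng, 1)
            n = t.sum()
            pearson = stats.chi2_contingency(t[0], correction=False)[0]
            assert cmh_test(st).statistic == pytest.approx(
                (n - 1) / n * pearson, rel=1e-12)

    def test_matches_reference_implementation(self):
        from statsmodels.stats.contingency_tables import StratifiedTable
        rng = np.random.default_rng(1)
        for _ in range(30):
            st, t = _random_tables(rng, int(rng.integers(1, 5)))
            ref = StratifiedTable([x for x in t]).test_null_odds(
                correction=False)
            r = cmh_test(st)
            assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert r.pvalue == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_null_tables_give_zero(self):
        st = StratTable(a=[5, 5], b=[5, 5], c=[5, 5], d=[5, 5])
        r = cmh_test(st)
        assert r.statistic == 0.0
        assert r.pvalue == 1.0

    def test_consistent_effect_beats_cancelling_arrangement(self):
        # same three 2x2 tables; consistent direction vs flipped strata
        consistent = StratTable(a=[15, 14, 16], b=[5, 6, 4],
                                c=[5, 6, 4], d=[15, 14, 16])
        cancelling = StratTable(a=[15, 6, 16], b=[5, 14, 4],
                                c=[5, 14, 4], d=[15, 6, 16])
        p_cons = cmh_test(consistent).pvalue
        p_canc = cmh_test(cancelling).pvalue
        assert p_cons < 0.05
        assert p_canc > p_cons

    def test_consistent_effect_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(2)
        st = StratTable(a=[15, 14, 16], b=[5, 6, 4],
                        c=[5, 6, 4], d=[15, 14, 16])
        obs = cmh_test(st).statistic
        # permutation oracle: shuffle group labels within each stratum
        count = 0
        n_perm = 500
        for _ in range(n_perm):
            a = b = c = d = []
            av, bv, cv, dv = [], [], [], []
            for k in range(3):
                r1 = int(st.a[k] + st.b[k])
                s1 = int(st.a[k] + st.c[k])
                t = int(st.totals[k])
                labels = np.zeros(t, dtype=int)
                labels[:r1] = 1  # condition membership
                pos = np.zeros(t, dtype=int)
                pos[:s1] = 1
                rng.shuffle(pos)
                av.append(int(((labels == 1) & (pos == 1)).sum()))
                bv.append(int(((labels == 1) & (pos == 0)).sum()))
                cv.append(int(((labels == 0) & (pos == 1)).sum()))
                dv.append(int(((labels == 0) & (pos == 0)).sum()))
            perm = StratTable(a=av, b=bv, c=cv, d=dv)
            if cmh_test(perm).statistic >= obs:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        assert p_perm < 0.05

    def test_degenerate_margins_flagged(self):
        st = StratTable(a=[5], b=[5], c=[0], d=[0])
        r = cmh_test(st)
        assert r.degenerate and r.pvalue == 1.0

    def test_empty_strata_dropped(self):
        st = StratTable(a=[5, 0], b=[5, 0], c=[5, 0], d=[5, 0])
        assert st.n_strata == 1


class TestBreslowDay:
    def test_exactly_homogeneous_strata_give_zero(self):
        st = StratTable(a=[10, 10], b=[5, 5], c=[5, 5], d=[10, 10])
        r = breslow_day(st)
        assert r.psi_mh == pytest.approx(4.0)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.pvalue == pytest.approx(1.0)

    def test_opposed_odds_ratios_detected(self):
        # OR = 4 vs OR = 1/4 at equal size, >= 20 per cell
        st = StratTable(a=[40, 20], b=[20, 40], c=[20, 40], d=[40, 20])
        r = breslow_day(st)
        assert r.statistic > 0
        assert r.pvalue < 0.05

    def test_matches_reference_implementation(self):
        from statsmodels.stats.contingency_tables import StratifiedTable
        rng = np.random.default_rng(3)
        for _ in range(30):
            st, t = _random_tables(rng, 3)
            ref = StratifiedTable([x for x in t]).test_equal_odds(
                adjust=False)
            r = breslow_day(st)
            assert abs(r.statistic - ref.statistic) < 1e-6

    def test_fitted_counts_respect_margin_bounds(self):
        from spherotype.phenostats import _fitted_a
        rng = np.random.default_rng(4)
        for _ in range(200):
            st, _ = _random_tables(rng, 3)
            psi = mantel_haenszel_or(st)
            for k in range(3):
                r = float(st.a[k] + st.b[k])
                s = float(st.a[k] + st.c[k])
                t = float(st.totals[k])
                x = _fitted_a(r, s, t, psi)
                assert max(0.0, r + s - t) < x < min(r, s)

    def test_degenerate_or_uses_haldane(self):
        st = StratTable(a=[5, 6], b=[5, 4], c=[0, 0], d=[10, 10])
        r = breslow_day(st)
        assert r.haldane
        assert np.isfinite(r.statistic)

    def test_requires_two_strata(self):
        with pytest.raises(ValueError):
            breslow_day(StratTable(a=[5], b=[5], c=[5], d=[5]))


class TestBonferroni:
    def test_scaling_and_cap(self):
        adj = adjust_bonferroni([0.01, 0.4], m=5)
        assert adj[0] == pytest.approx(0.05)
        assert adj[1] == 1.0

    def test_order_preserved(self):
        rng = np.random.default_rng(5)
        p = np.sort(rng.random(20))
        adj = adjust_bonferroni(p, m=25)
        assert np.all(np.diff(adj) >= 0)

    def test_family_smaller_than_input_rejected(self):
        with pytest.raises(ValueError):
            adjust_bonferroni([0.1, 0.2, 0.3], m=2)


def _labelled(n_frames=72, prop=0.3, n_obj=10, condition="c",
              experiment="E1", well="W1"):
    rows = []
    n_pos = int(round(prop * n_obj))
    for f in range(1, n_frames + 1):
        for i in range(n_obj):
            rows.append({
                "experiment": experiment, "condition": condition,
                "well": well, "frame": f, "track_id": i,
                "phenotype_label": ("Hyper-protrusive" if i < n_pos
                                    else "Spherical"),
                "Area": 400.0 + 10 * i})
    return pd.DataFrame(rows)


class TestBinChunks:
    def test_72_hours_gives_12_chunks(self):
        binned = bin_chunks(_labelled(72), chunk_hours=6)
        assert len(binned) == 12
        assert binned["chunk_start"].tolist() == list(range(1, 72, 6))
        assert binned["chunk_end"].tolist() == list(range(6, 73, 6))

    def test_constant_proportion_preserved(self):
        binned = bin_chunks(_labelled(12, prop=0.3), chunk_hours=6)
        assert np.allclose(binned["mean_prop"], 0.3)
        assert (binned["n_pos"] == 3).all()
        assert (binned["n_neg"] == 7).all()

    def test_counts_conserved_per_object_chunk(self):
        df = _labelled(24, prop=0.5, n_obj=8)
        binned = bin_chunks(df, chunk_hours=6)
        # one count per object per chunk
        assert (binned["n_pos"] + binned["n_neg"]).sum() == 8 * 4

    def test_out_of_focus_rows_ignored(self):
        df = _labelled(6)
        df.loc[df["frame"] == 1, "phenotype_label"] = pd.NA
        binned = bin_chunks(df, chunk_hours=6)
        assert len(binned) == 1  # still one chunk, NA frames dropped


class TestSummarize:
    def _binned_two_conditions(self, p_ctrl, p_cond, n=100, k=3,
                               chunks=2):
        rows = []
        for e in range(1, k + 1):
            for ch in range(chunks):
                for cond, p in [("control", p_ctrl), ("treated", p_cond)]:
                    rows.append({
                        "condition": cond, "experiment": f"E{e}",
                        "chunk": ch, "chunk_start": 6 * ch + 1,
                        "chunk_end": 6 * ch + 6,
                        "n_pos": int(p * n), "n_neg": n - int(p * n),
                        "mean_prop": p})
        return pd.DataFrame(rows)

    def test_doubling_gives_log2fc_one(self):
        binned = self._binned_two_conditions(0.25, 0.5)
        out = summarize(binned, control="control")
        assert np.allclose(out["log2fc"], 1.0)

    def test_strong_effect_significant_and_homogeneous(self):
        binned = self._binned_two_conditions(0.1, 0.7)
        out = summarize(binned, control="control")
        assert (out["p_adj"] < 0.05).all()
        assert out["homogeneous"].all()
        assert (out["psi_mh"] > 1).all()

    def test_missing_control_is_hard_error(self):
        binned = self._binned_two_conditions(0.2, 0.4)
        with pytest.raises(ValueError, match="control"):
            summarize(binned, control="nope")

    def test_build_strat_table_layout(self):
        binned = self._binned_two_conditions(0.25, 0.5, n=20, k=2)
        tab = build_strat_table(binned, "treated", "control", 0)
        assert tab.n_strata == 2
        np.testing.assert_array_equal(tab.a, [10, 10])
        np.testing.assert_array_equal(tab.b, [10, 10])
        np.testing.assert_array_equal(tab.c, [5, 5])
        np.testing.assert_array_equal(tab.d, [15, 15])


class TestAreaSummary:
    def test_shifted_areas_score_two_sigma(self):
        ctrl = _labelled(6, prop=0.5, n_obj=20, condition="control")
        sd = ctrl["Area"].std(ddof=1)
        shifted = ctrl.copy()
        shifted["condition"] = "treated"
        shifted["Area"] += 2 * sd
        out = area_summary(pd.concat([ctrl, shifted]), control="control")
        z = out.set_index("condition")["mean_z_area"]
        assert z["control"] == pytest.approx(0.0, abs=1e-9)
        assert z["treated"] == pytest.approx(2.0, rel=0.05)

    def test_invariant_to_pixel_rescaling(self):
        df = _labelled(6, prop=0.5, n_obj=20, condition="control")
        other = df.copy()
        other["condition"] = "t"
        other["Area"] *= 1.3
        both = pd.concat([df, other])
        out1 = area_summary(both, control="control")
        scaled = both.copy()
        scaled["Area"] *= 4.0  # uniform pixel-size change
        out2 = area_summary(scaled, control="control")
        pd.testing.assert_frame_equal(out1, out2)

    def test_zero_variance_control_flagged_as_zero(self):
        df = _labelled(6, prop=0.5, n_obj=5, condition="control")
        df["Area"] = 100.0
        out = area_summary(df, control="control")
        assert (out["mean_z_area"] == 0.0).all()
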