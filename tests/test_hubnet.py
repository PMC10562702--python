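import numpy as np
import pandas as pd
import pytest

from wavewire import hubnet


def profiles_with_target_corr(n, length, seed, loading_exponent=None):
    """Factor-model profiles; power-law loadings give scale-free-ish degree."""
    rng = np.random.default_rng(seed)
    f = rng.normal(size=length)
    if loading_exponent is None:
        w = rng.uniform(0.2, 0.95, n)
    else:
        w = np.linspace(1, n, n) ** (-loading_exponent)
        w = 0.05 + 0.9 * (w - w.min()) / (w.max() - w.min())
    x = np.outer(w, f) + rng.normal(size=(n, length)) * np.sqrt(1 - w ** 2)[:, None]
    return pd.DataFrame(x, index=[f"g{i:03d}" for i in range(n)])


class TestAdjacency:
    def test_two_gene_hand_case(self):
        p = profiles_with_target_corr(2, 30, seed=1)
        r = abs(np.corrcoef(p.to_numpy())[0, 1])
        a = hubnet.adjacency(p, beta=1)
        assert a.iloc[0, 1] == pytest.approx(r)
        assert a.iloc[0, 0] == 0.0

    def test_bounds_symmetry_and_power_monotonicity(self):
        p = profiles_with_target_corr(20, 12, seed=2)
        a2 = hubnet.adjacency(p, 2).to_numpy()
        a6 = hubnet.adjacency(p, 6).to_numpy()
        assert ((a2 >= 0) & (a2 <= 1)).all()
        np.testing.assert_allclose(a2, a2.T)
        assert (a6 <= a2 + 1e-12).all()

    def test_zero_variance_member_excluded(self):
        p = profiles_with_target_corr(5, 10, seed=3)
        p.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            a = hubnet.adjacency(p, 2)
        assert "flat" not in a.index


class TestConnectivity:
    def test_k_matches_hand_summed_adjacency(self):
        p = profiles_with_target_corr(3, 25, seed=4)
        r = np.corrcoef(p.to_numpy())
        table = hubnet.connectivity(p, beta=2)
        for i in range(3):
            hand = sum(abs(r[i, j]) ** 2 for j in range(3) if j != i)
            assert table["k"].iloc[i] == pytest.approx(hand, abs=1e-12)

    def test_forty_member_wave_yields_exactly_four_hubs(self):
        p = profiles_with_target_corr(40, 15, seed=5)
        table = hubnet.connectivity(p, beta=6)
        assert int(table["hub"].sum()) == 4

    def test_hub_ceiling_rule(self):
        for n, expected in [(10, 1), (11, 2), (20, 2), (41, 5)]:
            p = profiles_with_target_corr(n, 15, seed=n)
            table = hubnet.connectivity(p, beta=2)
            assert int(table["hub"].sum()) == expected

    def test_deterministic_tie_break_by_identifier(self):
        # identical profiles: all correlations tie at 1
        base = np.linspace(0, 1, 8)
        p = pd.DataFrame([base] * 10, index=[f"g{i}" for i in range(10)])
        t1 = hubnet.connectivity(p, beta=3)
        t2 = hubnet.connectivity(p.iloc[::-1], beta=3)
        assert set(t1.index[t1["hub"]]) == set(t2.index[t2["hub"]]) == {"g0"}

    def test_k_bounded_by_wave_size(self):
        p = profiles_with_target_corr(30, 12, seed=6)
        table = hubnet.connectivity(p, beta=1)
        assert (table["k"] <= 29 + 1e-9).all()


class TestSoftPower:
    def test_single_power_grid(self):
        p = profiles_with_target_corr(12, 10, seed=7)
        assert hubnet.pick_soft_power(p, powers=(6,)) == 6

    def test_degenerate_identical_profiles(self):
        base = np.linspace(0, 1, 10)
        p = pd.DataFrame([base] * 12, index=[f"g{i}" for i in range(12)])
        with pytest.warns(UserWarning, match="degenerate"):
            assert hubnet.pick_soft_power(p) == 1

    def test_scale_free_structure_reaches_fit_threshold(self):
        p = profiles_with_target_corr(300, 120, seed=8, loading_exponent=0.8)
        beta = hubnet.pick_soft_power(p, fit_threshold=0.80)
        # independent regression oracle on the binned degree distribution
        r = np.abs(np.corrcoef(p.to_numpy()))
        np.fill_diagonal(r, 0.0)
        k = (r ** beta).sum(axis=1)
        edges = np.linspace(k.min(), k.max(), 11)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        xs = [np.log10(k[which == b].mean()) for b in range(10) if (which == b).any()]
        ys = [np.log10((which == b).mean()) for b in range(10) if (which == b).any()]
        slope, intercept = np.polyfit(xs, ys, 1)
        pred = slope * np.asarray(xs) + intercept
        r2 = 1 - ((np.asarray(ys) - pred) ** 2).sum() / ((ys - np.mean(ys)) ** 2).sum()
        assert slope < 0
        assert r2 >= 0.80

    def test_requires_minimum_membership(self):
        p = profiles_with_target_corr(5, 10, seed=9)
        with pytest.raises(ValueError, match=">= 10"):
            hubnet.pick_soft_power(p)


class TestHubOverlap:
    @staticmethod
    def _network(genotype, wave, name, hub_ids):
        table = pd.DataFrame({"k": np.arange(len(hub_ids), dtype=float),
                              "hub": True}, index=hub_ids)
        return hubnet.WaveNetwork(genotype=genotype, wave=wave, name=name,
                                  beta=6, table=table)

    def test_identical_hub_sets_fully_conserved(self):
        wt = [self._network("WT", 0, "+1", ["a", "b", "c"])]
        onc = [self._network("Onc", 0, "+1", ["a", "b", "c"])]
        out = hubnet.hub_overlap(wt, onc)
        assert out.loc["overall", "conserved_fraction"] == 1.0

    def test_disjoint_hub_sets(self):
        wt = [self._network("WT", 0, "+1", ["a", "b"])]
        onc = [self._network("Onc", 0, "+1", ["x", "y"])]
        assert hubnet.hub_overlap(wt, onc).loc["overall", "conserved_fraction"] == 0.0

    def test_default_denominator_is_mutant_side(self):
        onc_hubs = [f"h{i}" for i in range(20)]
        wt = [self._network("WT", 0, "+1", onc_hubs[:5] + ["w1", "w2"])]
        onc = [self._network("Onc", 0, "+1", onc_hubs)]
        out = hubnet.hub_overlap(wt, onc)
        assert out.loc["overall", "conserved_fraction"] == pytest.approx(0.25)
        union = hubnet.hub_overlap(wt, onc, denominator="union")
        assert union.loc["overall", "conserved_fraction"] == pytest.approx(5 / 22)

    def test_phase_restricted_fractions(self):
        wt = [self._network("WT", 0, "+0.6", ["a", "b"]),
              self._network("WT", 1, "-12", ["c", "d"])]
        onc = [self._network("Onc", 0, "+0.6+1", ["a", "x"]),
               self._network("Onc", 1, "-12", ["y", "z"])]
        out = hubnet.hub_overlap(wt, onc)
        assert out.loc["very early", "conserved_fraction"] == pytest.approx(0.5)
        assert out.loc["late", "conserved_fraction"] == 0.0
        assert np.isnan(out.loc["middle", "conserved_fraction"])

    def test_empty_hub_set_reported_missing(self):
        wt = [self._network("WT", 0, "+1", ["a"])]
        out = hubnet.hub_overlap(wt, [])
        assert np.isnan(out.loc["overall", "conserved_fraction"])


class TestTfLabels:
    def _contrasts(self):
        return pd.DataFrame({
            "adj_pvalue": [0.04, 0.5, 0.06, 0.9],
            "time_months": [0.6, 1.0, 0.6, 1.0],
        }, index=["tf1", "tf1", "tf2", "tf2"])

    def test_threshold_cases(self):
        nws = [TestHubOverlap._network("Onc", 0, "+1", ["tf1", "tf2", "g1"])]
        out = hubnet.label_tf_hubs(nws, ["tf1", "tf2"], self._contrasts())
        out = out.set_index("feature")
        assert bool(out.loc["tf1", "transcriptionally_regulated"])
        assert not bool(out.loc["tf2", "transcriptionally_regulated"])
        assert not bool(out.loc["g1", "is_tf"])

    def test_tf_absent_from_contrasts_not_regulated(self):
        nws = [TestHubOverlap._network("Onc", 0, "+1", ["tf9"])]
        out = hubnet.label_tf_hubs(nws, ["tf9"], self._contrasts())
        assert not bool(out["transcriptionally_regulated"].iloc[0])

    def test_regulated_fraction_matches_brute_scan(self):
        rng = np.random.default_rng(11)
        feats = [f"tf{i}" for i in range(30)]
        contrasts = pd.DataFrame({
            "adj_pvalue": rng.uniform(0, 0.2, 60),
            "time_months": np.tile([0.6, 12.0], 30),
        }, index=np.repeat(feats, 2))
        nws = [TestHubOverlap._network("Onc", 0, "+1", feats)]
        out = hubnet.label_tf_hubs(nws, feats, contrasts, fdr=0.05)
        brute = {f: (contrasts.loc[[f], "adj_pvalue"] <= 0.05).any()
                 for f in feats}
        got = dict(zip(out["feature"], out["transcriptionally_regulated"]))
        assert got == brute

    def test_empty_tf_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hubnet.label_tf_hubs([], [], pd.DataFrame())


class TestPlantedHubRecovery:
    def test_noisy_hub_recall(self, noisy_data):
        from wavewire import dynamics, waves
        from wavewire.simulate import hub_metrics
        study, truth = noisy_data
        calls = dynamics.chi2_dynamic(study, "WT")
        dyn = list(calls.index[calls["dynamic"]])
        means = study.time_point_means("WT").loc[dyn]
        ws = waves.build_waveset(dynamics.standardize_rows(means), "WT",
                                 member_log2_means=means, c=6, seed=3)
        with pytest.warns(UserWarning):
            nws = hubnet.build_wave_networks(ws, means)
        recall, precision = hub_metrics(nws, truth, "WT")
        assert recall >= 0.9
        assert precision >= 0.8
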