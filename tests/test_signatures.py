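import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wavewire import signatures
from wavewire.io import GeneSetCollection
from wavewire.simulate import truth_gene_sets, typing_accuracy
from .conftest import build_study


def brute_force_ssgsea(values, ids, gene_set, alpha):
    """Independent running-sum evaluation, one explicit step per rank."""
    order = sorted(range(len(values)), key=lambda i: -values[i])
    in_set = [ids[i] in set(gene_set) for i in order]
    w = [abs(values[i]) ** alpha for i in order]
    denom_in = sum(wi for wi, m in zip(w, in_set) if m)
    n_out = len(values) - sum(in_set)
    score, p_in, p_out = 0.0, 0.0, 0.0
    for wi, m in zip(w, in_set):
        if m:
            p_in += wi / denom_in
        else:
            p_out += 1.0 / n_out
        score += p_in - p_out
    return score


class TestSsgsea:
    def test_top_gene_singleton_set_matches_brute_force(self):
        values = [3.0, 2.0, 1.0]
        ids = ["a", "b", "c"]
        got = signatures.ssgsea(np.array(values), ids, ["a"], alpha=0.25)
        assert got == pytest.approx(brute_force_ssgsea(values, ids, ["a"], 0.25))

    def test_random_profile_matches_brute_force(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(4, 14, 20)
        ids = [f"g{i}" for i in range(20)]
        gene_set = ["g3", "g7", "g11", "g19"]
        got = signatures.ssgsea(values, ids, gene_set, alpha=0.25)
        assert got == pytest.approx(
            brute_force_ssgsea(list(values), ids, gene_set, 0.25), abs=1e-12)

    def test_identical_profiles_identical_scores(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(4, 14, 30)
        ids = [f"g{i}" for i in range(30)]
        s1 = signatures.ssgsea(values, ids, ["g2", "g5"])
        s2 = signatures.ssgsea(values.copy(), ids, ["g2", "g5"])
        assert s1 == s2

    def test_alpha_zero_is_rank_only(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(1, 10, 25)
        ids = [f"g{i}" for i in range(25)]
        s1 = signatures.ssgsea(values, ids, ["g1", "g8"], alpha=0.0)
        s2 = signatures.ssgsea(np.exp(values), ids, ["g1", "g8"], alpha=0.0)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_sign_symmetry_on_reversed_ranking(self):
        # symmetric profile: reversing the ranking negates the score
        values = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        ids = list("abcdef")
        fwd = signatures.ssgsea(values, ids, ["a", "b"], alpha=1.0)
        rev = signatures.ssgsea(-values, ids, ["a", "b"], alpha=1.0)
        assert rev == pytest.approx(-fwd, abs=1e-12)

    def test_zero_overlap_errors(self):
        with pytest.raises(ValueError, match="no overlap"):
            signatures.ssgsea(np.array([1.0, 2.0]), ["a", "b"], ["zzz"])


class TestCorrelationBound:
    def test_r_crit_n6_value(self):
        assert signatures.pearson_r_crit(6, 0.05) == pytest.approx(0.811, abs=1e-3)

    def test_r_crit_inverts_t_transform(self):
        for n in (5, 6, 10, 30):
            r = signatures.pearson_r_crit(n, 0.05)
            t = r * np.sqrt((n - 2) / (1 - r * r))
            assert 2 * stats.t.sf(t, n - 2) == pytest.approx(0.05, abs=1e-10)


class TestTyping:
    @staticmethod
    def _study(member_profiles: dict[str, list[float]]):
        return build_study({"WT": member_profiles, "Onc": member_profiles})

    def test_shared_profile_is_coregulated_type2(self):
        p = [8, 9, 10, 9, 8, 7.0]
        study = self._study({f"m{i}": p for i in range(6)})
        t = signatures.intra_signature_typing(study, "WT", "sig",
                                              [f"m{i}" for i in range(6)])
        assert t.type == 2
        assert t.f_plus == 1.0 and t.f_minus == 0.0

    def test_anti_correlated_halves_are_bimodal_type4(self):
        p = np.array([8, 9, 10, 9, 8, 7.0])
        profiles = {f"u{i}": list(p) for i in range(5)}
        profiles |= {f"d{i}": list(16 - p) for i in range(5)}
        study = self._study(profiles)
        t = signatures.intra_signature_typing(study, "WT", "sig",
                                              list(profiles))
        assert t.type == 4
        assert t.f_plus == pytest.approx(20 / 45)
        assert t.f_minus == pytest.approx(25 / 45)

    def test_adding_coregulated_members_keeps_type2(self):
        p = [8, 9, 10, 9, 8, 7.0]
        for extra in (0, 3, 8):
            study = self._study({f"m{i}": p for i in range(5 + extra)})
            t = signatures.intra_signature_typing(
                study, "WT", "sig", [f"m{i}" for i in range(5 + extra)])
            assert t.type == 2

    def test_zero_variance_member_dropped_with_warning(self):
        profiles = {f"m{i}": [8, 9, 10, 9, 8, 7.0] for i in range(4)}
        profiles["flat"] = [8.0] * 6
        study = self._study(profiles)
        with pytest.warns(UserWarning, match="zero-variance"):
            t = signatures.intra_signature_typing(study, "WT", "sig",
                                                  list(profiles))
        assert "flat" not in t.r_matrix.index

    def test_planted_truth_type_calls(self, noisy_data):
        study, truth = noisy_data
        sets = truth_gene_sets(truth)
        for g in ("WT", "Onc"):
            table = signatures.type_all_signatures(study, sets, g)
            assert typing_accuracy(table, truth) >= 0.9


class TestKs:
    def test_identical_samples_d_zero(self):
        a = np.array([0.1, 0.5, 0.9])
        d, _ = signatures.compare_r_distributions(a, a.copy())
        assert d == 0.0

    def test_disjoint_supports_d_one(self):
        d, p = signatures.compare_r_distributions([-0.9, -0.8], [0.8, 0.9])
        assert d == 1.0
        assert p < 0.2

    def test_five_vs_five_matches_ecdf_scan(self):
        a = np.array([0.05, 0.2, 0.4, 0.6, 0.8])
        b = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        d, _ = signatures.compare_r_distributions(a, b)
        grid = np.concatenate([a, b])
        brute = max(abs((a <= x).mean() - (b <= x).mean()) for x in grid)
        assert d == pytest.approx(brute, abs=1e-12)


class TestSignatureClusters:
    def test_perfectly_correlated_trio_is_one_cluster(self):
        base = np.array([1, 2, 3, 4, 5, 6.0])
        profiles = pd.DataFrame([base, 2 * base, -base + 10],
                                index=["A", "B", "C"])
        out = signatures.signature_clusters(profiles)
        assert out.clusters[0] == ["A", "B", "C"]

    def test_chain_yields_two_overlapping_cliques(self):
        # B correlates with A and C; A and C are unrelated
        a = np.array([1, 2, 3, 4, 5, 6.0])
        c = np.array([1, 5, 2, 6, 3, 4.0])
        b = a + c
        assert stats.pearsonr(a, c).pvalue > 0.05
        profiles = pd.DataFrame([a, b, c], index=["A", "B", "C"])
        out = signatures.signature_clusters(profiles)
        assert sorted(map(tuple, out.clusters)) == [("A", "B"), ("B", "C")]

    def test_no_significant_pairs_all_singletons(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            profiles = pd.DataFrame(rng.normal(size=(3, 6)),
                                    index=["A", "B", "C"])
            out = signatures.signature_clusters(profiles)
            if all(len(c) == 1 for c in out.clusters):
                break
        else:
            pytest.fail("never found an all-insignificant draw")
        assert sorted(map(tuple, out.clusters)) == [("A",), ("B",), ("C",)]

    def test_constant_profile_excluded(self):
        base = np.array([1, 2, 3, 4, 5, 6.0])
        profiles = pd.DataFrame([base, 2 * base, np.full(6, 3.0)],
                                index=["A", "B", "flat"])
        with pytest.warns(UserWarning, match="constant"):
            out = signatures.signature_clusters(profiles)
        assert "flat" not in out.correlation.index

    def test_every_cluster_passes_pairwise_recheck(self, noisy_data):
        study, truth = noisy_data
        sets = truth_gene_sets(truth)
        profiles = signatures.enrichment_profiles(study, sets, "Onc")
        out = signatures.signature_clusters(profiles)
        for clique in out.clusters:
            for i, a in enumerate(clique):
                for b in clique[i + 1:]:
                    p = stats.pearsonr(profiles.loc[a], profiles.loc[b]).pvalue
                    assert p <= 0.05


class TestEnrichmentProfiles:
    def test_profile_shape_and_finiteness(self, noisy_data):
        study, truth = noisy_data
        sets = truth_gene_sets(truth)
        prof = signatures.enrichment_profiles(study, sets, "WT")
        assert prof.shape == (len(sets), 6)
        assert np.isfinite(prof.to_numpy()).all()

    def test_coregulated_signature_tracks_its_wave(self, zero_noise_data):
        study, truth = zero_noise_data
        sets = truth_gene_sets(truth)
        prof = signatures.enrichment_profiles(study, sets, "WT")
        from wavewire.simulate import wave_profile
        shape = wave_profile("WT", 0, 1.5)   # SIG_COREG_1 lives in WT wave 0
        r = stats.pearsonr(prof.loc["SIG_COREG_1"], shape).statistic
        assert r > 0.9
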