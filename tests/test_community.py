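"""Distance matrices, PCoA, MRPP and ANOVA for the non-target community."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import squareform

from weevilstats import (
    CommunityMatrix,
    DistanceMatrix,
    SimulationConfig,
    distance_matrix,
    mrpp,
    oneway_anova,
    pcoa,
    richness_abundance,
    simulate_community,
)


def naive_distance(x: np.ndarray, metric: str) -> np.ndarray:
    """Brute-force double-loop oracle for the three supported metrics."""
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a, b = x[i], x[j]
            if metric == "euclidean":
                d[i, j] = np.sqrt(((a - b) ** 2).sum())
            else:
                if metric == "sorensen":
                    a, b = (a > 0).astype(float), (b > 0).astype(float)
                denom = (a + b).sum()
                d[i, j] = 0.0 if denom == 0 else np.abs(a - b).sum() / denom
    return d


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        x = pd.DataFrame([[3, 1, 0], [3, 1, 0]])
        for metric in ("bray_curtis", "sorensen", "euclidean"):
            assert distance_matrix(x, metric).values[0, 1] == 0.0

    def test_disjoint_presence_sorensen_is_one(self):
        x = pd.DataFrame([[4, 0, 2], [0, 7, 0]])
        assert distance_matrix(x, "sorensen").values[0, 1] == 1.0

    @pytest.mark.parametrize("metric", ["bray_curtis", "sorensen", "euclidean"])
    def test_matches_naive_oracle(self, rng, metric):
        x = pd.DataFrame(rng.poisson(4.0, size=(6, 4)))
        dm = distance_matrix(x, metric)
        assert np.allclose(dm.values, naive_distance(x.to_numpy(float), metric), atol=1e-12)

    def test_all_zero_pair_warns_and_is_zero(self):
        x = pd.DataFrame([[0, 0], [0, 0], [1, 2]])
        with pytest.warns(UserWarning, match="all-zero"):
            dm = distance_matrix(x, "bray_curtis")
        assert dm.values[0, 1] == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="metric"):
            distance_matrix(pd.DataFrame([[1, 2], [3, 4]]), "manhattan")
        with pytest.raises(ValueError, match="two traps"):
            distance_matrix(pd.DataFrame([[1, 2]]), "euclidean")


class TestPCoA:
    def test_two_points_closed_form(self):
        d = 3.0
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, d], [d, 0.0]]), "euclidean")
        res = pcoa(dm)
        assert res.coordinates.shape == (2, 1)
        assert sorted(res.coordinates.iloc[:, 0]) == pytest.approx([-d / 2, d / 2])

    def test_euclidean_round_trip(self, rng):
        pts = rng.normal(size=(12, 2))
        x = pd.DataFrame(pts)
        dm = distance_matrix(x, "euclidean")
        res = pcoa(dm)
        coords = res.coordinates.to_numpy()
        recon = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(recon, dm.values, atol=1e-9)

    def test_all_identical_points(self):
        dm = DistanceMatrix(tuple("abc"), np.zeros((3, 3)), "euclidean")
        res = pcoa(dm)
        assert res.coordinates.shape[1] == 0

    def test_eigenvalues_match_skbio(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        x = pd.DataFrame(rng.poisson(5.0, size=(10, 6)))
        dm = distance_matrix(x, "bray_curtis")
        res = pcoa(dm)
        import skbio

        ref = skbio_ord.pcoa(skbio.DistanceMatrix(dm.values), method="eigh")
        ref_pos = np.sort(ref.eigvals[ref.eigvals > 1e-8])[::-1]
        assert np.allclose(np.sort(res.eigenvalues)[::-1], ref_pos, atol=1e-8)

    def test_truncation_warns(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 2)))
        dm = distance_matrix(x, "euclidean")
        with pytest.warns(UserWarning, match="truncated"):
            res = pcoa(dm, n_axes=4)
        assert res.coordinates.shape[1] <= 2


class TestMRPP:
    def test_perfect_separation(self):
        # two tight clusters far apart
        x = pd.DataFrame(
            np.vstack([np.zeros((6, 2)), 100 + np.zeros((6, 2))])
            + 0.01 * np.arange(12)[:, None]
        )
        dm = distance_matrix(x, "euclidean")
        res = mrpp(dm, ["g1"] * 6 + ["g2"] * 6, n_permutations=999, seed=0)
        assert res.A > 0.99
        # ties with the observed delta arise only when a shuffle recreates
        # the original split (~2/924 of relabellings), so p sits near its
        # 1/(1+B) floor
        assert res.p < 0.02

    def test_matches_exhaustive_enumeration(self, rng):
        """Monte-Carlo delta_expected/p agree with the exact average over all
        C(6,3) = 20 label assignments."""
        x = pd.DataFrame(rng.normal(size=(6, 3)))
        dm = distance_matrix(x, "euclidean")
        labels = ["a"] * 3 + ["b"] * 3

        def delta_for(assignment):
            tot = 0.0
            for g in ("a", "b"):
                idx = [i for i, lab in enumerate(assignment) if lab == g]
                pairs = list(itertools.combinations(idx, 2))
                tot += (len(idx) / 6) * np.mean([dm.values[i, j] for i, j in pairs])
            return tot

        all_deltas = []
        for combo in itertools.combinations(range(6), 3):
            assignment = ["b"] * 6
            for i in combo:
                assignment[i] = "a"
            all_deltas.append(delta_for(assignment))
        delta_obs = delta_for(labels)
        exact_expected = np.mean(all_deltas)
        exact_p = np.mean([d <= delta_obs + 1e-12 for d in all_deltas])

        res = mrpp(dm, labels, n_permutations=20000, seed=1)
        assert res.delta_observed == pytest.approx(delta_obs, abs=1e-12)
        assert res.delta_expected == pytest.approx(exact_expected, abs=0.01)
        assert res.p == pytest.approx(exact_p, abs=0.02)

    def test_null_A_centred_on_zero(self, rng):
        a_values = []
        for _ in range(50):
            x = pd.DataFrame(rng.poisson(6.0, size=(12, 5)))
            dm = distance_matrix(x, "bray_curtis")
            labels = ["g1"] * 6 + ["g2"] * 6
            res = mrpp(dm, labels, n_permutations=199, seed=int(rng.integers(2**31)))
            a_values.append(res.A)
            assert res.A <= 1.0
            assert res.p > 0.0  # add-one estimator never returns 0
        assert abs(np.mean(a_values)) < 0.05

    def test_treatment_effect_detected(self, rng):
        detected = 0
        for i in range(10):
            effect = {"control": 1.0, "fungi": 5.0, "halfmix": 1.0, "nematodes": 1.0}
            cfg = SimulationConfig(seed=300 + i, n_blocks=5, community_effect=effect)
            cm = simulate_community(cfg)
            dm = distance_matrix(cm, "bray_curtis")
            res = mrpp(dm, cm.grouping("treatment"), n_permutations=499, seed=i)
            detected += res.p < 0.05
        assert detected >= 7

    def test_singleton_group_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 2)))
        dm = distance_matrix(x, "euclidean")
        with pytest.raises(ValueError, match="singleton"):
            mrpp(dm, ["a", "a", "a", "a", "b"], n_permutations=99)

    def test_all_zero_distances(self):
        dm = DistanceMatrix(tuple("abcd"), np.zeros((4, 4)), "euclidean")
        res = mrpp(dm, ["a", "a", "b", "b"], n_permutations=99, seed=0)
        assert res.A == 0.0 and res.p == 1.0


class TestOnewayAnova:
    def test_identical_group_means(self):
        f, dfb, dfw, p = oneway_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert (dfb, dfw) == (1, 4)

    def test_two_groups_equal_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        f, dfb, dfw, p_f = oneway_anova(np.r_[a, b], ["a"] * 12 + ["b"] * 15)
        t, p_t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-9)

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        for _ in range(2000):
            y = rng.normal(size=24)
            _, _, _, p = oneway_anova(y, np.repeat(["a", "b", "c"], 8))
            rejections += p < 0.05
        assert 0.035 < rejections / 2000 < 0.065


class TestRichnessAbundance:
    def test_known_rows(self):
        cm = CommunityMatrix(
            counts=pd.DataFrame([[3, 0, 1], [0, 0, 0]], index=["t1", "t2"]),
            meta=pd.DataFrame({"block": ["B1", "B1"], "treatment": ["control", "fungi"]},
                              index=["t1", "t2"]),
        )
        ra = richness_abundance(cm)
        assert tuple(ra.loc["t1"]) == (4, 2)
        assert tuple(ra.loc["t2"]) == (0, 0)

    def test_matches_naive_loop(self, rng):
        counts = pd.DataFrame(rng.poisson(2.0, size=(8, 5)))
        meta = pd.DataFrame({"block": "B1", "treatment": "control"}, index=counts.index)
        ra = richness_abundance(CommunityMatrix(counts=counts, meta=meta))
        for i in counts.index:
            assert ra.loc[i, "abundance"] == sum(counts.loc[i])
            assert ra.loc[i, "richness"] == sum(1 for v in counts.loc[i] if v > 0)
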