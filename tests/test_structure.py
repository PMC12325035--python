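"""Weighted PCA against a dense eigen-oracle, bootstrap stability,
Hudson FST closed forms and parameter recovery, polygenic scores."""
import numpy as np
import pandas as pd
import pytest

import admixaudit as aa
from admixaudit.errors import DataError, ParameterError, SchemaError
from admixaudit.structure import _sample_weights, _standardize, procrustes_align
from conftest import make_cohort


def dense_eigen_oracle(genotypes, samples, weight_mode, k):
    """Independent full eigendecomposition of the weighted covariance."""
    w = _sample_weights(samples, weight_mode)
    x, used, _ = _standardize(genotypes, w)
    cov = x.T @ np.diag(w) @ x
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order][:k], x @ evecs[:, order][:, :k]


def assert_same_up_to_sign(a, b, atol=1e-8):
    for j in range(a.shape[1]):
        d = min(np.abs(a[:, j] - b[:, j]).max(), np.abs(a[:, j] + b[:, j]).max())
        assert d < atol, f"component {j} differs by {d}"


@pytest.fixture(scope="module")
def unbalanced_cohort():
    rng = np.random.default_rng(31)
    g = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
    g[2, 5] = -1
    return make_cohort(g, populations=["A"] * 9 + ["B"] * 3)


class TestWeightedPCA:

    def test_matches_dense_eigen_oracle(self, unbalanced_cohort):
        c = unbalanced_cohort
        res = aa.weighted_pca(c, aa.PCAConfig(k=4))
        evals, scores = dense_eigen_oracle(c.genotypes, c.samples, "inverse-group-size", 4)
        assert np.allclose(res.eigenvalues, evals, atol=1e-8)
        assert_same_up_to_sign(res.coordinates.to_numpy(), scores)

    def test_tiny_matrix_matches_oracle(self):
        g = np.array([[0, 2], [1, 1], [2, 0], [2, 2]], dtype=np.int8)
        c = make_cohort(g, populations=["A", "A", "B", "B"])
        res = aa.weighted_pca(c, aa.PCAConfig(k=2))
        evals, scores = dense_eigen_oracle(g, c.samples, "inverse-group-size", 2)
        assert np.allclose(res.eigenvalues, evals, atol=1e-8)
        assert_same_up_to_sign(res.coordinates.to_numpy(), scores)

    def test_equal_group_sizes_equals_uniform_pca(self):
        rng = np.random.default_rng(32)
        g = rng.integers(0, 3, size=(10, 25)).astype(np.int8)
        c = make_cohort(g, populations=["A"] * 5 + ["B"] * 5)
        inv = aa.weighted_pca(c, aa.PCAConfig(k=3))
        uni = aa.weighted_pca(c, aa.PCAConfig(k=3, weight_mode="uniform"))
        assert_same_up_to_sign(
            inv.coordinates.to_numpy(), uni.coordinates.to_numpy()
        )

    def test_total_weighted_variance_conserved(self, unbalanced_cohort):
        c = unbalanced_cohort
        k_full = min(c.n_samples, int(aa.weighted_pca(c, aa.PCAConfig(k=2)).used_variants.sum()))
        res = aa.weighted_pca(c, aa.PCAConfig(k=k_full))
        assert res.eigenvalues.sum() == pytest.approx(
            res.total_weighted_variance, abs=1e-8
        )
        assert (np.diff(res.eigenvalues) <= 1e-10).all()

    def test_k_too_large_rejected(self, unbalanced_cohort):
        with pytest.raises(ParameterError):
            aa.weighted_pca(unbalanced_cohort, aa.PCAConfig(k=500))

    def test_single_population_needs_uniform_mode(self):
        g = np.random.default_rng(0).integers(0, 3, size=(6, 10)).astype(np.int8)
        c = make_cohort(g)
        with pytest.raises(DataError):
            aa.weighted_pca(c, aa.PCAConfig(k=2))
        aa.weighted_pca(c, aa.PCAConfig(k=2, weight_mode="uniform"))

    def test_centroids_track_admixture_gradient(self):
        # population PC1 centroids should order by Native-ancestry fraction
        panel = aa.draw_ancestral_frequencies(4000, seed=33)
        pops = aa.default_populations(8)
        cohort = aa.simulate_admixed_cohort(panel, pops, seed=34)
        res = aa.weighted_pca(cohort, aa.PCAConfig(k=2))
        coords = res.coordinates.to_numpy()
        q_nat = {p.name: p.q["NAT"] for p in pops}
        names, cent = [], []
        for name in sorted(q_nat):
            sel = (cohort.samples["population"] == name).to_numpy()
            names.append(name)
            cent.append(coords[sel, 0].mean())
        from scipy.stats import spearmanr

        rho = abs(spearmanr([q_nat[n] for n in names], cent).statistic)
        assert rho > 0.9


class TestBootstrapStability:
    def test_degenerate_resampling_gives_zero_rmsd(self):
        # identical rows within each population: every resample is the same multiset
        row_a = np.array([0, 2, 0, 2, 1] * 4, dtype=np.int8)
        row_b = np.array([2, 0, 2, 0, 1] * 4, dtype=np.int8)
        g = np.stack([row_a] * 4 + [row_b] * 4)
        c = make_cohort(g, populations=["A"] * 4 + ["B"] * 4)
        res = aa.stratified_bootstrap_stability(c, aa.PCAConfig(k=1), B=5, seed=1)
        assert res.mean_rmsd == pytest.approx(0.0, abs=1e-10)

    def test_two_separated_populations_fully_consistent(self):
        panel = aa.draw_ancestral_frequencies(800, ancestries=("P",), F_between=0.2, seed=31)
        pops = [
            aa.PopulationSpec(name=n, n=50, F={"P": 0.1}, q={"P": 1.0})
            for n in ("A", "B")
        ]
        c = aa.simulate_admixed_cohort(panel, pops, seed=32)
        res = aa.stratified_bootstrap_stability(c, aa.PCAConfig(k=2), B=50, seed=33)
        assert (res.cluster_consistency == 1.0).all()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(40)
        g = rng.integers(0, 3, size=(20, 60)).astype(np.int8)
        c = make_cohort(g, populations=["A"] * 12 + ["B"] * 8)
        r1 = aa.stratified_bootstrap_stability(c, aa.PCAConfig(k=2), B=10, seed=41)
        r2 = aa.stratified_bootstrap_stability(c, aa.PCAConfig(k=2), B=10, seed=41)
        assert r1.mean_rmsd == r2.mean_rmsd
        pd.testing.assert_frame_equal(r1.per_sample_sd, r2.per_sample_sd)

    def test_singleton_population_flagged(self):
        rng = np.random.default_rng(42)
        g = rng.integers(0, 3, size=(9, 50)).astype(np.int8)
        c = make_cohort(g, populations=["A"] * 4 + ["B"] * 4 + ["LONE"])
        res = aa.stratified_bootstrap_stability(c, aa.PCAConfig(k=2), B=4, seed=2)
        assert res.singleton_populations == ["LONE"]

    def test_rmsd_invariant_to_rotation(self):
        rng = np.random.default_rng(50)
        x = rng.normal(size=(30, 2))
        ref = rng.normal(size=(30, 2))
        theta = 1.1
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        _, r1 = procrustes_align(x, ref)
        _, r2 = procrustes_align(x @ rot, ref)
        _, r3 = procrustes_align(x @ np.array([[1, 0], [0, -1]]), ref)  # reflection
        assert r1 == pytest.approx(r2, abs=1e-10)
        assert r1 == pytest.approx(r3, abs=1e-10)


class TestHudsonFST:
    def test_identical_frequencies_near_zero(self):
        panel = aa.draw_ancestral_frequencies(5000, ancestries=("P",), F_between=0.2, seed=51)
        pops = [
            aa.PopulationSpec(name=n, n=100, F={"P": 1e-9}, q={"P": 1.0})
            for n in ("A", "B")
        ]
        c = aa.simulate_admixed_cohort(panel, pops, seed=52)
        assert abs(aa.hudson_fst(c, "A", "B").mean_fst) < 0.01

    def test_fixed_difference_is_one(self):
        g = np.array([[0, 0], [0, 0], [2, 2], [2, 2]], dtype=np.int8)
        c = make_cohort(g, populations=["A", "A", "B", "B"])
        res = aa.hudson_fst(c, "A", "B")
        assert np.allclose(res.per_variant["fst"].dropna(), 1.0)

    def test_closed_form_two_frequency_case(self):
        # p1=0.2, p2=0.8 at large n: FST -> 0.36 / 0.68
        n = 2000
        g1 = np.zeros((n, 1), dtype=np.int8)
        g1[: int(0.2 * n)] = 2
        g2 = np.zeros((n, 1), dtype=np.int8)
        g2[: int(0.8 * n)] = 2
        c = make_cohort(np.vstack([g1, g2]), populations=["A"] * n + ["B"] * n)
        res = aa.hudson_fst(c, "A", "B")
        assert res.per_variant["fst"].iloc[0] == pytest.approx(0.36 / 0.68, abs=1e-3)

    def test_monomorphic_in_both_excluded_and_counted(self):
        g = np.array([[0, 2, 0], [0, 2, 1], [0, 2, 2], [0, 2, 2]], dtype=np.int8)
        c = make_cohort(g, populations=["A", "A", "B", "B"])
        res = aa.hudson_fst(c, "A", "B")
        assert res.n_excluded_monomorphic == 2
        assert res.n_used == 1

    def test_recovers_drift_parameter(self):
        # two populations drifted F=0.05 from one ancestral panel
        panel = aa.draw_ancestral_frequencies(10_000, ancestries=("P",), F_between=0.2, seed=11)
        F = 0.05
        pops = [
            aa.PopulationSpec(name=n, n=100, F={"P": F}, q={"P": 1.0})
            for n in ("A", "B")
        ]
        c = aa.simulate_admixed_cohort(panel, pops, seed=12)
        fst = aa.hudson_fst(c, "A", "B").mean_fst
        assert abs(fst - F) / F < 0.15

    def test_small_population_rejected(self):
        g = np.zeros((3, 4), dtype=np.int8)
        c = make_cohort(g, populations=["A", "A", "B"])
        with pytest.raises(DataError):
            aa.hudson_fst(c, "A", "B")


class TestUnweightedGRS:
    def _risk_table(self, cohort, n, risk_from="alt"):
        df = cohort.variants.data.iloc[:n][["chrom", "pos", "ref", "alt"]].copy()
        df["risk_allele"] = df["alt" if risk_from == "alt" else "ref"]
        return aa.VariantTable(df)

    def test_homozygous_carrier_maximum_score(self):
        g = np.full((1, 10), 2, dtype=np.int8)
        c = make_cohort(g)
        res = aa.unweighted_grs(c, self._risk_table(c, 10))
        assert float(res.per_sample.iloc[0]) == 20.0

    def test_risk_on_ref_allele_flips_dosage(self):
        g = np.zeros((2, 4), dtype=np.int8)
        c = make_cohort(g)
        res = aa.unweighted_grs(c, self._risk_table(c, 4, risk_from="ref"))
        assert (res.per_sample == 8.0).all()

    def test_all_missing_scores_expected_dosage(self):
        g = np.array([[1, 1], [1, 1], [-1, -1]], dtype=np.int8)
        c = make_cohort(g)
        res = aa.unweighted_grs(c, self._risk_table(c, 2))
        # population frequency 0.5 -> expected dosage 1 per variant
        assert float(res.per_sample.iloc[2]) == pytest.approx(2.0)

    def test_absent_risk_variants_reported(self):
        g = np.zeros((2, 3), dtype=np.int8)
        c = make_cohort(g)
        df = pd.DataFrame(
            {"chrom": ["1", "9"], "pos": [100, 12345], "ref": ["A", "C"],
             "alt": ["G", "T"], "risk_allele": ["G", "T"]}
        )
        res = aa.unweighted_grs(c, aa.VariantTable(df))
        assert len(res.missing_risk_variants) == 1
        assert res.n_risk_variants_used == 1

    def test_zero_overlap_raises(self):
        g = np.zeros((2, 2), dtype=np.int8)
        c = make_cohort(g)
        df = pd.DataFrame(
            {"chrom": ["9"], "pos": [999], "ref": ["A"], "alt": ["G"],
             "risk_allele": ["G"]}
        )
        with pytest.raises(DataError):
            aa.unweighted_grs(c, aa.VariantTable(df))

    def test_elevated_population_ranks_highest(self):
        # risk alleles at higher frequency in population A: A should have the
        # top mean GRS in >95% of replicates
        rng = np.random.default_rng(60)
        wins = 0
        B = 100
        for _ in range(B):
            m, n = 30, 25
            pa, po = 0.6, 0.3
            blocks = []
            for p in (pa, po, po):
                blocks.append(
                    ((rng.random((n, m)) < p).astype(np.int8)
                     + (rng.random((n, m)) < p)).astype(np.int8)
                )
            c = make_cohort(
                np.vstack(blocks), populations=["A"] * n + ["B"] * n + ["C"] * n
            )
            res = aa.unweighted_grs(c, self._risk_table(c, m))
            if res.per_population["mean"].idxmax() == "A":
                wins += 1
        assert wins / B > 0.95
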