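"""QC metrics, the HWE exact test against an integer-enumeration oracle,
relatedness pruning, audits and categorical summaries."""
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import admixaudit as aa
from admixaudit.errors import DataError, ParameterError
from admixaudit._util import alt_allele_freq
from conftest import make_cohort


def hwe_enumeration_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-integer Levene–Haldane enumeration, independent of the
    implementation's floating-point recurrence."""
    n = n_hom_ref + n_het + n_hom_alt
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_minor = (rare - h) // 2
        hom_major = n - h - hom_minor
        weights[h] = (
            math.factorial(n)
            // (math.factorial(hom_minor) * math.factorial(h) * math.factorial(hom_major))
            * 2**h
        )
    total = sum(weights.values())
    w_obs = weights[n_het]
    return sum(w for w in weights.values() if w <= w_obs) / total


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert aa.hwe_exact_pvalue(5, 0, 0) == 1.0
        assert aa.hwe_exact_pvalue(0, 0, 7) == 1.0

    def test_mode_table_is_one(self):
        # observed het count is the Levene-Haldane mode for (25, 50, 25)
        assert aa.hwe_exact_pvalue(25, 50, 25) == pytest.approx(1.0, abs=1e-12)

    def test_all_homozygote_table_is_extreme_tail(self):
        # exact enumeration gives 252/184756 for (5, 0, 5)
        p = aa.hwe_exact_pvalue(5, 0, 5)
        assert p == pytest.approx(252 / 184756, abs=1e-12)
        assert p < 0.01

    def test_matches_enumeration_oracle_small_sweep(self):
        for n in range(1, 16):
            for n_alt in range(0, 2 * n + 1):
                for h in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
                    hom_alt = (n_alt - h) // 2
                    hom_ref = n - h - hom_alt
                    got = aa.hwe_exact_pvalue(hom_ref, h, hom_alt)
                    want = hwe_enumeration_oracle(hom_ref, h, hom_alt)
                    assert got == pytest.approx(want, abs=1e-12), (hom_ref, h, hom_alt)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            aa.hwe_exact_pvalue(-1, 0, 0)
        with pytest.raises(ParameterError):
            aa.hwe_exact_pvalue(0, 0, 0)


class TestVariantQC:
    def test_forced_arithmetic(self):
        cohort = make_cohort(np.array([[0], [0], [1], [1], [2], [2]]))
        res = aa.variant_qc(cohort)
        assert res.metrics["maf"].iloc[0] == pytest.approx(0.5)
        assert res.metrics["call_rate"].iloc[0] == pytest.approx(1.0)
        assert res.metrics["het_rate"].iloc[0] == pytest.approx(2 / 6)

    def test_call_rate_threshold(self):
        g = np.zeros((10, 2), dtype=np.int8)
        g[:, 1] = 1  # keep variant 2 polymorphic
        g[:5, 0] = 1
        g[0, 0] = -1  # 90% call rate on variant 1
        cohort = make_cohort(g)
        res = aa.variant_qc(cohort, aa.QCThresholds(min_call_rate=0.95, min_maf=0.0))
        assert not res.mask[0]
        assert res.mask[1]

    def test_all_missing_variant_undefined_and_fails(self):
        g = np.array([[0, -1], [1, -1], [2, -1]], dtype=np.int8)
        res = aa.variant_qc(make_cohort(g))
        assert np.isnan(res.metrics["maf"].iloc[1])
        assert not res.mask[1]

    def test_empty_cohort_raises(self):
        with pytest.raises(DataError):
            aa.variant_qc(make_cohort(np.zeros((0, 0), dtype=np.int8)))

    def test_hwe_null_false_positive_rate_below_5pct(self):
        # 10,000 variants simulated under HWE; threshold 1e-6
        rng = np.random.default_rng(17)
        m, n = 10_000, 100
        p = rng.uniform(0.05, 0.5, size=m)
        g = (rng.random((n, m)) < p).astype(np.int8) + (rng.random((n, m)) < p)
        cohort = make_cohort(g.astype(np.int8))
        res = aa.variant_qc(cohort)
        frac_fail = (res.metrics["hwe_p"] < 1e-6).mean()
        assert frac_fail < 0.05

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_maf_invariant_to_ref_alt_swap(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(-1, 3, size=(12, 20)).astype(np.int8)
        swapped = np.where(g >= 0, 2 - g, g).astype(np.int8)
        p = alt_allele_freq(g)
        q = alt_allele_freq(swapped)
        both = ~np.isnan(p)
        assert np.allclose(
            np.minimum(p[both], 1 - p[both]), np.minimum(q[both], 1 - q[both])
        )


@pytest.fixture(scope="module")
def one_pop_cohort():
    panel = aa.draw_ancestral_frequencies(10_000, seed=21)
    pop = aa.PopulationSpec(
        name="A", n=40, F={"NAT": 0.02, "EUR": 0.02, "AFR": 0.02}, q={"NAT": 1.0}
    )
    return aa.simulate_admixed_cohort(panel, [pop], seed=22)


class TestKinship:

    def test_duplicate_sample_pihat_near_one(self, one_pop_cohort):
        c = one_pop_cohort
        g = np.vstack([c.genotypes, c.genotypes[:1]])
        samples = pd.concat(
            [c.samples, c.samples.iloc[:1].assign(sample_id="DUP")], ignore_index=True
        )
        cd = aa.Cohort(genotypes=g, variants=c.variants, samples=samples)
        pairs = aa.kinship_pihat(cd)
        dup = pairs[(pairs.sample_a == "A_000") & (pairs.sample_b == "DUP")]
        assert float(dup["pihat"].iloc[0]) == pytest.approx(1.0, abs=0.02)

    def test_unrelated_samples_pihat_near_zero(self, one_pop_cohort):
        pairs = aa.kinship_pihat(one_pop_cohort)
        assert abs(pairs["pihat"].mean()) < 0.05

    def test_single_sample_returns_empty_table(self, one_pop_cohort):
        pairs = aa.kinship_pihat(one_pop_cohort.subset_samples([0]))
        assert len(pairs) == 0


class TestIBDPrune:
    def _dup_cohort(self, missing_in="first"):
        rng = np.random.default_rng(5)
        base = (rng.random(4000) < 0.4).astype(np.int8) + (rng.random(4000) < 0.4)
        g = np.stack([base, base.copy(), rng.integers(0, 3, 4000)]).astype(np.int8)
        if missing_in == "first":
            g[0, :200] = -1
        return make_cohort(g, populations=["P", "P", "P"])

    def test_lower_call_rate_member_removed(self):
        cohort = self._dup_cohort()
        pruned, log = aa.ibd_prune(cohort)
        assert list(log["removed"]) == ["s000"]  # s000 has the missing calls
        assert "s000" not in set(pruned.samples["sample_id"])

    def test_tie_breaks_on_lexicographic_id(self):
        cohort = self._dup_cohort(missing_in=None)
        pruned, log = aa.ibd_prune(cohort)
        assert list(log["removed"]) == ["s001"]  # equal call rates: larger ID goes

    def test_pruning_is_idempotent(self):
        cohort = self._dup_cohort()
        once, log1 = aa.ibd_prune(cohort)
        twice, log2 = aa.ibd_prune(once)
        assert once.samples.equals(twice.samples)
        assert len(log2) == 0


class TestSampleSizeAudit:
    def _meta(self, sizes):
        rows = []
        for i, n in enumerate(sizes):
            rows += [{"sample_id": f"p{i}_{j}", "population": f"P{i:02d}"} for j in range(n)]
        return pd.DataFrame(rows)

    def test_study_layout_flags_42_percent(self):
        # 26 populations, 11 below 30, 4 below 10, sizes spanning 8:1
        sizes = [80, 75, 70, 65, 60, 55, 50, 45, 42, 40, 38, 36, 34, 32, 30,
                 28, 26, 24, 22, 20, 18, 9, 9, 8, 7, 10]
        audit = aa.sample_size_audit(self._meta(sizes))
        assert audit.n_populations == 26
        assert audit.n_below_min == 11
        assert audit.pct_below_min == 42.0
        assert audit.n_below_critical == 4
        assert audit.size_ratio == pytest.approx(80 / 7)

    def test_all_above_threshold(self):
        audit = aa.sample_size_audit(self._meta([40, 50, 60]))
        assert audit.pct_below_min == 0.0
        assert audit.size_ratio == pytest.approx(1.5)

    def test_eight_to_one_ratio(self):
        audit = aa.sample_size_audit(self._meta([80, 30, 10]))
        assert audit.size_ratio == pytest.approx(8.0)

    def test_empty_metadata_raises(self):
        with pytest.raises(DataError):
            aa.sample_size_audit(pd.DataFrame())


class TestPhenotypeSummary:
    def test_cohort_style_sex_percentages(self):
        # 382/1149 = 33.246% and 767/1149 = 66.754%: one-decimal rounding
        # half away from zero gives 33.2 / 66.8
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(1149)],
                "ancestry_group": ["native"] * 506 + ["mestizo"] * 643,
                "sex": ["female"] * 382 + ["male"] * 767,
            }
        )
        out = aa.phenotype_summary(meta, columns={"sex": ["female", "male"]})
        all_rows = out[(out.group == "All")].set_index("category")
        assert all_rows.loc["female", "n"] == 382
        assert all_rows.loc["female", "pct"] == 33.2
        assert all_rows.loc["male", "pct"] == 66.8

    def test_single_category_is_100(self):
        meta = pd.DataFrame(
            {"sample_id": ["a", "b"], "ancestry_group": ["native", "native"],
             "smoke": ["never", "never"]}
        )
        out = aa.phenotype_summary(meta, columns={"smoke": None})
        assert set(out["pct"]) == {100.0}

    def test_unknown_category_counted_as_other_with_warning(self):
        meta = pd.DataFrame(
            {"sample_id": ["a", "b", "c"], "ancestry_group": ["x", "x", "x"],
             "diet": ["veg", "veg", "mystery"]}
        )
        with pytest.warns(UserWarning):
            out = aa.phenotype_summary(meta, columns={"diet": ["veg"]})
        other = out[(out.category == "other") & (out.group == "All")]
        assert int(other["n"].iloc[0]) == 1

    def test_flagged_and_unflagged_percent_sum_to_100(self):
        audit = aa.sample_size_audit(
            pd.DataFrame(
                {"sample_id": [str(i) for i in range(90)],
                 "population": ["A"] * 50 + ["B"] * 25 + ["C"] * 15}
            )
        )
        assert audit.pct_below_min + (100 - audit.pct_below_min) == 100
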