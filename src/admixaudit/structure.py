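"""Sample-size-bias-corrected population structure.

Unequal group sizes let large populations dominate both the allele-frequency
estimates and the covariance that PCA diagonalizes.  The correction here
assigns each sample the weight ``w_i = 1 / n_{g(i)}`` (normalized to sum 1),
and uses the weights twice: in the allele-frequency estimate that centers and
scales the genotype matrix, and in the covariance itself — otherwise large
groups would still dominate the centering.  Stability under resampling is
quantified with a stratified bootstrap: individuals are resampled with
replacement within each population, the weighted PCA re-run, and each
replicate Procrustes-aligned (rotation, reflection, scaling, translation) to
the full-data solution.

Also here: the Hudson FST estimator (ratio-of-averages across sites) and
unweighted polygenic risk scores (risk-allele counts).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes, svd
from sklearn.utils.extmath import randomized_svd

from ._util import as_seed_sequence
from .errors import DataError, ParameterError, SchemaError
from .types import Cohort, PCAConfig, VariantTable, variant_key

#: Matrices with at most this many cells use exact LAPACK SVD; larger ones a
#: seeded randomized SVD (accurate to well below bootstrap noise).
_EXACT_SVD_CELLS = 2_000_000


# ---------------------------------------------------------------------------
# Weighted PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coordinates: pd.DataFrame      # samples x k, columns PC1..PCk
    eigenvalues: np.ndarray        # non-increasing, weighted variances
    weights: pd.Series             # per-sample weight, sums to 1
    used_variants: np.ndarray      # mask of variants with nonzero weighted variance
    total_weighted_variance: float


def _sample_weights(samples: pd.DataFrame, mode: str) -> np.ndarray:
    n = len(samples)
    if mode == "uniform":
        w = np.full(n, 1.0 / n)
    else:
        counts = samples["population"].value_counts()
        zero = counts[counts == 0]
        if len(zero):
            raise DataError(f"population(s) with no samples after QC: {list(zero.index)}")
        w = 1.0 / counts.loc[samples["population"]].to_numpy(dtype=float)
        w /= w.sum()
    return w


def _standardize(genotypes: np.ndarray, w: np.ndarray):
    """Weighted-frequency centering/scaling with mean imputation of missing."""
    g = genotypes.astype(np.float64)
    obs = genotypes >= 0
    w_col = (w[:, None] * obs).sum(axis=0)
    p_hat = np.where(
        w_col > 0, (np.where(obs, g, 0.0) * w[:, None]).sum(axis=0) / (2.0 * np.maximum(w_col, 1e-300)), np.nan
    )
    with np.errstate(invalid="ignore"):
        scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    used = np.nan_to_num(scale, nan=0.0) > 0
    x = np.where(obs, g, 2.0 * p_hat[None, :])  # mean imputation
    x = (x - 2.0 * p_hat[None, :])[:, used] / scale[used][None, :]
    return x, used, p_hat


def weighted_pca(cohort: Cohort, config: PCAConfig | None = None) -> PCAResult:
    """PCA of the weighted genotype covariance.

    Genotypes are mean-imputed at the weighted allele frequency, centered at
    ``2 p_hat`` and scaled by ``sqrt(2 p_hat (1 - p_hat))``; the
    decomposition is of ``X^T W X`` with ``W = diag(w)``.  All samples are
    projected onto the component loadings, and each component's sign is fixed
    so its largest-magnitude loading is positive.
    """
    config = config or PCAConfig()
    if cohort.n_samples < 2:
        raise DataError("need at least 2 samples for PCA")
    if config.weight_mode == "inverse-group-size":
        if cohort.samples["population"].nunique() < 2:
            raise DataError("inverse-group-size weighting needs >= 2 populations")
    w = _sample_weights(cohort.samples, config.weight_mode)
    x, used, _ = _standardize(cohort.genotypes, w)
    n, m_used = x.shape
    if config.k > min(n, m_used):
        raise ParameterError(
            f"k={config.k} exceeds min(samples, usable variants)={min(n, m_used)}"
        )
    y = np.sqrt(w)[:, None] * x
    if n * m_used <= _EXACT_SVD_CELLS:
        _, s, vt = svd(y, full_matrices=False)
        s, vt = s[: config.k], vt[: config.k]
    else:
        _, s, vt = randomized_svd(
            y, n_components=config.k, n_oversamples=10, n_iter=7,
            random_state=config.seed,
        )
    v = vt.T
    # sign convention: largest-magnitude loading of each component positive
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    v = v * flip[None, :]
    scores = x @ v
    coords = pd.DataFrame(
        scores,
        index=cohort.samples["sample_id"],
        columns=[f"PC{i + 1}" for i in range(v.shape[1])],
    )
    return PCAResult(
        coordinates=coords,
        eigenvalues=s**2,
        weights=pd.Series(w, index=cohort.samples["sample_id"], name="weight"),
        used_variants=used,
        total_weighted_variance=float(np.sum(y**2)),
    )


# ---------------------------------------------------------------------------
# Stratified bootstrap stability
# ---------------------------------------------------------------------------

def procrustes_align(x: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, float]:
    """Align ``x`` onto ``ref`` by translation, rotation/reflection and
    scaling; returns the aligned coordinates and the RMSD in the reference
    frame.  Invariant to any global rotation/reflection of ``x``."""
    if x.shape != ref.shape:
        raise ParameterError(f"shape mismatch {x.shape} vs {ref.shape}")
    mu_x, mu_r = x.mean(axis=0), ref.mean(axis=0)
    xc, rc = x - mu_x, ref - mu_r
    norm_sq = float(np.sum(xc**2))
    if norm_sq == 0:
        aligned = np.broadcast_to(mu_r, ref.shape).copy()
        return aligned, float(np.sqrt(np.mean(rc**2)))
    rot, scale_num = orthogonal_procrustes(xc, rc)
    aligned = (scale_num / norm_sq) * xc @ rot + mu_r
    rmsd = float(np.sqrt(np.mean((aligned - ref) ** 2)))
    return aligned, rmsd


@dataclass
class BootstrapResult:
    B: int
    mean_rmsd: float
    per_sample_sd: pd.DataFrame       # per-sample, per-component SD of aligned coords
    cluster_consistency: pd.Series    # per population, fraction of replicates with
                                      # unchanged nearest-centroid neighbour
    singleton_populations: list[str]  # size-1 groups: resampled as themselves


def _nearest_centroids(coords: np.ndarray, pops: np.ndarray) -> dict[str, str]:
    labels = np.unique(pops)
    cents = {p: coords[pops == p].mean(axis=0) for p in labels}
    nearest = {}
    for p in labels:
        others = [q for q in labels if q != p]
        if not others:
            return {}
        d = [float(np.linalg.norm(cents[p] - cents[q])) for q in others]
        nearest[p] = others[int(np.argmin(d))]
    return nearest


def stratified_bootstrap_stability(
    cohort: Cohort,
    config: PCAConfig | None = None,
    B: int = 100,
    seed=None,
) -> BootstrapResult:
    """Bootstrap the weighted PCA by resampling individuals within populations.

    Each replicate resamples every population with replacement at its own
    size, re-runs :func:`weighted_pca`, and is Procrustes-aligned to the
    full-data solution on the samples it contains.  Reported: the mean
    Procrustes RMSD, the per-sample SD of aligned coordinates across the
    replicates containing the sample, and per-population nearest-centroid
    consistency.  Size-1 populations are resampled as themselves and flagged.
    """
    if B < 2:
        raise ParameterError("B must be >= 2")
    config = config or PCAConfig()
    full = weighted_pca(cohort, config)
    ref = full.coordinates.to_numpy()
    pops_all = cohort.samples["population"].to_numpy()
    counts = cohort.samples["population"].value_counts()
    singletons = sorted(counts[counts == 1].index)
    full_nearest = _nearest_centroids(ref, pops_all)
    pop_indices = {
        p: np.flatnonzero(pops_all == p) for p in counts.index
    }
    seeds = as_seed_sequence(seed).spawn(B)
    k = ref.shape[1]
    n = cohort.n_samples
    sum_c = np.zeros((n, k))
    sum_c2 = np.zeros((n, k))
    n_present = np.zeros(n)
    rmsds = []
    consistent = {p: 0 for p in full_nearest}
    for child in seeds:
        rng = np.random.default_rng(child)
        idx = np.concatenate(
            [rng.choice(ix, size=ix.size, replace=True) for ix in pop_indices.values()]
        )
        # resampled duplicates need unique ids for the container contract
        rep_samples = cohort.samples.iloc[idx].reset_index(drop=True)
        rep_samples = rep_samples.assign(
            sample_id=[f"{s}__r{i}" for i, s in enumerate(rep_samples["sample_id"])]
        )
        rep = Cohort(
            genotypes=cohort.genotypes[idx],
            variants=cohort.variants,
            samples=rep_samples,
        )
        res = weighted_pca(rep, config)
        coords = res.coordinates.to_numpy()
        uniq, first = np.unique(idx, return_index=True)
        aligned_sub, rmsd = procrustes_align(coords[first], ref[uniq])
        rmsds.append(rmsd)
        sum_c[uniq] += aligned_sub
        sum_c2[uniq] += aligned_sub**2
        n_present[uniq] += 1
        # centroid consistency on the full replicate (all drawn individuals)
        aligned_all, _ = procrustes_align(coords, ref[idx])
        rep_nearest = _nearest_centroids(aligned_all, pops_all[idx])
        for p, q in full_nearest.items():
            if rep_nearest.get(p) == q:
                consistent[p] += 1
    with np.errstate(invalid="ignore"):
        mean_c = sum_c / n_present[:, None]
        var_c = np.maximum(sum_c2 / n_present[:, None] - mean_c**2, 0.0)
    per_sample_sd = pd.DataFrame(
        np.sqrt(var_c),
        index=cohort.samples["sample_id"],
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    consistency = pd.Series(
        {p: consistent[p] / B for p in sorted(full_nearest)}, name="consistency"
    )
    return BootstrapResult(
        B=B,
        mean_rmsd=float(np.mean(rmsds)),
        per_sample_sd=per_sample_sd,
        cluster_consistency=consistency,
        singleton_populations=singletons,
    )


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------

@dataclass
class FSTResult:
    per_variant: pd.DataFrame      # numerator, denominator, fst (NaN if excluded)
    mean_fst: float                # ratio of averages
    n_used: int
    n_excluded_monomorphic: int


def hudson_fst(cohort: Cohort, pop_a: str, pop_b: str) -> FSTResult:
    """Hudson's FST estimator with sample-size correction, per variant, and
    the ratio-of-averages mean across variants.

    Per variant, with allele frequencies ``p1, p2`` and allele counts
    ``n1, n2``: numerator ``(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)``,
    denominator ``p1(1-p2) + p2(1-p1)``.  Sites monomorphic in both
    populations are excluded from the mean and counted; negative per-variant
    values are retained.
    """
    pops = cohort.samples["population"]
    sel_a = (pops == pop_a).to_numpy()
    sel_b = (pops == pop_b).to_numpy()
    for name, sel in ((pop_a, sel_a), (pop_b, sel_b)):
        if sel.sum() < 2:
            raise DataError(f"population {name!r} has fewer than 2 samples")

    def _freq_counts(sel):
        g = cohort.genotypes[sel]
        obs = g >= 0
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        return p, n_alleles

    p1, n1 = _freq_counts(sel_a)
    p2, n2 = _freq_counts(sel_b)
    valid = (n1 >= 2) & (n2 >= 2) & ~np.isnan(p1) & ~np.isnan(p2)
    mono_both = valid & (
        ((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1))
    )
    use = valid & ~mono_both
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
            - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = np.where(use & (den > 0), num / np.where(den > 0, den, 1.0), np.nan)
    per_variant = pd.DataFrame(
        {
            "numerator": np.where(use, num, np.nan),
            "denominator": np.where(use, den, np.nan),
            "fst": fst,
        }
    )
    if use.sum() == 0 or np.nansum(den[use]) == 0:
        raise DataError(f"no usable polymorphic variants between {pop_a} and {pop_b}")
    mean = float(np.nansum(num[use]) / np.nansum(den[use]))
    return FSTResult(
        per_variant=per_variant,
        mean_fst=mean,
        n_used=int(use.sum()),
        n_excluded_monomorphic=int(mono_both.sum()),
    )


def pairwise_fst(cohort: Cohort, populations: list[str] | None = None) -> pd.DataFrame:
    """Symmetric matrix of mean Hudson FST for all population pairs."""
    pops = populations or sorted(cohort.samples["population"].unique())
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            f = hudson_fst(cohort, a, b).mean_fst
            mat.loc[a, b] = mat.loc[b, a] = f
    return mat


# ---------------------------------------------------------------------------
# Unweighted polygenic risk scores
# ---------------------------------------------------------------------------

@dataclass
class GRSResult:
    per_sample: pd.Series
    per_population: pd.DataFrame   # mean, sd, n
    rank_test_p: float | None      # Kruskal-Wallis across populations
    n_risk_variants_used: int
    missing_risk_variants: list[tuple]


def unweighted_grs(cohort: Cohort, risk_variants: VariantTable) -> GRSResult:
    """Per-sample count of risk alleles across a risk-variant list.

    ``risk_variants`` must carry a ``risk_allele`` column naming either the
    ref or the alt allele of each variant.  Missing genotypes contribute the
    sample's expected dosage, ``2 x`` the risk-allele frequency in the
    sample's population.  Risk variants absent from the cohort are reported,
    not silently dropped.
    """
    if "risk_allele" not in risk_variants.data.columns:
        raise SchemaError("risk variant table lacks a risk_allele column")
    key_to_col = {k: j for j, k in enumerate(cohort.variants.keys())}
    cols, flip, missing = [], [], []
    for _, row in risk_variants.data.iterrows():
        key = variant_key(row["chrom"], row["pos"], row["ref"], row["alt"])
        j = key_to_col.get(key)
        if j is None:
            missing.append(key)
            continue
        risk = str(row["risk_allele"]).upper()
        if risk == cohort.variants.data["alt"].iat[j]:
            flip.append(False)
        elif risk == cohort.variants.data["ref"].iat[j]:
            flip.append(True)
        else:
            raise SchemaError(
                f"risk allele {risk!r} matches neither allele of variant {key}"
            )
        cols.append(j)
    if not cols:
        raise DataError("no risk variants overlap the cohort")
    g = cohort.genotypes[:, cols].astype(float)
    g[g < 0] = np.nan
    dose = np.where(np.isnan(g), np.nan, np.where(np.array(flip)[None, :], 2.0 - g, g))
    pops = cohort.samples["population"].to_numpy()
    for p in np.unique(pops):
        sel = pops == p
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pop_mean = np.nanmean(dose[sel], axis=0)
        pop_mean = np.nan_to_num(pop_mean, nan=0.0)
        block = dose[sel]
        block[np.isnan(block)] = np.broadcast_to(pop_mean, block.shape)[np.isnan(block)]
        dose[sel] = block
    scores = pd.Series(
        dose.sum(axis=1), index=cohort.samples["sample_id"], name="grs"
    )
    per_pop = (
        pd.DataFrame({"grs": scores.to_numpy(), "population": pops})
        .groupby("population")["grs"]
        .agg(mean="mean", sd="std", n="size")
    )
    groups = [scores.to_numpy()[pops == p] for p in per_pop.index]
    rank_p = None
    if len(groups) >= 2 and all(len(gr) > 0 for gr in groups):
        rank_p = float(stats.kruskal(*groups).pvalue)
    return GRSResult(
        per_sample=scores,
        per_population=per_pop,
        rank_test_p=rank_p,
        n_risk_variants_used=len(cols),
        missing_risk_variants=missing,
    )


@dataclass
class StructureResult:
    """Aggregate result bundle for the structure stage."""

    pca: PCAResult
    bootstrap: BootstrapResult | None = None
    fst: pd.DataFrame | None = None
    grs: GRSResult | None = None
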