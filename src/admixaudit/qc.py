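"""Per-variant and per-sample QC, HWE exact test, IBD pruning, cohort audits.

Default thresholds follow common array/WGS practice: call rate >= 0.95,
MAF >= 0.01, HWE exact p >= 1e-6, pairwise pi-hat <= 0.185 (halfway between
second- and third-degree relatives).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import alt_allele_freq, round_half_away
from .errors import DataError, ParameterError
from .types import Cohort, QCThresholds


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE test (Levene–Haldane distribution).

    The p-value is the total probability, over all heterozygote counts
    compatible with the observed allele counts, of outcomes no more probable
    than the observed one.  Monomorphic variants return 1 by convention.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or int(c) != c for c in counts):
        raise ParameterError(f"genotype counts must be non-negative integers: {counts}")
    n = int(sum(counts))
    if n < 1:
        raise ParameterError("need at least one genotyped individual")
    n_het = int(n_het)
    rare = min(2 * int(n_hom_ref) + n_het, 2 * int(n_hom_alt) + n_het)
    if rare == 0:
        return 1.0
    # Unnormalized probabilities over het counts h (same parity as rare),
    # built outward from the distribution's mode for numerical stability.
    mode = int(round(rare * (2 * n - rare) / (2.0 * n - 1.0)))
    if mode % 2 != rare % 2:
        mode += 1 if mode < rare else -1
    mode = min(max(mode, rare % 2), rare)

    def _ratio_up(h):  # P(h+2)/P(h)
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))

    probs = {mode: 1.0}
    h = mode
    while h + 2 <= rare:
        probs[h + 2] = probs[h] * _ratio_up(h)
        h += 2
    h = mode
    while h - 2 >= 0:
        probs[h - 2] = probs[h] / _ratio_up(h - 2)
        h -= 2
    total = sum(probs.values())
    p_obs = probs[n_het]
    p = sum(v for v in probs.values() if v <= p_obs * (1.0 + 1e-12)) / total
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Variant / sample QC
# ---------------------------------------------------------------------------

@dataclass
class VariantQCResult:
    metrics: pd.DataFrame            # call_rate, maf, het_rate, hwe_p per variant
    mask: np.ndarray                 # True = variant passes all thresholds
    sample_call_rates: pd.Series
    frac_samples_passing: float
    thresholds: QCThresholds


def variant_qc(cohort: Cohort, thresholds: QCThresholds | None = None) -> VariantQCResult:
    """Call rate, MAF (non-missing genotypes), heterozygosity and HWE exact p
    per variant, with the combined pass/fail mask."""
    if cohort.n_variants == 0 or cohort.n_samples == 0:
        raise DataError("cohort is empty")
    thresholds = thresholds or QCThresholds()
    g = cohort.genotypes
    observed = g >= 0
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / cohort.n_samples
    p_alt = alt_allele_freq(g)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    with np.errstate(invalid="ignore"):
        het_rate = np.where(n_obs > 0, (g == 1).sum(axis=0) / np.maximum(n_obs, 1), np.nan)
    hom_ref = (g == 0).sum(axis=0)
    het = (g == 1).sum(axis=0)
    hom_alt = (g == 2).sum(axis=0)
    hwe_p = np.array(
        [
            hwe_exact_pvalue(int(a), int(b), int(c)) if (a + b + c) > 0 else np.nan
            for a, b, c in zip(hom_ref, het, hom_alt)
        ]
    )
    metrics = pd.DataFrame(
        {"call_rate": call_rate, "maf": maf, "het_rate": het_rate, "hwe_p": hwe_p}
    )
    with np.errstate(invalid="ignore"):
        mask = (
            (call_rate >= thresholds.min_call_rate)
            & np.nan_to_num(maf >= thresholds.min_maf, nan=False)
            & np.nan_to_num(hwe_p >= thresholds.min_hwe_p, nan=False)
        )
    sample_cr = pd.Series(
        observed.sum(axis=1) / max(cohort.n_variants, 1),
        index=cohort.samples["sample_id"],
        name="call_rate",
    )
    return VariantQCResult(
        metrics=metrics,
        mask=np.asarray(mask),
        sample_call_rates=sample_cr,
        frac_samples_passing=float((sample_cr >= thresholds.min_call_rate).mean()),
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# Relatedness (method-of-moments pi-hat) and IBD pruning
# ---------------------------------------------------------------------------

def kinship_pihat(
    cohort: Cohort, min_maf: float = 0.01, max_variants: int | None = 20_000
) -> pd.DataFrame:
    """Pairwise pi-hat via the classic method-of-moments on IBS sharing.

    Allele frequencies are estimated from the cohort itself; variants below
    ``min_maf`` are excluded, and at most ``max_variants`` (deterministic
    stride) are used.  Returns a table of pairs (i < j) with pi-hat.
    """
    if cohort.n_samples < 2:
        return pd.DataFrame(columns=["sample_a", "sample_b", "pihat"])
    p = alt_allele_freq(cohort.genotypes)
    with np.errstate(invalid="ignore"):
        keep = np.nan_to_num(np.minimum(p, 1 - p), nan=0.0) >= min_maf
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise DataError(f"no variants with MAF >= {min_maf} available for kinship")
    if max_variants is not None and idx.size > max_variants:
        idx = idx[np.linspace(0, idx.size - 1, max_variants).round().astype(int)]
    g = cohort.genotypes[:, idx].astype(np.float32)
    p = p[idx].astype(np.float64)
    q = 1.0 - p
    obs = (g >= 0).astype(np.float32)
    i0 = ((g == 0) & (obs > 0)).astype(np.float32)
    i1 = (g == 1).astype(np.float32)
    i2 = (g == 2).astype(np.float32)
    ibs0 = i0 @ i2.T + i2 @ i0.T
    ibs2 = i0 @ i0.T + i1 @ i1.T + i2 @ i2.T
    n_obs = obs @ obs.T
    ibs1 = n_obs - ibs0 - ibs2
    # expected IBS probabilities conditional on IBD state, per variant
    e00 = (2 * p**2 * q**2).astype(np.float32)                  # P(IBS0|Z=0)
    e10 = (4 * p**3 * q + 4 * p * q**3).astype(np.float32)      # P(IBS1|Z=0)
    e20 = (p**4 + q**4 + 4 * p**2 * q**2).astype(np.float32)    # P(IBS2|Z=0)
    e11 = (2 * p**2 * q + 2 * p * q**2).astype(np.float32)      # P(IBS1|Z=1)
    e21 = (p**3 + q**3 + p**2 * q + p * q**2).astype(np.float32)  # P(IBS2|Z=1)
    s00 = (obs * e00) @ obs.T
    s10 = (obs * e10) @ obs.T
    s20 = (obs * e20) @ obs.T
    s11 = (obs * e11) @ obs.T
    s21 = (obs * e21) @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        z0 = ibs0 / s00
        z1 = (ibs1 - z0 * s10) / s11
        z2 = (ibs2 - z0 * s20 - z1 * s21) / n_obs
    pihat = np.clip(z2 + 0.5 * z1, 0.0, 1.0)
    ids = cohort.samples["sample_id"].to_numpy()
    iu, ju = np.triu_indices(cohort.n_samples, k=1)
    return pd.DataFrame(
        {"sample_a": ids[iu], "sample_b": ids[ju], "pihat": pihat[iu, ju]}
    )


def ibd_prune(
    cohort: Cohort,
    thresholds: QCThresholds | None = None,
    min_maf: float = 0.01,
    max_variants: int | None = 20_000,
) -> tuple[Cohort, pd.DataFrame]:
    """Remove one member of every pair with pi-hat above the threshold.

    The member with the lower call rate is removed; on ties the
    lexicographically larger sample ID goes.  Returns the pruned cohort and
    a removal log.  Pruning is idempotent.
    """
    thresholds = thresholds or QCThresholds()
    pairs = kinship_pihat(cohort, min_maf=min_maf, max_variants=max_variants)
    call_rate = dict(
        zip(
            cohort.samples["sample_id"],
            (cohort.genotypes >= 0).mean(axis=1),
        )
    )
    flagged = pairs[pairs["pihat"] > thresholds.max_pihat].sort_values(
        ["pihat", "sample_a", "sample_b"], ascending=[False, True, True]
    )
    removed: list[dict] = []
    gone: set = set()
    for _, row in flagged.iterrows():
        a, b = row["sample_a"], row["sample_b"]
        if a in gone or b in gone:
            continue
        if call_rate[a] < call_rate[b]:
            victim = a
        elif call_rate[b] < call_rate[a]:
            victim = b
        else:
            victim = max(a, b)
        gone.add(victim)
        removed.append(
            {"removed": victim, "kept": b if victim == a else a, "pihat": row["pihat"]}
        )
    keep_idx = np.array(
        [sid not in gone for sid in cohort.samples["sample_id"]], dtype=bool
    )
    log = pd.DataFrame(removed, columns=["removed", "kept", "pihat"])
    return cohort.subset_samples(keep_idx), log


# ---------------------------------------------------------------------------
# Cohort audits and categorical summaries
# ---------------------------------------------------------------------------

@dataclass
class AuditReport:
    """Per-population sample-size audit against recommended minimums."""

    per_population: pd.Series
    n_populations: int
    n_below_min: int
    pct_below_min: float
    n_below_critical: int
    pct_below_critical: float
    size_ratio: float
    min_n: int
    critical_n: int

    def to_frame(self) -> pd.DataFrame:
        df = self.per_population.rename("n").to_frame()
        df[f"below_{self.min_n}"] = df["n"] < self.min_n
        df[f"below_{self.critical_n}"] = df["n"] < self.critical_n
        return df


def sample_size_audit(
    samples: pd.DataFrame, min_n: int = 30, critical_n: int = 10
) -> AuditReport:
    """Count populations under the recommended (``min_n``) and critical
    (``critical_n``) sample sizes, and the max:min size ratio."""
    if samples is None or len(samples) == 0:
        raise DataError("empty sample metadata")
    if "population" not in samples.columns:
        raise DataError("sample metadata lacks a population column")
    counts = samples["population"].value_counts().sort_index()
    n_pops = len(counts)
    below_min = int((counts < min_n).sum())
    below_crit = int((counts < critical_n).sum())
    return AuditReport(
        per_population=counts,
        n_populations=n_pops,
        n_below_min=below_min,
        pct_below_min=round_half_away(100.0 * below_min / n_pops, 0),
        n_below_critical=below_crit,
        pct_below_critical=round_half_away(100.0 * below_crit / n_pops, 0),
        size_ratio=float(counts.max() / counts.min()),
        min_n=min_n,
        critical_n=critical_n,
    )


def phenotype_summary(
    samples: pd.DataFrame,
    columns: dict[str, list[str] | None],
    group_by: str = "ancestry_group",
) -> pd.DataFrame:
    """Categorical count/percent summary stratified by ``group_by``.

    Returns a tidy frame (characteristic, category, group, n, pct) including
    an ``All`` group; percentages are of the group's column total, rounded to
    one decimal half away from zero.  Values outside a column's declared
    categories are counted under ``other`` with a warning.
    """
    if samples is None or len(samples) == 0:
        raise DataError("empty sample metadata")
    if group_by not in samples.columns:
        raise DataError(f"group_by column {group_by!r} not in metadata")
    groups = ["All"] + sorted(samples[group_by].astype(str).unique())
    records = []
    for col, allowed in columns.items():
        if col not in samples.columns:
            raise DataError(f"summary column {col!r} not in metadata")
        values = samples[col].astype(str)
        if allowed is not None:
            unknown = set(values) - set(allowed)
            if unknown:
                warnings.warn(
                    f"column {col!r}: values {sorted(unknown)} counted as 'other'",
                    stacklevel=2,
                )
                values = values.where(values.isin(allowed), "other")
            cats = list(allowed) + (["other"] if (set(values) - set(allowed)) else [])
        else:
            cats = sorted(values.unique())
        for grp in groups:
            sel = values if grp == "All" else values[samples[group_by].astype(str) == grp]
            total = len(sel)
            for cat in cats:
                n = int((sel == cat).sum())
                pct = round_half_away(100.0 * n / total, 1) if total else float("nan")
                records.append(
                    {
                        "characteristic": col,
                        "category": cat,
                        "group": grp,
                        "n": n,
                        "pct": pct,
                    }
                )
    return pd.DataFrame.from_records(records)
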