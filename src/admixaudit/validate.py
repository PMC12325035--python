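"""Variant-level validation: Ts/Tv, burden, multiallelic rate, error bound.

The error model treats the observed call set as a mixture of true variants
(Ts/Tv ratio ``R_exp``, default 2.1 — the middle of the genome-wide
high-quality band 2.0–2.2) and artifacts (``R_err``, default 0.4 — the ratio
expected when substitution classes arise uniformly at random, 4 transitions
to 8 transversions being 0.5, depressed further by ref-biased error modes).
Two estimators of the artifact fraction ``e`` are provided:

ratio-linear (default)
    ``e = (R_exp - R_obs) / (R_exp - R_err)`` — linear interpolation on the
    ratio scale; a conservative upper bound.
proportion-mixture
    Solves ``p_obs = (1 - e) p_exp + e p_err`` with ``p = R / (1 + R)`` the
    transition proportion, the scale on which a site mixture is actually
    linear.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_sig
from .errors import DataError
from .types import Cohort, TsTvModel, VariantTable, classify_substitution

#: Genome-wide high-quality Ts/Tv band for human WGS call sets.
DEFAULT_QUALITY_BAND = (2.0, 2.2)


@dataclass
class TsTvResult:
    n_transitions: int
    n_transversions: int
    n_other: int
    ratio: float | None          # None when no transversions were observed

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def tstv_ratio(variants: VariantTable) -> TsTvResult:
    """Transitions / transversions over SNVs.

    Multiallelic records are decomposed and each single-base alt classified
    separately; non-SNV substitutions count as ``other`` and are excluded
    from the ratio.  With zero transversions the ratio is reported as
    undefined (None) alongside the raw counts.
    """
    n_ts = n_tv = n_other = 0
    for ref, alt in zip(variants.data["ref"], variants.data["alt"]):
        for a in alt.split(","):
            cls = classify_substitution(ref, a)
            if cls == "transition":
                n_ts += 1
            elif cls == "transversion":
                n_tv += 1
            else:
                n_other += 1
    if n_ts + n_tv == 0:
        raise DataError("no classified SNVs: Ts/Tv undefined")
    ratio = n_ts / n_tv if n_tv > 0 else None
    return TsTvResult(n_ts, n_tv, n_other, ratio)


@dataclass
class ErrorBound:
    """Artifact-fraction upper bound and its complement."""

    e: float                      # artifact fraction in [0, 1]
    model: TsTvModel

    @property
    def high_confidence(self) -> float:
        return 1.0 - self.e

    @property
    def e_percent(self) -> float:
        """Artifact bound as a percentage at 2 significant figures."""
        return round_sig(100.0 * self.e, 2)

    @property
    def high_confidence_percent(self) -> float:
        return round_sig(100.0 * self.high_confidence, 2)


def error_upper_bound(model: TsTvModel) -> ErrorBound:
    """Estimate the artifact fraction from the observed Ts/Tv under the
    two-component mixture; the result is clipped to [0, 1]."""
    r_obs = min(max(model.R_obs, model.R_err), model.R_exp)  # clip into the model range
    if model.mode == "ratio-linear":
        e = (model.R_exp - r_obs) / (model.R_exp - model.R_err)
    else:  # proportion-mixture
        p_obs = r_obs / (1.0 + r_obs)
        p_exp = model.R_exp / (1.0 + model.R_exp)
        p_err = model.R_err / (1.0 + model.R_err)
        e = (p_exp - p_obs) / (p_exp - p_err)
    return ErrorBound(e=float(np.clip(e, 0.0, 1.0)), model=model)


@dataclass
class BurdenStats:
    per_sample: pd.Series          # non-reference genotype count per sample
    multiallelic_rate: float
    n_variants: int
    n_multiallelic: int

    def quantiles(self, q=(0.0, 0.25, 0.5, 0.75, 1.0)) -> pd.Series:
        return self.per_sample.quantile(list(q))


def burden_stats(cohort: Cohort) -> BurdenStats:
    """Per-individual non-reference variant counts and the multiallelic
    site rate (records counted once regardless of alt count)."""
    if cohort.n_variants == 0 or cohort.n_samples == 0:
        raise DataError("cohort is empty")
    burden = pd.Series(
        (cohort.genotypes >= 1).sum(axis=1),
        index=cohort.samples["sample_id"],
        name="non_ref_count",
    )
    n_multi = int(cohort.variants.is_multiallelic.sum())
    return BurdenStats(
        per_sample=burden,
        multiallelic_rate=n_multi / cohort.n_variants,
        n_variants=cohort.n_variants,
        n_multiallelic=n_multi,
    )


@dataclass
class ValidationReport:
    tstv: TsTvResult
    in_quality_band: bool | None
    quality_band: tuple[float, float]
    error_bound: ErrorBound
    burden: BurdenStats

    def summary(self) -> dict:
        return {
            "tstv_ratio": self.tstv.ratio,
            "n_transitions": self.tstv.n_transitions,
            "n_transversions": self.tstv.n_transversions,
            "n_other": self.tstv.n_other,
            "in_quality_band": self.in_quality_band,
            "quality_band": list(self.quality_band),
            "error_mode": self.error_bound.model.mode,
            "artifact_pct": self.error_bound.e_percent,
            "high_confidence_pct": self.error_bound.high_confidence_percent,
            "multiallelic_rate": self.burden.multiallelic_rate,
            "n_variants": self.burden.n_variants,
            "burden_median": float(self.burden.per_sample.median()),
        }


def validation_report(
    cohort: Cohort,
    R_exp: float = 2.1,
    R_err: float = 0.4,
    mode: str = "ratio-linear",
    quality_band: tuple[float, float] = DEFAULT_QUALITY_BAND,
) -> ValidationReport:
    """Full variant-validation report for a cohort."""
    tstv = tstv_ratio(cohort.variants)
    model = TsTvModel(
        R_obs=tstv.ratio if tstv.ratio is not None else R_err,
        R_exp=R_exp,
        R_err=R_err,
        mode=mode,
    )
    in_band = (
        None
        if tstv.ratio is None
        else bool(quality_band[0] <= tstv.ratio <= quality_band[1])
    )
    return ValidationReport(
        tstv=tstv,
        in_quality_band=in_band,
        quality_band=quality_band,
        error_bound=error_upper_bound(model),
        burden=burden_stats(cohort),
    )
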