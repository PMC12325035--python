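"""Array-vs-WGS ascertainment bias: capture rate and MAF-spectrum distortion.

Variants are matched across platforms by (chrom, pos, sorted alleles) only —
never by ID — and each platform's frequency spectrum is computed over its own
variant list, so the per-bin differences are directly interpretable as
percentage-point distortion of the array's spectrum relative to WGS.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import minor_allele_freq
from .errors import ConfigError, DataError
from .types import Cohort, VariantTable

#: Default MAF bin edges; 0.005 and 0.10 are the rare/common cutpoints, the
#: interior edges are conventional MAF thresholds.
DEFAULT_BINS = (0.0, 0.005, 0.01, 0.05, 0.10, 0.5)


@dataclass
class SpectrumReport:
    """MAF-bin capture/distortion statistics for an array against WGS."""

    bin_edges: tuple[float, ...]
    wgs_fraction: np.ndarray
    array_fraction: np.ndarray
    distortion_pp: np.ndarray          # (array - wgs) * 100 per bin
    n_wgs: int
    n_array: int
    n_monomorphic_wgs: int
    n_monomorphic_array: int
    capture_rate: float | None = None
    per_chromosome_capture: pd.Series | None = None

    @property
    def rare_bin_pp(self) -> float:
        """Distortion of the rarest bin (MAF below the first interior edge)."""
        return float(self.distortion_pp[0])

    @property
    def common_bin_pp(self) -> float:
        """Distortion of the most common bin (MAF above the last interior edge)."""
        return float(self.distortion_pp[-1])

    def to_frame(self) -> pd.DataFrame:
        edges = self.bin_edges
        labels = [f"({edges[i]:g}, {edges[i + 1]:g}]" for i in range(len(edges) - 1)]
        labels[0] = f"(0, {edges[1]:g})"
        return pd.DataFrame(
            {
                "maf_bin": labels,
                "wgs_fraction": self.wgs_fraction,
                "array_fraction": self.array_fraction,
                "distortion_pp": self.distortion_pp,
            }
        )


def capture_rate(
    wgs: VariantTable, array: VariantTable
) -> tuple[float, pd.Series]:
    """Fraction of WGS variant keys present on the array, overall and per
    chromosome (denominators are each chromosome's WGS variant count)."""
    if len(wgs) == 0:
        raise DataError("WGS variant table is empty: capture rate undefined")
    array_keys = set(array.keys())
    wgs_keys = wgs.keys()
    captured = np.array([k in array_keys for k in wgs_keys])
    chroms = wgs.data["chrom"].to_numpy()
    per_chrom = (
        pd.DataFrame({"chrom": chroms, "captured": captured})
        .groupby("chrom", sort=True)["captured"]
        .mean()
        .rename("capture_rate")
    )
    return float(captured.mean()), per_chrom


def maf_spectrum_distortion(
    wgs_cohort: Cohort,
    array_cohort: Cohort,
    bins: tuple[float, ...] = DEFAULT_BINS,
) -> SpectrumReport:
    """Per-bin spectrum fractions for each platform and their difference in
    percentage points.  Monomorphic variants (MAF = 0) are excluded from the
    binning and counted separately."""
    bins = tuple(float(b) for b in bins)
    if len(bins) < 2 or bins[0] != 0.0 or bins[-1] < 0.5 or list(bins) != sorted(bins):
        raise ConfigError(
            f"bins {bins} must be increasing, start at 0 and cover (0, 0.5]"
        )

    def _fractions(cohort: Cohort) -> tuple[np.ndarray, int, int]:
        maf = minor_allele_freq(cohort.genotypes)
        maf = maf[~np.isnan(maf)]
        poly = maf[maf > 0]
        if poly.size == 0:
            raise DataError("no polymorphic variants with computable MAF")
        counts, _ = np.histogram(poly, bins=bins)
        return counts / poly.size, int(poly.size), int(maf.size - poly.size)

    wgs_frac, n_wgs, mono_wgs = _fractions(wgs_cohort)
    arr_frac, n_arr, mono_arr = _fractions(array_cohort)
    overall, per_chrom = capture_rate(wgs_cohort.variants, array_cohort.variants)
    return SpectrumReport(
        bin_edges=bins,
        wgs_fraction=wgs_frac,
        array_fraction=arr_frac,
        distortion_pp=(arr_frac - wgs_frac) * 100.0,
        n_wgs=n_wgs,
        n_array=n_arr,
        n_monomorphic_wgs=mono_wgs,
        n_monomorphic_array=mono_arr,
        capture_rate=overall,
        per_chromosome_capture=per_chrom,
    )
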