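"""Domain containers shared across the pipeline.

The central object is :class:`Cohort` — an int8 dosage matrix (samples x
variants, ``-1`` = missing) plus a :class:`VariantTable` and a sample-metadata
frame.  Variants are identified for cross-platform matching by the key
``(chrom, pos, sorted uppercased alleles)`` so that ref/alt orientation and
rsID vocabularies play no role.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError

#: Single-base changes counted as transitions; everything else single-base is a transversion.
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = ("A", "C", "G", "T")
#: Transition partner of each base.
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
#: The two transversion partners of each base.
TRANSVERSION_PARTNERS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "class")


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a ref>alt change as ``transition`` / ``transversion`` / ``other``.

    Multi-base alleles, symbolic alleles and multiallelic alt strings
    (comma-joined) are ``other``; multiallelic records are decomposed per alt
    where a per-substitution classification is needed (see
    :func:`admixaudit.validate.tstv_ratio`).
    """
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) == 1 and len(alt) == 1 and ref in _BASES and alt in _BASES and ref != alt:
        return "transition" if (ref, alt) in TRANSITIONS else "transversion"
    return "other"


def variant_key(chrom, pos, ref: str, alt: str) -> tuple:
    """Matching key: chrom, pos and the sorted, uppercased set of alleles."""
    alleles = [ref.upper()] + [a.upper() for a in str(alt).split(",")]
    return (str(chrom), int(pos), tuple(sorted(alleles)))


@dataclass
class VariantTable:
    """Per-variant records: chrom, pos (1-based), ref, alt (comma-joined if
    multiallelic) and substitution class."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in df.columns]
        if missing:
            raise SchemaError(f"variant table lacks columns {missing}")
        df = df.reset_index(drop=True).copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["ref"] = df["ref"].astype(str).str.upper()
        df["alt"] = df["alt"].astype(str).str.upper()
        if (df["pos"] < 1).any():
            raise SchemaError("variant positions must be 1-based (>= 1)")
        if "class" not in df.columns:
            df["class"] = [
                classify_substitution(r, a) if "," not in a else "other"
                for r, a in zip(df["ref"], df["alt"])
            ]
        keys = self._key_list(df)
        if len(set(keys)) != len(keys):
            raise SchemaError("variant keys (chrom, pos, alleles) are not unique")
        self.data = df

    @staticmethod
    def _key_list(df: pd.DataFrame) -> list[tuple]:
        return [
            variant_key(c, p, r, a)
            for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
        ]

    @classmethod
    def from_arrays(cls, chrom, pos, ref, alt) -> "VariantTable":
        return cls(pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}))

    def keys(self) -> list[tuple]:
        return self._key_list(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_biallelic_snv(self) -> np.ndarray:
        """Boolean mask of biallelic single-nucleotide rows."""
        df = self.data
        return (
            (df["ref"].str.len() == 1)
            & (df["alt"].str.len() == 1)
            & df["ref"].isin(_BASES)
            & df["alt"].isin(_BASES)
        ).to_numpy()

    @property
    def is_multiallelic(self) -> np.ndarray:
        return self.data["alt"].str.contains(",").to_numpy()

    def subset(self, index) -> "VariantTable":
        return VariantTable(self.data.iloc[np.asarray(index)].reset_index(drop=True))


@dataclass
class AncestralPanel:
    """Ancestral allele frequencies: one row of `p` per ancestry, one column per variant."""

    ancestries: tuple[str, ...]
    p: np.ndarray
    variants: VariantTable

    def __post_init__(self):
        self.ancestries = tuple(self.ancestries)
        if len(set(self.ancestries)) != len(self.ancestries):
            raise SchemaError("ancestry labels must be unique")
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.ancestries), len(self.variants)):
            raise SchemaError(
                f"frequency matrix shape {self.p.shape} does not match "
                f"{len(self.ancestries)} ancestries x {len(self.variants)} variants"
            )
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise SchemaError("ancestral frequencies must lie in [0, 1]")

    def freq(self, ancestry: str) -> np.ndarray:
        if ancestry not in self.ancestries:
            raise SchemaError(f"ancestry {ancestry!r} not in panel {self.ancestries}")
        return self.p[self.ancestries.index(ancestry)]


@dataclass
class PopulationSpec:
    """A named population: size, per-ancestry drift F, admixture proportions q."""

    name: str
    n: int
    F: Mapping[str, float]
    q: Mapping[str, float]
    region: str = "unknown"
    altitude_band: str = "low"

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError(f"population {self.name}: n must be >= 1, got {self.n}")
        total = float(sum(self.q.values()))
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(
                f"population {self.name}: admixture proportions sum to {total}, not 1"
            )
        for anc, f in self.F.items():
            if not (0.0 < f < 1.0):
                raise ParameterError(
                    f"population {self.name}: drift F[{anc}]={f} outside (0, 1)"
                )
        if self.altitude_band not in ("low", "mid", "high"):
            raise ParameterError(
                f"population {self.name}: altitude_band must be low|mid|high"
            )


@dataclass
class ArrayDesign:
    """A genotyping array's discovery design: which ancestry the content was
    ascertained in, with how many haplotypes, and at what MAF cutoff."""

    discovery_ancestry: str = "EUR"
    discovery_n: int = 120
    maf_cutoff: float = 0.05
    panel: VariantTable | None = None

    def __post_init__(self):
        if not (0.0 <= self.maf_cutoff <= 0.5):
            raise ParameterError(f"maf_cutoff {self.maf_cutoff} outside [0, 0.5]")
        if self.discovery_n < 1:
            raise ParameterError("discovery_n must be >= 1")


@dataclass
class CohortTruth:
    """Ground truth carried by synthetic cohorts: realized per-sample admixture,
    per-variant artifact flags, and the generating ancestral panel."""

    admixture: pd.DataFrame | None = None
    error_flags: np.ndarray | None = None
    panel: AncestralPanel | None = None

    def subset_variants(self, index) -> "CohortTruth":
        flags = None if self.error_flags is None else np.asarray(self.error_flags)[index]
        return CohortTruth(admixture=self.admixture, error_flags=flags, panel=self.panel)

    def subset_samples(self, index) -> "CohortTruth":
        adm = None if self.admixture is None else self.admixture.iloc[np.asarray(index)]
        return CohortTruth(admixture=adm, error_flags=self.error_flags, panel=self.panel)


@dataclass
class Cohort:
    """Genotype matrix (samples x variants, int8 dosage, -1 missing) plus
    variant table and sample metadata."""

    genotypes: np.ndarray
    variants: VariantTable
    samples: pd.DataFrame
    truth: CohortTruth | None = None

    def __post_init__(self):
        g = np.asarray(self.genotypes)
        if g.dtype != np.int8:
            g = g.astype(np.int8)
        if g.ndim != 2:
            raise SchemaError("genotype matrix must be 2-D (samples x variants)")
        bad = ~np.isin(g, (-1, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SchemaError(
                f"dosage {int(g[i, j])} at sample {i}, variant {j} outside {{0,1,2,missing}}"
            )
        samples = self.samples.reset_index(drop=True)
        if "sample_id" not in samples.columns:
            raise SchemaError("sample metadata lacks a sample_id column")
        if samples["sample_id"].duplicated().any():
            raise SchemaError("sample_id values are not unique")
        if g.shape != (len(samples), len(self.variants)):
            raise SchemaError(
                f"genotype matrix {g.shape} does not match "
                f"{len(samples)} samples x {len(self.variants)} variants"
            )
        self.genotypes = g
        self.samples = samples

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def subset_variants(self, index) -> "Cohort":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return Cohort(
            genotypes=self.genotypes[:, index],
            variants=self.variants.subset(index),
            samples=self.samples,
            truth=None if self.truth is None else self.truth.subset_variants(index),
        )

    def subset_samples(self, index) -> "Cohort":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return Cohort(
            genotypes=self.genotypes[index],
            variants=self.variants,
            samples=self.samples.iloc[index],
            truth=None if self.truth is None else self.truth.subset_samples(index),
        )

    def equals(self, other: "Cohort") -> bool:
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.variants.data.equals(other.variants.data)
            and self.samples.equals(other.samples.reset_index(drop=True))
        )


@dataclass
class QCThresholds:
    """Variant/sample QC cutoffs."""

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    max_pihat: float = 0.185

    def __post_init__(self):
        for name in ("min_call_rate", "min_maf", "min_hwe_p", "max_pihat"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v} outside [0, 1]")


@dataclass
class TsTvModel:
    """Two-component Ts/Tv mixture: true variants at ratio R_exp, artifacts at R_err."""

    R_obs: float
    R_exp: float = 2.1
    R_err: float = 0.4
    mode: str = "ratio-linear"

    def __post_init__(self):
        if self.R_err <= 0:
            raise ParameterError(f"R_err must be positive, got {self.R_err}")
        if self.R_exp <= self.R_err:
            raise ParameterError(
                f"invalid model: R_exp ({self.R_exp}) must exceed R_err ({self.R_err})"
            )
        if self.mode not in ("ratio-linear", "proportion-mixture"):
            raise ParameterError(f"unknown mode {self.mode!r}")


@dataclass
class PCAConfig:
    """Weighted-PCA settings; weights are 1/group-size, normalized over samples."""

    k: int = 10
    weight_mode: str = "inverse-group-size"
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.weight_mode not in ("inverse-group-size", "uniform"):
            raise ParameterError(f"unknown weight_mode {self.weight_mode!r}")
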