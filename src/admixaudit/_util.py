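"""Shared helpers: RNG plumbing, rounding conventions, allele-frequency arithmetic."""
from __future__ import annotations

import hashlib
import math

import numpy as np

#: Sentinel for a missing genotype in the int8 dosage matrix.
MISSING = np.int8(-1)


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        return np.random.SeedSequence(int(seed.integers(2**31)))
    return np.random.SeedSequence(seed)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the global seed and stage name."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def round_half_away(x: float, ndigits: int = 0) -> float:
    # np.round / builtin round are half-even; summary tables use half-away-from-zero
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def round_sig(x: float, sig: int = 2) -> float:
    """Round to `sig` significant figures, half away from zero."""
    if x == 0 or not math.isfinite(x):
        return float(x)
    exponent = math.floor(math.log10(abs(x)))
    return round_half_away(x, sig - 1 - exponent)


def alt_allele_freq(genotypes: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per variant over non-missing genotypes (NaN if none observed)."""
    g = np.asarray(genotypes)
    observed = g >= 0
    n_alleles = 2 * observed.sum(axis=0)
    alt = np.where(observed, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / np.maximum(n_alleles, 1)
    return np.where(n_alleles > 0, freq, np.nan)


def minor_allele_freq(genotypes: np.ndarray) -> np.ndarray:
    p = alt_allele_freq(genotypes)
    return np.minimum(p, 1.0 - p)
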