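"""Synthetic admixed cohorts under the Balding–Nichols model.

The generator emulates the statistical structure of an Andean/Amazonian-style
admixed study cohort: ~26 populations drawing ancestry from three sources
(Native American, European, African), strongly unequal sample sizes (8:1
between largest and smallest), a rare-variant-rich site-frequency spectrum,
and a European-ascertained genotyping-array subset that depletes variants
rare outside the discovery panel.

Model summary
-------------
Ancestral frequencies ``p0`` per variant come from a truncated Beta(0.2, 0.2)
spectrum (excess of rare alleles).  Each ancestry ``k`` drifts from ``p0``
under Balding–Nichols: ``p_k ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F)``, so
``E[p_k] = p0`` and ``Var[p_k] = F p0 (1-p0)``.  Each population applies the
same law again with its own per-ancestry drift to model population-level
isolation.  A diploid genotype is the sum of two allele copies; each copy
independently picks an ancestry from the population's admixture vector ``q``
and then an allele Bernoulli(p at that ancestry).  All draws are
bit-reproducible given a seed.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .._util import as_rng, as_seed_sequence
from ..errors import EmptyPanelError, ParameterError, SchemaError
from ..types import (
    AncestralPanel,
    ArrayDesign,
    Cohort,
    CohortTruth,
    PopulationSpec,
    TRANSITION_PARTNER,
    TRANSVERSION_PARTNERS,
    VariantTable,
)

#: Default ancestry labels, in panel order.
DEFAULT_ANCESTRIES = ("NAT", "EUR", "AFR")

#: Default between-ancestry drift from the shared ancestral frequency.
#: Native American populations are the most drifted of the three sources.
DEFAULT_F_BETWEEN = {"NAT": 0.20, "EUR": 0.12, "AFR": 0.08}

#: Approximate autosome lengths (bp), used only to lay variants out on a map.
_CHROM_LENGTHS = {
    "1": 249_000_000, "2": 243_000_000, "3": 198_000_000, "4": 190_000_000,
    "5": 182_000_000, "6": 171_000_000, "7": 159_000_000, "8": 146_000_000,
    "9": 141_000_000, "10": 136_000_000, "11": 135_000_000, "12": 133_000_000,
    "13": 115_000_000, "14": 107_000_000, "15": 102_000_000, "16": 90_000_000,
    "17": 83_000_000, "18": 80_000_000, "19": 59_000_000, "20": 64_000_000,
    "21": 47_000_000, "22": 51_000_000,
}

#: Ts share of true SNVs; gives the genome-wide high-quality ratio of ~2.1.
_TS_PROB = 2.1 / 3.1

# Demographic mix used for synthetic sample metadata (cohort-level rates of
# the study design this generator emulates).
_P_FEMALE = 0.333
_BMI_CLASSES = ("underweight", "normal", "overweight", "obese")
_BMI_PROBS = (0.02, 0.45, 0.37, 0.16)


def _random_variant_table(m: int, rng: np.random.Generator) -> VariantTable:
    """Random biallelic SNV map across the 22 autosomes with realistic Ts share."""
    chroms = list(_CHROM_LENGTHS)
    lengths = np.array([_CHROM_LENGTHS[c] for c in chroms], dtype=float)
    counts = rng.multinomial(m, lengths / lengths.sum())
    rows_chrom, rows_pos = [], []
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        L = _CHROM_LENGTHS[chrom]
        pos = np.unique(rng.integers(1, L, size=int(k * 1.1) + 8))
        while len(pos) < k:  # top up in the (vanishingly rare) collision case
            pos = np.unique(np.concatenate([pos, rng.integers(1, L, size=k)]))
        pos = np.sort(rng.choice(pos, size=k, replace=False))
        rows_chrom.append(np.repeat(chrom, k))
        rows_pos.append(pos)
    chrom_arr = np.concatenate(rows_chrom)
    pos_arr = np.concatenate(rows_pos)
    bases = np.array(["A", "C", "G", "T"])
    ref = bases[rng.integers(0, 4, size=m)]
    is_ts = rng.random(m) < _TS_PROB
    pick = rng.integers(0, 2, size=m)
    alt = np.array(
        [
            TRANSITION_PARTNER[r] if ts else TRANSVERSION_PARTNERS[r][p]
            for r, ts, p in zip(ref, is_ts, pick)
        ]
    )
    return VariantTable.from_arrays(chrom_arr, pos_arr, ref, alt)


def balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Draw drifted frequencies Beta(p(1-F)/F, (1-p)(1-F)/F) elementwise."""
    ratio = (1.0 - F) / F
    out = rng.beta(np.maximum(p * ratio, 1e-12), np.maximum((1.0 - p) * ratio, 1e-12))
    return np.clip(out, 1e-12, 1.0 - 1e-12)


def draw_ancestral_frequencies(
    m: int,
    ancestries: Sequence[str] = DEFAULT_ANCESTRIES,
    F_between: float | Mapping[str, float] | None = None,
    base_spectrum: tuple[float, float] = (0.2, 0.2),
    seed=None,
) -> AncestralPanel:
    """Draw an ancestral frequency panel with a rare-variant-rich spectrum.

    Parameters
    ----------
    m
        Number of variants.
    ancestries
        Ordered ancestry labels.
    F_between
        Balding–Nichols drift of each ancestry from the shared ancestral
        frequency; a scalar applies to all ancestries.  Defaults to
        :data:`DEFAULT_F_BETWEEN` for the default labels, 0.1 otherwise.
    base_spectrum
        (a, b) of the base Beta spectrum, truncated to [0.001, 0.999].
    seed
        Seed or Generator; identical seeds give identical panels.
    """
    if m < 1:
        raise ParameterError(f"m must be >= 1, got {m}")
    ancestries = tuple(ancestries)
    if F_between is None:
        F_between = (
            DEFAULT_F_BETWEEN
            if set(ancestries) <= set(DEFAULT_F_BETWEEN)
            else {a: 0.1 for a in ancestries}
        )
    if not isinstance(F_between, Mapping):
        F_between = {a: float(F_between) for a in ancestries}
    for a in ancestries:
        f = F_between.get(a)
        if f is None or not (0.0 < f < 1.0):
            raise ParameterError(f"F_between[{a}]={f} outside (0, 1)")
    rng = as_rng(seed)
    a_b, b_b = base_spectrum
    lo, hi = stats.beta.cdf([0.001, 0.999], a_b, b_b)
    p0 = stats.beta.ppf(lo + rng.random(m) * (hi - lo), a_b, b_b)
    p = np.stack([balding_nichols(rng, p0, F_between[a]) for a in ancestries])
    variants = _random_variant_table(m, rng)
    return AncestralPanel(ancestries=ancestries, p=p, variants=variants)


def simulate_admixed_cohort(
    panel: AncestralPanel,
    pops: Sequence[PopulationSpec],
    seed=None,
) -> Cohort:
    """Simulate diploid genotypes for a set of admixed populations.

    For every individual and locus, each of the two allele copies picks an
    ancestry from the population's admixture vector ``q`` and then an allele
    Bernoulli(p) at that ancestry's population-drifted frequency.  Realized
    per-sample ancestry fractions (over all 2m copies) are recorded in
    ``Cohort.truth.admixture``; the generating panel is kept in
    ``Cohort.truth.panel``.
    """
    if not pops:
        raise ParameterError("pops must be non-empty")
    for pop in pops:
        unknown = set(pop.q) - set(panel.ancestries)
        if unknown:
            raise SchemaError(
                f"population {pop.name} references ancestries {sorted(unknown)} "
                f"absent from panel {panel.ancestries}"
            )
    m = len(panel.variants)
    n_anc = len(panel.ancestries)
    seeds = as_seed_sequence(seed).spawn(len(pops))
    geno_blocks, meta_rows, admix_blocks = [], [], []
    for pop, child in zip(pops, seeds):
        rng = np.random.default_rng(child)
        qvec = np.array([float(pop.q.get(a, 0.0)) for a in panel.ancestries])
        # population-level drift of each ancestral component
        p_pop = np.stack(
            [
                balding_nichols(rng, panel.p[k], float(pop.F.get(a, 0.01)))
                if pop.q.get(a, 0.0) > 0
                else panel.p[k]
                for k, a in enumerate(panel.ancestries)
            ]
        )
        cum = np.cumsum(qvec)
        cum[-1] = 1.0 + 1e-12
        n = pop.n
        anc = np.minimum(
            np.searchsorted(cum, rng.random((n, m, 2)), side="right"), n_anc - 1
        )
        alleles = rng.random((n, m, 2)) < p_pop[anc, np.arange(m)[None, :, None]]
        geno_blocks.append(alleles.sum(axis=2).astype(np.int8))
        counts = np.stack([(anc == k).sum(axis=(1, 2)) for k in range(n_anc)], axis=1)
        admix_blocks.append(counts / (2.0 * m))
        q_nat = float(pop.q.get("NAT", 0.0))
        group = "native" if q_nat >= 0.8 else "mestizo"
        sex = np.where(rng.random(n) < _P_FEMALE, "female", "male")
        age = rng.integers(18, 81, size=n)
        bmi = rng.choice(_BMI_CLASSES, size=n, p=_BMI_PROBS)
        for i in range(n):
            meta_rows.append(
                {
                    "sample_id": f"{pop.name}_{i:03d}",
                    "population": pop.name,
                    "ancestry_group": group,
                    "region": pop.region,
                    "altitude_band": pop.altitude_band,
                    "sex": sex[i],
                    "age": int(age[i]),
                    "bmi_class": bmi[i],
                }
            )
    samples = pd.DataFrame(meta_rows)
    admixture = pd.DataFrame(
        np.concatenate(admix_blocks),
        columns=list(panel.ancestries),
        index=samples["sample_id"],
    )
    return Cohort(
        genotypes=np.concatenate(geno_blocks),
        variants=panel.variants,
        samples=samples,
        truth=CohortTruth(admixture=admixture, panel=panel),
    )


def ascertain_array_panel(
    cohort: Cohort, design: ArrayDesign, seed=None
) -> Cohort:
    """Apply array ascertainment: keep variants common in a discovery sample.

    Draws ``design.discovery_n`` haplotypes from the ancestral frequency of
    the discovery ancestry and keeps variants that are polymorphic in that
    sample with discovery MAF >= ``design.maf_cutoff``.  The selected panel
    is stored on ``design.panel`` and the array-typed sub-cohort returned.
    """
    if cohort.truth is None or cohort.truth.panel is None:
        raise SchemaError("cohort carries no ancestral panel truth; cannot ascertain")
    p_disc = cohort.truth.panel.freq(design.discovery_ancestry)
    rng = as_rng(seed)
    alt_counts = rng.binomial(design.discovery_n, p_disc)
    maf = np.minimum(alt_counts, design.discovery_n - alt_counts) / design.discovery_n
    keep = (alt_counts > 0) & (alt_counts < design.discovery_n) & (maf >= design.maf_cutoff)
    if not keep.any():
        raise EmptyPanelError(
            f"no variants pass discovery MAF >= {design.maf_cutoff} in a "
            f"{design.discovery_n}-haplotype {design.discovery_ancestry} sample"
        )
    design.panel = cohort.variants.subset(keep)
    sub = cohort.subset_variants(keep)
    # keep the panel truth aligned with the retained variants
    sub.truth.panel = AncestralPanel(
        ancestries=cohort.truth.panel.ancestries,
        p=cohort.truth.panel.p[:, keep],
        variants=sub.variants,
    )
    return sub


def inject_errors_and_missingness(
    cohort: Cohort,
    miss_rate: float = 0.0,
    err_rate: float = 0.0,
    R_err: float = 0.4,
    seed=None,
) -> Cohort:
    """Inject genotype missingness and artifact sites with a distinct Ts/Tv.

    Genotypes are set missing i.i.d. with probability ``miss_rate``.  Exactly
    ``round(err_rate * n_variants)`` biallelic SNVs are flagged as artifact
    sites; each flagged site's substitution is redrawn (keeping the ref base)
    as a transition with probability ``R_err / (1 + R_err)``, so the artifact
    class has expected Ts/Tv = ``R_err``.  Truth flags are stored in
    ``Cohort.truth.error_flags``.
    """
    for name, rate in (("miss_rate", miss_rate), ("err_rate", err_rate)):
        if not (0.0 <= rate < 1.0):
            raise ParameterError(f"{name}={rate} outside [0, 1)")
    if R_err <= 0:
        raise ParameterError(f"R_err must be positive, got {R_err}")
    rng = as_rng(seed)
    g = cohort.genotypes.copy()
    if miss_rate > 0:
        g[rng.random(g.shape) < miss_rate] = -1
    vdf = cohort.variants.data.copy()
    flags = np.zeros(len(vdf), dtype=bool)
    n_flag = int(round(err_rate * len(vdf)))
    if n_flag > 0:
        eligible = np.flatnonzero(cohort.variants.is_biallelic_snv)
        if n_flag > len(eligible):
            raise ParameterError(
                f"err_rate {err_rate} flags {n_flag} variants but only "
                f"{len(eligible)} biallelic SNVs are available"
            )
        chosen = rng.choice(eligible, size=n_flag, replace=False)
        flags[chosen] = True
        is_ts = rng.random(n_flag) < R_err / (1.0 + R_err)
        pick = rng.integers(0, 2, size=n_flag)
        refs = vdf.loc[chosen, "ref"].to_numpy()
        new_alt = [
            TRANSITION_PARTNER[r] if ts else TRANSVERSION_PARTNERS[r][p]
            for r, ts, p in zip(refs, is_ts, pick)
        ]
        vdf.loc[chosen, "alt"] = new_alt
        vdf.loc[chosen, "class"] = [
            "transition" if ts else "transversion" for ts in is_ts
        ]
    truth = cohort.truth or CohortTruth()
    new_truth = CohortTruth(
        admixture=truth.admixture, error_flags=flags, panel=truth.panel
    )
    # a redrawn alt may collide with an existing key at the same position;
    # VariantTable uniqueness validation will surface that (practically never
    # at genome-scale positions)
    return Cohort(
        genotypes=g, variants=VariantTable(vdf), samples=cohort.samples, truth=new_truth
    )


def default_populations(n_populations: int = 26) -> list[PopulationSpec]:
    """The default study layout: unequal sizes spanning 10..80 (8:1 ratio),
    native populations with 0.80–0.95 Native American ancestry and admixed
    (mestizo) populations with 0.60–0.74, European up to ~0.35 and African
    up to ~0.10."""
    if n_populations < 2:
        raise ParameterError("need at least 2 populations")
    sizes = np.linspace(10, 80, n_populations).round().astype(int)
    n_native = int(round(n_populations * 16 / 26))
    pops: list[PopulationSpec] = []
    regions = ("amazon", "andes", "coast")
    altitudes = {"amazon": "low", "andes": "high", "coast": "low"}
    for i in range(n_populations):
        native = i < n_native
        if native:
            q_nat = round(0.80 + 0.15 * i / max(n_native - 1, 1), 6)
            q_eur = (1.0 - q_nat) * 0.9
            region = regions[i % 2]  # amazon / andes
            f_nat = 0.02 + 0.06 * i / max(n_native - 1, 1)
            F = {"NAT": round(f_nat, 4), "EUR": 0.01, "AFR": 0.01}
            name = f"NATIVE{i + 1:02d}"
        else:
            j = i - n_native
            n_mest = n_populations - n_native
            q_nat = round(0.60 + 0.14 * j / max(n_mest - 1, 1), 6)
            q_eur = (1.0 - q_nat) * 0.78
            region = regions[(j % 2) + 1]  # andes / coast
            F = {"NAT": 0.01, "EUR": 0.005, "AFR": 0.005}
            name = f"MESTIZO{j + 1:02d}"
        q_afr = 1.0 - q_nat - q_eur
        band = altitudes[region] if region != "andes" else ("high" if i % 4 else "mid")
        pops.append(
            PopulationSpec(
                name=name,
                n=int(sizes[i]),
                F=F,
                q={"NAT": q_nat, "EUR": q_eur, "AFR": round(q_afr, 12)},
                region=region,
                altitude_band=band,
            )
        )
    return pops


def default_study(
    seed=None,
    m: int = 50_000,
    n_populations: int = 26,
    miss_rate: float = 0.002,
    err_rate: float = 0.0059,
    R_err: float = 0.4,
    design: ArrayDesign | None = None,
):
    """Generate the full default synthetic study: WGS-like cohort plus its
    European-ascertained array subset.

    Returns ``(wgs_cohort, array_cohort, design)``.
    """
    ss = np.random.SeedSequence(seed)
    s_panel, s_cohort, s_err, s_array = ss.spawn(4)
    panel = draw_ancestral_frequencies(m, seed=np.random.default_rng(s_panel))
    cohort = simulate_admixed_cohort(
        panel, default_populations(n_populations), seed=s_cohort
    )
    cohort = inject_errors_and_missingness(
        cohort, miss_rate=miss_rate, err_rate=err_rate, R_err=R_err,
        seed=np.random.default_rng(s_err),
    )
    design = design or ArrayDesign()
    array_cohort = ascertain_array_panel(
        cohort, design, seed=np.random.default_rng(s_array)
    )
    return cohort, array_cohort, design
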