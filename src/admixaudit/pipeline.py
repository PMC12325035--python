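"""Seeded multi-stage pipeline: simulate -> qc -> ascertain -> validate -> structure.

Every stochastic stage derives its seed deterministically from the global
seed plus the stage name, so identical configurations produce byte-identical
report bundles.  Outputs are written atomically (temp file + rename); each
stage logs its input/output record counts.
"""
from __future__ import annotations

import json
import logging
import os
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator

from ._util import derive_seed
from .ascertain import DEFAULT_BINS, maf_spectrum_distortion
from .errors import ConfigError, DataError
from .qc import ibd_prune, phenotype_summary, sample_size_audit, variant_qc
from .structure import pairwise_fst, stratified_bootstrap_stability, unweighted_grs, weighted_pca
from .synthio.generate import ascertain_array_panel, default_populations, \
    draw_ancestral_frequencies, inject_errors_and_missingness, simulate_admixed_cohort
from .synthio.io import read_cohort, write_cohort
from .types import ArrayDesign, Cohort, PCAConfig, QCThresholds, VariantTable
from .validate import validation_report

log = logging.getLogger("admixaudit")

STAGES = ("simulate", "qc", "ascertain", "validate", "structure")


class ArrayConfig(BaseModel):
    discovery_ancestry: str = "EUR"
    discovery_n: int = Field(120, ge=1)
    maf_cutoff: float = Field(0.05, ge=0.0, le=0.5)


class SimulateConfig(BaseModel):
    m: int = Field(50_000, ge=1)
    n_populations: int = Field(26, ge=2)
    miss_rate: float = Field(0.002, ge=0.0, lt=1.0)
    err_rate: float = Field(0.0059, ge=0.0, lt=1.0)
    r_err: float = Field(0.4, gt=0.0)
    array: ArrayConfig = ArrayConfig()


class InputConfig(BaseModel):
    """External inputs, used by pipelines that skip the simulator."""

    cohort_dir: Optional[str] = None
    cohort_basename: str = "cohort"
    array_dir: Optional[str] = None
    array_basename: str = "array"


class QCStageConfig(BaseModel):
    min_call_rate: float = Field(0.95, ge=0.0, le=1.0)
    min_maf: float = Field(0.01, ge=0.0, le=1.0)
    min_hwe_p: float = Field(1e-6, ge=0.0, le=1.0)
    max_pihat: float = Field(0.185, ge=0.0, le=1.0)
    kinship_max_variants: int = Field(20_000, ge=100)

    def thresholds(self) -> QCThresholds:
        return QCThresholds(
            min_call_rate=self.min_call_rate,
            min_maf=self.min_maf,
            min_hwe_p=self.min_hwe_p,
            max_pihat=self.max_pihat,
        )


class AscertainConfig(BaseModel):
    bins: list[float] = list(DEFAULT_BINS)


class ValidateConfig(BaseModel):
    r_exp: float = 2.1
    r_err: float = 0.4
    mode: Literal["ratio-linear", "proportion-mixture"] = "ratio-linear"


class StructureConfig(BaseModel):
    k: int = Field(5, ge=1)
    weight_mode: Literal["inverse-group-size", "uniform"] = "inverse-group-size"
    bootstrap_B: int = Field(100, ge=2)
    grs_n_auto: int = Field(50, ge=1)   # auto-picked common risk variants
    grs_variants: Optional[str] = None  # TSV path overriding the auto pick


class RunConfig(BaseModel):
    seed: int = 1
    stages: list[str] = list(STAGES)
    simulate: SimulateConfig = SimulateConfig()
    inputs: InputConfig = InputConfig()
    qc: QCStageConfig = QCStageConfig()
    ascertain: AscertainConfig = AscertainConfig()
    validate_: ValidateConfig = Field(ValidateConfig(), alias="validate")
    structure: StructureConfig = StructureConfig()

    model_config = {"populate_by_name": True}

    @field_validator("stages")
    @classmethod
    def _check_stages(cls, v):
        unknown = [s for s in v if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")
        return v


def load_config(path) -> RunConfig:
    import yaml

    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return RunConfig.model_validate(raw)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except (ValidationError, Exception) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid run configuration: {exc}") from None


def _write_json(obj, path: Path):
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)


def _write_tsv(df: pd.DataFrame, path: Path, index=False):
    tmp = path.with_name(path.name + ".tmp")
    df.to_csv(tmp, sep="\t", index=index, float_format="%.10g")
    os.replace(tmp, path)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured stage prefix; returns a summary dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": config.stages}
    cohort: Cohort | None = None
    array_cohort: Cohort | None = None
    qc_cohort: Cohort | None = None

    def _load_inputs() -> Cohort:
        if config.inputs.cohort_dir is None:
            raise DataError(
                "stage needs a cohort: run the simulate stage or set inputs.cohort_dir"
            )
        return read_cohort(config.inputs.cohort_dir, config.inputs.cohort_basename)

    if "simulate" in config.stages:
        sc = config.simulate
        panel = draw_ancestral_frequencies(sc.m, seed=derive_seed(config.seed, "panel"))
        cohort = simulate_admixed_cohort(
            panel, default_populations(sc.n_populations),
            seed=derive_seed(config.seed, "cohort"),
        )
        cohort = inject_errors_and_missingness(
            cohort, miss_rate=sc.miss_rate, err_rate=sc.err_rate, R_err=sc.r_err,
            seed=derive_seed(config.seed, "errors"),
        )
        design = ArrayDesign(
            discovery_ancestry=sc.array.discovery_ancestry,
            discovery_n=sc.array.discovery_n,
            maf_cutoff=sc.array.maf_cutoff,
        )
        array_cohort = ascertain_array_panel(
            cohort, design, seed=derive_seed(config.seed, "array")
        )
        stage_dir = out_dir / "simulate"
        write_cohort(cohort, stage_dir, "wgs", formats=("vcf", "metadata"))
        write_cohort(array_cohort, stage_dir, "array", formats=("vcf", "metadata"))
        summary["simulate"] = {
            "n_samples": cohort.n_samples,
            "n_variants": cohort.n_variants,
            "n_array_variants": array_cohort.n_variants,
        }
        log.info(
            "simulate: %d samples, %d WGS variants, %d array variants",
            cohort.n_samples, cohort.n_variants, array_cohort.n_variants,
        )

    if "qc" in config.stages:
        if cohort is None:
            cohort = _load_inputs()
        stage_dir = out_dir / "qc"
        stage_dir.mkdir(parents=True, exist_ok=True)
        res = variant_qc(cohort, config.qc.thresholds())
        metrics = res.metrics.copy()
        metrics.insert(0, "chrom", cohort.variants.data["chrom"])
        metrics.insert(1, "pos", cohort.variants.data["pos"])
        metrics["pass"] = res.mask
        _write_tsv(metrics, stage_dir / "variant_qc.tsv")
        filtered = cohort.subset_variants(res.mask)
        pruned, removals = ibd_prune(
            filtered, config.qc.thresholds(),
            max_variants=config.qc.kinship_max_variants,
        )
        _write_tsv(removals, stage_dir / "ibd_removals.tsv")
        write_cohort(pruned, stage_dir, "pruned", formats=("vcf", "metadata"))
        audit = sample_size_audit(pruned.samples)
        _write_tsv(audit.to_frame(), stage_dir / "sample_size_audit.tsv", index=True)
        pheno = phenotype_summary(
            cohort.samples,
            columns={"sex": None, "bmi_class": None, "region": None, "altitude_band": None},
        )
        _write_tsv(pheno, stage_dir / "phenotype_summary.tsv")
        qc_summary = {
            "n_variants_in": cohort.n_variants,
            "n_variants_pass": int(res.mask.sum()),
            "frac_samples_passing_call_rate": res.frac_samples_passing,
            "n_samples_in": cohort.n_samples,
            "n_samples_after_ibd": pruned.n_samples,
            "n_removed_ibd": len(removals),
            "audit": {
                "n_populations": audit.n_populations,
                "n_below_min": audit.n_below_min,
                "pct_below_min": audit.pct_below_min,
                "n_below_critical": audit.n_below_critical,
                "pct_below_critical": audit.pct_below_critical,
                "size_ratio": audit.size_ratio,
            },
        }
        _write_json(qc_summary, stage_dir / "summary.json")
        summary["qc"] = qc_summary
        qc_cohort = pruned
        log.info(
            "qc: %d/%d variants pass, %d/%d samples kept after IBD pruning",
            int(res.mask.sum()), cohort.n_variants, pruned.n_samples, cohort.n_samples,
        )

    if "ascertain" in config.stages:
        if cohort is None:
            cohort = _load_inputs()
        if array_cohort is None:
            if config.inputs.array_dir is None:
                raise DataError(
                    "ascertain stage needs an array cohort: run simulate or set inputs.array_dir"
                )
            array_cohort = read_cohort(
                config.inputs.array_dir, config.inputs.array_basename
            )
        report = maf_spectrum_distortion(
            cohort, array_cohort, bins=tuple(config.ascertain.bins)
        )
        stage_dir = out_dir / "ascertain"
        stage_dir.mkdir(parents=True, exist_ok=True)
        _write_tsv(report.to_frame(), stage_dir / "spectrum.tsv")
        _write_tsv(
            report.per_chromosome_capture.to_frame(), stage_dir / "capture_by_chrom.tsv",
            index=True,
        )
        asc_summary = {
            "capture_rate": report.capture_rate,
            "rare_bin_pp": report.rare_bin_pp,
            "common_bin_pp": report.common_bin_pp,
            "n_wgs_polymorphic": report.n_wgs,
            "n_array_polymorphic": report.n_array,
        }
        _write_json(asc_summary, stage_dir / "summary.json")
        summary["ascertain"] = asc_summary
        log.info(
            "ascertain: capture %.3f, rare %.1fpp, common %+.1fpp",
            report.capture_rate, report.rare_bin_pp, report.common_bin_pp,
        )

    if "validate" in config.stages:
        if cohort is None:
            cohort = _load_inputs()
        vc = config.validate_
        rep = validation_report(cohort, R_exp=vc.r_exp, R_err=vc.r_err, mode=vc.mode)
        stage_dir = out_dir / "validate"
        stage_dir.mkdir(parents=True, exist_ok=True)
        _write_tsv(
            rep.burden.per_sample.rename("non_ref_count").reset_index(),
            stage_dir / "burden.tsv",
        )
        _write_json(rep.summary(), stage_dir / "summary.json")
        summary["validate"] = rep.summary()
        log.info(
            "validate: Ts/Tv %.4f, artifact bound %.2f%%",
            rep.tstv.ratio or float("nan"), rep.error_bound.e_percent,
        )

    if "structure" in config.stages:
        target = qc_cohort if qc_cohort is not None else (cohort or _load_inputs())
        st = config.structure
        pca_cfg = PCAConfig(
            k=st.k, weight_mode=st.weight_mode,
            seed=derive_seed(config.seed, "pca"),
        )
        stage_dir = out_dir / "structure"
        stage_dir.mkdir(parents=True, exist_ok=True)
        pca = weighted_pca(target, pca_cfg)
        _write_tsv(pca.coordinates.reset_index(), stage_dir / "coordinates.tsv")
        _write_tsv(
            pd.DataFrame({"eigenvalue": pca.eigenvalues}), stage_dir / "eigenvalues.tsv"
        )
        boot = stratified_bootstrap_stability(
            target, pca_cfg, B=st.bootstrap_B,
            seed=derive_seed(config.seed, "bootstrap"),
        )
        _write_tsv(
            boot.cluster_consistency.to_frame().reset_index(names="population"),
            stage_dir / "cluster_consistency.tsv",
        )
        fst = pairwise_fst(target)
        _write_tsv(fst, stage_dir / "fst_matrix.tsv", index=True)
        risk = _risk_variants(target, st, config.seed)
        grs = unweighted_grs(target, risk)
        _write_tsv(grs.per_population.reset_index(), stage_dir / "grs_by_population.tsv")
        st_summary = {
            "k": st.k,
            "eigenvalues": [float(e) for e in pca.eigenvalues],
            "bootstrap_B": boot.B,
            "bootstrap_mean_rmsd": boot.mean_rmsd,
            "mean_cluster_consistency": float(boot.cluster_consistency.mean()),
            "singleton_populations": boot.singleton_populations,
            "max_pairwise_fst": float(np.asarray(fst).max()),
            "grs_rank_test_p": grs.rank_test_p,
        }
        _write_json(st_summary, stage_dir / "summary.json")
        summary["structure"] = st_summary
        log.info(
            "structure: k=%d, bootstrap RMSD %.4f, mean consistency %.2f",
            st.k, boot.mean_rmsd, float(boot.cluster_consistency.mean()),
        )

    _write_json(summary, out_dir / "run_summary.json")
    return summary


def _risk_variants(cohort: Cohort, st: StructureConfig, seed: int) -> VariantTable:
    """Risk-variant list for the GRS stage: a TSV if configured, otherwise a
    seeded pick of common biallelic SNVs with the alt allele as risk allele."""
    if st.grs_variants is not None:
        df = pd.read_csv(st.grs_variants, sep="\t", dtype={"chrom": str})
        return VariantTable(df)
    from ._util import minor_allele_freq

    maf = minor_allele_freq(cohort.genotypes)
    common = np.flatnonzero(
        (np.nan_to_num(maf, nan=0.0) >= 0.10) & cohort.variants.is_biallelic_snv
    )
    if common.size == 0:
        raise DataError("no common biallelic SNVs available for the GRS demo pick")
    rng = np.random.default_rng(derive_seed(seed, "grs"))
    pick = np.sort(rng.choice(common, size=min(st.grs_n_auto, common.size), replace=False))
    df = cohort.variants.data.iloc[pick][["chrom", "pos", "ref", "alt"]].copy()
    df["risk_allele"] = cohort.variants.data["alt"].iloc[pick].to_numpy()
    return VariantTable(df)
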