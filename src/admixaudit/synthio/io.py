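"""Cohort I/O: VCF v4.2 (GT-only), PLINK-style transposed text dosages, metadata TSV.

A cohort on disk is a set of sibling files sharing a directory and basename:

``<base>.vcf``              VCFv4.2, 1-based positions, FORMAT=GT, missing ``./.``
``<base>.traw``             transposed dosage table (variants x samples, NA missing)
``<base>.map``              4-column variant map (chrom, id, 0, pos)
``<base>.samples.tsv``      tab-separated sample metadata with header
``<base>.admixture.tsv``    (optional) realized per-sample admixture truth
``<base>.flags.tsv``        (optional) per-variant artifact truth flags

Write -> read round-trips preserve dosages, variant keys and metadata exactly,
and a second write is byte-identical to the first.
"""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ..errors import ParseError, SchemaError
from ..types import Cohort, CohortTruth, VariantTable

_GT_CODE = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _atomic(path: Path):
    return path.with_name(path.name + ".tmp")


def write_vcf(cohort: Cohort, path) -> Path:
    """Write a GT-only VCFv4.2 file; deterministic byte output for a given cohort."""
    path = Path(path)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    seen = []
    for chrom in cohort.variants.data["chrom"]:
        if chrom not in seen:
            seen.append(chrom)
    for chrom in seen:
        header.add_line(f"##contig=<ID={chrom}>")
    for sid in cohort.samples["sample_id"]:
        header.add_sample(str(sid))
    tmp = _atomic(path)
    with pysam.VariantFile(str(tmp), "w", header=header) as vcf:
        vdf = cohort.variants.data
        g = cohort.genotypes
        sample_ids = list(cohort.samples["sample_id"].astype(str))
        for j, (chrom, pos, ref, alt) in enumerate(
            zip(vdf["chrom"], vdf["pos"], vdf["ref"], vdf["alt"])
        ):
            rec = vcf.new_record(
                contig=chrom, start=int(pos) - 1, alleles=(ref, *alt.split(","))
            )
            for i, sid in enumerate(sample_ids):
                dosage = int(g[i, j])
                if dosage < 0:
                    rec.samples[sid]["GT"] = (None, None)
                else:
                    # multiallelic dosages collapse onto the first alt on write
                    rec.samples[sid]["GT"] = _GT_CODE[dosage]
            vcf.write(rec)
    os.replace(tmp, path)
    return path


def read_vcf(path, samples: pd.DataFrame | None = None) -> Cohort:
    """Read a GT-only VCF into a Cohort; dosage = count of non-reference alleles.

    Genotypes with any missing allele are recorded as missing.  Malformed
    records raise :class:`ParseError` naming the approximate file line.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from None
    n_header = str(vcf.header).count("\n")
    sample_ids = list(vcf.header.samples)
    rows = {"chrom": [], "pos": [], "ref": [], "alt": []}
    dosages = []
    idx = 0
    try:
        for rec in vcf:
            idx += 1
            if rec.alts is None:
                raise ValueError("record without ALT allele")
            rows["chrom"].append(rec.chrom)
            rows["pos"].append(rec.pos)
            rows["ref"].append(rec.ref)
            rows["alt"].append(",".join(rec.alts))
            col = np.empty(len(sample_ids), dtype=np.int8)
            for i, sid in enumerate(sample_ids):
                gt = rec.samples[sid].get("GT", (None, None))
                if gt is None or any(a is None for a in gt):
                    col[i] = -1
                else:
                    col[i] = sum(1 for a in gt if a > 0)
            dosages.append(col)
    except (ValueError, OSError) as exc:
        raise ParseError(
            f"malformed VCF record in {path}: {exc}", line=n_header + idx + 1
        ) from None
    finally:
        vcf.close()
    if not dosages:
        genotypes = np.zeros((len(sample_ids), 0), dtype=np.int8)
    else:
        genotypes = np.stack(dosages, axis=1)
    if samples is None:
        samples = pd.DataFrame({"sample_id": sample_ids, "population": "unknown"})
    else:
        got = list(samples["sample_id"].astype(str))
        if got != sample_ids:
            raise SchemaError("metadata sample order does not match VCF sample order")
    return Cohort(genotypes=genotypes, variants=VariantTable(pd.DataFrame(rows)), samples=samples)


def _variant_ids(vdf: pd.DataFrame) -> list[str]:
    return [
        f"{c}:{p}:{r}:{a}"
        for c, p, r, a in zip(vdf["chrom"], vdf["pos"], vdf["ref"], vdf["alt"])
    ]


def write_plink_text(cohort: Cohort, traw_path, map_path) -> tuple[Path, Path]:
    """Write the transposed-dosage text dialect (.traw) plus a .map file."""
    traw_path, map_path = Path(traw_path), Path(map_path)
    vdf = cohort.variants.data
    ids = _variant_ids(vdf)
    sample_ids = list(cohort.samples["sample_id"].astype(str))
    tmp = _atomic(traw_path)
    with open(tmp, "w") as fh:
        fh.write("\t".join(["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"] + sample_ids))
        fh.write("\n")
        g = cohort.genotypes
        for j in range(len(vdf)):
            row = [
                str(vdf["chrom"].iat[j]), ids[j], "0", str(vdf["pos"].iat[j]),
                vdf["alt"].iat[j], vdf["ref"].iat[j],
            ]
            row += [str(int(d)) if d >= 0 else "NA" for d in g[:, j]]
            fh.write("\t".join(row))
            fh.write("\n")
    os.replace(tmp, traw_path)
    tmp = _atomic(map_path)
    with open(tmp, "w") as fh:
        for j in range(len(vdf)):
            fh.write(f"{vdf['chrom'].iat[j]}\t{ids[j]}\t0\t{vdf['pos'].iat[j]}\n")
    os.replace(tmp, map_path)
    return traw_path, map_path


def read_plink_text(traw_path, samples: pd.DataFrame | None = None) -> Cohort:
    traw_path = Path(traw_path)
    rows = {"chrom": [], "pos": [], "ref": [], "alt": []}
    dosages = []
    with open(traw_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:6] != ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]:
            raise ParseError(f"{traw_path} lacks a valid traw header", line=1)
        sample_ids = header[6:]
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6 + len(sample_ids):
                raise ParseError(
                    f"{traw_path}: expected {6 + len(sample_ids)} fields, got {len(fields)}",
                    line=lineno,
                )
            rows["chrom"].append(fields[0])
            rows["pos"].append(fields[3])
            rows["alt"].append(fields[4])
            rows["ref"].append(fields[5])
            col = np.empty(len(sample_ids), dtype=np.int8)
            for i, tok in enumerate(fields[6:]):
                if tok == "NA":
                    col[i] = -1
                else:
                    try:
                        val = int(tok)
                    except ValueError:
                        raise ParseError(
                            f"{traw_path}: bad dosage {tok!r}", line=lineno
                        ) from None
                    if val not in (0, 1, 2):
                        raise SchemaError(
                            f"{traw_path} line {lineno}: dosage {val} outside {{0,1,2,missing}}"
                        )
                    col[i] = val
            dosages.append(col)
    try:
        pos = [int(p) for p in rows["pos"]]
    except ValueError as exc:
        raise ParseError(f"{traw_path}: bad position ({exc})") from None
    rows["pos"] = pos
    genotypes = (
        np.stack(dosages, axis=1) if dosages else np.zeros((len(sample_ids), 0), np.int8)
    )
    if samples is None:
        samples = pd.DataFrame({"sample_id": sample_ids, "population": "unknown"})
    return Cohort(genotypes=genotypes, variants=VariantTable(pd.DataFrame(rows)), samples=samples)


def write_metadata(samples: pd.DataFrame, path) -> Path:
    path = Path(path)
    tmp = _atomic(path)
    samples.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)
    return path


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise ParseError(f"cannot parse metadata {path}: {exc}") from None
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path} lacks a sample_id column")
    return df


def write_cohort(
    cohort: Cohort,
    directory,
    basename: str = "cohort",
    formats: tuple[str, ...] = ("vcf", "metadata"),
    include_truth: bool = True,
) -> dict[str, Path]:
    """Write a cohort as sibling files; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / basename
    paths: dict[str, Path] = {}
    for fmt in formats:
        if fmt == "vcf":
            paths["vcf"] = write_vcf(cohort, base.with_suffix(".vcf"))
        elif fmt == "plink-text":
            traw, mp = write_plink_text(
                cohort, base.with_suffix(".traw"), base.with_suffix(".map")
            )
            paths["traw"], paths["map"] = traw, mp
        elif fmt == "metadata":
            paths["metadata"] = write_metadata(
                cohort.samples, directory / f"{basename}.samples.tsv"
            )
        else:
            raise SchemaError(f"unknown cohort format {fmt!r}")
    if include_truth and cohort.truth is not None:
        if cohort.truth.admixture is not None:
            p = directory / f"{basename}.admixture.tsv"
            tmp = _atomic(p)
            cohort.truth.admixture.to_csv(tmp, sep="\t")
            os.replace(tmp, p)
            paths["admixture"] = p
        if cohort.truth.error_flags is not None:
            p = directory / f"{basename}.flags.tsv"
            tmp = _atomic(p)
            pd.DataFrame(
                {"flagged": cohort.truth.error_flags.astype(int)}
            ).to_csv(tmp, sep="\t", index=False)
            os.replace(tmp, p)
            paths["flags"] = p
    return paths


def read_cohort(directory, basename: str = "cohort") -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    base = directory / basename
    meta_path = directory / f"{basename}.samples.tsv"
    samples = read_metadata(meta_path) if meta_path.exists() else None
    vcf_path = base.with_suffix(".vcf")
    traw_path = base.with_suffix(".traw")
    if vcf_path.exists():
        cohort = read_vcf(vcf_path, samples=samples)
    elif traw_path.exists():
        cohort = read_plink_text(traw_path, samples=samples)
    else:
        raise ParseError(f"no {basename}.vcf or {basename}.traw under {directory}")
    adm_path = directory / f"{basename}.admixture.tsv"
    flags_path = directory / f"{basename}.flags.tsv"
    if adm_path.exists() or flags_path.exists():
        admixture = (
            pd.read_csv(adm_path, sep="\t", index_col=0) if adm_path.exists() else None
        )
        flags = (
            pd.read_csv(flags_path, sep="\t")["flagged"].to_numpy().astype(bool)
            if flags_path.exists()
            else None
        )
        cohort.truth = CohortTruth(admixture=admixture, error_flags=flags)
    return cohort
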