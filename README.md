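# admixaudit

A cohort-audit toolkit for admixed population genomics. It addresses a
recurring situation in genome projects of under-represented populations —
South American cohorts mixing Native American, European and African ancestry
are the motivating case: many small, unevenly sampled populations (sample
sizes spanning 8:1), genotyping arrays whose content was ascertained in
European discovery panels, and call sets whose quality must be argued from
summary statistics because the genotypes themselves are controlled-access.

The toolkit provides, as a library and a CLI:

- **Synthetic admixed cohorts with ground truth** (`admixaudit.synthio`).
  Ancestral allele frequencies follow a rare-variant-rich truncated
  Beta(0.2, 0.2) spectrum; each ancestry and each population drifts under the
  Balding–Nichols model, `p' ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, so
  `E[p'] = p` and `Var[p'] = F·p(1−p)`. Diploid genotypes draw each allele
  copy's ancestry from the population's admixture vector `q` and then the
  allele Bernoulli(`p`). Array ascertainment keeps variants with MAF ≥ cutoff
  in a discovery haplotype sample from one ancestry; artifact sites with a
  distinct Ts/Tv ratio and i.i.d. missingness can be injected. VCF v4.2
  (GT-only), PLINK-style transposed text and metadata TSV round-trip exactly.
- **QC** (`admixaudit.qc`): per-variant call rate, MAF, heterozygosity and
  the Levene–Haldane HWE exact test; method-of-moments IBS pi-hat and IBD
  pruning; per-population sample-size audits (30- and 10-sample thresholds);
  Table-style categorical summaries.
- **Ascertainment bias** (`admixaudit.ascertain`): capture rate (fraction of
  WGS variant keys on the array, overall and per chromosome) and MAF-spectrum
  distortion in percentage points per bin, with rare (<0.5% MAF) and common
  (>10%) cutpoints.
- **Variant validation** (`admixaudit.validate`): Ts/Tv with multiallelic
  decomposition, per-individual burden, multiallelic rate, and a two-component
  Ts/Tv-mixture artifact bound: ratio-linear
  `e = (R_exp − R_obs)/(R_exp − R_err)` (conservative default) or the
  proportion-mixture solution of `p_obs = (1−e)p_exp + e·p_err` with
  `p = R/(1+R)`.
- **Population structure** (`admixaudit.structure`): weighted PCA with
  per-sample weights `w_i = 1/n_{g(i)}` entering both the allele-frequency
  standardization and the covariance; stratified bootstrap with Procrustes
  alignment (rotation/reflection/scaling/translation) and nearest-centroid
  cluster consistency; Hudson FST (ratio-of-averages across sites); and
  unweighted polygenic risk scores.

## Worked example

```python
import admixaudit as aa

# 8 admixed populations, sizes 10..80, European-discovery array (120
# haplotypes, MAF >= 0.05), 0.59% injected artifact sites
wgs, array, design = aa.default_study(seed=1, m=20_000, n_populations=8)

report = aa.maf_spectrum_distortion(wgs, array)
print(f"capture rate: {report.capture_rate:.3f}")
print(f"rare-bin (<0.5% MAF) distortion: {report.rare_bin_pp:+.1f} pp")
print(f"common-bin (>10% MAF) distortion: {report.common_bin_pp:+.1f} pp")

val = aa.validation_report(wgs)
print(f"Ts/Tv: {val.tstv.ratio:.3f}  artifact bound: {val.error_bound.e_percent}%")

audit = aa.sample_size_audit(wgs.samples)
print(f"below 30 samples: {audit.n_below_min} populations, ratio {audit.size_ratio:.0f}:1")
```

prints

```
capture rate: 0.498
rare-bin (<0.5% MAF) distortion: -9.7 pp
common-bin (>10% MAF) distortion: +17.5 pp
Ts/Tv: 2.057  artifact bound: 2.5%
below 30 samples: 2 populations, ratio 8:1
```

The array keeps half of the WGS variants, depletes the rare end of the
spectrum by ~10 percentage points and enriches the common end — the
directional signature of discovery-panel ascertainment. The Ts/Tv of 2.057
sits in the high-quality 2.0–2.2 band; the ratio-linear mixture converts the
shortfall from 2.1 into a conservative artifact-fraction bound.

The same stages run from the shell on synthetic or user-supplied cohorts:

```bash
admixaudit demo-config --out demo.yaml
admixaudit run --config demo.yaml --out results/demo
admixaudit qc --cohort-dir my_data --out results/qc   # own VCF + metadata TSV
```

`run` executes simulate → qc → ascertain → validate → structure; identical
config and seed give byte-identical report bundles. Exit codes: 0 success,
2 configuration error, 3 data/format error, 4 stage failure.

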