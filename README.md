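# cgprofiler

A decision engine for tumor-normal comprehensive genomic profiling (CGP)
panels. Given annotated somatic/germline variant calls, a panel definition,
depth profiles, microsatellite repeat-length tables, breakpoint evidence and
plasma amplicon pileups, it computes every biomarker decision such an assay
reports, plus the analytical-validation statistics used to qualify one:

- **Sample QC** — pass iff mean on-target depth ≥ 150X *and* ≥ 75% of panel
  bases covered at 100X (both inclusive).
- **TMB** — eligible somatic variants (PASS, non-dbSNP, coding,
  non-synonymous, VAF ≥ 5%, alt depth ≥ 5, total depth ≥ 15) divided by the
  effective panel size in Mb (coding bases at ≥ 15X); TMB-High at
  ≥ 10 mut/Mb. Includes an in-silico tumor-fraction dilution experiment.
- **MSI** — per-locus tumor-vs-normal chi-squared test on repeat-length
  histograms with a modal-shift requirement; MSI-High when ≥ 20% of
  detected loci are unstable. A 5-marker PCR classifier (MSI-High at ≥ 2 of
  5 altered markers) is included.
- **Gene amplification** — 100-bp-binned coverage against a
  panel-of-normals median baseline; a gene is amplified when its segment
  mean copy ratio (linear scale) is ≥ 2.0.
- **Gene fusions** — split-read breakpoint evidence clustered within a
  positional tolerance; reported at ≥ 2 spanning reads.
- **ctDNA / MRD tracking** — composite ranking of tumor variants
  (tissue VAF, pathogenicity, mutation type, database recurrence,
  whitelist), top 2–5 selection, amplicon positivity (evaluable at
  ≥ 10,000X, positive strictly above 0.05% VAF) and longitudinal
  clearance / molecular-relapse events.
- **Validation statistics** — sensitivity/specificity against truth sets,
  limit of detection (minimum VAF detected in ≥ 95% of replicates),
  categorical concordance and ordinary-least-squares fits with R².

A first-class synthetic-data module (`cgprofiler.synth`) generates every
input with a known truth manifest, emulating the commercial reference
standards used for analytical validation (a 228-variant truth set of
211 SNVs + 17 indels, +3-copy amplification standards, a six-junction
fusion standard, ~800-locus microsatellite tables, 100,000X plasma
amplicons).

## Worked example

```python
from cgprofiler import synth, tmb

fx = synth.generate_somatic_fixture(
    synth.SomaticSpec(n_snv=17, n_indel=0, n_ineligible=20,
                      coding_bases=1_700_000, noncoding_bases_per_gene=0),
    seed=3,
)
result = tmb.compute_tmb(fx.variants, fx.depth_profile, fx.panel)
print(result)
```

prints

```
TmbResult(eligible_count=17, panel_mb=1.7, score=10.0, status='TMB-H')
```

Seventeen eligible mutations over a 1.7 Mb effective coding panel give
exactly 10 mutations/Mb — the inclusive TMB-High boundary — while the 20
planted decoys (synonymous, dbSNP, non-coding, low-VAF or filter-failed
variants) are correctly excluded from the numerator.

The same pipeline is available from the shell:

```sh
cgprofiler simulate --seed 3 --out bundle/
cgprofiler tmb --vcf bundle/tumor.vcf --panel bundle/panel.bed --depth bundle/depth.tsv
cgprofiler profile --vcf ... --panel ... --depth ... [--msi-tumor ... --cnv-sample ...]
```

`profile` emits one JSON report with every biomarker block, its threshold
and inclusivity; a sample failing QC yields a QC-only report and exit
code 3 (uncallable is never conflated with negative).

## Layout

| module | contents |
| --- | --- |
| `cgprofiler.core` | domain types, QC gate, effective panel size, artifact filter |
| `cgprofiler.vcfio` | VCF/BED/depth-TSV readers and writers |
| `cgprofiler.tmb` | eligibility filter, TMB score, mixing + dilution experiment |
| `cgprofiler.msi` | per-locus instability test, NGS and PCR classifiers |
| `cgprofiler.cnv` | panel-of-normals baseline, amplification calling |
| `cgprofiler.fusion` | breakpoint clustering, fusion detection |
| `cgprofiler.mrd` | variant ranking, plasma calling, trajectories |
| `cgprofiler.valstats` | confusion, LOD, concordance, linear fits |
| `cgprofiler.synth` | truth-manifested fixture generators |
| `cgprofiler.cli` | `cgprofiler` command-line entry point |

See `docs/methods.md` for the statistical model behind each stage and the
design choices where the published rules leave room.
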