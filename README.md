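# escirc

Detection, quantification and interpretation of **excised signal circles
(ESCs)** — the circular DNA by-products of deletional V(D)J recombination —
from targeted (LAM-style) amplicon sequencing and paired-end WGS, with
replication/persistence inference and cryptic-RSS structural-variant
classification. Every stage is exercisable offline through a bundled
synthetic-data generator.

## What's inside

| module | purpose |
|---|---|
| `escirc.locus_model` | toy Ig locus (segments, RSSs, KDE) and enumeration of coding-junction / signal-joint reference databases |
| `escirc.synthetic_data` | clonal populations with ESC replication/dilution/segregation, WGS-style and LAM amplicon read simulation, SV sets with planted cryptic RSSs |
| `escirc.wgs_sj_detect` | signal-joint detection from divergent (outward-facing) read pairs with split-read breakpoint refinement |
| `escirc.lam_junction_caller` | demultiplex by nested J primer, merge pairs by 3' overlap, seeded banded local alignment to the junction database, quantification and control-based thresholding |
| `escirc.replication_dynamics` | doubling/dilution arithmetic, observed/predicted SJ ratios, recent-event filter, clonotype extraction, major-event (knee) detection |
| `escirc.rss_sv_classifier` | PWM scan for cryptic RSSs, ±50 bp breakpoint windows, SV typing and mechanism attribution (cut-and-run / reintegration / RAG insertion / two-cRSS), gene-set enrichment |
| `escirc.stats_report` | exact Fisher, Mann–Whitney U, Wilcoxon signed-rank and hypergeometric upper tail; threshold contingency tables |
| `escirc.io`, `escirc.cli` | FASTA/FASTQ/SAM/BED/TSV/YAML round-trip I/O and the `esc` umbrella CLI |

## CLI

All stages hang off one entry point:

```bash
# full demo pipeline (simulate -> lam-call -> replication -> svscan)
esc run-all --config src/escirc/data/demo_config.yaml --outdir results/demo

# individual stages
esc simulate population --config cfg.yaml --outdir out/
esc simulate wgs        --config cfg.yaml --outdir out/
esc simulate lam        --config cfg.yaml --assay signal --outdir out/
esc simulate sv         --config cfg.yaml --outdir out/
esc detect-wgs  --sam out/wgs.sam --loci-bed out/loci.bed --db out/junction_db.tsv --out cands.tsv
esc lam-call    --fastq1 R1.fastq --fastq2 R2.fastq --primers primers.tsv \
                --db junction_db.tsv --assay esc --out quant.tsv
esc replication ratio --summary population_truth.tsv --out ratios.tsv
esc replication majors --rec-table quant_coding.tsv --out majors.tsv
esc svscan      --genome genome.fasta --sv svs.tsv --loci-bed loci.bed --out ann.tsv
esc report      --quant s1=q1.tsv --quant s2=q2.tsv --design design.tsv --out report.json
```

`run-all` writes a `manifest.json` recording every derived seed and parameter
block; rerunning with the same config reproduces byte-identical tables.
Existing non-empty result directories are refused unless `--force` is given.

Config is YAML with a mandatory global `seed`; each stochastic stage receives
a deterministic seed derived from it by stage name (overridable per stage).
See `src/escirc/data/demo_config.yaml` for the full schema with defaults.

## Conventions

- Coordinates are 0-based, half-open (BED-compatible) throughout.
- SJ and coding reference sequences are written in sequencing orientation:
  J-side flank 5'→3' first, then the partner side, matching amplification
  primed from J regions.
- Detection from WGS is presence/absence only; low-depth WGS cannot
  quantify circles.
- Normalized reads = reads per junction / total assay reads in the
  experiment; thresholds are strict (`>`), so control samples define zero
  positives by construction.
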