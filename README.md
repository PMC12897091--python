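# msquant

Quantitative microsatellite-instability (MSI) scoring from aligned
tumor-only amplicon reads, without an external reference genome.

The method works directly on SAM records: reads are filtered by mapping
quality and FLAG bits, assigned to a user-supplied microsatellite locus
panel, the local reference sequence is recovered from CIGAR strings and MD
tags (preferring mutation-free "reference reads", falling back to a majority
consensus of per-read reconstructions), and insertions, deletions and base
substitutions inside each repeat tract are counted. Two sample-level scores
are produced — the mean percentage of mutated reads per gene, and the mean
percentage of total mutation events per gene (which may exceed 100%) — and
dichotomized at cutoffs calibrated by ROC analysis with the Youden index.
Concordance against reference assays (sensitivity, specificity, overall
agreement) and the classic ≥30% marker-panel PCR rule are also implemented.

## Layout

| module | responsibility |
| --- | --- |
| `msquant.sam_model` | SAM record model, FLAG decoding, validity filters (MAPQ ≥ 60; excludes 0x4/0x100/0x800) |
| `msquant.panel` | panel TSV loading (BED dialect) and read-to-locus assignment by full coverage |
| `msquant.refrecon` | MD-tag parsing, reference-read detection, reference reconstruction and per-locus consensus |
| `msquant.msi_metrics` | in-window mutation-event extraction and the two instability metrics |
| `msquant.msi_stats` | ROC/Youden cutoff calibration, MSI/MSS calls, PCR panel rule, concordance statistics |
| `msquant.synthetic` | consistent synthetic read/sample/cohort generation and the three functional test scenarios |
| `msquant.pipeline` + `msquant.cli` | end-to-end orchestration and the `msquant` command |

## CLI

```sh
# simulate a labeled synthetic cohort (built-in 10-locus demo panel)
msquant simulate --out cohort/ --seed 7 --n-msi 8 --n-mss 8 --reads-per-locus 50

# quantify one sample, optionally classifying at supplied cutoffs (%)
msquant run --alignments cohort/sams/MSI_01.sam --panel cohort/panel.tsv \
    --out run/ --sample-id MSI_01 \
    --cutoff-mutated-reads 44.72 --cutoff-total-mutations 71.00

# calibrate cutoffs from labeled per-sample scores
msquant calibrate --scores cohort/scores.tsv --out calib/

# concordance from an explicit 2x2 table (tp/fp/fn/tn) or a paired-calls TSV
msquant concord --tp 14 --fp 3 --fn 0 --tn 14
```

Panel files are 6-column TSV in BED coordinates
(`chrom  start  end  locus_id  gene  repeat_unit`, `#` comments allowed).
The bundled demo panel (`msquant.synthetic.demo_panel`) uses synthetic
coordinates and is for simulation/testing only — it is not a clinical panel.

## Notes

- Cutoff boundary convention: a score exactly at the cutoff is called MSI.
- ROC candidate thresholds are the observed scores (a midpoint dialect of the
  threshold grid is deliberately not the default); Youden ties break toward
  higher specificity, then the lower cutoff.
- Duplicate (0x400) and QC-fail (0x200) reads are retained by default but can
  be excluded via `ReadFilterPolicy(forbidden_flags=...)`.
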