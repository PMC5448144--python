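# triodx

Trio-aware diagnostic sequencing analysis for developmental-delay /
intellectual-disability (DD/ID) cohorts.

Clinical genome/exome sequencing of a child with unexplained DD/ID works
best when both biological parents are sequenced alongside the proband: a
trio makes de novo variation directly observable, resolves compound-het
phase by transmission, and distinguishes X-linked maternal inheritance.
`triodx` packages that whole analysis as a tested pipeline for methods
development and benchmarking:

- **cohortsim** — a synthetic-cohort generator (families, multi-sample
  VCFs, annotation tables, CNV callsets, family-history records) with a
  planted-variant truth ledger, so every downstream stage can be scored
  against known answers;
- **pedcore** — pedigree model, analysis-unit enumeration (trio / duo /
  singleton per affected proband), within-family KING-robust kinship
  verification (φ = (N_het,both − 2·N_opp,hom)/(N_het,i + N_het,j)) and
  Mendelian-violation QC;
- **inherit_filter** — inheritance-mode detection (de novo, homozygous
  recessive, compound het, X-linked maternal; duo/singleton
  modifications) and a replayable quality/frequency/impact filter cascade
  (depth ≥ 10 in every unit member, batch allele count ≤ 1 per unrelated
  family, mode-specific AF caps, consequence classes), plus a
  filter-independent scan for alleles asserted pathogenic/likely
  pathogenic;
- **cnvmerge** — dual-caller CNV consensus at ≥ 90% reciprocal overlap,
  segmental-duplication (< 50%) and parental-frequency (≤ 5 unaffected
  carriers) filters, curation flags within 5 kb of panel genes;
- **classify** — a five-tier (P / LP / VUS / LB / B) ordered-rule engine
  over evidence bundles, plus the three parental secondary-findings
  screens (actionable 56-gene panel, self-reported-condition matches,
  carrier status) and a mate-pair shared-carrier scan;
- **reanalysis** — replay of filtering + classification under updated
  knowledge snapshots, with per-variant reclassification records and
  upgrade metrics;
- **singleton_rank** — the parent-blind experiment: strip parental
  genotypes, filter under nested scenarios, rank by CADD-scaled score,
  report rank curves of designated P/LP variants;
- **yieldstats** — per-proband results table, diagnostic yield by family
  structure / history / assay, half-up-rounded printed-style percentages,
  two-sided Fisher exact comparisons.

## Worked example

Simulate a study-scale cohort (371 analysis units) and run it end to end:

```sh
triodx simulate --seed 5 --out-dir cohort
triodx prioritize --cohort-dir cohort --out-dir run
triodx cnv --cohort-dir cohort --out-dir cnv
triodx classify --cohort-dir cohort --run-dir run --cnv-dir cnv --out-dir cls
triodx report --results cls/results.tsv --out-dir report
```

which logs

```
simulate:   {'families': 371, 'analysis_units': 371, 'truth_events': 134}
prioritize: {'candidates': 1513, 'surviving': 92, 'planted_eligible': 92,
             'planted_recovered': 92, 'clinvar_hits': 37}
cnv:        {'consensus_calls': 8, 'retained': 8, 'findings': 8}
classify:   {'probands': 371, 'plp': 100, 'secondary_findings': 12,
             'carrier_couples': 1}
```

and prints (`report/report.txt`):

```
## yield by structure
group              n_PLP       n   percent
duo                    6      35      17.1
singleton              2      14      14.3
trio                  92     322      28.6
```

Reading: of 371 simulated probands, 100 (27%) received a pathogenic or
likely pathogenic finding — 92 SNV/indel events recovered by the trio
filter cascade (every planted event whose evidence met the default depth
floor, with its inheritance mode correctly re-derived) plus 8 consensus
CNVs. Trio units yield at ~29%, duos and singletons lower, and simplex
families (~33% here) above multiplex families (~17%), reproducing the
qualitative structure-and-history gradient the pipeline is designed to
expose. `qc`, `reanalyze` and `rankbench` subcommands cover relationship
verification, knowledge-snapshot reanalysis and the parent-blind ranking
benchmark; every stage writes a `manifest.json` with input references,
record counts and SHA-256 checksums of its outputs.

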