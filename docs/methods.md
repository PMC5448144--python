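# Methods

`triodx` reimplements, as a reusable and testable pipeline, the analysis
pattern used in diagnostic sequencing of developmental-delay / intellectual-
disability (DD/ID) cohorts: proband-parent trios are sequenced, variants are
prioritized by inheritance mode and filtered on quality, frequency and
impact, survivors are classified into five pathogenicity tiers, copy-number
variants are consensus-called from two read-depth callers, parents are
screened for secondary findings, and everything is periodically reanalyzed
against updated gene-disease knowledge. A synthetic-cohort generator with a
planted-variant truth ledger drives all stages, so the whole pipeline runs
and is scored without access to protected patient data.

## The synthetic cohort

The generator's defaults encode the study conditions of a 371-proband
DD/ID cohort:

| parameter | default | meaning |
|---|---|---|
| `n_families` | 371 | one affected proband per family unless configured otherwise |
| `structure_mix` | trio 309/371, duo 42/371, singleton 20/371 | number of sequenced biological parents |
| `history_mix` | simplex 93/301, intermediate 85/301, multiplex 123/301 | family-history stratum |
| `yield_by_history` | 0.376 / 0.26 / 0.195 | probability a family carries a returnable (P/LP) planted event |
| `mode_mix` | de novo 0.76, recessive/comp-het 0.12, X-linked maternal 0.05, unknown 0.07 | inheritance mode of planted events |
| `consequence_mix` | missense 0.52, nonsense-or-frameshift 0.39, splice 0.07, inframe 0.02 | consequence class of planted events |
| `history_missing_rate` | 38/339 | families with no reported-relative records (history "unknown") |
| `n_sites` | 120 | shared background biallelic panel (plus a small X panel) |
| background AF | Beta(0.2, 2) truncated to [0.001, 0.5] | skewed toward rare alleles |
| depth | negative binomial, mean 35, dispersion 0.1 | WGS-like per-sample read depth |
| `cnv.n_events` | 8 | causal CNVs substituted for SNV events in yielding families |

Design points worth knowing:

- **Per-class yield probabilities are generative parameters, not paper
  claims.** The study reports observed rates; we adopt them as the
  underlying event probabilities (the pipeline then re-observes them with
  sampling noise). The expected overall yield is
  0.309·0.376 + 0.282·0.26 + 0.409·0.195 ≈ 0.27.
- **Mode drives structure for planted families.** Informative modes
  (de novo, recessive, X-linked) are only provable in trios; unknown-mode
  events only occur in duos/singletons. A planted family's structure is
  therefore chosen among structures compatible with its drawn mode, and the
  configured structure mix holds marginally for unplanted families. The
  realized trio share runs a few percent above its target as a consequence;
  mode fractions are exact in expectation.
- **CNV events substitute for SNV events.** About 8 of the ~100 yielding
  families carry a causal CNV instead of an SNV/indel, mirroring the
  composition of returnable findings; those probands are forced to the WGS
  assay (CNV calling here is WGS-only).
- **Background sites are Hardy-Weinberg with exact Mendelian
  transmission.** Latent parents are always simulated, so duo and singleton
  proband genotypes still follow transmission. Genotype error is off by
  default (`genotype_error_rate=0`) and is switched on only by QC tests.
- **Planted sites are family-private**, so their cohort-internal batch
  allele count is 1 by construction; background panel sites are shared
  across families, making the batch-count filter meaningful.
- **Compound-het events are emitted unphased.** Parental origin must be
  re-derived from transmission (one het parent per site), as with real
  short-read data. The truth ledger records the intended origins.
- **X chromosome**: one non-pseudoautosomal contig; males are haploid
  (hemizygous genotype states, haploid VCF genotypes).
- Small numbers of auxiliary events are planted for the secondary-findings
  machinery: ClinVar-style asserted carrier alleles (AF set to 0.002 —
  rare but present in the population, so a het carrier never inflates the
  diagnostic yield), actionable-panel parental hits, a shared-carrier
  couple, and parents whose biallelic recessive genotypes match a
  self-reported condition.

What the generator does **not** emulate: read-level data, linkage
disequilibrium, recombination, population structure, annotation error,
caller-specific artifact spectra, or mosaicism. Passing tests therefore
demonstrate the *logic* of the pipeline (mode detection, filter replay,
classification determinism, merge/rank bookkeeping), not robustness to the
noise structure of real sequencing data.

## Prioritization and filtering

Trio logic: de novo (proband carries alt, both parents hom-ref with a
parental alt-read fraction ≤ 0.05 as a mosaicism guard), homozygous
recessive (proband hom-alt, parents het), X-linked maternal (male proband
hemizygous alt, carrier mother, ref father), and compound het (all
maternal × paternal pairs within a gene; variants carried by both parents
never pair). Duos keep modes compatible with the single sequenced parent at
reduced confidence; singleton probands pass every alt genotype through with
mode `unknown`.

The filter cascade (all thresholds in `FilterConfig`) requires, per
candidate site: ≥ 10 reads in every sequenced member of the unit; batch
allele count ≤ 1 counted **per unrelated family** (per-sample counting is
available for replaying the older behavior that misses variants shared by
affected identical twins); population AF ≤ 0.001 for dominant-acting
candidates and ≤ 0.005 for recessive/X candidates (the exact "rare"
cutoffs are not published, so these conventional values are configurable);
and an allowed consequence class. Every rule outcome is recorded in a
filter trail so reanalysis can identify rescue causes. Unannotated
variants are retained with a `no_annotation` flag rather than dropped —
only a later annotation snapshot can adjudicate them.

## Classification

A versioned, ordered rule table (YAML) maps an evidence bundle —
inheritance mode, population AF, batch count, prior-report strength,
mechanism consistency, consequence, deleteriousness score, phenotype
overlap — to one of five tiers. The shipped default
(`triodx-default-1`) approximates the published weighting: frequency caps
first (AF > 0.05 benign, > 0.01 likely benign); then informative-mode
variants absent from the population in established or previously-reported
genes (truncating → pathogenic, missense/inframe → likely pathogenic);
unknown-mode variants cap at likely pathogenic unless the exact variant was
previously reported pathogenic; mechanism-inconsistent variants in
established genes park at VUS (e.g. a loss-of-function splice variant in a
gene whose known mechanism is gain-of-function missense); everything else
is VUS. Missing evidence defaults to its least-informative value. The
engine is deterministic and first-match; a property test asserts tier
monotonicity under evidence strengthening. The deleteriousness score is
deliberately unused by the default rules (custom configs may add
`score_ge` conditions).

## CNV consensus

Same-type calls from two callers merge when their reciprocal overlap
(min of mutual overlap fractions) reaches 0.90, greedily 1:1 by descending
reciprocity with leftmost tie-breaking; consensus coordinates are the
intersection of the pair (a conservative choice — the merged representation
is not specified by the source protocol). Consensus calls are removed when
≥ 50% covered by segmental duplications or carried by more than five
distinct unaffected parents (carrier criterion: reciprocal overlap ≥ 0.5,
a deliberately lenient reading of "observed in", counted cohort-wide);
retained calls are flagged for curation when within 5 kb of a DD/ID- or
OMIM-panel gene or intersecting any exon. DEL and DUP never merge.

## Kinship and Mendelian QC

Claimed parent-offspring pairs are verified with the within-family
KING-robust estimator, φ = (N_het,both − 2·N_opp,hom) / (N_het,i +
N_het,j), which is 0.5 for identical genomes, ≈ 0.25 for first-degree
pairs and ≈ 0 for unrelated pairs and needs no allele-frequency model.
Pairs outside the conventional first-degree window [0.177, 0.354] are
flagged; trios additionally report a Mendelian-violation site fraction.
The report never auto-excludes samples. On the default 120-site panel the
estimator is noisy (by design the panel is small and rare-skewed), so QC
flags on simulated cohorts are advisory; the recovery tests use 10,000-site
panels with AF ~ U(0.05, 0.5).

## Reanalysis

An analysis run persists its pre-filter candidate store with filter trails
(tab-delimited sidecars; no VCF re-parsing). A `KnowledgeSnapshot`
(annotations, gene-disease table, criteria, filter config; totally ordered
version ids) replays filtering and classification; previously removed
variants are re-eligible. The upgrade report emits one record per changed
variant tier — downgrades included, the engine is symmetric — with a
reason inferred from what changed (filter relaxation if the old trail
failed a now-passing rule; otherwise the changed gene-disease entry's
source: publication or gene-matching; phenotype clarification is carried
as a snapshot-supplied reason code). Because the source distinguishes
"variants" from "individuals" in its upgrade counts (15 variants across 17
individuals), the summary computes and labels both explicitly, plus
originally-negative families gaining a returnable finding.

## Parent-blind ranking

For trio probands, parental genotype/depth fields are stripped and the
proband-only variant list is filtered under nested scenarios (rare at
AF ≤ 0.001; + protein-altering only; + OMIM/DD-panel genes only), sorted by
descending CADD-scaled score with genomic-coordinate tie-breaking. The
designated set is the trio-defined de novo P/LP findings; each designated
variant's 1-based rank (or `filtered_out`) and cumulative rank curves at
k ∈ {1, 5, 25} are reported, with filtered-out variants kept in the
denominator so fractions are comparable across scenarios. On synthetic
cohorts the planted variants sit in the top of the score distribution and
private rare-variant lists are short, so rank-1 fractions are much higher
than a real cohort would show; the published fractions depend on the real
per-proband variant spectra and are treated as reference behavior only.

## Yield statistics

One results-table row per affected proband (best finding = maximum tier
across returned SNV/indel and CNV findings). Percentages are rounded
half-up to the printed precision; `verify_printed_rates` recomputes every
transcribed printed percentage from its printed numerator/denominator and
flags the five rows of the source table that are not reproducible under
any single rounding rule (a mix of truncation and rounding in the source).
The family-history classifier assigns simplex (single affected proband, no
affected relatives of degree ≤ 3), multiplex (any affected first-degree
relative, including an affected sibling proband), intermediate (affected
degree-2/3 relatives only) or unknown (no records; excluded from
stratified rates). `fisher_exact_2x2` is the standard two-sided exact test
(scipy), verified in tests against full hypergeometric enumeration. Note
that a correct Fisher test on the published simplex-vs-multiplex counts
gives p = 0.0035 (all families) and p = 0.012 (trios only); the
comparisons are significant, but the source's printed p-values (0.002,
0.008) are not reproducible from its printed counts under this (or any
single standard) test.

## Problem sizes and determinism

Default test and acceptance runs use cohorts of 371 and 500 families with a
120-site background panel, a 500-event CNV-recall experiment, and
10,000-site kinship panels — sizes chosen so the statistical checks have
power while the whole suite stays interactive. All randomness flows from a
single integer seed through `numpy.random.default_rng`; a fixed seed gives
byte-identical output files, which the run manifests (SHA-256 per output)
make checkable.

## Known limitations

- The five-tier default criteria are an approximation of an unpublished
  assertion protocol; they are versioned and swappable but not a clinical
  instrument.
- CNV "pathogenicity" in the pipeline is recovery of planted events plus
  curation flags; manual curation itself is out of scope.
- Duo/singleton compound-het pairing with unknown-transmission members is
  flagged but cannot exclude same-haplotype pairs.
- Female X-linked inheritance follows autosomal logic.
- Phenotype overlap is a boolean flag; no ontology semantics.
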