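"""End-to-end orchestration: simulate, prioritize, classify, report.

Thin glue over the analysis modules; every stage consumes and produces plain
files (or their in-memory equivalents) so stages can be re-run
independently, which is what reanalysis requires.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotations import AnnotationTable
from .classify import default_criteria, CriteriaConfig, RETURNABLE
from .cnvmerge import (
    CnvMergeConfig,
    ConsensusCall,
    filter_and_flag,
    merge_callsets,
    reciprocal_overlap,
    CnvCall,
)
from .cohortsim import CohortData
from .inherit_filter import (
    COMPOUND_HET,
    DE_NOVO,
    FilterConfig,
    HOMOZYGOUS_RECESSIVE,
    X_LINKED_MATERNAL,
    UNKNOWN_MODE,
    apply_filters,
    compute_batch_allele_counts,
    detect_inheritance_modes,
)
from .reanalysis import KnowledgeSnapshot, RunState, classify_run
from .singleton_rank import (
    DEFAULT_SCENARIOS,
    FilterScenario,
    RankResult,
    baseline_de_novo_rank,
    scenario_filter_and_rank,
    strip_parents,
)
from .yieldstats import build_results_table, history_classify

def load_cohort(cohort_dir: str) -> CohortData:
    """Reload a written synthetic cohort from its plain-file artifacts."""
    from .annotations import GeneDiseaseTable
    from .cnvmerge import GeneModel, read_bed_calls
    from .cohortsim import SimConfig
    from .pedcore import load_pedigree
    from .variants import read_vcf

    root = Path(cohort_dir)
    pedigree = load_pedigree(root / "cohort.ped")
    family_samples = {}
    family_calls = {}
    for vcf_path in sorted((root / "vcf").glob("*.vcf")):
        fam_id = vcf_path.stem
        samples, calls = read_vcf(vcf_path)
        family_samples[fam_id] = samples
        family_calls[fam_id] = calls
    truth = pd.read_csv(root / "truth.tsv", sep="\t", keep_default_na=False)
    relatives = pd.read_csv(root / "relatives.tsv", sep="\t")
    assays = dict(
        pd.read_csv(root / "assays.tsv", sep="\t").itertuples(index=False, name=None)
    )
    conditions: dict[str, set[str]] = {}
    cond = pd.read_csv(root / "conditions.tsv", sep="\t")
    for row in cond.itertuples(index=False):
        conditions.setdefault(row.parent, set()).add(row.condition)
    gene_conditions = dict(
        pd.read_csv(root / "gene_conditions.tsv", sep="\t").itertuples(
            index=False, name=None
        )
    )
    cnv_calls = {}
    for bed in sorted((root / "cnv").glob("*.bed")):
        if bed.stem in ("truth", "parents"):
            continue
        cnv_calls[bed.stem] = read_bed_calls(bed)
    segdups = []
    with open(root / "segdups.bed") as handle:
        for line in handle:
            contig, start, end = line.split()[:3]
            segdups.append((contig, int(start), int(end)))
    gene_models: dict[str, GeneModel] = {}
    with open(root / "genes.bed") as handle:
        for line in handle:
            contig, ex_start, ex_end, gene, start, end = line.split()[:6]
            gm = gene_models.setdefault(
                gene, GeneModel(gene, contig, int(start), int(end))
            )
            gm.exons.append((int(ex_start), int(ex_end)))
    with open(root / "panel_genes.txt") as handle:
        panel_genes = {line.strip() for line in handle if line.strip()}
    return CohortData(
        config=SimConfig(),
        pedigree=pedigree,
        family_samples=family_samples,
        family_calls=family_calls,
        annotations=AnnotationTable.read_tsv(root / "annotations.tsv"),
        gene_disease=GeneDiseaseTable.read_tsv(root / "gene_disease.tsv"),
        truth=truth,
        relatives=relatives,
        assays=assays,
        conditions=conditions,
        gene_conditions=gene_conditions,
        cnv_truth=read_bed_calls(root / "cnv" / "truth.bed")
        if (root / "cnv" / "truth.bed").exists()
        else [],
        cnv_calls=cnv_calls,
        cnv_parent_calls=read_bed_calls(root / "cnv" / "parents.bed")
        if (root / "cnv" / "parents.bed").exists()
        else [],
        segdups=segdups,
        gene_models=list(gene_models.values()),
        panel_genes=panel_genes,
    )


#: planted truth mode -> acceptable candidate modes
TRUTH_MODE_MAP = {
    "de_novo": {DE_NOVO},
    "recessive_or_comphet": {HOMOZYGOUS_RECESSIVE, COMPOUND_HET},
    "x_linked_maternal": {X_LINKED_MATERNAL},
    "unknown": {UNKNOWN_MODE},
}


def baseline_snapshot(
    cohort: CohortData,
    version: str = "v1",
    filter_config: FilterConfig | None = None,
    criteria: CriteriaConfig | None = None,
) -> KnowledgeSnapshot:
    return KnowledgeSnapshot(
        version=version,
        annotations=cohort.annotations,
        gene_disease=cohort.gene_disease,
        criteria=criteria or default_criteria(),
        filter_config=filter_config or FilterConfig(),
    )


def analyze_cohort(
    cohort: CohortData, snapshot: KnowledgeSnapshot | None = None
) -> RunState:
    """Detect inheritance-mode candidates per analysis unit, run the filter
    cascade with cohort-wide batch allele counts, and classify survivors."""
    snapshot = snapshot or baseline_snapshot(cohort)
    units = {u.proband.sample_id: u for u in cohort.pedigree.analysis_units()}
    batch_counts = compute_batch_allele_counts(
        cohort.family_calls, per=snapshot.filter_config.batch_count_per
    )
    candidates = []
    for proband_id in sorted(units):
        unit = units[proband_id]
        candidates.extend(
            detect_inheritance_modes(
                cohort.family_calls[unit.family_id], unit, snapshot.annotations
            )
        )
    candidates = apply_filters(
        candidates, snapshot.annotations, snapshot.filter_config, batch_counts, units
    )
    run = RunState(
        snapshot=snapshot, candidates=candidates, units=units, batch_counts=batch_counts
    )
    classify_run(run)
    return run


# ---------------------------------------------------------------------------
# CNV stage
# ---------------------------------------------------------------------------


def analyze_cnvs(
    cohort: CohortData, config: CnvMergeConfig | None = None
) -> tuple[list[ConsensusCall], dict[str, str]]:
    """Two-caller consensus + filters per sample; planted-event recovery.

    Returns all consensus calls (with retained/flag state) and a per-proband
    CNV tier: ``pathogenic`` where a retained consensus call recovers a
    planted causal CNV (reciprocal overlap >= 0.5 with truth). Manual
    curation of flagged calls is out of scope, so non-truth retained calls
    contribute no finding.
    """
    config = config or CnvMergeConfig()
    callers = sorted(cohort.cnv_calls)
    by_sample: dict[str, dict[str, list[CnvCall]]] = {}
    for caller in callers:
        for call in cohort.cnv_calls[caller]:
            by_sample.setdefault(call.sample, {}).setdefault(caller, []).append(call)
    consensus: list[ConsensusCall] = []
    for sample in sorted(by_sample):
        per_caller = by_sample[sample]
        if len(callers) >= 2:
            a = per_caller.get(callers[0], [])
            b = per_caller.get(callers[1], [])
            consensus.extend(merge_callsets(a, b, config))
    consensus = filter_and_flag(
        consensus,
        cohort.segdups,
        cohort.cnv_parent_calls,
        cohort.gene_models,
        cohort.panel_genes,
        config,
    )
    tiers: dict[str, str] = {}
    for call in consensus:
        if not call.retained:
            continue
        as_cnv = CnvCall(call.contig, call.start, call.end, call.type, sample=call.sample)
        for truth in cohort.cnv_truth:
            if truth.sample == call.sample and reciprocal_overlap(as_cnv, truth) >= 0.5:
                tiers[call.sample] = "pathogenic"
    return consensus, tiers


# ---------------------------------------------------------------------------
# results table and recovery scoring
# ---------------------------------------------------------------------------


def proband_metadata(cohort: CohortData) -> pd.DataFrame:
    rows = []
    rel = cohort.relatives
    for unit in cohort.pedigree.analysis_units():
        fam_rel = rel[rel["family"] == unit.family_id]
        n_affected = len(cohort.pedigree.families[unit.family_id].probands())
        rows.append(
            {
                "proband": unit.proband.sample_id,
                "family": unit.family_id,
                "structure": unit.structure,
                "assay": cohort.assays.get(unit.proband.sample_id, "WGS"),
                "history": history_classify(
                    fam_rel if len(fam_rel) else None, n_affected
                ),
            }
        )
    return pd.DataFrame(rows)


def cohort_results(
    cohort: CohortData, run: RunState, cnv_tiers: dict[str, str] | None = None
) -> pd.DataFrame:
    return build_results_table(
        proband_metadata(cohort), run.proband_best_tier(), cnv_tiers
    )


def planted_recovery(cohort: CohortData, run: RunState) -> pd.DataFrame:
    """Score each planted causal event against the surviving candidates.

    ``eligible`` marks events whose emitted evidence satisfies the run's
    filter thresholds (all unit members at or above the depth floor);
    ``recovered`` requires a surviving candidate on exactly the planted
    site(s) with the declared inheritance mode.
    """
    min_depth = run.snapshot.filter_config.min_depth
    surviving = {}
    for cand in run.candidates:
        if cand.survived:
            surviving.setdefault(cand.proband_id, []).append(cand)
    rows = []
    causal = cohort.truth[cohort.truth["kind"] == "causal"]
    for row in causal.itertuples(index=False):
        sites = set(row.sites.split("|"))
        eligible = row.min_depth >= min_depth
        recovered = False
        mode_correct = False
        for cand in surviving.get(row.samples, []):
            if set(cand.keys) == sites:
                recovered = True
                mode_correct = cand.mode in TRUTH_MODE_MAP[row.mode]
                if mode_correct:
                    break
        rows.append(
            {
                "family": row.family,
                "proband": row.samples,
                "mode": row.mode,
                "eligible": eligible,
                "recovered": recovered,
                "mode_correct": mode_correct,
            }
        )
    return pd.DataFrame(
        rows, columns=["family", "proband", "mode", "eligible", "recovered", "mode_correct"]
    )


# ---------------------------------------------------------------------------
# parent-blind ranking bench
# ---------------------------------------------------------------------------


def designated_plp_variants(
    cohort: CohortData, run: RunState, de_novo_only: bool = True
) -> dict[str, list[str]]:
    """Per-proband designated P/LP variant keys from the trio analysis.

    By default restricted to de novo findings — the parent-blind benchmark
    asks how those variants rank once parental information is withheld.
    With ``de_novo_only=False``, every returnable finding is designated
    (compound-het pairs contribute their best-scoring member).
    """
    tiers = run.variant_tiers()
    mode_by_key = {(c.proband_id, c.gene_key): c.mode for c in run.candidates}
    designated: dict[str, list[str]] = {}
    for (proband, gene_key), tier in sorted(tiers.items()):
        if tier not in RETURNABLE:
            continue
        if de_novo_only and mode_by_key.get((proband, gene_key)) != DE_NOVO:
            continue
        keys = gene_key.split(";")
        best = max(keys, key=lambda k: (run.snapshot.annotations.get(k).score, k))
        designated.setdefault(proband, []).append(best)
    return designated


def rank_bench(
    cohort: CohortData,
    run: RunState,
    scenarios: tuple[FilterScenario, ...] = DEFAULT_SCENARIOS,
    designated: dict[str, list[str]] | None = None,
) -> list[RankResult]:
    """Strip parents from trio probands and rank designated variants under
    each scenario; the baseline scenario instead ranks within the
    trio-informed de novo list."""
    if designated is None:
        designated = designated_plp_variants(cohort, run)
    units = {u.proband.sample_id: u for u in cohort.pedigree.analysis_units()}
    trio_designated = {
        p: keys for p, keys in designated.items() if units[p].structure == "trio"
    }
    de_novo_keys: dict[str, list[str]] = {}
    for cand in run.candidates:
        if cand.survived and cand.mode == DE_NOVO:
            de_novo_keys.setdefault(cand.proband_id, []).extend(cand.keys)

    results: list[RankResult] = []
    stripped_cache: dict[str, list] = {}
    for scenario in scenarios:
        if scenario.baseline:
            results.extend(
                baseline_de_novo_rank(
                    de_novo_keys, run.snapshot.annotations, trio_designated, scenario.name
                )
            )
            continue
        for proband_id in sorted(trio_designated):
            unit = units[proband_id]
            if proband_id not in stripped_cache:
                stripped_cache[proband_id] = strip_parents(
                    cohort.family_calls[unit.family_id], unit
                )
            results.extend(
                scenario_filter_and_rank(
                    stripped_cache[proband_id],
                    run.snapshot.annotations,
                    scenario,
                    {proband_id: trio_designated[proband_id]},
                )
            )
    return results
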