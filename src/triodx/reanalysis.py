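"""Systematic reanalysis against updated knowledge snapshots.

An initial analysis run persists its pre-filter candidate store together
with every candidate's filter trail. Reanalysis replays filtering and
classification under a newer :class:`KnowledgeSnapshot` (updated annotation
table, gene-disease knowledge, classification criteria and filter
thresholds), so variants originally removed by a filter or parked as VUS can
resurface, and emits per-variant reclassification records plus cohort-level
upgrade metrics. Tier decreases are reported symmetrically, never dropped.
"""

from __future__ import annotations

import importlib.resources
import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .annotations import AnnotationTable, GeneDiseaseTable
from .classify import (
    Classification,
    CriteriaConfig,
    RETURNABLE,
    TIER_ORDER,
    build_evidence,
    classify_variant,
)
from .inherit_filter import Candidate, FilterConfig, apply_filters
from .pedcore import AnalysisUnit
from .variants import VariantCall

NO_RETURNABLE = "NR"

UPGRADE_REASONS = (
    "publication",
    "gene_matching",
    "filter_relaxation",
    "phenotype_clarification",
)


class VersionError(ValueError):
    pass


@dataclass(frozen=True)
class KnowledgeSnapshot:
    """One versioned state of annotations, gene-disease knowledge and configs."""

    version: str
    annotations: AnnotationTable
    gene_disease: GeneDiseaseTable
    criteria: CriteriaConfig
    filter_config: FilterConfig


@dataclass
class RunState:
    """A persisted analysis run: candidates with trails plus classifications."""

    snapshot: KnowledgeSnapshot
    candidates: list[Candidate]
    units: dict[str, AnalysisUnit]
    batch_counts: dict[str, int]
    classifications: dict[int, Classification] = field(default_factory=dict)

    def variant_tiers(self) -> dict[tuple[str, str], str]:
        """(proband, variant-key-group) -> tier for surviving candidates;
        candidates removed by the cascade do not appear (no returnable)."""
        tiers: dict[tuple[str, str], str] = {}
        for i, cand in enumerate(self.candidates):
            if not cand.survived:
                continue
            cls = self.classifications.get(i)
            if cls is None:
                continue
            key = (cand.proband_id, cand.gene_key)
            prev = tiers.get(key)
            if prev is None or TIER_ORDER[cls.tier] > TIER_ORDER[prev]:
                tiers[key] = cls.tier
        return tiers

    def proband_best_tier(self) -> dict[str, str | None]:
        best: dict[str, str | None] = {p: None for p in self.units}
        for (proband, _), tier in self.variant_tiers().items():
            prev = best.get(proband)
            if prev is None or TIER_ORDER[tier] > TIER_ORDER[prev]:
                best[proband] = tier
        return best


def classify_run(run: RunState, phenotype_overlap: dict[str, bool] | None = None) -> None:
    """(Re)classify every surviving candidate in place."""
    phenotype_overlap = phenotype_overlap or {}
    run.classifications = {}
    snap = run.snapshot
    for i, cand in enumerate(run.candidates):
        if not cand.survived:
            continue
        bundle = build_evidence(
            cand,
            snap.annotations,
            snap.gene_disease,
            phenotype_overlap=phenotype_overlap.get(cand.proband_id, False),
        )
        bundle = replace(
            bundle, batch_count=max(run.batch_counts.get(k, 1) for k in cand.keys)
        )
        run.classifications[i] = classify_variant(bundle, snap.criteria)


def reanalyze(run: RunState, snapshot: KnowledgeSnapshot) -> RunState:
    """Replay filtering and classification under a newer snapshot.

    The stored pre-filter candidate set is refiltered with the snapshot's
    thresholds (so previously removed variants are re-eligible) and every
    survivor is reclassified with the snapshot's annotations, gene-disease
    table and criteria. Raises :class:`VersionError` unless the snapshot
    version is strictly newer than the run's.
    """
    if not snapshot.version > run.snapshot.version:
        raise VersionError(
            f"snapshot version {snapshot.version!r} is not newer than "
            f"{run.snapshot.version!r}"
        )
    new_cands = apply_filters(
        [replace(c, trail=[], survived=None) for c in run.candidates],
        snapshot.annotations,
        snapshot.filter_config,
        run.batch_counts,
        run.units,
    )
    new_run = RunState(
        snapshot=snapshot,
        candidates=new_cands,
        units=run.units,
        batch_counts=run.batch_counts,
    )
    classify_run(new_run)
    return new_run


def _infer_reason(
    old: RunState, new: RunState, cand_old: Candidate | None, cand_new: Candidate, gene: str
) -> str:
    if cand_old is not None and not cand_old.survived and cand_new.survived:
        return "filter_relaxation"
    old_entry = old.snapshot.gene_disease.get(gene)
    new_entry = new.snapshot.gene_disease.get(gene)
    if (old_entry.association, old_entry.mechanism) != (
        new_entry.association,
        new_entry.mechanism,
    ):
        return new_entry.source if new_entry.source in UPGRADE_REASONS else "publication"
    return "publication"


def upgrade_report(
    old: RunState, new: RunState
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-variant reclassification records plus cohort upgrade metrics.

    Records exist only where the tier changed (absent/filtered variants
    count as ``NR``); downgrades are reported symmetrically. Metrics:
    ``vus_upgrade_fraction`` (originally-VUS variants now P/LP),
    ``negative_family_upgrade_fraction`` (originally-negative families
    gaining P/LP) and ``reanalysis_share_of_plp`` (share of current P/LP
    probands whose finding arrived at reanalysis).
    """
    old_tiers = old.variant_tiers()
    new_tiers = new.variant_tiers()
    by_key_old = {(c.proband_id, c.gene_key): c for c in old.candidates}
    by_key_new = {(c.proband_id, c.gene_key): c for c in new.candidates}

    rows = []
    for key in sorted(set(old_tiers) | set(new_tiers)):
        old_tier = old_tiers.get(key, NO_RETURNABLE)
        new_tier = new_tiers.get(key, NO_RETURNABLE)
        if old_tier == new_tier:
            continue
        proband, gene_key = key
        cand_new = by_key_new.get(key) or by_key_old[key]
        gene = new.snapshot.annotations.get(cand_new.keys[0]).gene
        rows.append(
            {
                "variant": gene_key,
                "gene": gene,
                "individuals": proband,
                "family": cand_new.family_id,
                "old_tier": old_tier,
                "new_tier": new_tier,
                "reason": _infer_reason(old, new, by_key_old.get(key), cand_new, gene),
            }
        )
    records = pd.DataFrame(
        rows,
        columns=["variant", "gene", "individuals", "family", "old_tier", "new_tier", "reason"],
    )

    old_best = old.proband_best_tier()
    new_best = new.proband_best_tier()
    old_vus = {k for k, t in old_tiers.items() if t == "VUS"}
    upgraded_vus = {k for k in old_vus if new_tiers.get(k) in RETURNABLE}
    fams_all = {u.family_id for u in old.units.values()}
    fam_plp_old = {
        old.units[p].family_id for p, t in old_best.items() if t in RETURNABLE
    }
    neg_fams = fams_all - fam_plp_old
    fam_plp_new = {
        new.units[p].family_id for p, t in new_best.items() if t in RETURNABLE
    }
    upgraded_neg = neg_fams & fam_plp_new
    plp_new_probands = {p for p, t in new_best.items() if t in RETURNABLE}
    newly_plp = {p for p in plp_new_probands if old_best.get(p) not in RETURNABLE}

    metrics = {
        "vus_upgrade_fraction": (len(upgraded_vus) / len(old_vus)) if old_vus else 0.0,
        "negative_family_upgrade_fraction": (
            len(upgraded_neg) / len(neg_fams) if neg_fams else 0.0
        ),
        "reanalysis_share_of_plp": (
            len(newly_plp) / len(plp_new_probands) if plp_new_probands else 0.0
        ),
    }
    return records, metrics


# ---------------------------------------------------------------------------
# persistence: tab-delimited sidecars so reanalysis never re-parses raw VCFs
# ---------------------------------------------------------------------------


def save_run(run: RunState, out_dir: str | os.PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for cand in run.candidates:
        rows.append(
            {
                "family": cand.family_id,
                "proband": cand.proband_id,
                "structure": cand.structure,
                "mode": cand.mode,
                "confidence": cand.confidence,
                "pair_id": cand.pair_id or "",
                "origins": "|".join(cand.origins),
                "survived": bool(cand.survived),
                "trail": cand.trail_str(),
                "variants": json.dumps(
                    [
                        {
                            "chrom": v.chrom,
                            "pos": v.pos,
                            "ref": v.ref,
                            "alt": v.alt,
                            "gt": v.genotypes,
                            "dp": v.depth,
                            "ad": v.alt_depth,
                        }
                        for v in cand.variants
                    ]
                ),
            }
        )
    pd.DataFrame(rows).to_csv(out / "candidates.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(run.batch_counts.items()), columns=["key", "count"]
    ).to_csv(out / "batch_counts.tsv", sep="\t", index=False)
    with open(out / "version.txt", "w") as handle:
        handle.write(run.snapshot.version + "\n")


def load_candidates(path: str | os.PathLike) -> list[Candidate]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in frame.itertuples(index=False):
        variants = [
            VariantCall(
                chrom=v["chrom"],
                pos=int(v["pos"]),
                ref=v["ref"],
                alt=v["alt"],
                genotypes=v["gt"],
                depth={k: int(d) for k, d in v["dp"].items()},
                alt_depth={k: int(d) for k, d in v["ad"].items()},
            )
            for v in json.loads(row.variants)
        ]
        out.append(
            Candidate(
                variants=variants,
                mode=row.mode,
                proband_id=row.proband,
                family_id=row.family,
                structure=row.structure,
                confidence=row.confidence,
                origins=row.origins.split("|") if row.origins else [],
                pair_id=row.pair_id or None,
                survived=bool(row.survived),
            )
        )
    return out


# ---------------------------------------------------------------------------
# published reclassification records (transcribed printed reanalysis table)
# ---------------------------------------------------------------------------


def load_published_reclassifications() -> pd.DataFrame:
    ref = importlib.resources.files("triodx.data").joinpath(
        "reanalysis_upgrades_published.tsv"
    )
    with ref.open() as handle:
        return pd.read_csv(handle, sep="\t")


def summarize_reclassifications(records: pd.DataFrame) -> dict[str, int]:
    """Counts over a reclassification table: distinct upgraded variants,
    affected individuals, and originally-negative (``NR``) families."""
    n_variants = len(records.drop_duplicates(subset=["gene", "variant"]))
    individuals = set()
    for ids in records["individuals"]:
        individuals.update(x.strip() for x in str(ids).split(","))
    nr = records[records["old_tier"] == NO_RETURNABLE]
    neg_families = set()
    for ids in nr["individuals"]:
        for x in str(ids).split(","):
            neg_families.add(x.strip().rsplit("-", 1)[0])
    return {
        "n_variants": n_variants,
        "n_individuals": len(individuals),
        "n_negative_families": len(neg_families),
    }


def snapshot_with_updates(
    base: KnowledgeSnapshot,
    version: str,
    gene_changes: dict | None = None,
    filter_config: FilterConfig | None = None,
    criteria: CriteriaConfig | None = None,
    annotations: AnnotationTable | None = None,
) -> KnowledgeSnapshot:
    """Convenience constructor for an updated snapshot."""
    return KnowledgeSnapshot(
        version=version,
        annotations=annotations or base.annotations,
        gene_disease=base.gene_disease.updated(gene_changes or {}),
        criteria=criteria or base.criteria,
        filter_config=filter_config or base.filter_config,
    )
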