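"""Five-tier variant classification and parental secondary-findings screens.

Variants are classified into pathogenic / likely pathogenic / VUS / likely
benign / benign by an ordered, versioned rule table evaluated over an
:class:`EvidenceBundle`. Inheritance mode, population allele frequency and
the quality of prior gene-disease reports weigh most heavily; the
deleteriousness score is available to rules but the shipped default treats
it as a tie-breaker only. Missing evidence defaults to its least-informative
value and never supports pathogenicity.
"""

from __future__ import annotations

import importlib.resources
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .annotations import AnnotationTable, GeneDiseaseTable, most_severe
from .inherit_filter import Candidate
from .pedcore import Pedigree
from .variants import VariantCall, HET, HOM_ALT, HEMI_ALT, carries_alt

PATHOGENIC = "pathogenic"
LIKELY_PATHOGENIC = "likely_pathogenic"
VUS = "VUS"
LIKELY_BENIGN = "likely_benign"
BENIGN = "benign"

TIERS = (BENIGN, LIKELY_BENIGN, VUS, LIKELY_PATHOGENIC, PATHOGENIC)
TIER_ORDER = {t: i for i, t in enumerate(TIERS)}

RETURNABLE = frozenset({PATHOGENIC, LIKELY_PATHOGENIC})

# prior-report strength, least to most informative
PRIOR_LEVELS = (
    "none",
    "reported_variant_uncertain",
    "established_gene_match",
    "reported_variant_pathogenic",
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EvidenceBundle:
    """Inputs to one classification decision."""

    mode: str = "unknown"
    af: float = 0.0
    batch_count: int = 1
    prior_report: str = "none"
    mechanism_consistent: bool = True
    consequence: str = "missense"
    score: float = 0.0
    phenotype_overlap: bool = False
    gene_constrained: bool = False
    gene: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.af <= 1.0:
            raise ValueError(f"allele frequency {self.af} outside [0, 1]")

    @property
    def absent_from_population(self) -> bool:
        return self.af == 0.0 and self.batch_count <= 1


@dataclass(frozen=True)
class Classification:
    tier: str
    fired: tuple[str, ...]
    config_version: str


@dataclass(frozen=True)
class Rule:
    name: str
    tier: str
    when: dict


@dataclass
class CriteriaConfig:
    """Ordered rule table; the first matching rule assigns the tier."""

    version: str
    rules: list[Rule] = field(default_factory=list)

    @classmethod
    def from_dict(cls, payload: dict) -> "CriteriaConfig":
        rules = []
        for raw in payload.get("rules", []):
            tier = raw.get("tier")
            if tier not in TIERS:
                raise ConfigError(f"unknown tier {tier!r} in rule {raw.get('name')!r}")
            rules.append(Rule(raw["name"], tier, dict(raw.get("when", {}))))
        if not rules or rules[-1].when:
            raise ConfigError("rule table must end with an unconditional default rule")
        return cls(version=str(payload.get("version", "unversioned")), rules=rules)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "CriteriaConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


_KNOWN_CONDITIONS = {
    "af_gt",
    "af_le",
    "mode_in",
    "consequence_in",
    "prior_in",
    "mechanism_consistent",
    "absent_from_population",
    "phenotype_overlap",
    "score_ge",
}


def _matches(rule: Rule, bundle: EvidenceBundle) -> bool:
    for cond, value in rule.when.items():
        if cond not in _KNOWN_CONDITIONS:
            raise ConfigError(f"unknown condition {cond!r} in rule {rule.name!r}")
        if cond == "af_gt" and not bundle.af > value:
            return False
        if cond == "af_le" and not bundle.af <= value:
            return False
        if cond == "mode_in" and bundle.mode not in value:
            return False
        if cond == "consequence_in" and bundle.consequence not in value:
            return False
        if cond == "prior_in" and bundle.prior_report not in value:
            return False
        if cond == "mechanism_consistent" and bundle.mechanism_consistent != value:
            return False
        if cond == "absent_from_population" and bundle.absent_from_population != value:
            return False
        if cond == "phenotype_overlap" and bundle.phenotype_overlap != value:
            return False
        if cond == "score_ge" and not bundle.score >= value:
            return False
    return True


def default_criteria() -> CriteriaConfig:
    ref = importlib.resources.files("triodx.data").joinpath("criteria_default.yaml")
    return CriteriaConfig.from_dict(yaml.safe_load(ref.read_text()))


def classify_variant(bundle: EvidenceBundle, criteria: CriteriaConfig) -> Classification:
    """Deterministic first-match evaluation of the ordered rule table."""
    for rule in criteria.rules:
        if _matches(rule, bundle):
            fired = tuple([rule.name] + sorted(rule.when))
            return Classification(rule.tier, fired, criteria.version)
    raise ConfigError("no rule matched; rule table lacks a default")  # pragma: no cover


def build_evidence(
    candidate: Candidate,
    annotations: AnnotationTable,
    gene_disease: GeneDiseaseTable,
    phenotype_overlap: bool = False,
) -> EvidenceBundle:
    """Assemble the evidence bundle for one candidate.

    For compound-het pairs the most severe member's consequence and the
    maximum score/AF are used. Mechanism consistency compares the variant's
    consequence with the gene's established mechanism: a loss-of-function
    gene accepts any damaging class, a gain-of-function missense gene
    accepts missense only, and an unknown mechanism never contradicts.
    """
    recs = [annotations.get(k) for k in candidate.keys]
    consequence = most_severe([r.consequence for r in recs])
    af = max(r.af for r in recs)
    score = max(r.score for r in recs)
    gene = recs[0].gene
    entry = gene_disease.get(gene)
    assertion = [r.assertion for r in recs]
    if any(a == "pathogenic" for a in assertion):
        prior = "reported_variant_pathogenic"
    elif entry.association == "established":
        prior = "established_gene_match"
    elif entry.association == "single_report" or any(a == "uncertain" for a in assertion):
        prior = "reported_variant_uncertain"
    else:
        prior = "none"
    if entry.mechanism == "lof":
        consistent = consequence not in ("synonymous", "noncoding")
    elif entry.mechanism == "gof_missense":
        consistent = consequence == MISSENSE
    else:
        consistent = True
    return EvidenceBundle(
        mode=candidate.mode,
        af=af,
        batch_count=1,
        prior_report=prior,
        mechanism_consistent=consistent,
        consequence=consequence,
        score=score,
        phenotype_overlap=phenotype_overlap,
        gene=gene,
    )


# ---------------------------------------------------------------------------
# secondary findings in parents
# ---------------------------------------------------------------------------


def screen_secondary(
    family_calls: dict[str, list[VariantCall]],
    annotations: AnnotationTable,
    pedigree: Pedigree,
    self_reported: dict[str, set[str]] | None = None,
    gene_conditions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Three-part secondary-findings report over sequenced parents.

    Parts: (1) P/LP hits in the 56-gene medically actionable panel;
    (2) P/LP genotypes in recessive-disease genes consistent with a parent's
    self-reported condition (``self_reported`` maps parent id to condition
    labels, ``gene_conditions`` maps gene to condition label); (3) carrier-
    panel heterozygous P/LP hits. Proband phenotype information is never
    consulted.
    """
    self_reported = self_reported or {}
    gene_conditions = gene_conditions or {}
    parent_ids = {p.sample_id for p in pedigree.unaffected_parents()}
    # include affected parents too: the screen covers all sequenced parents
    for fam in pedigree.families.values():
        for s in fam.samples.values():
            if s.mother_id and s.mother_id in fam.samples:
                parent_ids.add(s.mother_id)
            if s.father_id and s.father_id in fam.samples:
                parent_ids.add(s.father_id)

    rows = []
    biallelic: dict[tuple[str, str], list[str]] = {}
    for fam_id in sorted(family_calls):
        for call in family_calls[fam_id]:
            rec = annotations.get(call.key_str)
            if rec.assertion not in ("pathogenic", "likely_pathogenic"):
                continue
            for sample_id in sorted(call.genotypes):
                if sample_id not in parent_ids:
                    continue
                gt = call.genotypes[sample_id]
                if not carries_alt(gt):
                    continue
                if "ACMG56" in rec.flags:
                    rows.append(
                        {
                            "part": "acmg56",
                            "family": fam_id,
                            "parent": sample_id,
                            "gene": rec.gene,
                            "key": call.key_str,
                            "zygosity": gt,
                            "detail": rec.assertion,
                        }
                    )
                if "carrier_panel" in rec.flags and gt == HET:
                    rows.append(
                        {
                            "part": "carrier",
                            "family": fam_id,
                            "parent": sample_id,
                            "gene": rec.gene,
                            "key": call.key_str,
                            "zygosity": gt,
                            "detail": rec.assertion,
                        }
                    )
                if "recessive_OMIM" in rec.flags:
                    biallelic.setdefault((sample_id, rec.gene), []).append(gt)
                    if gt in (HOM_ALT, HEMI_ALT) or len(
                        biallelic[(sample_id, rec.gene)]
                    ) >= 2:
                        condition = gene_conditions.get(rec.gene)
                        if condition and condition in self_reported.get(sample_id, set()):
                            rows.append(
                                {
                                    "part": "condition_match",
                                    "family": fam_id,
                                    "parent": sample_id,
                                    "gene": rec.gene,
                                    "key": call.key_str,
                                    "zygosity": gt,
                                    "detail": condition,
                                }
                            )
    frame = pd.DataFrame(
        rows,
        columns=["part", "family", "parent", "gene", "key", "zygosity", "detail"],
    )
    return frame.drop_duplicates(subset=["part", "parent", "gene", "key"]).reset_index(
        drop=True
    )


def mate_pair_carrier_scan(
    pedigree: Pedigree,
    family_calls: dict[str, list[VariantCall]],
    annotations: AnnotationTable,
) -> pd.DataFrame:
    """Couples in which both partners carry het P/LP alleles in one recessive gene."""
    couples = []
    for fam in sorted(pedigree.families.values(), key=lambda f: f.family_id):
        pairs = set()
        for s in fam.samples.values():
            if s.mother_id and s.father_id:
                pairs.add((s.mother_id, s.father_id))
        couples.extend((fam.family_id, m, f) for m, f in sorted(pairs))

    carrier_genes: dict[str, set[str]] = {}
    for fam_id in sorted(family_calls):
        for call in family_calls[fam_id]:
            rec = annotations.get(call.key_str)
            if rec.assertion not in ("pathogenic", "likely_pathogenic"):
                continue
            if "recessive_OMIM" not in rec.flags and "carrier_panel" not in rec.flags:
                continue
            for sample_id, gt in call.genotypes.items():
                if gt == HET:
                    carrier_genes.setdefault(sample_id, set()).add(rec.gene)

    rows = []
    for fam_id, mother, father in couples:
        shared = carrier_genes.get(mother, set()) & carrier_genes.get(father, set())
        for gene in sorted(shared):
            rows.append(
                {"family": fam_id, "mother": mother, "father": father, "gene": gene}
            )
    return pd.DataFrame(rows, columns=["family", "mother", "father", "gene"])


def best_tier(tiers: list[str]) -> str | None:
    """Most pathogenic tier in a list, or None if empty."""
    if not tiers:
        return None
    return max(tiers, key=lambda t: TIER_ORDER[t])
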