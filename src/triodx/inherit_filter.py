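"""Inheritance-mode detection and the quality/frequency/impact filter cascade.

Trio logic searches affected probands for rare, damaging de novo variation or
inherited X-linked, recessive or compound-heterozygous variation. Duos keep
modes compatible with the single sequenced parent (reduced confidence);
singletons pass all proband alt genotypes through with mode ``unknown``.
Every filter decision is recorded in a replayable *filter trail* so a later
reanalysis can identify exactly which rule removed a variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .annotations import (
    AnnotationTable,
    CANONICAL_SPLICE,
    FRAMESHIFT,
    INFRAME,
    MISSENSE,
    NEAR_SPLICE,
    NONSENSE,
)
from .pedcore import AnalysisUnit, Pedigree, TRIO, DUO, SINGLETON, MALE
from .variants import (
    VariantCall,
    X_CONTIG,
    HET,
    HOM_REF,
    HOM_ALT,
    HEMI_ALT,
    HEMI_REF,
    carries_alt,
)

DE_NOVO = "de_novo"
HOMOZYGOUS_RECESSIVE = "homozygous_recessive"
COMPOUND_HET = "compound_het"
X_LINKED_MATERNAL = "x_linked_maternal"
INHERITED_DOMINANT = "inherited_dominant"
UNKNOWN_MODE = "unknown"

MODES = (
    DE_NOVO,
    HOMOZYGOUS_RECESSIVE,
    COMPOUND_HET,
    X_LINKED_MATERNAL,
    INHERITED_DOMINANT,
    UNKNOWN_MODE,
)

#: modes filtered with the recessive/X allele-frequency cap
_RECESSIVE_LIKE = {HOMOZYGOUS_RECESSIVE, COMPOUND_HET, X_LINKED_MATERNAL}

MATERNAL = "maternal"
PATERNAL = "paternal"
BIPARENTAL = "both"
UNKNOWN_ORIGIN = "unknown"

DEFAULT_ALLOWED_CONSEQUENCES = frozenset(
    {MISSENSE, NONSENSE, FRAMESHIFT, CANONICAL_SPLICE, INFRAME, NEAR_SPLICE}
)


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.

    ``min_depth`` applies to every sequenced member of the analysis unit at
    the candidate site. ``max_batch_count`` caps cohort-internal recurrence,
    counted per unrelated family by default (``batch_count_per='sample'``
    restores per-carrier counting, which misses variants shared by affected
    siblings such as identical twins). Allele-frequency caps are
    mode-specific: dominant-acting candidates (de novo, unknown) use
    ``max_af_dominant``; recessive/X candidates use ``max_af_recessive``.
    """

    min_depth: int = 10
    max_batch_count: int = 1
    batch_count_per: str = "family"  # or "sample"
    max_af_dominant: float = 0.001
    max_af_recessive: float = 0.005
    allowed_consequences: frozenset[str] = DEFAULT_ALLOWED_CONSEQUENCES
    min_score: float | None = None
    max_parent_alt_fraction: float = 0.05  # de novo parental mosaicism guard

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        for af in (self.max_af_dominant, self.max_af_recessive):
            if not 0.0 <= af <= 1.0:
                raise ValueError("allele-frequency caps must lie in [0, 1]")
        if self.batch_count_per not in ("family", "sample"):
            raise ValueError("batch_count_per must be 'family' or 'sample'")


@dataclass
class Candidate:
    """One prioritized variant (or compound-het pair) in one analysis unit."""

    variants: list[VariantCall]
    mode: str
    proband_id: str
    family_id: str
    structure: str
    confidence: str = "full"  # 'reduced' for duo/singleton calls
    origins: list[str] = field(default_factory=list)  # per-variant transmission
    pair_id: str | None = None
    trail: list[tuple[str, str, str]] = field(default_factory=list)
    survived: bool | None = None

    @property
    def keys(self) -> list[str]:
        return [v.key_str for v in self.variants]

    @property
    def gene_key(self) -> str:
        return ";".join(self.keys)

    def trail_str(self) -> str:
        return ";".join(
            f"{rule}:{outcome}" + (f"({detail})" if detail else "")
            for rule, outcome, detail in self.trail
        )


def transmission_origin(
    variant: VariantCall, unit: AnalysisUnit
) -> str:
    """Parental origin of a proband het inferred from unphased transmission."""
    mother = unit.mother.sample_id if unit.mother else None
    father = unit.father.sample_id if unit.father else None
    m_carries = mother is not None and carries_alt(variant.genotypes.get(mother, "missing"))
    f_carries = father is not None and carries_alt(variant.genotypes.get(father, "missing"))
    if m_carries and f_carries:
        return BIPARENTAL
    if m_carries:
        return MATERNAL
    if f_carries:
        return PATERNAL
    return UNKNOWN_ORIGIN


def compound_het_pairs(
    labeled_variants: list[tuple[VariantCall, str]],
    allow_unknown: bool = False,
) -> list[tuple[VariantCall, VariantCall]]:
    """Candidate compound-het pairs among one gene's proband het variants.

    Each variant carries a transmission label (maternal/paternal/both/
    unknown). Pairs are (maternal, paternal) combinations; variants carried
    by both parents never pair (same-haplotype ambiguity). With
    ``allow_unknown`` (duo/singleton analysis) unknown-transmission variants
    pair with any non-identical partner not proven same-haplotype.
    """
    maternal = [v for v, o in labeled_variants if o == MATERNAL]
    paternal = [v for v, o in labeled_variants if o == PATERNAL]
    unknown = [v for v, o in labeled_variants if o == UNKNOWN_ORIGIN]
    pairs: list[tuple[VariantCall, VariantCall]] = []
    for mv in maternal:
        for pv in paternal:
            pairs.append((mv, pv))
    if allow_unknown:
        for uv in unknown:
            for other in maternal + paternal:
                pairs.append(_ordered(uv, other))
        for i in range(len(unknown)):
            for j in range(i + 1, len(unknown)):
                pairs.append(_ordered(unknown[i], unknown[j]))
    return pairs


def _ordered(a: VariantCall, b: VariantCall) -> tuple[VariantCall, VariantCall]:
    return (a, b) if (a.chrom, a.pos, a.ref, a.alt) <= (b.chrom, b.pos, b.ref, b.alt) else (b, a)


def _check_unit_genotypes(variants: list[VariantCall], unit: AnalysisUnit) -> None:
    needed = set(unit.samples)
    for v in variants:
        missing = needed - set(v.genotypes)
        if missing:
            raise InputError(
                f"samples {sorted(missing)} of unit {unit.proband.sample_id} "
                f"lack genotypes at {v.key_str}"
            )


def detect_inheritance_modes(
    variants: list[VariantCall],
    unit: AnalysisUnit,
    annotations: AnnotationTable | None = None,
) -> list[Candidate]:
    """Enumerate candidate inheritance modes for one analysis unit.

    Trio rules: de novo (proband carries alt, both parents hom-ref),
    homozygous recessive (proband hom-alt, both parents het), X-linked
    maternal (male proband hemizygous alt, mother het, father ref), and
    compound het via :func:`compound_het_pairs` over per-gene transmission
    labels (gene assignment requires ``annotations``). Duo candidates keep
    modes compatible with the sequenced parent, at reduced confidence;
    singleton probands yield mode ``unknown`` for every alt genotype.
    """
    _check_unit_genotypes(variants, unit)
    proband = unit.proband.sample_id
    structure = unit.structure
    out: list[Candidate] = []
    het_by_gene: dict[str, list[tuple[VariantCall, str]]] = {}

    for v in variants:
        gt = v.genotypes[proband]
        if not carries_alt(gt):
            continue
        on_x = v.chrom == X_CONTIG
        male = unit.proband.sex == MALE

        if structure == TRIO:
            m = v.genotypes[unit.mother.sample_id]
            f = v.genotypes[unit.father.sample_id]
            if on_x and male:
                if gt == HEMI_ALT and m == HET and f == HEMI_REF:
                    out.append(
                        Candidate([v], X_LINKED_MATERNAL, proband, unit.family_id, structure)
                    )
                elif gt == HEMI_ALT and m in (HOM_REF, HEMI_REF) and f == HEMI_REF:
                    out.append(Candidate([v], DE_NOVO, proband, unit.family_id, structure))
                continue
            if m == HOM_REF and f == HOM_REF:
                out.append(Candidate([v], DE_NOVO, proband, unit.family_id, structure))
            elif gt == HOM_ALT and m == HET and f == HET:
                out.append(
                    Candidate([v], HOMOZYGOUS_RECESSIVE, proband, unit.family_id, structure)
                )
            elif gt == HET:
                origin = transmission_origin(v, unit)
                if annotations is not None:
                    gene = annotations.get(v.key_str).gene
                    if gene:
                        het_by_gene.setdefault(gene, []).append((v, origin))
        elif structure == DUO:
            parent = unit.mother or unit.father
            pgt = v.genotypes[parent.sample_id]
            if on_x and male and gt == HEMI_ALT and unit.mother is not None and pgt == HET:
                out.append(
                    Candidate(
                        [v], X_LINKED_MATERNAL, proband, unit.family_id, structure,
                        confidence="reduced",
                    )
                )
                continue
            if not carries_alt(pgt):
                out.append(
                    Candidate(
                        [v], UNKNOWN_MODE, proband, unit.family_id, structure,
                        confidence="reduced",
                    )
                )
            elif gt == HOM_ALT and pgt == HET:
                out.append(
                    Candidate(
                        [v], HOMOZYGOUS_RECESSIVE, proband, unit.family_id, structure,
                        confidence="reduced",
                    )
                )
            if gt == HET and annotations is not None:
                origin = MATERNAL if parent is unit.mother else PATERNAL
                gene = annotations.get(v.key_str).gene
                if gene:
                    het_by_gene.setdefault(gene, []).append((v, origin))
        else:  # singleton
            out.append(
                Candidate(
                    [v], UNKNOWN_MODE, proband, unit.family_id, structure,
                    confidence="reduced",
                )
            )
            if gt == HET and annotations is not None:
                gene = annotations.get(v.key_str).gene
                if gene:
                    het_by_gene.setdefault(gene, []).append((v, UNKNOWN_ORIGIN))

    allow_unknown = structure in (DUO, SINGLETON)
    for gene in sorted(het_by_gene):
        labeled = het_by_gene[gene]
        if structure == DUO:
            # hets not carried by the sequenced parent have unknown other-side origin
            labeled = [
                (v, o if carries_alt(v.genotypes[(unit.mother or unit.father).sample_id]) else UNKNOWN_ORIGIN)
                for v, o in labeled
            ]
        for a, b in compound_het_pairs(labeled, allow_unknown=allow_unknown):
            origins = []
            for v in (a, b):
                if structure == TRIO:
                    origins.append(transmission_origin(v, unit))
                else:
                    origins.append(UNKNOWN_ORIGIN)
            out.append(
                Candidate(
                    [a, b],
                    COMPOUND_HET,
                    proband,
                    unit.family_id,
                    structure,
                    confidence="full" if structure == TRIO else "reduced",
                    origins=origins,
                    pair_id=f"{proband}:{gene}:{a.pos}-{b.pos}",
                )
            )
    return out


def compute_batch_allele_counts(
    family_calls: dict[str, list[VariantCall]],
    per: str = "family",
) -> dict[str, int]:
    """Cohort-internal allele recurrence per variant key.

    ``per='family'`` counts distinct families with at least one carrier;
    ``per='sample'`` counts carrier samples.
    """
    counts: dict[str, int] = {}
    for fam_id in sorted(family_calls):
        for call in family_calls[fam_id]:
            carriers = call.carriers()
            if not carriers:
                continue
            add = 1 if per == "family" else len(carriers)
            counts[call.key_str] = counts.get(call.key_str, 0) + add
    return counts


def _af_cap(mode: str, config: FilterConfig) -> float:
    return config.max_af_recessive if mode in _RECESSIVE_LIKE else config.max_af_dominant


def apply_filters(
    candidates: list[Candidate],
    annotations: AnnotationTable,
    config: FilterConfig,
    batch_counts: dict[str, int],
    units: dict[str, AnalysisUnit],
) -> list[Candidate]:
    """Run the filter cascade, recording a replayable trail per candidate.

    A candidate survives iff every rule passes at every one of its sites:
    unit-wide depth, batch allele count, mode-specific population AF,
    allowed consequence class, optional deleteriousness floor, and (for de
    novo calls) a parental-evidence guard limiting parent alt-read fraction.
    Unannotated variants are retained with a ``no_annotation`` trail flag.
    Filtering is total: every input candidate is returned, with
    ``survived`` set.
    """
    out = []
    for cand in candidates:
        cand = replace(cand, trail=[], survived=None)
        unit = units[cand.proband_id]
        trail: list[tuple[str, str, str]] = []

        def rule(name: str, ok: bool, detail: str = "") -> None:
            trail.append((name, "pass" if ok else "fail", detail))

        for v in cand.variants:
            depths = [v.depth.get(s, 0) for s in unit.samples]
            ok = all(d >= config.min_depth for d in depths)
            rule("depth", ok, "" if ok else f"min={min(depths)}<{config.min_depth}")

            bc = batch_counts.get(v.key_str, 0)
            rule(
                "batch_count",
                bc <= config.max_batch_count,
                "" if bc <= config.max_batch_count else f"{bc}>{config.max_batch_count}",
            )

            rec = annotations.get(v.key_str)
            if not annotations.has(v.key_str):
                # unannotated variants pass the annotation-driven rules so a
                # later knowledge snapshot can still rescue them
                trail.append(("no_annotation", "pass", "retained"))
            else:
                cap = _af_cap(cand.mode, config)
                rule("af", rec.af <= cap, "" if rec.af <= cap else f"{rec.af:g}>{cap:g}")
                ok = rec.consequence in config.allowed_consequences
                rule("consequence", ok, "" if ok else rec.consequence)
                if config.min_score is not None:
                    ok = rec.score >= config.min_score
                    rule("score", ok, "" if ok else f"{rec.score:g}<{config.min_score:g}")

            if cand.mode == DE_NOVO and unit.structure == TRIO:
                ok = True
                worst = 0.0
                for parent in (unit.mother, unit.father):
                    dp = v.depth.get(parent.sample_id, 0)
                    ad = v.alt_depth.get(parent.sample_id, 0)
                    frac = ad / dp if dp > 0 else 0.0
                    worst = max(worst, frac)
                    if frac > config.max_parent_alt_fraction:
                        ok = False
                rule(
                    "parental_evidence",
                    ok,
                    "" if ok else f"parent_alt_fraction={worst:.3f}",
                )

        cand.trail = trail
        cand.survived = all(outcome == "pass" for _, outcome, _ in trail)
        out.append(cand)
    return out


def surviving(candidates: list[Candidate]) -> list[Candidate]:
    return [c for c in candidates if c.survived]


def clinvar_scan(
    family_calls: dict[str, list[VariantCall]],
    annotations: AnnotationTable,
    pedigree: Pedigree,
) -> list[dict]:
    """P/LP-assertion scan over every genotype of every sequenced sample.

    Independent of the filter cascade and of inheritance or affected status:
    any sample carrying an allele asserted pathogenic or likely pathogenic is
    reported with carrier context (zygosity, affected flag).
    """
    hits = []
    for fam_id in sorted(family_calls):
        fam = pedigree.families[fam_id]
        for call in family_calls[fam_id]:
            rec = annotations.get(call.key_str)
            if rec.assertion not in ("pathogenic", "likely_pathogenic"):
                continue
            for sample_id in sorted(call.genotypes):
                gt = call.genotypes[sample_id]
                if not carries_alt(gt):
                    continue
                meta = fam.samples.get(sample_id)
                hits.append(
                    {
                        "family": fam_id,
                        "sample": sample_id,
                        "key": call.key_str,
                        "gene": rec.gene,
                        "assertion": rec.assertion,
                        "zygosity": gt,
                        "affected": bool(meta.affected) if meta else False,
                    }
                )
    return hits
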