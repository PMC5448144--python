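"""Synthetic DD/ID cohort generator with a planted-variant truth ledger.

Families are simulated with the statistical structure the downstream
analysis assumes: a mix of trio/duo/singleton analysis units, family-history
strata (simplex / intermediate / multiplex) with class-specific probabilities
of carrying a returnable pathogenic or likely pathogenic (P/LP) event, an
inheritance-mode mix dominated by de novo variation, and a consequence mix
dominated by missense changes. Background genotypes follow Hardy-Weinberg
sampling of parental alleles with Mendelian transmission to probands; planted
causal events are written both into the emitted genotypes and into a
tab-delimited truth ledger so every downstream stage can be scored against
known answers.

Planted events are placed at family-private sites so their cohort-internal
(batch) allele count is one. Compound-het events are emitted unphased: the
pipeline must re-derive parental origin from transmission, as with real
short-read data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotations import (
    AnnotationRecord,
    AnnotationTable,
    GeneDiseaseEntry,
    GeneDiseaseTable,
    TRUNCATING,
)
from .cnvmerge import CnvCall, GeneModel, write_bed_calls
from .pedcore import (
    Family,
    Pedigree,
    Sample,
    MALE,
    FEMALE,
    TRIO,
    DUO,
    SINGLETON,
    write_pedigree,
)
from .variants import (
    VariantCall,
    X_CONTIG,
    HOM_REF,
    HET,
    HOM_ALT,
    HEMI_REF,
    HEMI_ALT,
    expected_vaf,
    write_vcf,
)

DE_NOVO = "de_novo"
RECESSIVE_OR_COMPHET = "recessive_or_comphet"
X_LINKED_MATERNAL = "x_linked_maternal"
UNKNOWN = "unknown"

SIMPLEX = "simplex"
INTERMEDIATE = "intermediate"
MULTIPLEX = "multiplex"

_BASES = ("A", "C", "G", "T")


class ConfigError(ValueError):
    pass


class PlantingError(ValueError):
    pass


def _check_mix(name: str, mix: dict[str, float]) -> None:
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in mix.values()):
        raise ConfigError(f"{name} contains negative probabilities")


@dataclass(frozen=True)
class CnvParams:
    """Truth CNV counts, length distribution and caller noise."""

    n_events: int = 8
    min_length: int = 20_000
    max_length: int = 1_000_000
    jitter_sd: float = 0.0  # breakpoint jitter per caller, bp
    fn_rate: float = 0.0  # per-caller miss probability
    fp_per_caller: int = 0
    n_common_events: int = 0  # events also carried by unaffected parents
    carriers_per_common_event: int = 0

    def validate(self) -> None:
        if self.min_length <= 0 or self.max_length < self.min_length:
            raise ConfigError("CNV length bounds must satisfy 0 < min <= max")
        if self.jitter_sd >= self.min_length:
            raise ConfigError(
                f"breakpoint jitter {self.jitter_sd} exceeds minimum interval "
                f"length {self.min_length}"
            )
        if not 0.0 <= self.fn_rate <= 1.0:
            raise ConfigError("fn_rate must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the synthetic cohort.

    Defaults mirror the study conditions: 371 analysis units dominated by
    trios; history strata in proportion 93/85/123 with per-class P/LP
    probabilities 0.376 / 0.26 / 0.195; a planted-event mode mix of 76% de
    novo, 12% recessive or compound-het, 5% X-linked maternal and 7%
    unknown-inheritance (duo/singleton) events; and a consequence mix of 52%
    missense, 39% nonsense/frameshift, 7% splice and 2% inframe. Background
    allele frequencies follow Beta(0.2, 2) truncated to [0.001, 0.5]; read
    depths are negative-binomial with WGS-like mean 35.
    """

    n_families: int = 371
    structure_mix: dict[str, float] = field(
        default_factory=lambda: {TRIO: 309 / 371, DUO: 42 / 371, SINGLETON: 20 / 371}
    )
    history_mix: dict[str, float] = field(
        default_factory=lambda: {
            SIMPLEX: 93 / 301,
            INTERMEDIATE: 85 / 301,
            MULTIPLEX: 123 / 301,
        }
    )
    yield_by_history: dict[str, float] = field(
        default_factory=lambda: {SIMPLEX: 0.376, INTERMEDIATE: 0.26, MULTIPLEX: 0.195}
    )
    mode_mix: dict[str, float] = field(
        default_factory=lambda: {
            DE_NOVO: 0.76,
            RECESSIVE_OR_COMPHET: 0.12,
            X_LINKED_MATERNAL: 0.05,
            UNKNOWN: 0.07,
        }
    )
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 0.52,
            "nonsense_or_frameshift": 0.39,
            "splice": 0.07,
            "inframe": 0.02,
        }
    )
    assay_mix: dict[str, float] = field(
        default_factory=lambda: {"WGS": 244 / 371, "WES": 127 / 371}
    )
    history_missing_rate: float = 38 / 339
    n_sites: int = 120
    af_beta: tuple[float, float] = (0.2, 2.0)
    af_bounds: tuple[float, float] = (0.001, 0.5)
    depth_mean: float = 35.0
    depth_dispersion: float = 0.1
    genotype_error_rate: float = 0.0
    male_fraction: float = 0.58
    cnv: CnvParams = field(default_factory=CnvParams)
    n_clinvar_planted: int = 20
    n_acmg_planted: int = 8
    n_carrier_couples: int = 1
    n_condition_planted: int = 2
    n_upgradable_planted: int = 0
    n_depth_rescue_planted: int = 0
    two_hit_sibling_families: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if self.n_sites < 10:
            raise ConfigError("n_sites too small to host planted events")
        for name, mix in (
            ("structure_mix", self.structure_mix),
            ("history_mix", self.history_mix),
            ("mode_mix", self.mode_mix),
            ("consequence_mix", self.consequence_mix),
            ("assay_mix", self.assay_mix),
        ):
            _check_mix(name, mix)
        for cls, p in self.yield_by_history.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"yield probability for {cls} outside [0, 1]")
        self.cnv.validate()


def _choice(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = sorted(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


# ---------------------------------------------------------------------------
# cohort planning (cheap; no genotype emission)
# ---------------------------------------------------------------------------


@dataclass
class FamilyPlan:
    family_id: str
    structure: str
    duo_parent: str  # 'mother' or 'father' (used when structure == duo)
    history: str
    history_observed: bool
    n_probands: int
    proband_sexes: list[str]
    events: list[tuple[str, str]]  # (mode, concrete consequence class)
    assay: str
    cnv_event: bool = False  # causal event is a CNV instead of an SNV/indel


def _concrete_consequence(raw: str, rng: np.random.Generator) -> str:
    if raw == "missense":
        return "missense"
    if raw == "nonsense_or_frameshift":
        return "nonsense" if rng.random() < 0.5 else "frameshift"
    if raw == "splice":
        return "canonical_splice"
    if raw == "inframe":
        return "inframe"
    raise ConfigError(f"unknown consequence class {raw!r}")


def plan_cohort(config: SimConfig, rng: np.random.Generator) -> list[FamilyPlan]:
    """Draw family structures, history strata and planted events.

    Planted-event inheritance modes are drawn from ``mode_mix`` restricted
    to modes feasible under the configured structure mix (informative modes
    require trios; unknown-inheritance events require duos or singletons);
    the planted family's structure is then chosen among structures
    compatible with the drawn mode. Unplanted families draw their structure
    from ``structure_mix`` directly, so the realized mode fractions match
    ``mode_mix`` while the structure mix is approximately preserved.
    """
    non_trio_mass = config.structure_mix.get(DUO, 0) + config.structure_mix.get(SINGLETON, 0)
    feasible = {
        m: p
        for m, p in config.mode_mix.items()
        if (m == UNKNOWN and non_trio_mass > 0)
        or (m != UNKNOWN and config.structure_mix.get(TRIO, 0) > 0)
    }
    if not feasible:
        raise ConfigError("mode_mix incompatible with structure_mix")

    plans = []
    for i in range(config.n_families):
        fam_id = f"F{i:04d}"
        sibling_pair = i < config.two_hit_sibling_families
        structure = _choice(rng, config.structure_mix)
        history = _choice(rng, config.history_mix)
        observed = rng.random() >= config.history_missing_rate
        events: list[tuple[str, str]] = []
        n_probands = 1

        if sibling_pair:
            structure = TRIO
            history = MULTIPLEX
            n_probands = 2
            for _ in range(2):
                events.append(
                    (DE_NOVO, _concrete_consequence(_choice(rng, config.consequence_mix), rng))
                )
        elif rng.random() < config.yield_by_history[history]:
            mode = _choice(rng, feasible)
            consequence = _concrete_consequence(_choice(rng, config.consequence_mix), rng)
            if mode == UNKNOWN:
                sub = {
                    s: p
                    for s, p in config.structure_mix.items()
                    if s in (DUO, SINGLETON) and p > 0
                }
                structure = _choice(rng, sub)
            else:
                structure = TRIO
            events.append((mode, consequence))

        if n_probands > 1:
            history = MULTIPLEX  # affected sibling is a first-degree relative

        sexes = []
        for j in range(n_probands):
            forced_male = events and events[min(j, len(events) - 1)][0] == X_LINKED_MATERNAL
            sexes.append(
                MALE if forced_male or rng.random() < config.male_fraction else FEMALE
            )
        duo_parent = "mother" if rng.random() < 0.5 else "father"
        if events and events[0][0] == X_LINKED_MATERNAL and structure == DUO:
            duo_parent = "mother"
        plans.append(
            FamilyPlan(
                family_id=fam_id,
                structure=structure,
                duo_parent=duo_parent,
                history=history,
                history_observed=observed,
                n_probands=n_probands,
                proband_sexes=sexes,
                events=events,
                assay=_choice(rng, config.assay_mix),
            )
        )
    return plans


# ---------------------------------------------------------------------------
# genotype emission
# ---------------------------------------------------------------------------


@dataclass
class CohortData:
    """In-memory synthetic cohort: inputs plus the truth ledger."""

    config: SimConfig
    pedigree: Pedigree
    family_samples: dict[str, list[str]]
    family_calls: dict[str, list[VariantCall]]
    annotations: AnnotationTable
    gene_disease: GeneDiseaseTable
    truth: pd.DataFrame
    relatives: pd.DataFrame
    assays: dict[str, str]  # proband -> WES/WGS
    conditions: dict[str, set[str]]  # parent -> self-reported condition labels
    gene_conditions: dict[str, str]
    cnv_truth: list[CnvCall]
    cnv_calls: dict[str, list[CnvCall]]
    cnv_parent_calls: list[CnvCall]
    segdups: list[tuple[str, int, int]]
    gene_models: list[GeneModel]
    panel_genes: set[str]

    def write(self, out_dir: str | os.PathLike) -> None:
        out = Path(out_dir)
        (out / "vcf").mkdir(parents=True, exist_ok=True)
        (out / "cnv").mkdir(exist_ok=True)
        write_pedigree(self.pedigree, out / "cohort.ped")
        for fam_id in sorted(self.family_calls):
            write_vcf(
                out / "vcf" / f"{fam_id}.vcf",
                self.family_samples[fam_id],
                self.family_calls[fam_id],
            )
        self.annotations.write_tsv(out / "annotations.tsv")
        self.gene_disease.write_tsv(out / "gene_disease.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        self.relatives.to_csv(out / "relatives.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.assays.items()), columns=["proband", "assay"]
        ).to_csv(out / "assays.tsv", sep="\t", index=False)
        cond_rows = [
            {"parent": parent, "condition": c}
            for parent in sorted(self.conditions)
            for c in sorted(self.conditions[parent])
        ]
        pd.DataFrame(cond_rows, columns=["parent", "condition"]).to_csv(
            out / "conditions.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            sorted(self.gene_conditions.items()), columns=["gene", "condition"]
        ).to_csv(out / "gene_conditions.tsv", sep="\t", index=False)
        write_bed_calls(self.cnv_truth, out / "cnv" / "truth.bed")
        for caller in sorted(self.cnv_calls):
            write_bed_calls(self.cnv_calls[caller], out / "cnv" / f"{caller}.bed")
        write_bed_calls(self.cnv_parent_calls, out / "cnv" / "parents.bed")
        with open(out / "segdups.bed", "w") as handle:
            for contig, start, end in self.segdups:
                handle.write(f"{contig}\t{start}\t{end}\n")
        with open(out / "genes.bed", "w") as handle:
            for gm in self.gene_models:
                for ex_start, ex_end in gm.exons:
                    handle.write(
                        f"{gm.contig}\t{ex_start}\t{ex_end}\t{gm.gene}\t"
                        f"{gm.start}\t{gm.end}\n"
                    )
        with open(out / "panel_genes.txt", "w") as handle:
            handle.write("\n".join(sorted(self.panel_genes)) + "\n")
        with open(out / "config.yaml", "w") as handle:
            payload = {
                "n_families": self.config.n_families,
                "n_sites": self.config.n_sites,
                "seed": self.config.seed,
            }
            yaml.safe_dump(payload, handle)


class _SiteAllocator:
    """Hands out family-private positions so planted sites never collide."""

    def __init__(self) -> None:
        self._aut = 0
        self._x = 0

    def autosomal(self) -> tuple[str, int]:
        self._aut += 1
        return "1", 150_000_000 + self._aut * 2_000

    def x(self) -> tuple[str, int]:
        self._x += 1
        return X_CONTIG, 100_000_000 + self._x * 2_000


@dataclass
class _FamilyState:
    plan: FamilyPlan
    samples: list[str]  # emitted sample ids
    probands: list[str]
    mother: str | None
    father: str | None
    sexes: dict[str, str]
    genotypes: dict[tuple[str, int, str, str], dict[str, str]] = field(default_factory=dict)
    forced_depth: dict[tuple[tuple[str, int, str, str], str], int] = field(default_factory=dict)


def _alleles_for(pos: int) -> tuple[str, str]:
    ref = _BASES[pos % 4]
    alt = _BASES[(pos // 4 + 1 + pos % 4) % 4]
    if alt == ref:
        alt = _BASES[(pos % 4 + 1) % 4]
    return ref, alt


def _dosage_state(dos: int, haploid: bool) -> str:
    if haploid:
        return HEMI_ALT if dos else HEMI_REF
    return (HOM_REF, HET, HOM_ALT)[dos]


def plant_causal_event(
    state: _FamilyState,
    mode: str,
    consequence: str,
    proband: str,
    gene: str,
    allocator: _SiteAllocator,
    rng: np.random.Generator,
) -> dict:
    """Edit family genotypes for one planted event; return its truth row.

    De novo: proband het, parents hom-ref. Recessive-or-comphet splits
    evenly between a homozygous event (proband hom-alt, parents het) and a
    compound het (two sites in one gene, one transmitted from each parent,
    emitted unphased). X-linked maternal requires a male proband and a
    sequenced mother: proband hemizygous alt, mother het, father ref.
    Unknown-inheritance events (duo/singleton) plant a proband het absent
    from any sequenced parent.
    """
    mother, father = state.mother, state.father
    sites: list[tuple[str, int, str, str]] = []
    origins: list[str] = []
    submode = mode

    def new_site(on_x: bool = False) -> tuple[str, int, str, str]:
        contig, pos = allocator.x() if on_x else allocator.autosomal()
        ref, alt = _alleles_for(pos)
        return (contig, pos, ref, alt)

    if mode == DE_NOVO:
        if mother is None or father is None:
            raise PlantingError("de novo planting requires both parents")
        key = new_site()
        state.genotypes[key] = {proband: HET, mother: HOM_REF, father: HOM_REF}
        sites, origins = [key], ["de_novo"]
    elif mode == RECESSIVE_OR_COMPHET:
        if mother is None or father is None:
            raise PlantingError("recessive planting requires both parents")
        if rng.random() < 0.5:
            submode = "homozygous"
            key = new_site()
            state.genotypes[key] = {proband: HOM_ALT, mother: HET, father: HET}
            sites, origins = [key], ["biparental"]
        else:
            submode = "compound_het"
            k1, k2 = new_site(), new_site()
            state.genotypes[k1] = {proband: HET, mother: HET, father: HOM_REF}
            state.genotypes[k2] = {proband: HET, mother: HOM_REF, father: HET}
            sites, origins = [k1, k2], ["maternal", "paternal"]
    elif mode == X_LINKED_MATERNAL:
        if mother is None or state.sexes[proband] != MALE:
            raise PlantingError("X-linked maternal planting requires a male proband and mother")
        key = new_site(on_x=True)
        gts = {proband: HEMI_ALT, mother: HET}
        if father is not None:
            gts[father] = HEMI_REF
        state.genotypes[key] = gts
        sites, origins = [key], ["maternal"]
    elif mode == UNKNOWN:
        key = new_site()
        gts = {proband: HET}
        for parent in (mother, father):
            if parent is not None:
                gts[parent] = HOM_REF
        state.genotypes[key] = gts
        sites, origins = [key], ["unknown"]
    else:
        raise PlantingError(f"unknown planting mode {mode!r}")

    intended = (
        "likely_pathogenic"
        if mode == UNKNOWN or not any(
            c in TRUNCATING for c in [consequence]
        )
        else "pathogenic"
    )
    return {
        "family": state.plan.family_id,
        "samples": proband,
        "kind": "causal",
        "mode": mode,
        "submode": submode,
        "consequence": consequence,
        "gene": gene,
        "sites": "|".join(f"{c}:{p}:{r}:{a}" for c, p, r, a in sites),
        "origins": "|".join(origins),
        "intended_tier": intended,
        "assertion": "none",
        "af": 0.0,
    }


# ---------------------------------------------------------------------------
# CNV callset simulation
# ---------------------------------------------------------------------------


def simulate_cnv_callsets(
    truth_calls: list[CnvCall],
    params: CnvParams,
    rng: np.random.Generator,
    parent_pool: list[str] | None = None,
    callers: tuple[str, str] = ("erds", "rdepth"),
) -> tuple[dict[str, list[CnvCall]], list[CnvCall]]:
    """Emit two caller-attributed callsets plus parental background calls.

    Each truth call appears in each callset with probability
    ``1 - fn_rate``, with breakpoints jittered by a rounded Normal(0,
    jitter_sd) draw (clipped so intervals stay non-degenerate). False
    positives are random intervals attributed to the truth calls' samples.
    The first ``n_common_events`` truth events are additionally carried by
    ``carriers_per_common_event`` parents drawn from ``parent_pool``.
    """
    params.validate()
    for call in truth_calls:
        if call.end <= call.start:
            raise ConfigError("degenerate truth interval")
    callsets: dict[str, list[CnvCall]] = {c: [] for c in callers}
    for caller in callers:
        for call in truth_calls:
            if rng.random() < params.fn_rate:
                continue
            if params.jitter_sd > 0:
                max_shift = (call.length - 1) // 2
                ds = int(np.clip(round(rng.normal(0, params.jitter_sd)), -max_shift, max_shift))
                de = int(np.clip(round(rng.normal(0, params.jitter_sd)), -max_shift, max_shift))
            else:
                ds = de = 0
            start = max(0, call.start + ds)
            end = max(start + 1, call.end + de)
            callsets[caller].append(
                CnvCall(call.contig, start, end, call.type, caller, call.sample)
            )
        samples = sorted({c.sample for c in truth_calls}) or ["NA"]
        for _ in range(params.fp_per_caller):
            length = int(rng.integers(params.min_length, params.max_length + 1))
            start = int(rng.integers(1_000_000, 200_000_000))
            callsets[caller].append(
                CnvCall(
                    "1",
                    start,
                    start + length,
                    "DEL" if rng.random() < 0.5 else "DUP",
                    caller,
                    samples[int(rng.integers(len(samples)))],
                )
            )
    parent_calls: list[CnvCall] = []
    if parent_pool and params.n_common_events and params.carriers_per_common_event:
        for call in truth_calls[: params.n_common_events]:
            n = min(params.carriers_per_common_event, len(parent_pool))
            idx = rng.choice(len(parent_pool), size=n, replace=False)
            for k in sorted(idx):
                parent_calls.append(
                    CnvCall(
                        call.contig,
                        call.start,
                        call.end,
                        call.type,
                        "parent_bg",
                        parent_pool[int(k)],
                    )
                )
    return callsets, parent_calls


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimConfig) -> CohortData:
    """Generate the full synthetic cohort for the configured conditions.

    Deterministic for a fixed seed: identical configs produce byte-identical
    files from :meth:`CohortData.write`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    plans = plan_cohort(config, rng)
    allocator = _SiteAllocator()

    # a share of yielding families carries a causal CNV instead of an
    # SNV/indel (the study's returnable findings include large CNVs)
    planted_trios = [
        i
        for i, p in enumerate(plans)
        if p.events and p.structure == TRIO and p.n_probands == 1
    ]
    n_cnv = min(config.cnv.n_events, len(planted_trios))
    if n_cnv:
        chosen = rng.choice(len(planted_trios), size=n_cnv, replace=False)
        for k in sorted(chosen):
            plan = plans[planted_trios[int(k)]]
            plan.events = []
            plan.cnv_event = True
            plan.assay = "WGS"

    # shared background site panel
    n_aut = config.n_sites
    n_x = max(4, config.n_sites // 15)
    a, b = config.af_beta
    lo, hi = config.af_bounds
    afs = []
    while len(afs) < n_aut + n_x:
        draw = rng.beta(a, b)
        if lo <= draw <= hi:
            afs.append(draw)
    aut_sites = [("1", 1_000_000 + i * 10_000) for i in range(n_aut)]
    x_sites = [(X_CONTIG, 60_000_000 + i * 10_000) for i in range(n_x)]
    panel = []
    bg_consequences = {
        "missense": 0.2,
        "synonymous": 0.3,
        "noncoding": 0.25,
        "near_splice": 0.1,
        "inframe": 0.05,
        "nonsense": 0.05,
        "frameshift": 0.05,
    }
    ann_records: dict[str, AnnotationRecord] = {}
    for idx, (contig, pos) in enumerate(aut_sites + x_sites):
        ref, alt = _alleles_for(pos)
        af = afs[idx]
        gene = f"BG{idx // 3:04d}" if contig == "1" else f"BGX{idx // 3:03d}"
        cons = _choice(rng, bg_consequences)
        score = float(np.clip(abs(rng.normal(10, 8)), 0, 34))
        key = f"{contig}:{pos}:{ref}:{alt}"
        ann_records[key] = AnnotationRecord(
            key=key, af=round(af, 6), consequence=cons, gene=gene, score=round(score, 2)
        )
        panel.append((contig, pos, ref, alt, af))

    # gene-disease knowledge
    gene_entries: dict[str, GeneDiseaseEntry] = {}
    causal_genes = [f"DDID{i:03d}" for i in range(40)]
    for i, g in enumerate(causal_genes):
        gene_entries[g] = GeneDiseaseEntry(g, "established", "lof" if i % 10 else "any")
    for i in range(5):
        g = f"GOF{i:02d}"
        gene_entries[g] = GeneDiseaseEntry(g, "established", "gof_missense")
    novel_genes = [f"NOV{i:02d}" for i in range(max(8, config.n_upgradable_planted))]
    for g in novel_genes:
        gene_entries[g] = GeneDiseaseEntry(g, "none", "any")
    carrier_genes = ["CARRIER_CFTR", "CARRIER_HBB", "CARRIER_HEXA"]
    recessive_genes = [f"REC{i:02d}" for i in range(6)]
    acmg_genes = [f"ACMG{i:02d}" for i in range(10)]
    for g in carrier_genes + recessive_genes:
        gene_entries[g] = GeneDiseaseEntry(g, "established", "lof")
    for g in acmg_genes:
        gene_entries[g] = GeneDiseaseEntry(g, "established", "any")
    gene_conditions = {g: f"condition_{g}" for g in recessive_genes}
    for g in carrier_genes:
        gene_conditions[g] = f"condition_{g}"

    pedigree = Pedigree()
    family_samples: dict[str, list[str]] = {}
    family_calls: dict[str, list[VariantCall]] = {}
    truth_rows: list[dict] = []
    relatives_rows: list[dict] = []
    assays: dict[str, str] = {}
    conditions: dict[str, set[str]] = {}
    states: dict[str, _FamilyState] = {}

    for plan in plans:
        fam_id = plan.family_id
        mother_id = f"{fam_id}-M"
        father_id = f"{fam_id}-F"
        if plan.structure == TRIO:
            mother, father = mother_id, father_id
        elif plan.structure == DUO:
            mother = mother_id if plan.duo_parent == "mother" else None
            father = father_id if plan.duo_parent == "father" else None
        else:
            mother = father = None
        probands = [f"{fam_id}-C"] + [f"{fam_id}-C{j+1}" for j in range(1, plan.n_probands)]
        emitted = probands + [s for s in (mother, father) if s]
        sexes = {p: s for p, s in zip(probands, plan.proband_sexes)}
        if mother:
            sexes[mother] = FEMALE
        if father:
            sexes[father] = MALE

        fam = Family(fam_id)
        for p in probands:
            fam.samples[p] = Sample(p, fam_id, sexes[p], True, mother, father)
        if mother:
            fam.samples[mother] = Sample(mother, fam_id, FEMALE, False)
        if father:
            fam.samples[father] = Sample(father, fam_id, MALE, False)
        pedigree.families[fam_id] = fam
        family_samples[fam_id] = emitted
        for p in probands:
            assays[p] = plan.assay

        state = _FamilyState(
            plan=plan,
            samples=emitted,
            probands=probands,
            mother=mother,
            father=father,
            sexes=sexes,
        )
        states[fam_id] = state

        # background genotypes (latent parents always simulated, so duo and
        # singleton probands still follow Hardy-Weinberg transmission)
        for contig, pos, ref, alt, af in panel:
            key = (contig, pos, ref, alt)
            gts: dict[str, str] = {}
            if contig == X_CONTIG:
                m_dos = int(rng.binomial(2, af))
                f_dos = int(rng.binomial(1, af))
                for p in probands:
                    tm = int(rng.random() < m_dos / 2)
                    if sexes[p] == MALE:
                        gts[p] = _dosage_state(tm, haploid=True)
                    else:
                        gts[p] = _dosage_state(tm + f_dos, haploid=False)
                if mother:
                    gts[mother] = _dosage_state(m_dos, haploid=False)
                if father:
                    gts[father] = _dosage_state(f_dos, haploid=True)
            else:
                m_dos = int(rng.binomial(2, af))
                f_dos = int(rng.binomial(2, af))
                for p in probands:
                    tm = int(rng.random() < m_dos / 2)
                    tf = int(rng.random() < f_dos / 2)
                    gts[p] = _dosage_state(tm + tf, haploid=False)
                if mother:
                    gts[mother] = _dosage_state(m_dos, haploid=False)
                if father:
                    gts[father] = _dosage_state(f_dos, haploid=False)
            state.genotypes[key] = gts

        # planted causal events
        for j, (mode, consequence) in enumerate(plan.events):
            proband = probands[min(j, len(probands) - 1)]
            gene = causal_genes[int(rng.integers(len(causal_genes)))]
            row = plant_causal_event(state, mode, consequence, proband, gene, allocator, rng)
            truth_rows.append(row)
            for site_key, _ in zip(row["sites"].split("|"), row["origins"].split("|")):
                score = float(rng.uniform(28, 45))
                ann_records[site_key] = AnnotationRecord(
                    key=site_key,
                    af=0.0,
                    consequence=consequence,
                    gene=gene,
                    score=round(score, 2),
                    flags=frozenset({"OMIM_disease", "DDID_known"}),
                )

        # reported-relative records consistent with the latent history class
        if plan.history_observed:
            if plan.history == SIMPLEX:
                relatives_rows.append(
                    {"family": fam_id, "degree": int(rng.integers(1, 4)), "affected": False}
                )
            elif plan.history == INTERMEDIATE:
                relatives_rows.append(
                    {"family": fam_id, "degree": int(rng.integers(2, 4)), "affected": True}
                )
            else:
                relatives_rows.append({"family": fam_id, "degree": 1, "affected": True})
                if rng.random() < 0.3:
                    relatives_rows.append(
                        {"family": fam_id, "degree": int(rng.integers(2, 4)), "affected": True}
                    )

    # --- auxiliary plantings -------------------------------------------------
    all_emitted = [(f, s) for f in sorted(family_samples) for s in family_samples[f]]
    parent_ids = [
        (f, s) for f, s in all_emitted if s.endswith("-M") or s.endswith("-F")
    ]

    def _plant_assertion_site(
        fam_id: str,
        carriers: dict[str, str],
        gene: str,
        flags: frozenset[str],
        af: float,
        kind: str,
    ) -> None:
        contig, pos = allocator.autosomal()
        ref, alt = _alleles_for(pos)
        key = (contig, pos, ref, alt)
        state = states[fam_id]
        gts = {s: HOM_REF for s in state.samples}
        gts.update(carriers)
        state.genotypes[key] = gts
        key_str = f"{contig}:{pos}:{ref}:{alt}"
        ann_records[key_str] = AnnotationRecord(
            key=key_str,
            af=af,
            consequence="missense",
            gene=gene,
            score=round(float(rng.uniform(20, 35)), 2),
            flags=flags,
            assertion="pathogenic",
        )
        truth_rows.append(
            {
                "family": fam_id,
                "samples": ",".join(sorted(carriers)),
                "kind": kind,
                "mode": "n/a",
                "submode": "n/a",
                "consequence": "missense",
                "gene": gene,
                "sites": key_str,
                "origins": "n/a",
                "intended_tier": "n/a",
                "assertion": "pathogenic",
                "af": af,
            }
        )

    # ClinVar-asserted carrier alleles across probands and parents
    if config.n_clinvar_planted:
        idx = rng.choice(len(all_emitted), size=min(config.n_clinvar_planted, len(all_emitted)), replace=False)
        for k in sorted(idx):
            fam_id, sample = all_emitted[int(k)]
            state = states[fam_id]
            carriers = {sample: HET}
            if sample in state.probands:
                # transmitted from a sequenced parent where available
                parent = state.mother or state.father
                if parent is not None:
                    carriers[parent] = HET
            gene = recessive_genes[int(rng.integers(len(recessive_genes)))]
            _plant_assertion_site(
                fam_id, carriers, gene, frozenset({"recessive_OMIM"}), 0.002, "clinvar"
            )

    # actionable-panel hits in parents
    if config.n_acmg_planted and parent_ids:
        idx = rng.choice(len(parent_ids), size=min(config.n_acmg_planted, len(parent_ids)), replace=False)
        for k in sorted(idx):
            fam_id, parent = parent_ids[int(k)]
            gene = acmg_genes[int(rng.integers(len(acmg_genes)))]
            _plant_assertion_site(
                fam_id, {parent: HET}, gene, frozenset({"ACMG56"}), 0.001, "acmg"
            )

    # carrier couples sharing a recessive gene
    trio_fams = [p.family_id for p in plans if p.structure == TRIO]
    if config.n_carrier_couples and trio_fams:
        idx = rng.choice(len(trio_fams), size=min(config.n_carrier_couples, len(trio_fams)), replace=False)
        for k in sorted(idx):
            fam_id = trio_fams[int(k)]
            state = states[fam_id]
            gene = carrier_genes[int(rng.integers(len(carrier_genes)))]
            _plant_assertion_site(
                fam_id,
                {state.mother: HET},
                gene,
                frozenset({"carrier_panel", "recessive_OMIM"}),
                0.002,
                "carrier_couple",
            )
            _plant_assertion_site(
                fam_id,
                {state.father: HET},
                gene,
                frozenset({"carrier_panel", "recessive_OMIM"}),
                0.002,
                "carrier_couple",
            )

    # parents whose biallelic recessive genotypes match a self-reported condition
    if config.n_condition_planted and parent_ids:
        idx = rng.choice(len(parent_ids), size=min(config.n_condition_planted, len(parent_ids)), replace=False)
        for k in sorted(idx):
            fam_id, parent = parent_ids[int(k)]
            gene = recessive_genes[int(rng.integers(len(recessive_genes)))]
            state = states[fam_id]
            carriers = {parent: HOM_ALT}
            for p in state.probands:  # transmitted allele keeps Mendel consistency
                carriers[p] = HET
            _plant_assertion_site(
                fam_id, carriers, gene, frozenset({"recessive_OMIM"}), 0.002, "condition"
            )
            conditions.setdefault(parent, set()).add(gene_conditions[gene])

    # events rescued by future knowledge (novel gene, later established)
    unplanted_trios = [
        p.family_id for p in plans if p.structure == TRIO and not p.events
    ]
    rescue_cursor = 0
    for i in range(config.n_upgradable_planted):
        if rescue_cursor >= len(unplanted_trios):
            break
        fam_id = unplanted_trios[rescue_cursor]
        rescue_cursor += 1
        state = states[fam_id]
        gene = novel_genes[i % len(novel_genes)]
        row = plant_causal_event(
            state, DE_NOVO, "frameshift", state.probands[0], gene, allocator, rng
        )
        row["kind"] = "upgradable"
        row["intended_tier"] = "VUS"
        row["upgrade_reason"] = "publication" if i % 2 == 0 else "gene_matching"
        truth_rows.append(row)
        site_key = row["sites"]
        ann_records[site_key] = AnnotationRecord(
            key=site_key,
            af=0.0,
            consequence="frameshift",
            gene=gene,
            score=round(float(rng.uniform(28, 45)), 2),
        )

    # events lost to a parent-depth shortfall, rescued by filter relaxation
    for i in range(config.n_depth_rescue_planted):
        if rescue_cursor >= len(unplanted_trios):
            break
        fam_id = unplanted_trios[rescue_cursor]
        rescue_cursor += 1
        state = states[fam_id]
        gene = causal_genes[int(rng.integers(len(causal_genes)))]
        row = plant_causal_event(
            state, DE_NOVO, "canonical_splice", state.probands[0], gene, allocator, rng
        )
        row["kind"] = "depth_rescue"
        row["upgrade_reason"] = "filter_relaxation"
        truth_rows.append(row)
        site_key = row["sites"]
        ann_records[site_key] = AnnotationRecord(
            key=site_key,
            af=0.0,
            consequence="canonical_splice",
            gene=gene,
            score=round(float(rng.uniform(28, 45)), 2),
            flags=frozenset({"OMIM_disease", "DDID_known"}),
        )
        contig, pos, ref, alt = row["sites"].split(":")
        state.forced_depth[((contig, int(pos), ref, alt), state.father)] = 7

    # --- depth simulation and VariantCall emission ---------------------------
    disp = config.depth_dispersion
    for fam_id in sorted(states):
        state = states[fam_id]
        calls = []
        for key in sorted(state.genotypes, key=lambda k: (k[0] != "1", k[0], k[1])):
            contig, pos, ref, alt = key
            gts = dict(state.genotypes[key])
            if config.genotype_error_rate > 0:
                for s in state.samples:
                    if rng.random() < config.genotype_error_rate:
                        if gts[s] in (HEMI_REF, HEMI_ALT):
                            gts[s] = HEMI_ALT if gts[s] == HEMI_REF else HEMI_REF
                        else:
                            options = [g for g in (HOM_REF, HET, HOM_ALT) if g != gts[s]]
                            gts[s] = options[int(rng.integers(len(options)))]
            depth = {}
            alt_depth = {}
            for s in state.samples:
                forced = state.forced_depth.get((key, s))
                if forced is not None:
                    dp = forced
                else:
                    lam = rng.gamma(1.0 / disp, disp * config.depth_mean)
                    dp = int(rng.poisson(lam))
                depth[s] = dp
                alt_depth[s] = int(rng.binomial(dp, expected_vaf(gts[s]))) if dp else 0
            calls.append(
                VariantCall(
                    chrom=contig,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    genotypes=gts,
                    depth=depth,
                    alt_depth=alt_depth,
                )
            )
        family_calls[fam_id] = calls

    # truth min-depth bookkeeping (which planted events meet evidence thresholds)
    call_index = {
        (fam_id, c.key_str): c for fam_id, cl in family_calls.items() for c in cl
    }
    for row in truth_rows:
        fam_id = row["family"]
        state = states[fam_id]
        unit_samples = [row["samples"].split(",")[0]] if row["kind"] != "causal" else None
        samples = (
            [s for s in (row["samples"], state.mother, state.father) if s]
            if row["kind"] in ("causal", "upgradable", "depth_rescue")
            else row["samples"].split(",")
        )
        depths = []
        for site in row["sites"].split("|"):
            call = call_index[(fam_id, site)]
            depths.extend(call.depth[s] for s in samples)
        row["min_depth"] = min(depths)

    # --- CNVs ----------------------------------------------------------------
    cnv_truth: list[CnvCall] = []
    for plan in plans:
        if not plan.cnv_event:
            continue
        sample = f"{plan.family_id}-C"
        length = int(
            np.exp(
                rng.uniform(np.log(config.cnv.min_length), np.log(config.cnv.max_length))
            )
        )
        start = int(rng.integers(1_000_000, 200_000_000))
        cnv_type = "DEL" if rng.random() < 0.5 else "DUP"
        cnv_truth.append(CnvCall("1", start, start + length, cnv_type, "truth", sample))
        truth_rows.append(
            {
                "family": plan.family_id,
                "samples": sample,
                "kind": "causal_cnv",
                "mode": "de_novo",
                "submode": cnv_type,
                "consequence": "cnv",
                "gene": "",
                "sites": f"1:{start}-{start + length}",
                "origins": "de_novo",
                "intended_tier": "pathogenic",
                "assertion": "none",
                "af": 0.0,
                "min_depth": 0,
            }
        )
    parent_pool = [s for _, s in parent_ids]
    cnv_calls, cnv_parent_calls = simulate_cnv_callsets(
        cnv_truth, config.cnv, rng, parent_pool
    )

    # segmental duplications and gene models on the CNV contig
    segdups = []
    for _ in range(30):
        start = int(rng.integers(1_000_000, 230_000_000))
        segdups.append(("1", start, start + int(rng.integers(10_000, 200_000))))
    segdups.sort()
    gene_models = []
    panel_genes = set(causal_genes)
    for i, gene in enumerate(causal_genes + [f"BGGENE{i:03d}" for i in range(30)]):
        start = 2_000_000 + i * 3_000_000
        gene_models.append(
            GeneModel(
                gene,
                "1",
                start,
                start + 50_000,
                exons=[(start, start + 200), (start + 49_800, start + 50_000)],
            )
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "family", "samples", "kind", "mode", "submode", "consequence",
            "gene", "sites", "origins", "intended_tier", "assertion", "af",
            "upgrade_reason", "min_depth",
        ],
    )
    truth["upgrade_reason"] = truth.get("upgrade_reason", pd.Series(dtype=object)).fillna("")
    relatives = pd.DataFrame(relatives_rows, columns=["family", "degree", "affected"])

    return CohortData(
        config=config,
        pedigree=pedigree,
        family_samples=family_samples,
        family_calls=family_calls,
        annotations=AnnotationTable(ann_records),
        gene_disease=GeneDiseaseTable(gene_entries),
        truth=truth,
        relatives=relatives,
        assays=assays,
        conditions=conditions,
        gene_conditions=gene_conditions,
        cnv_truth=cnv_truth,
        cnv_calls=cnv_calls,
        cnv_parent_calls=cnv_parent_calls,
        segdups=segdups,
        gene_models=gene_models,
        panel_genes=panel_genes,
    )
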