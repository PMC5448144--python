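"""Five-tier rule engine: worked classifications, determinism, evidence
monotonicity, and the parental secondary-findings screens."""

import inspect
import io
from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st

from triodx import (
    AnnotationRecord,
    AnnotationTable,
    EvidenceBundle,
    classify_variant,
    default_criteria,
    mate_pair_carrier_scan,
    screen_secondary,
)
from triodx.annotations import GeneDiseaseEntry, GeneDiseaseTable
from triodx.classify import (
    BENIGN,
    ConfigError,
    CriteriaConfig,
    LIKELY_BENIGN,
    LIKELY_PATHOGENIC,
    PATHOGENIC,
    TIER_ORDER,
    VUS,
    build_evidence,
)
from triodx.pedcore import load_pedigree
from triodx.variants import HET, HOM_ALT, HOM_REF, VariantCall

CRITERIA = default_criteria()


def test_de_novo_nonsense_in_established_gene_is_pathogenic():
    bundle = EvidenceBundle(
        mode="de_novo",
        af=0.0,
        prior_report="established_gene_match",
        mechanism_consistent=True,
        consequence="nonsense",
        phenotype_overlap=True,
    )
    cls = classify_variant(bundle, CRITERIA)
    assert cls.tier == PATHOGENIC
    assert cls.config_version == CRITERIA.version


def test_mechanism_inconsistent_splice_is_vus():
    """Inherited loss-of-function splice variant in a gene whose established
    mechanism is gain-of-function missense stays a VUS."""
    bundle = EvidenceBundle(
        mode="unknown",
        af=0.0,
        prior_report="established_gene_match",
        mechanism_consistent=False,
        consequence="canonical_splice",
    )
    assert classify_variant(bundle, CRITERIA).tier == VUS


def test_common_variants_are_benign_regardless_of_other_evidence():
    strong = dict(
        mode="de_novo",
        prior_report="established_gene_match",
        mechanism_consistent=True,
        consequence="nonsense",
    )
    assert classify_variant(EvidenceBundle(af=0.05, **strong), CRITERIA).tier in (
        BENIGN,
        LIKELY_BENIGN,
    )
    assert classify_variant(EvidenceBundle(af=0.2, **strong), CRITERIA).tier == BENIGN


def test_de_novo_missense_established_is_likely_pathogenic():
    bundle = EvidenceBundle(
        mode="de_novo",
        af=0.0,
        prior_report="established_gene_match",
        mechanism_consistent=True,
        consequence="missense",
    )
    assert classify_variant(bundle, CRITERIA).tier == LIKELY_PATHOGENIC


def test_no_gene_association_caps_at_vus():
    bundle = EvidenceBundle(
        mode="de_novo", af=0.0, prior_report="none", consequence="nonsense"
    )
    assert classify_variant(bundle, CRITERIA).tier == VUS


def test_classification_is_deterministic():
    bundle = EvidenceBundle(
        mode="compound_het",
        af=0.0,
        prior_report="established_gene_match",
        consequence="frameshift",
    )
    results = {classify_variant(bundle, CRITERIA) for _ in range(5)}
    assert len(results) == 1


def test_malformed_criteria_rejected():
    with pytest.raises(ConfigError):
        CriteriaConfig.from_dict(
            {"version": "x", "rules": [{"name": "r", "tier": "plausible", "when": {}}]}
        )
    with pytest.raises(ConfigError):
        CriteriaConfig.from_dict(
            {"version": "x", "rules": [{"name": "r", "tier": "VUS", "when": {"af_gt": 0.5}}]}
        )


_PRIOR_ORDER = [
    "none",
    "reported_variant_uncertain",
    "established_gene_match",
    "reported_variant_pathogenic",
]
_MODE_ORDER = ["unknown", "de_novo"]
_CONSEQ_ORDER = ["missense", "nonsense"]

bundles = st.builds(
    EvidenceBundle,
    mode=st.sampled_from(["unknown", "de_novo", "compound_het", "x_linked_maternal"]),
    af=st.sampled_from([0.0, 0.0005, 0.02, 0.1]),
    batch_count=st.sampled_from([1, 3]),
    prior_report=st.sampled_from(_PRIOR_ORDER),
    mechanism_consistent=st.booleans(),
    consequence=st.sampled_from(["missense", "nonsense", "canonical_splice", "inframe"]),
    phenotype_overlap=st.booleans(),
)


def _tier(bundle):
    return TIER_ORDER[classify_variant(bundle, CRITERIA).tier]


@settings(max_examples=300, derandomize=True)
@given(bundle=bundles)
def test_strengthening_evidence_never_moves_away_from_pathogenic(bundle):
    """Partial-order monotonicity over the evidence lattice: upgrading one
    field (prior report, mode informativeness, frequency rarity, mechanism
    consistency) never lowers the tier."""
    base = _tier(bundle)
    i = _PRIOR_ORDER.index(bundle.prior_report)
    if i + 1 < len(_PRIOR_ORDER):
        assert _tier(replace(bundle, prior_report=_PRIOR_ORDER[i + 1])) >= base
    if bundle.mode == "unknown":
        assert _tier(replace(bundle, mode="de_novo")) >= base
    if bundle.af > 0.0:
        assert _tier(replace(bundle, af=0.0, batch_count=1)) >= base
    if not bundle.mechanism_consistent:
        assert _tier(replace(bundle, mechanism_consistent=True)) >= base
    if bundle.consequence == "missense":
        assert _tier(replace(bundle, consequence="nonsense")) >= base


def test_build_evidence_uses_most_severe_pair_member():
    from triodx.inherit_filter import Candidate

    v1 = VariantCall("1", 100, "A", "T", {"P": HET}, {"P": 30}, {"P": 15})
    v2 = VariantCall("1", 200, "A", "T", {"P": HET}, {"P": 30}, {"P": 15})
    ann = AnnotationTable(
        {
            "1:100:A:T": AnnotationRecord("1:100:A:T", 0.0, "missense", "G1", 20.0),
            "1:200:A:T": AnnotationRecord("1:200:A:T", 0.0, "nonsense", "G1", 35.0),
        }
    )
    gd = GeneDiseaseTable({"G1": GeneDiseaseEntry("G1", "established", "lof")})
    cand = Candidate([v1, v2], "compound_het", "P", "F", "trio")
    bundle = build_evidence(cand, ann, gd)
    assert bundle.consequence == "nonsense"
    assert bundle.score == 35.0
    assert bundle.prior_report == "established_gene_match"


# ---------------------------------------------------------------------------
# secondary findings
# ---------------------------------------------------------------------------

PED = """\
T1 T1-C T1-F T1-M 1 2
T1 T1-M 0 0 2 1
T1 T1-F 0 0 1 1
"""


def _ann(records):
    return AnnotationTable({r.key: r for r in records})


def _site(pos, gts):
    return VariantCall(
        "1", pos, "A", "T", gts, {s: 30 for s in gts}, {s: 15 for s in gts}
    )


def test_secondary_screen_three_parts():
    ped = load_pedigree(io.StringIO(PED))
    calls = {
        "T1": [
            _site(100, {"T1-C": HOM_REF, "T1-M": HET, "T1-F": HOM_REF}),  # ACMG
            _site(200, {"T1-C": HET, "T1-M": HOM_ALT, "T1-F": HOM_REF}),  # condition
            _site(300, {"T1-C": HOM_REF, "T1-M": HOM_REF, "T1-F": HET}),  # carrier
        ]
    }
    ann = _ann(
        [
            AnnotationRecord(
                "1:100:A:T", 0.001, "missense", "ACMG01", 25.0,
                flags=frozenset({"ACMG56"}), assertion="pathogenic",
            ),
            AnnotationRecord(
                "1:200:A:T", 0.002, "missense", "REC01", 25.0,
                flags=frozenset({"recessive_OMIM"}), assertion="pathogenic",
            ),
            AnnotationRecord(
                "1:300:A:T", 0.002, "missense", "CARRIER_HBB", 25.0,
                flags=frozenset({"carrier_panel"}), assertion="likely_pathogenic",
            ),
        ]
    )
    report = screen_secondary(
        calls,
        ann,
        ped,
        self_reported={"T1-M": {"carnitine_deficiency"}},
        gene_conditions={"REC01": "carnitine_deficiency"},
    )
    parts = report.groupby("part")["parent"].apply(list).to_dict()
    assert parts["acmg56"] == ["T1-M"]
    assert parts["condition_match"] == ["T1-M"]
    assert parts["carrier"] == ["T1-F"]
    # proband genotypes never surface in the parental screen
    assert "T1-C" not in set(report["parent"])


def test_secondary_screen_never_sees_proband_phenotypes():
    """Scope isolation by construction: the screen's signature has no
    proband or phenotype parameter."""
    params = set(inspect.signature(screen_secondary).parameters)
    assert params == {
        "family_calls", "annotations", "pedigree", "self_reported", "gene_conditions",
    }


def test_mate_pair_scan_requires_shared_gene():
    ped = load_pedigree(io.StringIO(PED))
    ann = _ann(
        [
            AnnotationRecord(
                "1:100:A:T", 0.002, "missense", "ATP7B_LIKE", 25.0,
                flags=frozenset({"recessive_OMIM"}), assertion="pathogenic",
            ),
            AnnotationRecord(
                "1:200:A:T", 0.002, "missense", "OTHER", 25.0,
                flags=frozenset({"recessive_OMIM"}), assertion="pathogenic",
            ),
        ]
    )
    shared = {
        "T1": [
            _site(100, {"T1-C": HOM_REF, "T1-M": HET, "T1-F": HOM_REF}),
            _site(100, {"T1-C": HOM_REF, "T1-M": HOM_REF, "T1-F": HET}),
        ]
    }
    couples = mate_pair_carrier_scan(ped, shared, ann)
    assert len(couples) == 1
    assert couples.iloc[0]["gene"] == "ATP7B_LIKE"
    split = {
        "T1": [
            _site(100, {"T1-C": HOM_REF, "T1-M": HET, "T1-F": HOM_REF}),
            _site(200, {"T1-C": HOM_REF, "T1-M": HOM_REF, "T1-F": HET}),
        ]
    }
    assert len(mate_pair_carrier_scan(ped, split, ann)) == 0


def test_planted_carrier_couples_recovered_exactly():
    """Simulator-ledger oracle: 3 planted shared-carrier couples among ~300
    parent pairs are all found, and nothing else."""
    from triodx import SimConfig, simulate_cohort
    from triodx.cohortsim import CnvParams

    cohort = simulate_cohort(
        SimConfig(
            n_families=320,
            seed=31,
            n_carrier_couples=3,
            n_clinvar_planted=0,
            n_condition_planted=0,
            n_acmg_planted=0,
            cnv=CnvParams(n_events=0),
        )
    )
    couples = mate_pair_carrier_scan(
        cohort.pedigree, cohort.family_calls, cohort.annotations
    )
    truth_fams = set(
        cohort.truth[cohort.truth["kind"] == "carrier_couple"]["family"]
    )
    assert len(truth_fams) == 3
    assert set(couples["family"]) == truth_fams
    assert len(couples) == 3
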