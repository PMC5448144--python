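"""Inheritance-mode detection, compound-het pairing, the filter cascade and
the assertion (ClinVar-style) scan."""

import io

import numpy as np
import pytest

from triodx import (
    AnnotationRecord,
    AnnotationTable,
    FilterConfig,
    apply_filters,
    clinvar_scan,
    compound_het_pairs,
    compute_batch_allele_counts,
    detect_inheritance_modes,
)
from triodx.inherit_filter import (
    COMPOUND_HET,
    DE_NOVO,
    HOMOZYGOUS_RECESSIVE,
    MATERNAL,
    PATERNAL,
    BIPARENTAL,
    UNKNOWN_MODE,
    UNKNOWN_ORIGIN,
    X_LINKED_MATERNAL,
    surviving,
)
from triodx.pedcore import load_pedigree
from triodx.pipeline import planted_recovery
from triodx.variants import (
    HET,
    HOM_ALT,
    HOM_REF,
    HEMI_ALT,
    HEMI_REF,
    VariantCall,
)

PED = """\
T1 T1-C T1-F T1-M 1 2
T1 T1-M 0 0 2 1
T1 T1-F 0 0 1 1
"""


@pytest.fixture
def trio_unit():
    return load_pedigree(io.StringIO(PED)).analysis_units()[0]


def _call(chrom, pos, gts, depth=30):
    return VariantCall(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="T",
        genotypes=gts,
        depth={s: depth for s in gts},
        alt_depth={
            s: depth if g in (HOM_ALT, HEMI_ALT) else depth // 2 if g == HET else 0
            for s, g in gts.items()
        },
    )


def _ann(records):
    return AnnotationTable({r.key: r for r in records})


def test_de_novo_definition(trio_unit):
    v = _call("1", 100, {"T1-C": HET, "T1-M": HOM_REF, "T1-F": HOM_REF})
    cands = detect_inheritance_modes([v], trio_unit)
    assert [c.mode for c in cands] == [DE_NOVO]


def test_homozygous_recessive(trio_unit):
    v = _call("1", 100, {"T1-C": HOM_ALT, "T1-M": HET, "T1-F": HET})
    cands = detect_inheritance_modes([v], trio_unit)
    assert [c.mode for c in cands] == [HOMOZYGOUS_RECESSIVE]


def test_two_hemizygous_brothers_from_carrier_mother():
    ped = load_pedigree(
        io.StringIO(
            "B1 B1-C B1-F B1-M 1 2\nB1 B1-C2 B1-F B1-M 1 2\n"
            "B1 B1-M 0 0 2 1\nB1 B1-F 0 0 1 1\n"
        )
    )
    v = _call(
        "X",
        500,
        {"B1-C": HEMI_ALT, "B1-C2": HEMI_ALT, "B1-M": HET, "B1-F": HEMI_REF},
    )
    modes = []
    for unit in ped.analysis_units():
        cands = detect_inheritance_modes([v], unit)
        modes.extend(c.mode for c in cands)
    assert modes == [X_LINKED_MATERNAL, X_LINKED_MATERNAL]


def test_compound_het_one_allele_from_each_parent(trio_unit):
    v1 = _call("1", 100, {"T1-C": HET, "T1-M": HET, "T1-F": HOM_REF})
    v2 = _call("1", 200, {"T1-C": HET, "T1-M": HOM_REF, "T1-F": HET})
    ann = _ann(
        [
            AnnotationRecord("1:100:A:T", 0.0, "missense", "G1", 30.0),
            AnnotationRecord("1:200:A:T", 0.0, "canonical_splice", "G1", 32.0),
        ]
    )
    cands = detect_inheritance_modes([v1, v2], trio_unit, ann)
    pairs = [c for c in cands if c.mode == COMPOUND_HET]
    assert len(pairs) == 1
    assert pairs[0].origins == [MATERNAL, PATERNAL]


def test_same_haplotype_hets_never_pair():
    labeled = [(_call("1", 100, {"P": HET}), MATERNAL), (_call("1", 200, {"P": HET}), MATERNAL)]
    assert compound_het_pairs(labeled) == []


def test_biparental_carriers_excluded_from_pairs():
    labeled = [
        (_call("1", 100, {"P": HET}), BIPARENTAL),
        (_call("1", 200, {"P": HET}), PATERNAL),
    ]
    assert compound_het_pairs(labeled) == []


def test_compound_het_pairs_match_brute_force(rng):
    """1,000 random gene configurations against all-pairs enumeration."""
    labels = [MATERNAL, PATERNAL, BIPARENTAL, UNKNOWN_ORIGIN]
    for trial in range(1000):
        n = int(rng.integers(0, 8))
        labeled = []
        for i in range(n):
            lab = labels[int(rng.integers(4))]
            labeled.append((_call("1", 100 + i, {"P": HET}), lab))
        got = compound_het_pairs(labeled)
        expect = []
        for v1, l1 in labeled:
            for v2, l2 in labeled:
                if v1.pos < v2.pos and {l1, l2} == {MATERNAL, PATERNAL}:
                    expect.append((v1.pos, v2.pos))
        got_set = sorted(
            tuple(sorted((a.pos, b.pos))) for a, b in got
        )
        assert got_set == sorted(expect), f"trial {trial}"
        k = sum(1 for _, l in labeled if l == MATERNAL)
        m = sum(1 for _, l in labeled if l == PATERNAL)
        assert len(got) == k * m


def test_duo_and_singleton_produce_unknown_mode():
    ped = load_pedigree(
        io.StringIO("D1 D1-C 0 D1-M 1 2\nD1 D1-M 0 0 2 1\nS1 S1-C 0 0 1 2\n")
    )
    units = {u.proband.sample_id: u for u in ped.analysis_units()}
    duo_v = _call("1", 100, {"D1-C": HET, "D1-M": HOM_REF})
    cands = detect_inheritance_modes([duo_v], units["D1-C"])
    assert [c.mode for c in cands] == [UNKNOWN_MODE]
    assert cands[0].confidence == "reduced"
    single_v = _call("1", 100, {"S1-C": HET})
    cands = detect_inheritance_modes([single_v], units["S1-C"])
    assert [c.mode for c in cands] == [UNKNOWN_MODE]


def test_single_variant_candidates_have_one_mode_each(cohort500, run500):
    seen = {}
    for cand in run500.candidates:
        if len(cand.variants) != 1:
            continue
        key = (cand.proband_id, cand.keys[0])
        assert key not in seen, key
        seen[key] = cand.mode


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------


def _filter_one(cand_gts, depths, ann_rec, config, mode=DE_NOVO, ped_text=PED):
    unit = load_pedigree(io.StringIO(ped_text)).analysis_units()[0]
    v = VariantCall(
        chrom="1",
        pos=100,
        ref="A",
        alt="T",
        genotypes=cand_gts,
        depth=depths,
        alt_depth={s: depths[s] // 2 if g == HET else 0 for s, g in cand_gts.items()},
    )
    from triodx.inherit_filter import Candidate

    cand = Candidate([v], mode, "T1-C", "T1", "trio")
    out = apply_filters(
        [cand], _ann([ann_rec]), config, {v.key_str: 1}, {"T1-C": unit}
    )
    return out[0]


def test_low_parent_depth_removed_then_rescued():
    """A splice candidate whose father was covered by only 7 reads fails the
    10-read floor but survives a 5-read floor."""
    gts = {"T1-C": HET, "T1-M": HOM_REF, "T1-F": HOM_REF}
    depths = {"T1-C": 30, "T1-M": 25, "T1-F": 7}
    rec = AnnotationRecord("1:100:A:T", 0.0, "canonical_splice", "G1", 33.0)
    strict = _filter_one(gts, depths, rec, FilterConfig(min_depth=10))
    assert not strict.survived
    assert ("depth", "fail", "min=7<10") in strict.trail
    relaxed = _filter_one(gts, depths, rec, FilterConfig(min_depth=5))
    assert relaxed.survived


def test_batch_count_per_family_keeps_twin_shared_variant():
    """A variant shared by identical twins in one family passes a
    per-family batch cap of 1 but fails per-sample counting."""
    fam_calls = {
        "T1": [
            _call("1", 100, {"T1-C": HET, "T1-C2": HET, "T1-M": HOM_REF, "T1-F": HOM_REF})
        ]
    }
    per_family = compute_batch_allele_counts(fam_calls, per="family")
    per_sample = compute_batch_allele_counts(fam_calls, per="sample")
    assert per_family["1:100:A:T"] == 1
    assert per_sample["1:100:A:T"] == 2
    ped = (
        "T1 T1-C T1-F T1-M 1 2\nT1 T1-C2 T1-F T1-M 1 2\n"
        "T1 T1-M 0 0 2 1\nT1 T1-F 0 0 1 1\n"
    )
    unit = load_pedigree(io.StringIO(ped)).analysis_units()[0]
    from triodx.inherit_filter import Candidate

    v = fam_calls["T1"][0]
    rec = AnnotationRecord("1:100:A:T", 0.0, "missense", "G1", 30.0)
    for counts, expect in ((per_family, True), (per_sample, False)):
        cand = Candidate([v], DE_NOVO, "T1-C", "T1", "trio")
        out = apply_filters(
            [cand], _ann([rec]), FilterConfig(), counts, {"T1-C": unit}
        )
        assert out[0].survived is expect


def test_common_variant_removed_under_any_rare_threshold():
    gts = {"T1-C": HET, "T1-M": HOM_REF, "T1-F": HOM_REF}
    depths = {s: 30 for s in gts}
    rec = AnnotationRecord("1:100:A:T", 0.2, "missense", "G1", 30.0)
    out = _filter_one(gts, depths, rec, FilterConfig())
    assert not out.survived
    assert any(r == "af" and o == "fail" for r, o, _ in out.trail)


def test_missing_annotation_retained_with_trail_flag():
    gts = {"T1-C": HET, "T1-M": HOM_REF, "T1-F": HOM_REF}
    depths = {s: 30 for s in gts}
    unit = load_pedigree(io.StringIO(PED)).analysis_units()[0]
    from triodx.inherit_filter import Candidate

    v = _call("1", 100, gts)
    cand = Candidate([v], DE_NOVO, "T1-C", "T1", "trio")
    out = apply_filters(
        [cand], AnnotationTable({}), FilterConfig(), {}, {"T1-C": unit}
    )
    assert out[0].survived
    assert ("no_annotation", "pass", "retained") in out[0].trail


def test_parental_mosaicism_guard():
    gts = {"T1-C": HET, "T1-M": HOM_REF, "T1-F": HOM_REF}
    unit = load_pedigree(io.StringIO(PED)).analysis_units()[0]
    from triodx.inherit_filter import Candidate

    v = VariantCall(
        chrom="1", pos=100, ref="A", alt="T", genotypes=gts,
        depth={"T1-C": 30, "T1-M": 30, "T1-F": 30},
        alt_depth={"T1-C": 15, "T1-M": 4, "T1-F": 0},  # mother 13% alt reads
    )
    rec = AnnotationRecord("1:100:A:T", 0.0, "missense", "G1", 30.0)
    cand = Candidate([v], DE_NOVO, "T1-C", "T1", "trio")
    out = apply_filters([cand], _ann([rec]), FilterConfig(), {}, {"T1-C": unit})
    assert not out[0].survived
    assert any(r == "parental_evidence" and o == "fail" for r, o, _ in out[0].trail)


def test_relaxing_any_threshold_never_removes_survivors(cohort500, run500):
    """Pairwise config dominance: every candidate surviving the strict
    config also survives each single-threshold relaxation."""
    from triodx.pipeline import baseline_snapshot, analyze_cohort

    strict_keys = {
        (c.proband_id, c.gene_key) for c in surviving(run500.candidates)
    }
    relaxations = [
        FilterConfig(min_depth=5),
        FilterConfig(max_af_dominant=0.01, max_af_recessive=0.05),
        FilterConfig(max_batch_count=3),
    ]
    for config in relaxations:
        run = analyze_cohort(
            cohort500, baseline_snapshot(cohort500, filter_config=config)
        )
        relaxed_keys = {(c.proband_id, c.gene_key) for c in surviving(run.candidates)}
        assert strict_keys <= relaxed_keys, config


def test_planted_events_recovered_with_correct_modes(cohort500, run500):
    """Noise-free cohort: every planted event meeting the default evidence
    thresholds survives the cascade with its declared inheritance mode."""
    rec = planted_recovery(cohort500, run500)
    eligible = rec[rec["eligible"]]
    assert len(eligible) > 80
    assert eligible["recovered"].all()
    assert eligible["mode_correct"].all()


# ---------------------------------------------------------------------------
# assertion scan
# ---------------------------------------------------------------------------


def test_empty_assertion_table_gives_empty_scan(trio_unit, cohort500):
    hits = clinvar_scan(
        {"T1": [_call("1", 100, {"T1-C": HET, "T1-M": HOM_REF, "T1-F": HOM_REF})]},
        AnnotationTable({}),
        load_pedigree(io.StringIO(PED)),
    )
    assert hits == []


def test_carrier_parent_reported_with_context():
    ped = load_pedigree(io.StringIO(PED))
    rec = AnnotationRecord(
        "1:100:A:T", 0.002, "missense", "REC1", 25.0,
        flags=frozenset({"recessive_OMIM"}), assertion="pathogenic",
    )
    hits = clinvar_scan(
        {"T1": [_call("1", 100, {"T1-C": HOM_REF, "T1-M": HET, "T1-F": HOM_REF})]},
        _ann([rec]),
        ped,
    )
    assert len(hits) == 1
    assert hits[0]["sample"] == "T1-M"
    assert hits[0]["zygosity"] == HET
    assert hits[0]["affected"] is False


def test_all_planted_asserted_alleles_recovered(cohort500):
    """Every carrier recorded in the truth ledger for an asserted
    pathogenic allele appears in the scan (simulator-ledger oracle)."""
    hits = clinvar_scan(
        cohort500.family_calls, cohort500.annotations, cohort500.pedigree
    )
    hit_set = {(h["sample"], h["key"]) for h in hits}
    truth = cohort500.truth[cohort500.truth["assertion"] == "pathogenic"]
    assert len(truth) >= 20
    for row in truth.itertuples(index=False):
        for sample in row.samples.split(","):
            assert (sample, row.sites) in hit_set
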