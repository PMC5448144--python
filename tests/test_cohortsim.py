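"""Simulator behavior: determinism, planted-event genotype semantics,
realized category fractions, and CNV callset noise models."""

import filecmp
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from triodx import SimConfig, simulate_cohort, simulate_cnv_callsets
from triodx.cnvmerge import CnvCall, CnvMergeConfig, merge_callsets
from triodx.cohortsim import (
    CnvParams,
    ConfigError,
    PlantingError,
    plan_cohort,
    DE_NOVO,
    RECESSIVE_OR_COMPHET,
    UNKNOWN,
    X_LINKED_MATERNAL,
)
from triodx.variants import HET, HOM_REF, HOM_ALT, HEMI_ALT, HEMI_REF


def _all_files(root: Path) -> list[Path]:
    return sorted(p for p in root.rglob("*") if p.is_file())


def test_fixed_seed_outputs_are_byte_identical(tmp_path):
    dirs = []
    for name in ("a", "b"):
        cohort = simulate_cohort(SimConfig(n_families=40, seed=7))
        out = tmp_path / name
        cohort.write(out)
        dirs.append(out)
    files_a = _all_files(dirs[0])
    files_b = _all_files(dirs[1])
    assert [p.relative_to(dirs[0]) for p in files_a] == [
        p.relative_to(dirs[1]) for p in files_b
    ]
    for pa, pb in zip(files_a, files_b):
        if pa.name == "config.yaml":
            continue
        assert filecmp.cmp(pa, pb, shallow=False), pa.name


def test_trio_only_structure_mix_gives_two_parents_everywhere():
    cfg = SimConfig(
        n_families=30,
        structure_mix={"trio": 1.0, "duo": 0.0, "singleton": 0.0},
        seed=3,
    )
    cohort = simulate_cohort(cfg)
    for unit in cohort.pedigree.analysis_units():
        assert unit.structure == "trio"
        assert unit.mother is not None and unit.father is not None


@pytest.mark.parametrize(
    "bad",
    [
        {"structure_mix": {"trio": 0.6, "duo": 0.2, "singleton": 0.1}},
        {"mode_mix": {DE_NOVO: 0.5, RECESSIVE_OR_COMPHET: 0.6, X_LINKED_MATERNAL: 0.0, UNKNOWN: 0.0}},
        {"n_sites": 3},
        {"n_families": 0},
    ],
)
def test_invalid_configs_raise(bad):
    with pytest.raises(ConfigError):
        simulate_cohort(SimConfig(**bad, seed=1))


def test_planted_mode_fraction_matches_configured_mix():
    """~1,000 planted events: realized de novo fraction inside the central
    99% binomial interval around 0.76."""
    cfg = SimConfig(n_families=3700, seed=5)
    rng = np.random.default_rng(cfg.seed)
    plans = plan_cohort(cfg, rng)
    events = [e for p in plans for e in p.events]
    assert len(events) > 900
    n = len(events)
    n_dn = sum(1 for mode, _ in events if mode == DE_NOVO)
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.76)
    assert lo <= n_dn <= hi


def test_category_fractions_converge_to_mixes():
    """Law-of-large-numbers check at n = 10,000 families (4 SE tolerance)."""
    cfg = SimConfig(n_families=10_000, seed=9)
    rng = np.random.default_rng(cfg.seed)
    plans = plan_cohort(cfg, rng)
    n = len(plans)
    for cls, p in cfg.history_mix.items():
        realized = sum(1 for pl in plans if pl.history == cls and pl.n_probands == 1) / n
        assert abs(realized - p) <= 4 * np.sqrt(p * (1 - p) / n) + 0.01
    events = [e for p in plans for e in p.events]
    m = len(events)
    for mode, p in cfg.mode_mix.items():
        realized = sum(1 for md, _ in events if md == mode) / m
        assert abs(realized - p) <= 4 * np.sqrt(p * (1 - p) / m)
    raw_map = {
        "missense": {"missense"},
        "nonsense_or_frameshift": {"nonsense", "frameshift"},
        "splice": {"canonical_splice"},
        "inframe": {"inframe"},
    }
    for raw, p in cfg.consequence_mix.items():
        realized = sum(1 for _, c in events if c in raw_map[raw]) / m
        assert abs(realized - p) <= 4 * np.sqrt(p * (1 - p) / m)


def _call_lookup(cohort, family):
    return {c.key_str: c for c in cohort.family_calls[family]}


def test_planted_genotypes_match_declared_modes(cohort500):
    causal = cohort500.truth[cohort500.truth["kind"] == "causal"]
    seen = set()
    for row in causal.itertuples(index=False):
        fam = cohort500.pedigree.families[row.family]
        proband = fam.samples[row.samples]
        calls = _call_lookup(cohort500, row.family)
        sites = row.sites.split("|")
        origins = row.origins.split("|")
        seen.add(row.mode)
        if row.mode == DE_NOVO:
            call = calls[sites[0]]
            assert call.genotypes[row.samples] == HET
            assert call.genotypes[proband.mother_id] == HOM_REF
            assert call.genotypes[proband.father_id] == HOM_REF
        elif row.mode == X_LINKED_MATERNAL:
            call = calls[sites[0]]
            assert call.chrom == "X"
            assert call.genotypes[row.samples] == HEMI_ALT
            assert call.genotypes[proband.mother_id] == HET
            assert call.genotypes[proband.father_id] == HEMI_REF
        elif row.mode == RECESSIVE_OR_COMPHET and row.submode == "compound_het":
            # re-derive parental origin from the emitted (unphased) genotypes
            derived = []
            for site in sites:
                call = calls[site]
                assert call.genotypes[row.samples] == HET
                m = call.genotypes[proband.mother_id]
                f = call.genotypes[proband.father_id]
                derived.append("maternal" if m == HET and f == HOM_REF else "paternal")
            assert derived == origins
        elif row.mode == RECESSIVE_OR_COMPHET:
            call = calls[sites[0]]
            assert call.genotypes[row.samples] == HOM_ALT
            assert call.genotypes[proband.mother_id] == HET
            assert call.genotypes[proband.father_id] == HET
        elif row.mode == UNKNOWN:
            call = calls[sites[0]]
            assert call.genotypes[row.samples] == HET
            for pid in (proband.mother_id, proband.father_id):
                if pid and pid in call.genotypes:
                    assert call.genotypes[pid] == HOM_REF
    assert {DE_NOVO, RECESSIVE_OR_COMPHET, X_LINKED_MATERNAL, UNKNOWN} <= seen


def test_background_sites_follow_mendelian_transmission(cohort500):
    """Noise-free trios never violate transmission at background sites."""
    from triodx.pedcore import mendelian_violation_fraction
    from triodx.variants import dosage_matrix

    checked = 0
    for unit in cohort500.pedigree.analysis_units()[:50]:
        if unit.structure != "trio":
            continue
        # background panel only: planted sites (de novo by design) live in
        # the family-private coordinate range
        calls = [
            c
            for c in cohort500.family_calls[unit.family_id]
            if c.pos < 150_000_000
        ]
        samples = [unit.proband.sample_id, unit.mother.sample_id, unit.father.sample_id]
        mat = dosage_matrix(calls, samples)
        assert mendelian_violation_fraction(mat[0], mat[1], mat[2]) == 0.0
        checked += 1
    assert checked > 10


def test_x_linked_requires_male_proband_with_mother(cohort500):
    from triodx.cohortsim import _FamilyState, _SiteAllocator, FamilyPlan

    plan = FamilyPlan("FX", "trio", "mother", "simplex", True, 1, ["female"], [], "WGS")
    state = _FamilyState(
        plan=plan,
        samples=["FX-C", "FX-M", "FX-F"],
        probands=["FX-C"],
        mother="FX-M",
        father="FX-F",
        sexes={"FX-C": "female", "FX-M": "female", "FX-F": "male"},
    )
    from triodx.cohortsim import plant_causal_event

    with pytest.raises(PlantingError):
        plant_causal_event(
            state, X_LINKED_MATERNAL, "missense", "FX-C", "DDID000",
            _SiteAllocator(), np.random.default_rng(0),
        )


# ---------------------------------------------------------------------------
# CNV callset simulation
# ---------------------------------------------------------------------------


def _truth_calls(n, rng, length=50_000):
    calls = []
    for i in range(n):
        start = int(rng.integers(1_000_000, 100_000_000))
        calls.append(
            CnvCall("1", start, start + length, "DEL" if i % 2 else "DUP", "truth", f"S{i}")
        )
    return calls


def test_noise_free_callsets_equal_truth(rng):
    truth = _truth_calls(20, rng)
    callsets, parents = simulate_cnv_callsets(truth, CnvParams(), np.random.default_rng(1))
    for caller, calls in callsets.items():
        assert [(c.contig, c.start, c.end, c.type, c.sample) for c in calls] == [
            (t.contig, t.start, t.end, t.type, t.sample) for t in truth
        ]
    assert parents == []


def test_excessive_jitter_is_a_config_error():
    with pytest.raises(ConfigError):
        CnvParams(jitter_sd=30_000, min_length=20_000).validate()


def test_consensus_recall_under_independent_caller_misses(rng):
    """500 events at 5% per-caller FN: consensus recall ~ 0.95^2 within a
    central binomial interval (independent misses)."""
    truth = _truth_calls(500, rng)
    params = CnvParams(fn_rate=0.05)
    callsets, _ = simulate_cnv_callsets(truth, params, np.random.default_rng(2))
    recovered = 0
    config = CnvMergeConfig()
    by_sample_a = {}
    by_sample_b = {}
    callers = sorted(callsets)
    for c in callsets[callers[0]]:
        by_sample_a.setdefault(c.sample, []).append(c)
    for c in callsets[callers[1]]:
        by_sample_b.setdefault(c.sample, []).append(c)
    for t in truth:
        consensus = merge_callsets(
            by_sample_a.get(t.sample, []), by_sample_b.get(t.sample, []), config
        )
        if any(c.start == t.start and c.end == t.end for c in consensus):
            recovered += 1
    p = 0.95**2
    lo, hi = stats.binom.ppf([0.005, 0.995], len(truth), p)
    assert lo <= recovered <= hi
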