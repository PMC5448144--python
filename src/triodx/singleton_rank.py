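"""Parent-blind ranking experiment: how findable are P/LP variants without trios?

Parental genotypes are stripped from trio records, tiered filter scenarios
are applied to the proband-only variant list, the survivors are ranked by
deleteriousness (CADD-scaled) score, and the rank of each designated P/LP
variant is reported. Cumulative rank curves summarize, per scenario, the
fraction of designated variants recoverable among a curator's top-k
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotations import AnnotationTable, PROTEIN_ALTERING
from .pedcore import AnalysisUnit
from .variants import VariantCall, carries_alt

FILTERED_OUT = "filtered_out"


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class FilterScenario:
    """One parent-blind filtering scenario.

    ``baseline`` marks the trio-informed de novo list — the only scenario
    allowed to consult parental genotypes; all others operate on the
    stripped, proband-only records.
    """

    name: str
    max_af: float = 1.0
    coding_only: bool = False
    panel_restriction: frozenset[str] = frozenset()  # subset of panel flags
    baseline: bool = False

    _KNOWN_PANELS = frozenset({"OMIM_disease", "DDID_known"})

    def __post_init__(self) -> None:
        unknown = self.panel_restriction - self._KNOWN_PANELS
        if unknown:
            raise ScenarioError(f"unknown panel(s) {sorted(unknown)} in scenario {self.name!r}")


DEFAULT_SCENARIOS = (
    FilterScenario("de_novo_baseline", baseline=True),
    FilterScenario("rare", max_af=0.001),
    FilterScenario("rare_coding", max_af=0.001, coding_only=True),
    FilterScenario(
        "rare_coding_panel",
        max_af=0.001,
        coding_only=True,
        panel_restriction=frozenset({"OMIM_disease", "DDID_known"}),
    ),
)


@dataclass(frozen=True)
class RankResult:
    proband_id: str
    designated_key: str
    scenario: str
    rank: int | None  # None == filtered out
    list_size: int

    @property
    def rank_label(self) -> str:
        return FILTERED_OUT if self.rank is None else str(self.rank)


def strip_parents(
    variants: list[VariantCall], unit: AnalysisUnit
) -> list[VariantCall]:
    """Proband-only copies of trio records: the site list is unchanged but
    parental genotype, depth and allele-depth fields are absent, so
    transmission and de novo status are no longer computable downstream."""
    pid = unit.proband.sample_id
    out = []
    for v in variants:
        out.append(
            VariantCall(
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                genotypes={pid: v.genotypes[pid]} if pid in v.genotypes else {},
                depth={pid: v.depth.get(pid, 0)},
                alt_depth={pid: v.alt_depth.get(pid, 0)},
                qual=v.qual,
            )
        )
    return out


def _passes(scenario: FilterScenario, rec, annotations_has: bool) -> bool:
    if rec.af > scenario.max_af:
        return False
    if scenario.coding_only and rec.consequence not in PROTEIN_ALTERING:
        return False
    if scenario.panel_restriction and not (rec.flags & scenario.panel_restriction):
        return False
    return True


def scenario_list(
    proband_records: list[VariantCall],
    annotations: AnnotationTable,
    scenario: FilterScenario,
    proband_id: str,
) -> list[VariantCall]:
    """Scenario-filtered carrier list, sorted by descending score with
    genomic-coordinate tie-breaking."""
    kept = []
    for v in proband_records:
        gt = v.genotypes.get(proband_id)
        if gt is None or not carries_alt(gt):
            continue
        rec = annotations.get(v.key_str)
        if _passes(scenario, rec, annotations.has(v.key_str)):
            kept.append(v)
    kept.sort(
        key=lambda v: (
            -annotations.get(v.key_str).score,
            v.chrom,
            v.pos,
            v.ref,
            v.alt,
        )
    )
    return kept


def scenario_filter_and_rank(
    proband_records: list[VariantCall],
    annotations: AnnotationTable,
    scenario: FilterScenario,
    designated: dict[str, list[str]],
) -> list[RankResult]:
    """Rank designated P/LP variants inside one scenario's filtered lists.

    ``designated`` maps proband id to that proband's designated variant
    keys (known P/LP from the trio analysis or the simulator's truth
    ledger). Ranks are 1-based positions in the score-sorted filtered list;
    a designated variant failing the scenario's filters reports
    ``filtered_out``.
    """
    results = []
    for proband_id in sorted(designated):
        ranked = scenario_list(proband_records, annotations, scenario, proband_id)
        order = {v.key_str: i + 1 for i, v in enumerate(ranked)}
        for key in designated[proband_id]:
            results.append(
                RankResult(
                    proband_id=proband_id,
                    designated_key=key,
                    scenario=scenario.name,
                    rank=order.get(key),
                    list_size=len(ranked),
                )
            )
    return results


def baseline_de_novo_rank(
    de_novo_keys: dict[str, list[str]],
    annotations: AnnotationTable,
    designated: dict[str, list[str]],
    scenario_name: str = "de_novo_baseline",
) -> list[RankResult]:
    """Trio-informed reference scenario: rank designated variants among each
    proband's de novo event list (the one list allowed to use parents)."""
    results = []
    for proband_id in sorted(designated):
        keys = sorted(
            de_novo_keys.get(proband_id, []),
            key=lambda k: (-annotations.get(k).score, k),
        )
        order = {k: i + 1 for i, k in enumerate(keys)}
        for key in designated[proband_id]:
            results.append(
                RankResult(
                    proband_id=proband_id,
                    designated_key=key,
                    scenario=scenario_name,
                    rank=order.get(key),
                    list_size=len(keys),
                )
            )
    return results


def rank_curve(results: list[RankResult], k_values: list[int]) -> pd.DataFrame:
    """Cumulative fraction of designated variants at rank <= k per scenario.

    Filtered-out variants stay in the denominator so fractions are
    comparable across scenarios. Raises on an empty result set.
    """
    if not results:
        raise ValueError("empty rank-result set: fractions undefined")
    if sorted(k_values) != list(k_values):
        raise ValueError("k values must be sorted ascending")
    rows = []
    by_scenario: dict[str, list[RankResult]] = {}
    for r in results:
        by_scenario.setdefault(r.scenario, []).append(r)
    for scenario in sorted(by_scenario):
        rs = by_scenario[scenario]
        for k in k_values:
            n_hit = sum(1 for r in rs if r.rank is not None and r.rank <= k)
            rows.append(
                {
                    "scenario": scenario,
                    "k": k,
                    "fraction": n_hit / len(rs),
                    "n": len(rs),
                }
            )
    return pd.DataFrame(rows, columns=["scenario", "k", "fraction", "n"])


def results_frame(results: list[RankResult]) -> pd.DataFrame:
    rows = [
        {
            "proband": r.proband_id,
            "key": r.designated_key,
            "scenario": r.scenario,
            "rank": r.rank_label,
            "list_size": r.list_size,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["proband", "key", "scenario", "rank", "list_size"])


def plot_rank_curves(curve: pd.DataFrame, path: str) -> None:
    """Rank-vs-cumulative-fraction plot, one line per scenario (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for scenario, sub in curve.groupby("scenario"):
        ax.plot(sub["k"], sub["fraction"], marker="o", label=scenario)
    ax.set_xlabel("rank threshold k")
    ax.set_ylabel("fraction of P/LP variants at rank <= k")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
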