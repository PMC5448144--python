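"""Cohort-level diagnostic-yield reporting and exact contingency tests.

One row per affected proband (the *results table*) powers every report:
yield by family structure, family-history class, phenotype flag and assay,
with percentages rounded half-up to the printed precision, plus two-sided
Fisher exact comparisons between strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import math

import pandas as pd
from scipy import stats


SIMPLEX = "simplex"
INTERMEDIATE = "intermediate"
MULTIPLEX = "multiplex"
UNKNOWN = "unknown"

RESULTS_COLUMNS = [
    "proband",
    "family",
    "structure",
    "assay",
    "history",
    "snv_finding",  # P | LP | VUS | negative
    "cnv_finding",
    "best_finding",
]

_FINDING_ORDER = {"negative": 0, "VUS": 1, "LP": 2, "P": 3}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (3.25 -> 3.3 at one digit), as used when
    reproducing printed table percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def finding_label(tier: str | None) -> str:
    if tier == "pathogenic":
        return "P"
    if tier == "likely_pathogenic":
        return "LP"
    if tier == "VUS":
        return "VUS"
    return "negative"


def best_finding(snv: str, cnv: str) -> str:
    return max((snv, cnv), key=lambda f: _FINDING_ORDER[f])


def history_classify(
    relative_records: pd.DataFrame | None, n_affected_probands: int = 1
) -> str:
    """Family-history class from reported-relative records of one family.

    Simplex: a single affected proband and no affected relatives of degree
    one to three. Multiplex: any affected first-degree relative (an affected
    sibling proband counts). Intermediate: affected relatives at degree two
    or three only. Unknown: no records at all.
    """
    if relative_records is None or len(relative_records) == 0:
        if n_affected_probands > 1:
            return MULTIPLEX
        return UNKNOWN
    degrees = relative_records["degree"].astype(int)
    if ((degrees < 1) | (degrees > 3)).any():
        bad = sorted(set(degrees[(degrees < 1) | (degrees > 3)]))
        raise ValueError(f"relative degree(s) {bad} outside {{1, 2, 3}}")
    affected = relative_records[relative_records["affected"].astype(bool)]
    if n_affected_probands > 1 or (affected["degree"].astype(int) == 1).any():
        return MULTIPLEX
    if len(affected) > 0:
        return INTERMEDIATE
    return SIMPLEX


def yield_table(
    results: pd.DataFrame,
    key: str,
    returnable: tuple[str, ...] = ("P", "LP"),
    ndigits: int = 1,
) -> pd.DataFrame:
    """Per-group P/LP counts and half-up-rounded percentages.

    Groups with an empty denominator report percentage NA. The grouping key
    must be a results-table column.
    """
    if key not in results.columns:
        raise KeyError(f"{key!r} is not a results-table column")
    rows = []
    for group, sub in results.groupby(key, dropna=False, sort=True):
        denom = len(sub)
        num = int(sub["best_finding"].isin(returnable).sum())
        pct = round_half_up(100.0 * num / denom, ndigits) if denom else math.nan
        rows.append(
            {"group": group, "numerator": num, "denominator": denom, "percent": pct}
        )
    return pd.DataFrame(rows, columns=["group", "numerator", "denominator", "percent"])


@dataclass(frozen=True)
class ContingencyTable2x2:
    """yes/no outcome counts for groups A and B."""

    a_yes: int
    a_no: int
    b_yes: int
    b_no: int

    def __post_init__(self) -> None:
        for v in (self.a_yes, self.a_no, self.b_yes, self.b_no):
            if v < 0:
                raise ValueError("contingency counts must be non-negative")


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value: the sum of hypergeometric
    probabilities of tables (at fixed margins) no more probable than the
    observed one. Raises on a zero margin (undefined test)."""
    row1 = table.a_yes + table.a_no
    row2 = table.b_yes + table.b_no
    col1 = table.a_yes + table.b_yes
    col2 = table.a_no + table.b_no
    if 0 in (row1, row2, col1, col2):
        raise ValueError("zero margin: Fisher exact test undefined")
    _, p = stats.fisher_exact(
        [[table.a_yes, table.a_no], [table.b_yes, table.b_no]], alternative="two-sided"
    )
    return float(p)


def history_contingency(
    results: pd.DataFrame, group_a: str, group_b: str
) -> ContingencyTable2x2:
    """P/LP-vs-not counts for two history classes (unknowns excluded)."""
    def counts(cls: str) -> tuple[int, int]:
        sub = results[results["history"] == cls]
        yes = int(sub["best_finding"].isin(("P", "LP")).sum())
        return yes, len(sub) - yes

    a_yes, a_no = counts(group_a)
    b_yes, b_no = counts(group_b)
    return ContingencyTable2x2(a_yes, a_no, b_yes, b_no)


def build_results_table(
    proband_meta: pd.DataFrame,
    snv_tiers: dict[str, str | None],
    cnv_tiers: dict[str, str | None] | None = None,
) -> pd.DataFrame:
    """Assemble the per-proband results table.

    ``proband_meta`` needs columns proband, family, structure, assay,
    history; ``snv_tiers``/``cnv_tiers`` map proband id to the most
    pathogenic returned tier (or None). The best finding is the maximum
    tier across a proband's returned variants.
    """
    cnv_tiers = cnv_tiers or {}
    rows = []
    for meta in proband_meta.itertuples(index=False):
        snv = finding_label(snv_tiers.get(meta.proband))
        cnv = finding_label(cnv_tiers.get(meta.proband))
        rows.append(
            {
                "proband": meta.proband,
                "family": meta.family,
                "structure": meta.structure,
                "assay": meta.assay,
                "history": meta.history,
                "snv_finding": snv,
                "cnv_finding": cnv,
                "best_finding": best_finding(snv, cnv),
            }
        )
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS)


def best_tier_label(tiers: list[str]) -> str:
    labels = [finding_label(t) for t in tiers]
    return max(labels, key=lambda f: _FINDING_ORDER[f]) if labels else "negative"


def load_published_table1() -> pd.DataFrame:
    """Transcribed printed per-stratum P/LP counts (clinical annotation,
    demographics, prior testing and family structure)."""
    import importlib.resources

    ref = importlib.resources.files("triodx.data").joinpath("table1_published.tsv")
    with ref.open() as handle:
        return pd.read_csv(handle, sep="\t")


def load_published_table2() -> pd.DataFrame:
    """Transcribed printed per-assay result counts by variant class and tier."""
    import importlib.resources

    ref = importlib.resources.files("triodx.data").joinpath("table2_published.tsv")
    with ref.open() as handle:
        return pd.read_csv(handle, sep="\t")


def verify_printed_rates(frame: pd.DataFrame, ndigits: int = 1) -> pd.DataFrame:
    """Recompute each printed percentage from its numerator/denominator.

    Adds ``computed_percent`` (half-up rounded) and ``consistent`` columns.
    A handful of printed percentages in the source table are not
    reproducible from their own printed counts under any single rounding
    rule; those rows come back flagged rather than silently accepted.
    """
    out = frame.copy()
    out["computed_percent"] = [
        round_half_up(100.0 * n / d, ndigits)
        for n, d in zip(out["numerator"], out["denominator"])
    ]
    # printed precision varies (e.g. '25' vs '25.0'); compare numerically
    out["consistent"] = [
        abs(float(p) - c) < 10 ** -ndigits / 2 + 1e-9
        for p, c in zip(out["printed_percent"], out["computed_percent"])
    ]
    return out


def format_rate_table(table: pd.DataFrame) -> str:
    """Aligned-text rendering of a yield table (printed-report layout)."""
    lines = [f"{'group':<16}{'n_PLP':>8}{'n':>8}{'percent':>10}"]
    for row in table.itertuples(index=False):
        pct = "NA" if isinstance(row.percent, float) and math.isnan(row.percent) else f"{row.percent:.1f}"
        lines.append(f"{str(row.group):<16}{row.numerator:>8}{row.denominator:>8}{pct:>10}")
    return "\n".join(lines)
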