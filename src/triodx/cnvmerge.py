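"""CNV consensus calling across two callers, filtering and curation flags.

Per-sample callsets from two read-depth callers are merged by reciprocal
overlap (calls of the same type whose mutual overlap fractions both reach the
threshold, default 0.90). Consensus calls are then removed when mostly inside
segmental duplications or when recurrently carried by unaffected parents, and
retained calls are flagged for manual curation when near known disease genes
or intersecting exons.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

DEL = "DEL"
DUP = "DUP"


@dataclass(frozen=True)
class CnvCall:
    """One caller-attributed structural interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    type: str  # DEL or DUP
    caller: str = ""
    sample: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"degenerate interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnvMergeConfig:
    reciprocity: float = 0.90
    max_segdup_fraction: float = 0.50
    max_parent_carriers: int = 5
    proximity_window: int = 5_000
    carrier_reciprocity: float = 0.50  # 'observed in a parent' criterion

    def __post_init__(self) -> None:
        for f in (self.reciprocity, self.max_segdup_fraction, self.carrier_reciprocity):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.proximity_window < 0:
            raise ValueError("proximity window must be >= 0")


@dataclass
class ConsensusCall:
    contig: str
    start: int
    end: int
    type: str
    sample: str
    source_a: CnvCall
    source_b: CnvCall
    reciprocity: float
    retained: bool = True
    removal_reason: str = ""
    curation_flags: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def reciprocal_overlap(a: CnvCall, b: CnvCall) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 across contigs or types."""
    if a.contig != b.contig or a.type != b.type:
        return 0.0
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return 0.0
    return min(overlap / a.length, overlap / b.length)


def merge_callsets(
    calls_a: list[CnvCall],
    calls_b: list[CnvCall],
    config: CnvMergeConfig = CnvMergeConfig(),
) -> list[ConsensusCall]:
    """Greedy 1:1 reciprocal-overlap consensus between two callsets.

    All cross-caller same-type pairs meeting the reciprocity threshold are
    ranked by descending reciprocity (ties: leftmost pair start, then
    coordinates); each input call joins at most one consensus record, whose
    coordinates are the intersection of the pair. Symmetric in caller order.
    """
    pairs = []
    for i, a in enumerate(calls_a):
        for j, b in enumerate(calls_b):
            ro = reciprocal_overlap(a, b)
            if ro >= config.reciprocity:
                lo, hi = sorted(
                    [(a.start, a.end, a.contig), (b.start, b.end, b.contig)]
                )
                pairs.append((-ro, lo, hi, i, j, a, b, ro))
    pairs.sort(key=lambda t: t[:5])
    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[ConsensusCall] = []
    for _, _, _, i, j, a, b, ro in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append(
            ConsensusCall(
                contig=a.contig,
                start=max(a.start, b.start),
                end=min(a.end, b.end),
                type=a.type,
                sample=a.sample or b.sample,
                source_a=a,
                source_b=b,
                reciprocity=ro,
            )
        )
    out.sort(key=lambda c: (c.contig, c.start, c.end, c.type))
    return out


def _interval_tree(intervals: list[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for contig, start, end in intervals:
        trees.setdefault(contig, IntervalTree()).addi(start, end)
    return trees


def covered_fraction(
    contig: str, start: int, end: int, trees: dict[str, IntervalTree]
) -> float:
    """Fraction of [start, end) covered by the (possibly overlapping) track."""
    tree = trees.get(contig)
    if tree is None:
        return 0.0
    hits = sorted(
        (max(iv.begin, start), min(iv.end, end)) for iv in tree.overlap(start, end)
    )
    covered = 0
    cursor = start
    for lo, hi in hits:
        lo = max(lo, cursor)
        if hi > lo:
            covered += hi - lo
            cursor = hi
    return covered / (end - start)


@dataclass
class GeneModel:
    gene: str
    contig: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)


def filter_and_flag(
    consensus: list[ConsensusCall],
    segdups: list[tuple[str, int, int]],
    parent_calls: list[CnvCall],
    gene_models: list[GeneModel],
    panel_genes: set[str],
    config: CnvMergeConfig = CnvMergeConfig(),
) -> list[ConsensusCall]:
    """Apply segdup and parental-frequency filters; set curation flags.

    A call is removed when its segdup-covered fraction reaches
    ``max_segdup_fraction`` or when more than ``max_parent_carriers``
    distinct unaffected parents carry an overlapping same-type call
    (reciprocal overlap >= ``carrier_reciprocity``). Retained calls are
    flagged for curation when within ``proximity_window`` of a panel
    (DD/ID- or OMIM-associated) gene or intersecting at least one exon of
    any gene. ``parent_calls`` must contain unaffected-parent calls only.
    """
    segdup_trees = _interval_tree(segdups)
    flagged: list[ConsensusCall] = []
    for call in consensus:
        call.curation_flags = []
        call.retained = True
        call.removal_reason = ""

        frac = covered_fraction(call.contig, call.start, call.end, segdup_trees)
        if frac >= config.max_segdup_fraction:
            call.retained = False
            call.removal_reason = f"segdup_fraction={frac:.2f}"
            flagged.append(call)
            continue

        as_cnv = CnvCall(call.contig, call.start, call.end, call.type, sample=call.sample)
        carriers = {
            pc.sample
            for pc in parent_calls
            if reciprocal_overlap(as_cnv, pc) >= config.carrier_reciprocity
        }
        if len(carriers) > config.max_parent_carriers:
            call.retained = False
            call.removal_reason = f"parent_carriers={len(carriers)}"
            flagged.append(call)
            continue

        for gm in gene_models:
            if gm.contig != call.contig:
                continue
            near = (
                call.start < gm.end + config.proximity_window
                and gm.start - config.proximity_window < call.end
            )
            if near and gm.gene in panel_genes:
                call.curation_flags.append(f"near_panel_gene:{gm.gene}")
            for ex_start, ex_end in gm.exons:
                if call.start < ex_end and ex_start < call.end:
                    call.curation_flags.append(f"exonic:{gm.gene}")
                    break
        flagged.append(call)
    return flagged


def read_bed_calls(path: str | os.PathLike) -> list[CnvCall]:
    """BED3+ with columns contig, start, end, type, caller, sample."""
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            names=["contig", "start", "end", "type", "caller", "sample"],
            dtype={"contig": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return []
    return [
        CnvCall(r.contig, int(r.start), int(r.end), str(r.type), str(r.caller), str(r.sample))
        for r in frame.itertuples(index=False)
    ]


def write_bed_calls(calls: list[CnvCall], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for c in calls:
            handle.write(
                f"{c.contig}\t{c.start}\t{c.end}\t{c.type}\t{c.caller}\t{c.sample}\n"
            )


def consensus_frame(consensus: list[ConsensusCall]) -> pd.DataFrame:
    rows = [
        {
            "contig": c.contig,
            "start": c.start,
            "end": c.end,
            "type": c.type,
            "sample": c.sample,
            "reciprocity": round(c.reciprocity, 4),
            "retained": c.retained,
            "removal_reason": c.removal_reason,
            "curation_flags": ",".join(c.curation_flags),
        }
        for c in consensus
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "start", "end", "type", "sample",
            "reciprocity", "retained", "removal_reason", "curation_flags",
        ],
    )
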