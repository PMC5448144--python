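"""Variant annotation tables and gene-disease knowledge.

Annotations are *inputs* to the pipeline (population allele frequency,
consequence class, CADD-scaled deleteriousness, gene-panel membership,
ClinVar-style assertions); this module only loads, indexes and joins them.
The gene-disease table records, per gene, the strength of its disease
association and its established mechanism, which the classifier consumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

# consequence classes, ordered roughly by decreasing severity
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
CANONICAL_SPLICE = "canonical_splice"
MISSENSE = "missense"
INFRAME = "inframe"
NEAR_SPLICE = "near_splice"
SYNONYMOUS = "synonymous"
NONCODING = "noncoding"

CONSEQUENCES = (
    NONSENSE,
    FRAMESHIFT,
    CANONICAL_SPLICE,
    MISSENSE,
    INFRAME,
    NEAR_SPLICE,
    SYNONYMOUS,
    NONCODING,
)

TRUNCATING = frozenset({NONSENSE, FRAMESHIFT, CANONICAL_SPLICE})
PROTEIN_ALTERING = frozenset({MISSENSE, NONSENSE, FRAMESHIFT, CANONICAL_SPLICE})

PANEL_FLAGS = ("OMIM_disease", "DDID_known", "ACMG56", "carrier_panel", "recessive_OMIM")

ASSERTIONS = (
    "pathogenic",
    "likely_pathogenic",
    "uncertain",
    "likely_benign",
    "benign",
    "none",
)

_SEVERITY = {c: i for i, c in enumerate(CONSEQUENCES)}


def most_severe(consequences: list[str]) -> str:
    return min(consequences, key=lambda c: _SEVERITY.get(c, len(_SEVERITY)))


@dataclass(frozen=True)
class AnnotationRecord:
    """Annotation for one (contig, pos, ref, alt) key."""

    key: str
    af: float
    consequence: str
    gene: str
    score: float
    flags: frozenset[str] = frozenset()
    assertion: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.af <= 1.0:
            raise ValueError(f"allele frequency {self.af} outside [0, 1]")


_MISSING = AnnotationRecord(
    key="", af=0.0, consequence=NONCODING, gene="", score=0.0
)


@dataclass
class AnnotationTable:
    """Keyed lookup of annotation records with a missing-record default.

    Variants without a row are treated as unannotated: AF 0, no gene, no
    assertion. Downstream filters keep such variants with a trail flag so a
    later knowledge snapshot can rescue them.
    """

    records: dict[str, AnnotationRecord] = field(default_factory=dict)

    def get(self, key: str) -> AnnotationRecord:
        return self.records.get(key, _MISSING)

    def has(self, key: str) -> bool:
        return key in self.records

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AnnotationTable":
        records = {}
        for row in frame.itertuples(index=False):
            key = f"{row.chrom}:{row.pos}:{row.ref}:{row.alt}"
            flags = frozenset(
                f for f in str(getattr(row, "flags", "")).split(",") if f and f != "nan"
            )
            records[key] = AnnotationRecord(
                key=key,
                af=float(row.af),
                consequence=str(row.consequence),
                gene=str(row.gene),
                score=float(row.score),
                flags=flags,
                assertion=str(getattr(row, "assertion", "none")),
            )
        return cls(records)

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "AnnotationTable":
        frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        return cls.from_frame(frame)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.records):
            rec = self.records[key]
            chrom, pos, ref, alt = key.split(":")
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos),
                    "ref": ref,
                    "alt": alt,
                    "af": rec.af,
                    "consequence": rec.consequence,
                    "gene": rec.gene,
                    "score": rec.score,
                    "flags": ",".join(sorted(rec.flags)),
                    "assertion": rec.assertion,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "pos", "ref", "alt", "af", "consequence",
                "gene", "score", "flags", "assertion",
            ],
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GeneDiseaseEntry:
    gene: str
    association: str  # established | single_report | none
    mechanism: str  # lof | gof_missense | any
    source: str = ""  # publication | gene_matching | '' (provenance of entry)


@dataclass
class GeneDiseaseTable:
    entries: dict[str, GeneDiseaseEntry] = field(default_factory=dict)

    def get(self, gene: str) -> GeneDiseaseEntry:
        return self.entries.get(gene, GeneDiseaseEntry(gene, "none", "any"))

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "GeneDiseaseTable":
        frame = pd.read_csv(path, sep="\t")
        entries = {
            str(r.gene): GeneDiseaseEntry(
                str(r.gene),
                str(r.association),
                str(r.mechanism),
                "" if pd.isna(getattr(r, "source", "")) else str(getattr(r, "source", "")),
            )
            for r in frame.itertuples(index=False)
        }
        return cls(entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": e.gene,
                "association": e.association,
                "mechanism": e.mechanism,
                "source": e.source,
            }
            for e in sorted(self.entries.values(), key=lambda e: e.gene)
        ]
        return pd.DataFrame(rows, columns=["gene", "association", "mechanism", "source"])

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def updated(self, changes: dict[str, GeneDiseaseEntry]) -> "GeneDiseaseTable":
        merged = dict(self.entries)
        merged.update(changes)
        return GeneDiseaseTable(merged)
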