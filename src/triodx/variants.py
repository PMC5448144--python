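"""Biallelic variant records and VCF input/output.

The pipeline's in-memory unit is :class:`VariantCall`: one biallelic site
with per-sample genotype state and read-depth evidence. Genotype states are
symbolic (``hom_ref``/``het``/``hom_alt``/``hemi_ref``/``hemi_alt``/
``missing``); hemizygous states are used for male samples on the X
chromosome, which is modelled as a single non-pseudoautosomal contig.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from cyvcf2 import VCF

X_CONTIG = "X"

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
HEMI_REF = "hemi_ref"
HEMI_ALT = "hemi_alt"
MISSING = "missing"

GENOTYPE_STATES = (HOM_REF, HET, HOM_ALT, HEMI_REF, HEMI_ALT, MISSING)

#: diploid/haploid alt-allele dosage per state (missing -> -1)
_DOSAGE = {HOM_REF: 0, HET: 1, HOM_ALT: 2, HEMI_REF: 0, HEMI_ALT: 1, MISSING: -1}

#: expected alt-read fraction used when simulating allele depths
_VAF = {HOM_REF: 0.0, HET: 0.5, HOM_ALT: 1.0, HEMI_REF: 0.0, HEMI_ALT: 1.0}


def carries_alt(state: str) -> bool:
    return state in (HET, HOM_ALT, HEMI_ALT)


def dosage(state: str) -> int:
    return _DOSAGE[state]


def expected_vaf(state: str) -> float:
    return _VAF[state]


@dataclass
class VariantCall:
    """One biallelic site with per-sample genotype and depth evidence."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, str] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)
    alt_depth: dict[str, int] = field(default_factory=dict)
    qual: float = 100.0

    def __post_init__(self) -> None:
        for sample, ad in self.alt_depth.items():
            dp = self.depth.get(sample, 0)
            if ad > dp:
                raise ValueError(
                    f"alt depth {ad} exceeds total depth {dp} for {sample} "
                    f"at {self.chrom}:{self.pos}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def carriers(self) -> list[str]:
        return [s for s, g in self.genotypes.items() if carries_alt(g)]


def parse_key(key: str) -> tuple[str, int, str, str]:
    chrom, pos, ref, alt = key.split(":")
    return (chrom, int(pos), ref, alt)


def _gt_string(state: str) -> str:
    return {
        HOM_REF: "0/0",
        HET: "0/1",
        HOM_ALT: "1/1",
        HEMI_REF: "0",
        HEMI_ALT: "1",
        MISSING: "./.",
    }[state]


def write_vcf(
    path: str | os.PathLike,
    samples: list[str],
    calls: Iterable[VariantCall],
    contigs: dict[str, int] | None = None,
) -> None:
    """Write a minimal multi-sample VCF 4.2 with GT:DP:AD fields.

    Male X genotypes are emitted haploid (``0``/``1``); everything else is
    unphased diploid. Records are written in (contig, position) order as
    provided by the caller.
    """
    if contigs is None:
        contigs = {"1": 249_000_000, X_CONTIG: 156_000_000}
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    for call in calls:
        fields = [
            call.chrom,
            str(call.pos),
            ".",
            call.ref,
            call.alt,
            f"{call.qual:g}",
            "PASS",
            ".",
            "GT:DP:AD",
        ]
        for sample in samples:
            gt = call.genotypes.get(sample, MISSING)
            dp = call.depth.get(sample, 0)
            ad = call.alt_depth.get(sample, 0)
            fields.append(f"{_gt_string(gt)}:{dp}:{dp - ad},{ad}")
        lines.append("\t".join(fields))
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def _state_from_alleles(alleles: list[int], chrom: str) -> str:
    if any(a < 0 for a in alleles):
        return MISSING
    if len(alleles) == 1:
        if chrom != X_CONTIG:
            raise ValueError("haploid genotype outside the X contig")
        return HEMI_ALT if alleles[0] == 1 else HEMI_REF
    total = sum(alleles)
    return (HOM_REF, HET, HOM_ALT)[total]


def read_vcf(path: str | os.PathLike) -> tuple[list[str], list[VariantCall]]:
    """Read a multi-sample VCF into :class:`VariantCall` records.

    Sites must be biallelic (multiallelics are expected to be decomposed
    upstream); haploid genotypes are accepted on the X contig only.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[VariantCall] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {variant.CHROM}:{variant.POS}; "
                "decompose before analysis"
            )
        gts = {}
        for sample, alleles in zip(samples, variant.genotypes):
            gts[sample] = _state_from_alleles(list(alleles[:-1]), variant.CHROM)
        dp_arr = variant.format("DP")
        ad_arr = variant.format("AD")
        depth = {}
        alt_depth = {}
        for i, sample in enumerate(samples):
            dp = int(dp_arr[i][0]) if dp_arr is not None else 0
            depth[sample] = max(dp, 0)
            if ad_arr is not None:
                ad = int(ad_arr[i][-1])
                alt_depth[sample] = max(ad, 0)
            else:
                alt_depth[sample] = 0
        calls.append(
            VariantCall(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=variant.ALT[0],
                genotypes=gts,
                depth=depth,
                alt_depth=alt_depth,
                qual=variant.QUAL if variant.QUAL is not None else 0.0,
            )
        )
    vcf.close()
    return samples, calls


def dosage_matrix(
    calls: list[VariantCall], samples: list[str], autosomal_only: bool = True
) -> np.ndarray:
    """Samples x sites matrix of alt dosages (-1 = missing)."""
    use = [c for c in calls if not (autosomal_only and c.chrom == X_CONTIG)]
    mat = np.full((len(samples), len(use)), -1, dtype=np.int8)
    for j, call in enumerate(use):
        for i, sample in enumerate(samples):
            mat[i, j] = dosage(call.genotypes.get(sample, MISSING))
    return mat
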