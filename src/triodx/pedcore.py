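"""Pedigree model, kinship-based relationship checks and Mendelian QC.

Families are read from 6-column PED files. Each affected proband anchors one
*analysis unit* whose structure is ``trio`` (both parents sequenced), ``duo``
(one parent) or ``singleton`` (neither). Claimed parent-offspring links are
verified with a within-family KING-robust kinship estimate, and per-trio
Mendelian-violation fractions provide a genotype-level sanity check.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_CODE = {"1": MALE, "2": FEMALE, "0": UNKNOWN}

TRIO = "trio"
DUO = "duo"
SINGLETON = "singleton"

#: conventional first-degree (parent-offspring) kinship acceptance window
PO_KINSHIP_RANGE = (0.177, 0.354)


class PedigreeError(ValueError):
    pass


@dataclass
class Sample:
    sample_id: str
    family_id: str
    sex: str = UNKNOWN
    affected: bool = False
    mother_id: str | None = None
    father_id: str | None = None


@dataclass
class Family:
    family_id: str
    samples: dict[str, Sample] = field(default_factory=dict)

    def probands(self) -> list[Sample]:
        return [s for s in self.samples.values() if s.affected]


@dataclass
class AnalysisUnit:
    """One affected proband plus whichever parents were sequenced."""

    family_id: str
    proband: Sample
    mother: Sample | None = None
    father: Sample | None = None

    @property
    def structure(self) -> str:
        n = (self.mother is not None) + (self.father is not None)
        return (SINGLETON, DUO, TRIO)[n]

    @property
    def samples(self) -> list[str]:
        ids = [self.proband.sample_id]
        if self.mother is not None:
            ids.append(self.mother.sample_id)
        if self.father is not None:
            ids.append(self.father.sample_id)
        return ids


@dataclass
class Pedigree:
    families: dict[str, Family] = field(default_factory=dict)

    def sample(self, sample_id: str) -> Sample:
        for fam in self.families.values():
            if sample_id in fam.samples:
                return fam.samples[sample_id]
        raise KeyError(sample_id)

    def analysis_units(self) -> list[AnalysisUnit]:
        units = []
        for fam in sorted(self.families.values(), key=lambda f: f.family_id):
            for proband in sorted(fam.probands(), key=lambda s: s.sample_id):
                mother = fam.samples.get(proband.mother_id) if proband.mother_id else None
                father = fam.samples.get(proband.father_id) if proband.father_id else None
                units.append(AnalysisUnit(fam.family_id, proband, mother, father))
        return units

    def structure_counts(self) -> dict[str, int]:
        counts = {TRIO: 0, DUO: 0, SINGLETON: 0}
        for unit in self.analysis_units():
            counts[unit.structure] += 1
        return counts

    def unaffected_parents(self) -> list[Sample]:
        out = []
        for fam in self.families.values():
            parent_ids = set()
            for s in fam.samples.values():
                if s.mother_id:
                    parent_ids.add(s.mother_id)
                if s.father_id:
                    parent_ids.add(s.father_id)
            for pid in sorted(parent_ids):
                parent = fam.samples.get(pid)
                if parent is not None and not parent.affected:
                    out.append(parent)
        return out


def load_pedigree(source: str | os.PathLike | io.TextIOBase) -> Pedigree:
    """Parse a 6-column PED file (family, id, father, mother, sex, affected).

    Raises :class:`PedigreeError` on duplicate sample ids or parent ids that
    do not resolve to a sample in the same family.
    """
    if isinstance(source, (str, os.PathLike)):
        handle = open(source)
        close = True
    else:
        handle, close = source, False
    pedigree = Pedigree()
    seen: set[str] = set()
    try:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise PedigreeError(f"line {lineno}: expected 6 columns, got {len(parts)}")
            fam_id, sid, father, mother, sex, aff = parts[:6]
            if sid in seen:
                raise PedigreeError(f"duplicate sample id {sid!r}")
            seen.add(sid)
            fam = pedigree.families.setdefault(fam_id, Family(fam_id))
            fam.samples[sid] = Sample(
                sample_id=sid,
                family_id=fam_id,
                sex=_SEX_CODE.get(sex, UNKNOWN),
                affected=aff == "2",
                mother_id=None if mother == "0" else mother,
                father_id=None if father == "0" else father,
            )
    finally:
        if close:
            handle.close()
    for fam in pedigree.families.values():
        for sample in fam.samples.values():
            for pid in (sample.mother_id, sample.father_id):
                if pid is not None and pid not in fam.samples:
                    raise PedigreeError(
                        f"parent id {pid!r} of sample {sample.sample_id!r} "
                        f"not present in family {fam.family_id!r}"
                    )
    return pedigree


def write_pedigree(pedigree: Pedigree, path: str | os.PathLike) -> None:
    sex_code = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}
    lines = []
    for fam in sorted(pedigree.families.values(), key=lambda f: f.family_id):
        for s in sorted(fam.samples.values(), key=lambda x: x.sample_id):
            lines.append(
                "\t".join(
                    [
                        fam.family_id,
                        s.sample_id,
                        s.father_id or "0",
                        s.mother_id or "0",
                        sex_code[s.sex],
                        "2" if s.affected else "1",
                    ]
                )
            )
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


@dataclass(frozen=True)
class KinshipEstimate:
    sample_i: str
    sample_j: str
    kinship: float  # NaN when no informative sites
    n_informative: int


def estimate_kinship(
    genotypes_i: np.ndarray,
    genotypes_j: np.ndarray,
    sample_i: str = "i",
    sample_j: str = "j",
) -> KinshipEstimate:
    """Within-family KING-robust kinship from autosomal dosage vectors.

    phi = (N_het_both - 2 * N_opposite_hom) / (N_het_i + N_het_j), computed
    over sites genotyped in both samples. Robust to allele-frequency
    misspecification; 0.5 for identical genomes, ~0.25 for parent-offspring,
    ~0 for unrelated pairs. Returns NaN when the denominator is zero.
    """
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors differ in length")
    mask = (gi >= 0) & (gj >= 0)
    gi, gj = gi[mask], gj[mask]
    n_het_i = int(np.sum(gi == 1))
    n_het_j = int(np.sum(gj == 1))
    n_het_both = int(np.sum((gi == 1) & (gj == 1)))
    n_opp = int(np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
    denom = n_het_i + n_het_j
    phi = math.nan if denom == 0 else (n_het_both - 2 * n_opp) / denom
    return KinshipEstimate(sample_i, sample_j, phi, int(mask.sum()))


def mendelian_violation_fraction(
    child: np.ndarray, mother: np.ndarray, father: np.ndarray
) -> float:
    """Fraction of jointly genotyped autosomal sites violating transmission."""
    c = np.asarray(child)
    m = np.asarray(mother)
    f = np.asarray(father)
    mask = (c >= 0) & (m >= 0) & (f >= 0)
    c, m, f = c[mask], m[mask], f[mask]
    if c.size == 0:
        return math.nan
    # possible child dosages given parents: child allele from each parent
    viol = np.zeros(c.size, dtype=bool)
    viol |= (c == 2) & ((m == 0) | (f == 0))
    viol |= (c == 0) & ((m == 2) | (f == 2))
    viol |= (c == 1) & (((m == 0) & (f == 0)) | ((m == 2) & (f == 2)))
    return float(viol.mean())


def verify_relationships(
    pedigree: Pedigree,
    genotypes: dict[str, np.ndarray],
    po_range: tuple[float, float] = PO_KINSHIP_RANGE,
) -> pd.DataFrame:
    """QC report over all claimed parent-offspring pairs.

    One row per checked pair with the kinship estimate, a ``flagged`` column
    (kinship outside ``po_range``), and the trio Mendelian-violation fraction
    where both parents are available. Report-only: nothing is excluded.
    """
    rows = []
    for unit in pedigree.analysis_units():
        child_g = genotypes.get(unit.proband.sample_id)
        mendel = math.nan
        if unit.structure == TRIO:
            mg = genotypes.get(unit.mother.sample_id)
            fg = genotypes.get(unit.father.sample_id)
            if child_g is not None and mg is not None and fg is not None:
                mendel = mendelian_violation_fraction(child_g, mg, fg)
        for role, parent in (("mother", unit.mother), ("father", unit.father)):
            if parent is None:
                continue
            pg = genotypes.get(parent.sample_id)
            if child_g is None or pg is None:
                continue
            est = estimate_kinship(
                child_g, pg, unit.proband.sample_id, parent.sample_id
            )
            flagged = not (
                not math.isnan(est.kinship)
                and po_range[0] <= est.kinship <= po_range[1]
            )
            rows.append(
                {
                    "family": unit.family_id,
                    "proband": unit.proband.sample_id,
                    "parent": parent.sample_id,
                    "role": role,
                    "kinship": est.kinship,
                    "n_informative": est.n_informative,
                    "flagged": flagged,
                    "mendel_violation_fraction": mendel,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "family",
            "proband",
            "parent",
            "role",
            "kinship",
            "n_informative",
            "flagged",
            "mendel_violation_fraction",
        ],
    )
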