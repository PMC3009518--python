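"""Pedigree, marker-map and haplotype-frequency data model with file I/O.

File dialects follow LINKAGE/PLINK conventions: a pre-makeped PED file with
six leading columns (family, individual, father, mother, sex, phenotype)
followed by two allele columns per SNP; a four-column MAP file (chromosome,
name, genetic position in cM, physical position in bp); and a two-column TSV
of haplotype allele strings with population frequencies.  All readers skip
blank lines and lines starting with ``#``.

Binary phenotypes are coded 1/0 for affected/normal; the missing-phenotype
sentinel is -9.  Allele 0 denotes a missing genotype call (accepted by the
reader, rejected by the phaser).  Marker indices are 0-based in memory and
1-based in files and reports.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

PHENO_MISSING = -9.0


class Sex(enum.Enum):
    MALE = 1
    FEMALE = 2
    UNKNOWN = 0

    @classmethod
    def from_code(cls, code: str) -> "Sex":
        try:
            return cls(int(code))
        except ValueError:
            return cls.UNKNOWN


class PedFormatError(ValueError):
    """Malformed PED/MAP/frequency file (ragged columns, bad tokens...)."""


class PedStructureError(ValueError):
    """Pedigree violates a structural invariant (unknown parent, loop...)."""


@dataclass
class Individual:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    phenotype: float
    genotype: list[tuple[int, int]]

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def phenotype_missing(self) -> bool:
        return self.phenotype == PHENO_MISSING or math.isnan(self.phenotype)


@dataclass
class Pedigree:
    family_id: str
    members: list[Individual] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    def member(self, individual_id: str) -> Individual:
        for m in self.members:
            if m.individual_id == individual_id:
                return m
        raise KeyError(individual_id)

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def n_markers(self) -> int:
        return len(self.members[0].genotype) if self.members else 0

    def validate(self) -> None:
        """Check structural invariants; raise PedStructureError on failure."""
        if not self.members:
            raise PedStructureError(f"family {self.family_id}: empty pedigree")
        ids = [m.individual_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedStructureError(f"family {self.family_id}: duplicate individual id")
        idset = set(ids)
        nmark = self.n_markers
        for m in self.members:
            if (m.father_id is None) != (m.mother_id is None):
                raise PedStructureError(
                    f"family {self.family_id}, individual {m.individual_id}: "
                    "exactly one parent named (need both or neither)"
                )
            for which, pid in (("father", m.father_id), ("mother", m.mother_id)):
                if pid is not None and pid not in idset:
                    raise PedStructureError(
                        f"family {self.family_id}, individual {m.individual_id}: "
                        f"unknown {which} id {pid!r}"
                    )
            if len(m.genotype) != nmark:
                raise PedStructureError(
                    f"family {self.family_id}, individual {m.individual_id}: "
                    f"genotype length {len(m.genotype)} != marker count {nmark}"
                )
        self._check_acyclic()
        self._check_no_marriage_loops()

    def _check_acyclic(self) -> None:
        # DFS over parent links; a back edge means an ancestry cycle.
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            state[iid] = 1
            m = self.member(iid)
            for pid in (m.father_id, m.mother_id):
                if pid is None:
                    continue
                s = state.get(pid, 0)
                if s == 1:
                    raise PedStructureError(
                        f"family {self.family_id}: ancestry cycle through {pid}"
                    )
                if s == 0:
                    visit(pid)
            state[iid] = 2

        for m in self.members:
            if state.get(m.individual_id, 0) == 0:
                visit(m.individual_id)

    def _check_no_marriage_loops(self) -> None:
        # The marriage graph joins spouses and parent-child pairs; any cycle in
        # the undirected version (beyond the trivial two-parents-one-child
        # triangles) marks a loop pedigree, which the phaser does not support.
        # Standard check: the undirected graph with one node per individual and
        # one node per union, edges union-spouse and union-child, must be a forest.
        unions: dict[tuple[str, str], list[str]] = {}
        for m in self.members:
            if m.father_id is not None:
                unions.setdefault((m.father_id, m.mother_id), []).append(m.individual_id)
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent.setdefault(x, x) != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a: str, b: str) -> bool:
            ra, rb = find(a), find(b)
            if ra == rb:
                return False
            parent[ra] = rb
            return True

        for (fa, mo), kids in unions.items():
            unode = f"U::{fa}::{mo}"
            for endpoint in (fa, mo, *kids):
                if not union(unode, endpoint):
                    raise PedStructureError(
                        f"family {self.family_id}: marriage loop involving "
                        f"couple ({fa}, {mo})"
                    )

    def topological_members(self) -> list[Individual]:
        """Members ordered parents-before-children."""
        out: list[Individual] = []
        seen: set[str] = set()

        def visit(m: Individual) -> None:
            if m.individual_id in seen:
                return
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(self.member(pid))
            seen.add(m.individual_id)
            out.append(m)

        for m in self.members:
            visit(m)
        return out


@dataclass
class Marker:
    name: str
    chromosome: str
    genetic_pos_cm: float
    physical_pos_bp: int


@dataclass
class MarkerMap:
    markers: list[Marker]

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, i: int) -> Marker:
        return self.markers[i]

    def validate(self) -> None:
        by_chrom: dict[str, float] = {}
        for mk in self.markers:
            prev = by_chrom.get(mk.chromosome)
            if prev is not None and mk.genetic_pos_cm < prev:
                raise PedFormatError(
                    f"marker {mk.name}: genetic position decreases on "
                    f"chromosome {mk.chromosome}"
                )
            by_chrom[mk.chromosome] = mk.genetic_pos_cm

    def drop(self, index: int) -> "MarkerMap":
        return MarkerMap([mk for i, mk in enumerate(self.markers) if i != index])


@dataclass
class HaplotypeFrequencyTable:
    haplotypes: list[str]  # allele strings, e.g. "1121..."
    frequencies: list[float]

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("haplotypes and frequencies differ in length")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("duplicate haplotype strings")
        lengths = {len(h) for h in self.haplotypes}
        if len(lengths) > 1:
            raise ValueError("haplotype strings have differing lengths")
        if any(f < 0 or f > 1 for f in self.frequencies):
            raise ValueError("frequencies must lie in [0, 1]")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError(
                f"frequencies sum to {sum(self.frequencies):.9f}, not 1"
            )

    @property
    def n_markers(self) -> int:
        return len(self.haplotypes[0]) if self.haplotypes else 0

    def allele_frequencies(self, marker: int) -> dict[int, float]:
        out: dict[int, float] = {}
        for h, f in zip(self.haplotypes, self.frequencies):
            a = int(h[marker])
            out[a] = out.get(a, 0.0) + f
        return out

    def minor_allele(self, marker: int) -> tuple[int, float]:
        """(minor allele, its frequency) at a marker; ties -> larger allele code."""
        freqs = self.allele_frequencies(marker)
        allele = min(freqs, key=lambda a: (freqs[a], -a))
        return allele, freqs[allele]


# ---------------------------------------------------------------------------
# readers / writers


def _data_lines(path: str) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def read_ped(path: str) -> list[Pedigree]:
    """Read a pre-makeped LINKAGE PED file into pedigrees grouped by family.

    Member order within each family is preserved.  Structural invariants
    (known parents, acyclic ancestry, no marriage loops, rectangular
    genotypes) are checked on every family.
    """
    fams: dict[str, Pedigree] = {}
    ncols: int | None = None
    for lineno, tok in _data_lines(path):
        if len(tok) < 6 or (len(tok) - 6) % 2 != 0:
            raise PedFormatError(f"{path}:{lineno}: expected 6+2k columns, got {len(tok)}")
        if ncols is None:
            ncols = len(tok)
        elif len(tok) != ncols:
            raise PedFormatError(
                f"{path}:{lineno}: ragged genotype columns ({len(tok)} vs {ncols})"
            )
        fam, iid, fid, mid, sex, pheno = tok[:6]
        try:
            geno = [
                (int(tok[i]), int(tok[i + 1])) for i in range(6, len(tok), 2)
            ]
            pheno_val = float(pheno)
        except ValueError as exc:
            raise PedFormatError(f"{path}:{lineno}: bad numeric token ({exc})") from None
        if any(a < 0 or b < 0 for a, b in geno):
            raise PedFormatError(f"{path}:{lineno}: negative allele code")
        ind = Individual(
            family_id=fam,
            individual_id=iid,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=Sex.from_code(sex),
            phenotype=pheno_val,
            genotype=geno,
        )
        fams.setdefault(fam, Pedigree(family_id=fam)).members.append(ind)
    peds = list(fams.values())
    for ped in peds:
        ped.validate()
    return peds


def write_ped(pedigrees: Sequence[Pedigree], path: str) -> None:
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                cols = [
                    m.family_id,
                    m.individual_id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    str(m.sex.value),
                    format_phenotype(m.phenotype),
                ]
                for a, b in m.genotype:
                    cols += [str(a), str(b)]
                fh.write(" ".join(cols) + "\n")


def format_phenotype(y: float) -> str:
    return str(int(y)) if float(y).is_integer() else repr(y)


def read_map(path: str) -> MarkerMap:
    markers = []
    for lineno, tok in _data_lines(path):
        if len(tok) != 4:
            raise PedFormatError(f"{path}:{lineno}: expected 4 columns, got {len(tok)}")
        chrom, name, cm, bp = tok
        try:
            markers.append(Marker(name, chrom, float(cm), int(bp)))
        except ValueError as exc:
            raise PedFormatError(f"{path}:{lineno}: bad numeric token ({exc})") from None
    mm = MarkerMap(markers)
    mm.validate()
    return mm


def write_map(marker_map: MarkerMap, path: str) -> None:
    with open(path, "w") as fh:
        for mk in marker_map.markers:
            fh.write(f"{mk.chromosome} {mk.name} {mk.genetic_pos_cm:g} {mk.physical_pos_bp}\n")


def read_frequency_table(path: str, renormalize: bool = False) -> HaplotypeFrequencyTable:
    """Read a haplotype-frequency TSV (allele string, frequency).

    The frequencies must sum to 1 within 1e-6 unless ``renormalize`` is set,
    in which case they are rescaled to sum exactly to 1.
    """
    haps: list[str] = []
    freqs: list[float] = []
    for lineno, tok in _data_lines(path):
        if len(tok) != 2:
            raise PedFormatError(f"{path}:{lineno}: expected 2 columns, got {len(tok)}")
        h, f = tok
        try:
            freqs.append(float(f))
        except ValueError:
            raise PedFormatError(f"{path}:{lineno}: bad frequency {f!r}") from None
        haps.append(h)
    total = sum(freqs)
    if abs(total - 1.0) > 1e-6:
        if not renormalize:
            raise ValueError(
                f"{path}: frequencies sum to {total:.6f}; pass renormalize=True "
                "(--renormalize) to rescale"
            )
        freqs = [f / total for f in freqs]
    else:
        # remove sub-1e-6 drift so the table invariant (1e-9) holds
        freqs = [f / total for f in freqs]
    return HaplotypeFrequencyTable(haps, freqs)


def write_frequency_table(table: HaplotypeFrequencyTable, path: str) -> None:
    with open(path, "w") as fh:
        for h, f in zip(table.haplotypes, table.frequencies):
            fh.write(f"{h}\t{f:.10g}\n")


# ---------------------------------------------------------------------------
# Mendelian consistency


@dataclass
class MendelViolation:
    family_id: str
    individual_id: str
    marker: int  # 0-based
    child_genotype: tuple[int, int]
    father_genotype: tuple[int, int]
    mother_genotype: tuple[int, int]


def validate_mendelian(pedigree: Pedigree) -> list[MendelViolation]:
    """List every (child, marker) whose unordered genotype is incompatible with
    drawing one allele from each parent.  Violations are data, not errors."""
    out: list[MendelViolation] = []
    for m in pedigree.members:
        if m.is_founder:
            continue
        fa = pedigree.member(m.father_id)
        mo = pedigree.member(m.mother_id)
        for l, (ca, cb) in enumerate(m.genotype):
            fg, mg = fa.genotype[l], mo.genotype[l]
            if 0 in (ca, cb) or 0 in fg or 0 in mg:
                continue  # missing call: not checkable
            ok = any(
                {a, b} == {ca, cb} or (a == ca and b == cb) or (a == cb and b == ca)
                for a in fg
                for b in mg
            )
            if not ok:
                out.append(
                    MendelViolation(
                        pedigree.family_id, m.individual_id, l, (ca, cb), fg, mg
                    )
                )
    return out
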