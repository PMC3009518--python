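"""Zero-recombination haplotype inference on complete, loop-free pedigrees.

Under the zero-recombination assumption each child inherits one *entire*
haplotype from each parent, so a single binary inheritance variable (h) per
parent-child edge determines descent at every locus, and one binary phase
variable (p) per undetermined heterozygous founder locus determines the
founder haplotypes.  Genotype constraints then become an affine linear
system over GF(2) in the h and p variables.  The solver collects those
constraints in one pass over the pedigree, row-reduces them, and returns the
full solution space as a particular solution plus free variables (alpha);
every alpha assignment is a valid haplotype configuration and distinct
assignments give distinct configurations.

Canonicalization removes the two trivial symmetries so that solution counts
are well defined: within each founder the first heterozygous locus puts the
smaller allele on the designated-first haplotype, and the h variable of an
edge whose parent is homozygous at every locus (both parental haplotypes
identical, so descent is unobservable) is pinned to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .ped_model import Individual, Pedigree, validate_mendelian

Haplotype = tuple[int, ...]
FounderLabel = tuple[str, int]  # (founder individual_id, which-of-two)


class PhaseError(ValueError):
    """Input cannot be phased (missing alleles, Mendelian violation...)."""


class PhaseConflictError(PhaseError):
    """The zero-recombination constraint system is inconsistent."""


def hap_str(h: Haplotype) -> str:
    """Render a haplotype; single-character join when all alleles are <= 9."""
    if all(a <= 9 for a in h):
        return "".join(str(a) for a in h)
    return ",".join(str(a) for a in h)


@dataclass(frozen=True)
class InheritanceAssignment:
    """Concrete 0/1 value of every parent-child inheritance variable."""

    h: dict[tuple[str, str], int]  # (parent_id, child_id) -> 0/1

    def __post_init__(self) -> None:
        bad = [v for v in self.h.values() if v not in (0, 1)]
        if bad:
            raise ValueError("h variables must be 0/1")


@dataclass
class HaplotypeConfiguration:
    """One fully resolved zero-recombination configuration for a family.

    ``haplotypes[iid]`` is the ordered (paternal, maternal) pair of allele
    tuples; ``origins[iid]`` labels the founder haplotype each one descends
    from.  For a founder the labels are its own (id, 0) and (id, 1).
    """

    family_id: str
    haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    origins: dict[str, tuple[FounderLabel, FounderLabel]]
    inheritance: InheritanceAssignment

    def key(self) -> tuple:
        """Canonical hashable identity (member order independent)."""
        return tuple(
            (iid, self.haplotypes[iid], self.origins[iid])
            for iid in sorted(self.haplotypes)
        )


# ---------------------------------------------------------------------------
# affine GF(2) expressions: value = parity(mask & assignment) ^ const

Expr = tuple[int, int]  # (variable bitmask, constant bit)

ZERO: Expr = (0, 0)
ONE: Expr = (0, 1)


def _xor(a: Expr, b: Expr) -> Expr:
    return (a[0] ^ b[0], a[1] ^ b[1])


def _eval(e: Expr, assignment: int) -> int:
    return (bin(e[0] & assignment).count("1") & 1) ^ e[1]


# An allele slot is either a constant allele value or a biallelic symbol
# (low_allele, high_allele, Expr): allele = low if expr evaluates to 0.
Slot = int | tuple[int, int, Expr]


def _slot_select(slot_a: Slot, slot_b: Slot, h: Expr) -> Slot:
    """Allele transmitted by a parent whose two slots at a locus are given,
    choosing slot_a when h = 0.  Parents are processed before children, so the
    two slots are either equal constants or complementary symbols."""
    if isinstance(slot_a, int):
        if isinstance(slot_b, int):
            if slot_a == slot_b:
                return slot_a
            lo, hi = sorted((slot_a, slot_b))
            bit = ZERO if slot_a == lo else ONE
            return (lo, hi, _xor(bit, h))
        raise AssertionError("mixed constant/symbol parent slots")
    lo, hi, e = slot_a
    return (lo, hi, _xor(e, h))


class _LinearSystem:
    """Incremental GF(2) row reduction with back-substitution."""

    def __init__(self) -> None:
        self.n_vars = 0
        self.pivots: dict[int, tuple[int, int]] = {}  # pivot var -> (mask, rhs)

    def new_var(self) -> Expr:
        v = self.n_vars
        self.n_vars += 1
        return (1 << v, 0)

    def require(self, e: Expr, value: int) -> None:
        """Add the constraint e == value; raise PhaseConflictError if it
        contradicts the rows collected so far."""
        mask, rhs = e[0], e[1] ^ value
        while mask:
            pv = mask & -mask  # lowest set bit
            piv = self.pivots.get(pv)
            if piv is None:
                self.pivots[pv] = (mask, rhs)
                return
            mask ^= piv[0]
            rhs ^= piv[1]
        if rhs:
            raise PhaseConflictError("inconsistent zero-recombination constraints")

    def solve(self) -> tuple[list[int], dict[int, Expr]]:
        """Return (free variable indices, map var index -> Expr over free vars).

        The expressions use a *compact* bitmask whose bit positions index the
        free-variable list, so alpha assignments are integers in
        [0, 2^dof).
        """
        # full RREF: eliminate pivot vars from every other pivot row
        rows = dict(self.pivots)
        for pv in sorted(rows, reverse=True):
            mask, rhs = rows[pv]
            m = mask ^ pv
            while m:
                q = m & -m
                if q in rows and q != pv:
                    qm, qr = rows[q]
                    mask ^= qm
                    rhs ^= qr
                m &= m - 1
            rows[pv] = (mask, rhs)
        pivot_vars = set(rows)
        free = [i for i in range(self.n_vars) if (1 << i) not in pivot_vars]
        free_pos = {1 << v: i for i, v in enumerate(free)}
        out: dict[int, Expr] = {}
        for i in range(self.n_vars):
            bit = 1 << i
            if bit in rows:
                mask, rhs = rows[bit]
                cmask = 0
                m = mask ^ bit
                while m:
                    q = m & -m
                    cmask |= 1 << free_pos[q]
                    m &= m - 1
                out[i] = (cmask, rhs)
            else:
                out[i] = (1 << free_pos[bit], 0)
        return free, out


@dataclass
class PhaseSolutionSpace:
    """All zero-recombination configurations of one family, parameterized by
    free binary variables alpha; ``materialize(alpha)`` yields the
    configuration for one assignment."""

    pedigree: Pedigree
    degrees_of_freedom: int
    # per individual, per hap (0/1), per locus: constant or (lo, hi, Expr with
    # compact free-variable mask)
    _slots: dict[str, tuple[list[Slot], list[Slot]]] = field(repr=False)
    _h_exprs: dict[tuple[str, str], Expr] = field(repr=False)

    @property
    def n_configurations(self) -> int:
        return 1 << self.degrees_of_freedom

    def materialize(self, alpha: int) -> HaplotypeConfiguration:
        if not 0 <= alpha < self.n_configurations:
            raise ValueError(f"alpha out of range [0, {self.n_configurations})")
        ped = self.pedigree
        h_vals = {
            edge: _eval(e, alpha) for edge, e in self._h_exprs.items()
        }
        haplotypes: dict[str, tuple[Haplotype, Haplotype]] = {}
        origins: dict[str, tuple[FounderLabel, FounderLabel]] = {}
        for m in ped.topological_members():
            iid = m.individual_id
            if m.is_founder:
                pair = tuple(
                    tuple(
                        s if isinstance(s, int) else (s[0] if _eval(s[2], alpha) == 0 else s[1])
                        for s in self._slots[iid][w]
                    )
                    for w in (0, 1)
                )
                haplotypes[iid] = pair  # type: ignore[assignment]
                origins[iid] = ((iid, 0), (iid, 1))
            else:
                hf = h_vals[(m.father_id, iid)]
                hm = h_vals[(m.mother_id, iid)]
                haplotypes[iid] = (
                    haplotypes[m.father_id][hf],
                    haplotypes[m.mother_id][hm],
                )
                origins[iid] = (
                    origins[m.father_id][hf],
                    origins[m.mother_id][hm],
                )
        return HaplotypeConfiguration(
            family_id=ped.family_id,
            haplotypes=haplotypes,
            origins=origins,
            inheritance=InheritanceAssignment(h_vals),
        )

    def __iter__(self) -> Iterator[HaplotypeConfiguration]:
        for alpha in range(self.n_configurations):
            yield self.materialize(alpha)


def _check_input(ped: Pedigree) -> None:
    ped.validate()  # raises PedStructureError on loops / bad structure
    for m in ped.members:
        for l, (a, b) in enumerate(m.genotype):
            if a == 0 or b == 0:
                raise PhaseError(
                    f"family {ped.family_id}, individual {m.individual_id}, "
                    f"SNP {l + 1}: missing allele (phaser requires complete data)"
                )
    viol = validate_mendelian(ped)
    if viol:
        v = viol[0]
        raise PhaseError(
            f"family {v.family_id}: Mendelian violation at SNP {v.marker + 1} "
            f"in individual {v.individual_id} "
            f"(child {v.child_genotype}, father {v.father_genotype}, "
            f"mother {v.mother_genotype})"
        )


def solve(pedigree: Pedigree) -> PhaseSolutionSpace:
    """Build and solve the zero-recombination constraint system of one family.

    Raises PhaseError for missing alleles or Mendelian violations,
    PedStructureError for loop pedigrees, and PhaseConflictError when the
    genotypes admit no zero-recombinant configuration.
    """
    _check_input(pedigree)
    sys_ = _LinearSystem()
    n_mark = pedigree.n_markers
    members = pedigree.topological_members()

    fully_hom = {
        m.individual_id: all(a == b for a, b in m.genotype) for m in members
    }

    slots: dict[str, tuple[list[Slot], list[Slot]]] = {}
    h_exprs: dict[tuple[str, str], Expr] = {}

    for m in members:
        iid = m.individual_id
        if m.is_founder:
            hap0: list[Slot] = []
            hap1: list[Slot] = []
            seen_het = False
            for a, b in m.genotype:
                if a == b:
                    hap0.append(a)
                    hap1.append(a)
                else:
                    lo, hi = sorted((a, b))
                    if not seen_het:
                        # canonical fix: smaller allele on the first haplotype
                        seen_het = True
                        hap0.append((lo, hi, ZERO))
                        hap1.append((lo, hi, ONE))
                    else:
                        p = sys_.new_var()
                        hap0.append((lo, hi, p))
                        hap1.append((lo, hi, _xor(p, ONE)))
            slots[iid] = (hap0, hap1)
            continue

        # child: one h variable per parent edge, pinned to 0 when the parent
        # carries two identical haplotypes (descent unobservable)
        hf = ZERO if fully_hom[m.father_id] else sys_.new_var()
        hm = ZERO if fully_hom[m.mother_id] else sys_.new_var()
        h_exprs[(m.father_id, iid)] = hf
        h_exprs[(m.mother_id, iid)] = hm

        pat: list[Slot] = []
        mat: list[Slot] = []
        for l in range(n_mark):
            fslot = _slot_select(slots[m.father_id][0][l], slots[m.father_id][1][l], hf)
            mslot = _slot_select(slots[m.mother_id][0][l], slots[m.mother_id][1][l], hm)
            g1, g2 = sorted(m.genotype[l])
            if g1 == g2:
                for slot in (fslot, mslot):
                    _require_slot(sys_, slot, g1, pedigree, m, l)
                pat.append(g1)
                mat.append(g1)
            else:
                f_can = {g for g in (g1, g2) if _slot_can_be(fslot, g)}
                m_can = {g for g in (g1, g2) if _slot_can_be(mslot, g)}
                branches = [
                    (pa, ma)
                    for pa, ma in ((g1, g2), (g2, g1))
                    if pa in f_can and ma in m_can
                ]
                if not branches:
                    raise PhaseConflictError(
                        f"family {pedigree.family_id}, individual {iid}, "
                        f"SNP {l + 1}: no zero-recombinant transmission"
                    )
                if len(branches) == 1:
                    pa, ma = branches[0]
                    _require_slot(sys_, fslot, pa, pedigree, m, l)
                    _require_slot(sys_, mslot, ma, pedigree, m, l)
                    pat.append(pa)
                    mat.append(ma)
                else:
                    # both orders possible: both parents heterozygous g1/g2
                    assert not isinstance(fslot, int) and not isinstance(mslot, int)
                    ef, em = fslot[2], mslot[2]
                    sys_.require(_xor(ef, em), 1)  # transmitted alleles differ
                    pat.append((g1, g2, ef))
                    mat.append((g1, g2, _xor(ef, ONE)))
        slots[iid] = (pat, mat)

    free, var_map = sys_.solve()

    def compact(e: Expr) -> Expr:
        mask, const = e
        cmask = 0
        m_ = mask
        while m_:
            q = m_ & -m_
            v = q.bit_length() - 1
            vm, vc = var_map[v]
            cmask ^= vm
            const ^= vc
            m_ &= m_ - 1
        return (cmask, const)

    def compact_slot(s: Slot) -> Slot:
        if isinstance(s, int):
            return s
        lo, hi, e = s
        ce = compact(e)
        if ce[0] == 0:  # fully determined by the constraints
            return lo if ce[1] == 0 else hi
        return (lo, hi, ce)

    cslots = {
        iid: (
            [compact_slot(s) for s in pair[0]],
            [compact_slot(s) for s in pair[1]],
        )
        for iid, pair in slots.items()
    }
    ch = {edge: compact(e) for edge, e in h_exprs.items()}
    return PhaseSolutionSpace(
        pedigree=pedigree,
        degrees_of_freedom=len(free),
        _slots=cslots,
        _h_exprs=ch,
    )


def _slot_can_be(slot: Slot, allele: int) -> bool:
    if isinstance(slot, int):
        return slot == allele
    return allele in (slot[0], slot[1])


def _require_slot(
    sys_: _LinearSystem, slot: Slot, allele: int, ped: Pedigree, m: Individual, l: int
) -> None:
    if isinstance(slot, int):
        if slot != allele:
            raise PhaseConflictError(
                f"family {ped.family_id}, individual {m.individual_id}, "
                f"SNP {l + 1}: no zero-recombinant transmission"
            )
        return
    lo, hi, e = slot
    if allele == lo:
        sys_.require(e, 0)
    elif allele == hi:
        sys_.require(e, 1)
    else:
        raise PhaseConflictError(
            f"family {ped.family_id}, individual {m.individual_id}, "
            f"SNP {l + 1}: no zero-recombinant transmission"
        )


DEFAULT_ENUMERATE_LIMIT = 1 << 20


def enumerate_configs(
    pedigree: Pedigree, limit: int = DEFAULT_ENUMERATE_LIMIT
) -> list[HaplotypeConfiguration]:
    """All canonical zero-recombination configurations of a family.

    Returns [] when the genotypes admit no zero-recombinant solution.
    Refuses to materialize more than ``limit`` configurations.
    """
    try:
        space = solve(pedigree)
    except PhaseConflictError:
        return []
    if space.n_configurations > limit:
        raise PhaseError(
            f"family {pedigree.family_id}: {space.n_configurations} "
            f"configurations exceed enumeration limit {limit}"
        )
    return list(space)


def pick_config(space: PhaseSolutionSpace, seed) -> HaplotypeConfiguration:
    """Uniform random draw over the solution space (reproducible by seed).

    ``seed`` may be an int or a numpy Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dof = space.degrees_of_freedom
    alpha = 0
    # draw 32 bits at a time so dof > 64 stays exact
    for start in range(0, dof, 32):
        width = min(32, dof - start)
        alpha |= int(rng.integers(0, 1 << width)) << start
    return space.materialize(alpha)


def founder_haplotypes(
    config: HaplotypeConfiguration,
) -> list[tuple[FounderLabel, Haplotype]]:
    """The two haplotypes of every founder, labeled; descent order preserved."""
    out: list[tuple[FounderLabel, Haplotype]] = []
    for iid, labels in config.origins.items():
        if labels[0] == (iid, 0):  # founders carry their own labels
            out.append(((iid, 0), config.haplotypes[iid][0]))
            out.append(((iid, 1), config.haplotypes[iid][1]))
    return out


def canonicalize(
    ped: Pedigree, config: HaplotypeConfiguration
) -> HaplotypeConfiguration:
    """Rewrite an arbitrary valid configuration (e.g. simulator ground truth)
    into canonical form: founder pairs ordered smaller-allele-first at their
    first heterozygous locus, and h pinned to 0 under fully homozygous
    parents.  The genotypes it implies are unchanged."""
    flip: dict[str, int] = {}
    fully_hom = {
        m.individual_id: all(a == b for a, b in m.genotype) for m in ped.members
    }
    founder_pairs: dict[str, tuple[Haplotype, Haplotype]] = {}
    for m in ped.members:
        if not m.is_founder:
            continue
        iid = m.individual_id
        h0, h1 = config.haplotypes[iid]
        f = 0
        for a, b in zip(h0, h1):
            if a != b:
                f = 1 if a > b else 0
                break
        flip[iid] = f
        founder_pairs[iid] = (h1, h0) if f else (h0, h1)

    h_vals: dict[tuple[str, str], int] = {}
    haplotypes: dict[str, tuple[Haplotype, Haplotype]] = {}
    origins: dict[str, tuple[FounderLabel, FounderLabel]] = {}
    for m in ped.topological_members():
        iid = m.individual_id
        if m.is_founder:
            haplotypes[iid] = founder_pairs[iid]
            origins[iid] = ((iid, 0), (iid, 1))
            continue
        new_h = {}
        for pid in (m.father_id, m.mother_id):
            h = config.inheritance.h[(pid, iid)]
            if fully_hom[pid]:
                h = 0
            elif pid in flip:
                h ^= flip[pid]
            new_h[pid] = h
            h_vals[(pid, iid)] = h
        haplotypes[iid] = (
            haplotypes[m.father_id][new_h[m.father_id]],
            haplotypes[m.mother_id][new_h[m.mother_id]],
        )
        origins[iid] = (
            origins[m.father_id][new_h[m.father_id]],
            origins[m.mother_id][new_h[m.mother_id]],
        )
    return HaplotypeConfiguration(
        family_id=config.family_id,
        haplotypes=haplotypes,
        origins=origins,
        inheritance=InheritanceAssignment(h_vals),
    )


def check_configuration(ped: Pedigree, config: HaplotypeConfiguration) -> None:
    """Assert genotype reconstruction, zero recombination and founder-label
    consistency; raises AssertionError on any failure (test/debug helper)."""
    for m in ped.members:
        iid = m.individual_id
        hp, hm_ = config.haplotypes[iid]
        for l, (a, b) in enumerate(m.genotype):
            assert {hp[l], hm_[l]} == {a, b} or (hp[l], hm_[l]) in ((a, b), (b, a))
        if not m.is_founder:
            fpair = config.haplotypes[m.father_id]
            mpair = config.haplotypes[m.mother_id]
            hf = config.inheritance.h[(m.father_id, iid)]
            hmv = config.inheritance.h[(m.mother_id, iid)]
            assert hp == fpair[hf], "paternal haplotype not copied whole"
            assert hm_ == mpair[hmv], "maternal haplotype not copied whole"
            assert config.origins[iid][0] == config.origins[m.father_id][hf]
            assert config.origins[iid][1] == config.origins[m.mother_id][hmv]
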