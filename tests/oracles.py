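"""Independent oracles used by the test suite.

These deliberately use naive exhaustive algorithms, kept free of the library
code paths they are checking.
"""

from __future__ import annotations

import itertools

import numpy as np

from fhapminer.ped_model import Individual, Pedigree, Sex


def brute_force_configs(ped: Pedigree) -> set:
    """All canonical zero-recombination configurations by exhaustive search
    over founder phase choices and per-edge inheritance choices.

    Canonical form matches the solver's: each founder's first heterozygous
    locus puts the smaller allele first, and the inheritance choice under a
    fully homozygous parent is pinned to 0.  Returns a set of configuration
    keys: tuples of (individual, (hapA, hapB), (originA, originB)).
    """
    members = ped.topological_members()
    fully_hom = {
        m.individual_id: all(a == b for a, b in m.genotype) for m in members
    }
    results: set = set()

    def founder_phases(m: Individual):
        het = [l for l, (a, b) in enumerate(m.genotype) if a != b]
        free = het[1:]
        for bits in itertools.product((0, 1), repeat=len(free)):
            h0, h1 = [], []
            for l, (a, b) in enumerate(m.genotype):
                if a == b:
                    h0.append(a)
                    h1.append(a)
                else:
                    lo, hi = sorted((a, b))
                    if l == het[0] or bits[free.index(l)] == 0:
                        h0.append(lo)
                        h1.append(hi)
                    else:
                        h0.append(hi)
                        h1.append(lo)
            yield (tuple(h0), tuple(h1))

    def rec(i: int, haps: dict, origins: dict) -> None:
        if i == len(members):
            results.add(
                tuple((iid, haps[iid], origins[iid]) for iid in sorted(haps))
            )
            return
        m = members[i]
        iid = m.individual_id
        if m.is_founder:
            for pair in founder_phases(m):
                haps[iid] = pair
                origins[iid] = ((iid, 0), (iid, 1))
                rec(i + 1, haps, origins)
            haps.pop(iid, None)
            origins.pop(iid, None)
        else:
            fopts = (0,) if fully_hom[m.father_id] else (0, 1)
            mopts = (0,) if fully_hom[m.mother_id] else (0, 1)
            for hf in fopts:
                for hm in mopts:
                    hp = haps[m.father_id][hf]
                    hq = haps[m.mother_id][hm]
                    if all(
                        (hp[l] == a and hq[l] == b) or (hp[l] == b and hq[l] == a)
                        for l, (a, b) in enumerate(m.genotype)
                    ):
                        haps[iid] = (hp, hq)
                        origins[iid] = (
                            origins[m.father_id][hf],
                            origins[m.mother_id][hm],
                        )
                        rec(i + 1, haps, origins)
            haps.pop(iid, None)
            origins.pop(iid, None)

    rec(0, {}, {})
    return results


def random_dropped_pedigree(rng: np.random.Generator, max_snps: int = 4) -> Pedigree:
    """Small random pedigree (<= 8 members) with gene-dropped genotypes from
    a random limited-diversity haplotype pool; always phase-consistent."""
    n_snps = int(rng.integers(1, max_snps + 1))
    n_haps = int(min(2**n_snps, rng.integers(2, 5)))
    pool: set = set()
    while len(pool) < n_haps:
        pool.add(tuple(int(a) for a in rng.integers(1, 3, size=n_snps)))
    pool_list = sorted(pool)

    members: list[Individual] = []

    def ind(iid: str, fa: str | None, mo: str | None) -> None:
        members.append(Individual("F", iid, fa, mo, Sex.UNKNOWN, 0.0, []))

    ind("a", None, None)
    ind("b", None, None)
    for i in range(int(rng.integers(1, 4))):
        ind(f"k{i}", "a", "b")
    if rng.random() < 0.5:  # add a third generation half the time
        ind("s", None, None)
        ind("g", "k0", "s")
    ped = Pedigree("F", members)

    haps: dict[str, tuple] = {}
    for m in ped.topological_members():
        if m.is_founder:
            haps[m.individual_id] = (
                pool_list[int(rng.integers(0, n_haps))],
                pool_list[int(rng.integers(0, n_haps))],
            )
        else:
            haps[m.individual_id] = (
                haps[m.father_id][int(rng.integers(0, 2))],
                haps[m.mother_id][int(rng.integers(0, 2))],
            )
        m.genotype = [(p, q) for p, q in zip(*haps[m.individual_id])]
    return ped


def allele_groups_at(haps: np.ndarray, focal: int, min_pts: int) -> set[frozenset[int]]:
    """Group-by-allele oracle for single-marker (window 1) clustering: the
    clusters must be exactly the focal-allele groups of size >= min_pts."""
    groups: dict[int, list[int]] = {}
    for i, allele in enumerate(haps[:, focal]):
        groups.setdefault(int(allele), []).append(i)
    return {frozenset(g) for g in groups.values() if len(g) >= min_pts}
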