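"""Pedigree disease-study simulator and penetrance analytics.

Simulation proceeds in three steps, mirroring family-based candidate-gene
study designs: (1) sample a CEPH-like pedigree skeleton (two or three
generations, 4-20 members, long-run mean size 13); (2) drop genes — each
founder receives two haplotypes drawn i.i.d. from a population haplotype
frequency table and every child inherits one whole parental haplotype per
parent by a fair coin (no recombination); (3) assign phenotypes from a
penetrance model, affected ~ Bernoulli(f_g) with g the count (0/1/2) of risk
alleles at a risk SNP or of risk haplotypes.  Families are kept only if at
least one member is affected, and in single-locus mode the risk SNP column
is removed before analysis so power reflects local LD rather than the typed
variant itself.

The closed-form penetrance analytics (population prevalence, genotype
distribution among the affected, genotype relative risks) assume
Hardy-Weinberg proportions at the risk locus.

All randomness flows from one root seed through named substreams
(structure / genedrop / phenotype / analysis) so experiments are exactly
reproducible and replicate-level parallelism cannot change results.
"""

from __future__ import annotations

import enum
import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ped_model import (
    PHENO_MISSING,
    HaplotypeFrequencyTable,
    Individual,
    Marker,
    MarkerMap,
    Pedigree,
    Sex,
)
from .zr_phase import FounderLabel, Haplotype, HaplotypeConfiguration, InheritanceAssignment


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Named child stream of a root seed; stable across runs and workers."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()), index))
    )


# ---------------------------------------------------------------------------
# penetrance analytics


class DiseaseMode(enum.Enum):
    SINGLE_LOCUS = "single-locus"
    RARE_HAPLOTYPE = "rare-hap"


@dataclass
class PenetranceModel:
    """Penetrance triple (f0, f1, f2) = P(affected | 0/1/2 risk copies)."""

    f0: float
    f1: float
    f2: float
    mode: DiseaseMode = DiseaseMode.SINGLE_LOCUS
    risk_snp: int | None = None  # 0-based, single-locus mode
    risk_allele: int | None = None  # default: minor allele of the table
    risk_haplotypes: frozenset[str] = frozenset()  # rare-haplotype mode

    def __post_init__(self) -> None:
        for f in (self.f0, self.f1, self.f2):
            if not 0.0 <= f <= 1.0:
                raise ValueError("penetrances must lie in [0, 1]")

    @property
    def triple(self) -> tuple[float, float, float]:
        return (self.f0, self.f1, self.f2)


#: The three penetrance sets used throughout the power studies.
PENETRANCE_SETS: dict[str, tuple[float, float, float]] = {
    "A": (0.05, 0.15, 0.25),
    "B": (0.01, 0.10, 0.15),
    "C": (0.05, 0.30, 0.50),
}


def _hwe(p_d: float) -> tuple[float, float, float]:
    return ((1 - p_d) ** 2, 2 * p_d * (1 - p_d), p_d**2)


def prevalence(model: PenetranceModel | Sequence[float], p_d: float) -> float:
    """Population prevalence K under HWE at risk-allele frequency p_d."""
    f0, f1, f2 = model.triple if isinstance(model, PenetranceModel) else tuple(model)
    g0, g1, g2 = _hwe(p_d)
    return g0 * f0 + g1 * f1 + g2 * f2


def genotype_given_affected(
    model: PenetranceModel | Sequence[float], p_d: float
) -> tuple[float, float, float]:
    """(Pr(dd|A), Pr(dD|A), Pr(DD|A)): Bayes inversion of HWE priors through
    the penetrances; the three components sum to 1."""
    f = model.triple if isinstance(model, PenetranceModel) else tuple(model)
    g = _hwe(p_d)
    k = sum(gi * fi for gi, fi in zip(g, f))
    if k == 0:
        raise ValueError("prevalence is 0: genotype-given-affected undefined")
    return tuple(gi * fi / k for gi, fi in zip(g, f))  # type: ignore[return-value]


def relative_risks(
    model: PenetranceModel | Sequence[float],
) -> tuple[float, float]:
    """Genotype relative risks (lambda1, lambda2) = (f1/f0, f2/f0); infinite
    when f0 = 0 and the numerator is positive."""
    f0, f1, f2 = model.triple if isinstance(model, PenetranceModel) else tuple(model)
    if f0 == 0:
        return (
            math.inf if f1 > 0 else float("nan"),
            math.inf if f2 > 0 else float("nan"),
        )
    return f1 / f0, f2 / f0


# ---------------------------------------------------------------------------
# pedigree structures


@dataclass
class StructureModel:
    """Parametric CEPH-like family structures.

    A three-generation family (probability ``p_three_gen``) is four
    grandparents, two parents (one child of each grandparental couple) and k
    grandchildren; a two-generation family is a couple with k children.
    Children counts follow negative binomials truncated so family sizes stay
    in [4, 20]; the defaults give a long-run mean size of about 13 with 80%
    three-generation families.
    """

    p_three_gen: float = 52 / 65
    # (negative-binomial n, p, truncation lo, hi) for the children count
    three_gen_children: tuple[float, float, int, int] = (8.0, 0.5, 1, 14)
    two_gen_children: tuple[float, float, int, int] = (7.0, 0.5, 2, 18)

    def sample_children(self, three_gen: bool, rng: np.random.Generator) -> int:
        n, p, lo, hi = self.three_gen_children if three_gen else self.two_gen_children
        while True:
            k = int(rng.negative_binomial(n, p))
            if lo <= k <= hi:
                return k


def sample_structure(
    model: StructureModel, rng: np.random.Generator | int, family_id: str = "F1"
) -> Pedigree:
    """Draw one pedigree skeleton (no genotypes, phenotypes all missing)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    three_gen = bool(rng.random() < model.p_three_gen)
    k = model.sample_children(three_gen, rng)
    members: list[Individual] = []

    def add(iid: str, father: str | None, mother: str | None, sex: Sex) -> None:
        members.append(
            Individual(
                family_id=family_id,
                individual_id=iid,
                father_id=father,
                mother_id=mother,
                sex=sex,
                phenotype=PHENO_MISSING,
                genotype=[],
            )
        )

    if three_gen:
        add("gf1", None, None, Sex.MALE)
        add("gm1", None, None, Sex.FEMALE)
        add("gf2", None, None, Sex.MALE)
        add("gm2", None, None, Sex.FEMALE)
        add("fa", "gf1", "gm1", Sex.MALE)
        add("mo", "gf2", "gm2", Sex.FEMALE)
    else:
        add("fa", None, None, Sex.MALE)
        add("mo", None, None, Sex.FEMALE)
    for i in range(1, k + 1):
        add(f"c{i}", "fa", "mo", Sex.MALE if rng.random() < 0.5 else Sex.FEMALE)
    ped = Pedigree(family_id=family_id, members=members)
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# gene dropping


def drop_genes(
    skeleton: Pedigree,
    freq_table: HaplotypeFrequencyTable,
    rng: np.random.Generator | int,
) -> tuple[Pedigree, HaplotypeConfiguration]:
    """Assign founder haplotypes i.i.d. from the table and drop them through
    the pedigree with fair-coin inheritance and no recombination.

    Returns the genotyped pedigree and the true configuration (ground truth
    for phasing and for haplotype-level disease models).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    haps = [tuple(int(a) for a in h) for h in freq_table.haplotypes]
    probs = np.asarray(freq_table.frequencies)
    haplotypes: dict[str, tuple[Haplotype, Haplotype]] = {}
    origins: dict[str, tuple[FounderLabel, FounderLabel]] = {}
    h_vals: dict[tuple[str, str], int] = {}
    for m in skeleton.topological_members():
        iid = m.individual_id
        if m.is_founder:
            i, j = rng.choice(len(haps), size=2, p=probs)
            haplotypes[iid] = (haps[int(i)], haps[int(j)])
            origins[iid] = ((iid, 0), (iid, 1))
        else:
            hf = int(rng.integers(0, 2))
            hm = int(rng.integers(0, 2))
            h_vals[(m.father_id, iid)] = hf
            h_vals[(m.mother_id, iid)] = hm
            haplotypes[iid] = (
                haplotypes[m.father_id][hf],
                haplotypes[m.mother_id][hm],
            )
            origins[iid] = (
                origins[m.father_id][hf],
                origins[m.mother_id][hm],
            )
    members = [
        Individual(
            family_id=m.family_id,
            individual_id=m.individual_id,
            father_id=m.father_id,
            mother_id=m.mother_id,
            sex=m.sex,
            phenotype=m.phenotype,
            genotype=[
                (pa, ma)
                for pa, ma in zip(*haplotypes[m.individual_id])
            ],
        )
        for m in skeleton.members
    ]
    ped = Pedigree(family_id=skeleton.family_id, members=members)
    truth = HaplotypeConfiguration(
        family_id=ped.family_id,
        haplotypes=haplotypes,
        origins=origins,
        inheritance=InheritanceAssignment(h_vals),
    )
    return ped, truth


# ---------------------------------------------------------------------------
# phenotypes, ascertainment


def risk_copy_count(
    member_haps: tuple[Haplotype, Haplotype], model: PenetranceModel
) -> int:
    """Number of risk copies (0/1/2) carried by one member's true haplotypes."""
    if model.mode is DiseaseMode.SINGLE_LOCUS:
        if model.risk_snp is None or model.risk_allele is None:
            raise ValueError("single-locus model needs risk_snp and risk_allele")
        return sum(1 for h in member_haps if h[model.risk_snp] == model.risk_allele)
    if not model.risk_haplotypes:
        raise ValueError("rare-haplotype model needs a non-empty risk set")
    return sum(
        1 for h in member_haps if "".join(str(a) for a in h) in model.risk_haplotypes
    )


def assign_phenotypes(
    pedigree: Pedigree,
    truth: HaplotypeConfiguration,
    model: PenetranceModel,
    rng: np.random.Generator | int,
) -> Pedigree:
    """Draw each member's affection status ~ Bernoulli(f_g) independently,
    g being its risk copy count; returns the pedigree with phenotypes set."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if model.mode is DiseaseMode.SINGLE_LOCUS:
        n_markers = pedigree.n_markers
        if model.risk_snp is None or not 0 <= model.risk_snp < n_markers:
            raise ValueError(f"risk SNP {model.risk_snp} out of range [0, {n_markers})")
    f = model.triple
    for m in pedigree.members:
        g = risk_copy_count(truth.haplotypes[m.individual_id], model)
        m.phenotype = 1.0 if rng.random() < f[g] else 0.0
    return pedigree


def null_phenotypes(
    pedigree: Pedigree, k: float, rng: np.random.Generator | int
) -> Pedigree:
    """Null-model phenotypes: affected ~ Bernoulli(k) independent of genotype
    (k is usually the scenario prevalence)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    for m in pedigree.members:
        m.phenotype = 1.0 if rng.random() < k else 0.0
    return pedigree


@dataclass
class SimulatedFamily:
    pedigree: Pedigree
    truth: HaplotypeConfiguration


@dataclass
class SimulatedDataset:
    families: list[SimulatedFamily]
    marker_map: MarkerMap
    model: PenetranceModel | None
    #: identity of the removed risk SNP in the *original* map (single-locus)
    removed_snp: int | None = None
    removed_marker: Marker | None = None

    @property
    def pedigrees(self) -> list[Pedigree]:
        return [f.pedigree for f in self.families]


def uniform_map(
    n_markers: int, spacing_cm: float = 0.01, spacing_bp: int = 10_000
) -> MarkerMap:
    """Evenly spaced synthetic map (defaults: 0.01 cM per 10 kb)."""
    return MarkerMap(
        [
            Marker(f"snp{i + 1}", "1", round(i * spacing_cm, 10), (i + 1) * spacing_bp)
            for i in range(n_markers)
        ]
    )


def _strip_snp(family: SimulatedFamily, snp: int) -> SimulatedFamily:
    ped = family.pedigree
    for m in ped.members:
        del m.genotype[snp]
    truth = family.truth
    strip = lambda h: h[:snp] + h[snp + 1 :]
    truth.haplotypes = {
        iid: (strip(a), strip(b)) for iid, (a, b) in truth.haplotypes.items()
    }
    return family


def simulate_dataset(
    freq_table: HaplotypeFrequencyTable,
    n_families: int,
    model: PenetranceModel | None,
    seed: int,
    structure: StructureModel | None = None,
    marker_map: MarkerMap | None = None,
    null_prevalence: float | None = None,
) -> SimulatedDataset:
    """Generate an ascertained dataset of ``n_families`` pedigrees.

    With ``model`` set, phenotypes follow the penetrance model; with
    ``model=None`` the null model applies and ``null_prevalence`` gives the
    Bernoulli affection probability.  Families are simulated until
    ``n_families`` of them contain at least one affected member.  In
    single-locus mode the risk SNP column is removed from genotypes, true
    haplotypes and the map; its identity is retained in ``removed_snp`` /
    ``removed_marker``.
    """
    structure = structure or StructureModel()
    n_markers = freq_table.n_markers
    marker_map = marker_map or uniform_map(n_markers)
    if len(marker_map) != n_markers:
        raise ValueError("map length does not match the frequency table")
    if model is None and null_prevalence is None:
        raise ValueError("null model needs null_prevalence")

    rng_struct = substream(seed, "structure")
    rng_drop = substream(seed, "genedrop")
    rng_pheno = substream(seed, "phenotype")

    families: list[SimulatedFamily] = []
    attempt = 0
    while len(families) < n_families:
        attempt += 1
        fid = f"F{attempt}"
        skel = sample_structure(structure, rng_struct, family_id=fid)
        ped, truth = drop_genes(skel, freq_table, rng_drop)
        if model is None:
            null_phenotypes(ped, float(null_prevalence), rng_pheno)
        else:
            assign_phenotypes(ped, truth, model, rng_pheno)
        if any(m.phenotype == 1 for m in ped.members):
            families.append(SimulatedFamily(ped, truth))

    removed = None
    removed_marker = None
    out_map = marker_map
    if model is not None and model.mode is DiseaseMode.SINGLE_LOCUS:
        removed = model.risk_snp
        removed_marker = marker_map[removed]
        out_map = marker_map.drop(removed)
        for fam in families:
            _strip_snp(fam, removed)
    return SimulatedDataset(
        families=families,
        marker_map=out_map,
        model=model,
        removed_snp=removed,
        removed_marker=removed_marker,
    )


# ---------------------------------------------------------------------------
# risk haplotype selection, synthetic frequency tables


def pick_rare_haplotypes(
    freq_table: HaplotypeFrequencyTable,
    k: int,
    threshold: float = 0.02,
    rng: np.random.Generator | int = 0,
) -> frozenset[str]:
    """Uniform draw of k distinct haplotypes with frequency below threshold."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    eligible = [
        h for h, f in zip(freq_table.haplotypes, freq_table.frequencies) if f < threshold
    ]
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} haplotypes under frequency {threshold}, need {k}"
        )
    idx = rng.choice(len(eligible), size=k, replace=False)
    return frozenset(eligible[int(i)] for i in idx)


def synthetic_frequency_table(
    seed: int = 0,
    n_markers: int = 19,
    n_common: int = 7,
    n_rare: int = 22,
    rare_freq: float = 0.01786,
) -> HaplotypeFrequencyTable:
    """Synthetic stand-in for a cystic-fibrosis-like haplotype panel.

    29 haplotypes over 19 biallelic SNPs by default: 22 rare haplotypes share
    the frequency 0.01786 and 7 common haplotypes carry the remaining mass.
    Rare haplotypes are one- or two-SNP mutants of common ones so the panel
    has block-like LD rather than independent alleles.  Purely synthetic:
    the allele strings are generated, not taken from any study.
    """
    rng = np.random.default_rng(seed)
    haps: list[str] = []
    # common backbones: start from one ancestral string, derive the others by
    # flipping random subsets so that common haplotypes share long segments
    ancestral = rng.integers(1, 3, size=n_markers)
    while len(haps) < n_common:
        h = ancestral.copy()
        if haps:  # first common haplotype is the ancestral string itself
            nflip = int(rng.integers(1, max(2, n_markers // 3)))
            for pos in rng.choice(n_markers, size=nflip, replace=False):
                h[pos] = 3 - h[pos]
        s = "".join(str(a) for a in h)
        if s not in haps:
            haps.append(s)
    while len(haps) < n_common + n_rare:
        base = np.array([int(c) for c in haps[int(rng.integers(0, n_common))]])
        for pos in rng.choice(n_markers, size=int(rng.integers(1, 3)), replace=False):
            base[pos] = 3 - base[pos]
        s = "".join(str(a) for a in base)
        if s not in haps:
            haps.append(s)
    common_mass = 1.0 - n_rare * rare_freq
    raw = rng.dirichlet(np.full(n_common, 2.0)) * common_mass
    freqs = list(raw) + [rare_freq] * n_rare
    total = sum(freqs)
    freqs = [f / total for f in freqs]
    return HaplotypeFrequencyTable(haps, freqs)
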