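"""Single-locus transmission disequilibrium test (TDT) over full pedigrees.

For every affected child with genotyped parents, each heterozygous parent
contributes one transmission tally: b counts transmissions of the designated
allele (the numerically smaller allele carried by the parent), c counts
non-transmissions.  The transmitted allele is deduced from the child and
other-parent genotypes; the fully ambiguous triple (both parents and the
child heterozygous for the same two alleles) contributes half a count to
each side.  The McNemar-form statistic chi2 = (b - c)^2 / (b + c) is
referred to a 1-df chi-square.  Affected children in every generation are
counted, treating each parent-child transmission as independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .ped_model import Pedigree


@dataclass
class TransmissionCounts:
    snp: int  # 0-based
    b: float  # transmissions of the designated allele
    c: float  # non-transmissions
    informative_parents: int

    @property
    def uninformative(self) -> bool:
        return self.b + self.c == 0


def count_transmissions(
    pedigrees: Iterable[Pedigree], snp: int
) -> TransmissionCounts:
    """Tally transmissions of the designated allele at one SNP.

    Affected children are those with phenotype 1; parents homozygous at the
    SNP contribute nothing.  Triples incompatible with Mendelian inheritance
    at this SNP are skipped (they are surfaced by validate_mendelian, not
    here).
    """
    b = c = 0.0
    informative = 0
    for ped in pedigrees:
        for child in ped.members:
            if child.is_founder or child.phenotype != 1:
                continue
            fa = ped.member(child.father_id)
            mo = ped.member(child.mother_id)
            fg, mg = fa.genotype[snp], mo.genotype[snp]
            cg = child.genotype[snp]
            if 0 in fg or 0 in mg or 0 in cg:
                continue
            # consistent (paternal, maternal) transmitted-allele assignments
            assignments = set()
            for pa, ma in ((cg[0], cg[1]), (cg[1], cg[0])):
                if pa in fg and ma in mg:
                    assignments.add((pa, ma))
            if not assignments:
                continue  # Mendelian inconsistency at this SNP
            for parent_idx, gt in ((0, fg), (1, mg)):
                if gt[0] == gt[1]:
                    continue  # homozygous parent: uninformative
                designated = min(gt)
                transmitted = {a[parent_idx] for a in assignments}
                informative += 1
                if transmitted == {designated}:
                    b += 1.0
                elif designated in transmitted:
                    b += 0.5  # ambiguous triple: both resolutions consistent
                    c += 0.5
                else:
                    c += 1.0
    return TransmissionCounts(snp=snp, b=b, c=c, informative_parents=informative)


def tdt_test(counts: TransmissionCounts) -> tuple[float, float]:
    """(chi2, p) for one SNP; an uninformative SNP gives (0, 1)."""
    n = counts.b + counts.c
    if n == 0:
        return 0.0, 1.0
    chi2 = (counts.b - counts.c) ** 2 / n
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class TdtScanResult:
    counts: list[TransmissionCounts]
    chi2: list[float]
    p_raw: list[float]
    p_adjusted: list[float]
    alpha: float

    @property
    def significant(self) -> list[bool]:
        return [p <= self.alpha for p in self.p_adjusted]

    @property
    def any_significant(self) -> bool:
        return any(self.significant)

    def p_values(self) -> list[float]:
        return list(self.p_adjusted)

    def raw_p_values(self) -> list[float]:
        return list(self.p_raw)


def tdt_scan(pedigrees: Sequence[Pedigree], alpha: float = 0.05) -> TdtScanResult:
    """Per-SNP TDT over all pedigrees with Bonferroni over the SNP count."""
    peds = list(pedigrees)
    if not peds:
        raise ValueError("no pedigrees")
    n_markers = peds[0].n_markers
    counts = [count_transmissions(peds, s) for s in range(n_markers)]
    chi2_p = [tdt_test(ct) for ct in counts]
    chi2 = [cp[0] for cp in chi2_p]
    p_raw = [cp[1] for cp in chi2_p]
    p_adj = [min(1.0, p * n_markers) for p in p_raw]
    return TdtScanResult(counts, chi2, p_raw, p_adj, alpha)
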