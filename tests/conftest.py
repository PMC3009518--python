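import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fhapminer.fam_sim import synthetic_frequency_table
from fhapminer.ped_model import HaplotypeFrequencyTable, Individual, Pedigree, Sex


def make_individual(
    iid: str,
    genotype,
    father: str | None = None,
    mother: str | None = None,
    phenotype: float = 0.0,
    family: str = "F1",
    sex: Sex = Sex.UNKNOWN,
) -> Individual:
    return Individual(
        family_id=family,
        individual_id=iid,
        father_id=father,
        mother_id=mother,
        sex=sex,
        phenotype=phenotype,
        genotype=[tuple(g) for g in genotype],
    )


def make_trio(father_geno, mother_geno, child_geno, phenotypes=(0, 0, 0)) -> Pedigree:
    """Trio pedigree: father f, mother m, child c."""
    return Pedigree(
        "F1",
        [
            make_individual("f", father_geno, phenotype=phenotypes[0], sex=Sex.MALE),
            make_individual("m", mother_geno, phenotype=phenotypes[1], sex=Sex.FEMALE),
            make_individual("c", child_geno, "f", "m", phenotypes[2]),
        ],
    )


# Eight-member, two-SNP family in the classic three-generation shape used to
# illustrate pedigree phasing: grandparental couple (1, 2) -> 4; couple
# (3, 4) -> 5, 6; couple (7, 5) -> 8.  Founders 1, 2, 3, 7 are each
# heterozygous somewhere; after fixing one heterozygous locus per founder,
# five heterozygous loci remain and the solution space has exactly one
# degree of freedom (validated against exhaustive enumeration).
FIG_SHAPE_GENOTYPES = {
    "1": [(1, 2), (2, 2)],
    "2": [(1, 2), (1, 2)],
    "3": [(1, 1), (1, 2)],
    "4": [(1, 2), (2, 2)],
    "5": [(1, 2), (1, 2)],
    "6": [(1, 1), (2, 2)],
    "7": [(1, 2), (2, 2)],
    "8": [(1, 1), (1, 2)],
}


def make_three_generation_family(genotypes=None) -> Pedigree:
    g = genotypes or FIG_SHAPE_GENOTYPES
    return Pedigree(
        "F1",
        [
            make_individual("1", g["1"]),
            make_individual("2", g["2"]),
            make_individual("4", g["4"], "1", "2"),
            make_individual("3", g["3"]),
            make_individual("5", g["5"], "3", "4"),
            make_individual("6", g["6"], "3", "4"),
            make_individual("7", g["7"]),
            make_individual("8", g["8"], "7", "5"),
        ],
    )


@pytest.fixture(scope="session")
def cf_like_table() -> HaplotypeFrequencyTable:
    """Synthetic 29-haplotype, 19-SNP panel (22 rare rows at 0.01786)."""
    return synthetic_frequency_table(0)


@pytest.fixture(scope="session")
def small_table() -> HaplotypeFrequencyTable:
    return HaplotypeFrequencyTable(
        ["1122", "1212", "2211", "2121", "1111"], [0.3, 0.25, 0.2, 0.15, 0.1]
    )
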