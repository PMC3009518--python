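"""End-to-end experiment orchestration: the full association pipeline,
type-I error, power studies and mapping precision.

The pipeline for one dataset is phase -> (random configuration pick) ->
founder scores -> pooled cluster scan; the single-locus TDT runs on the same
pedigrees as the comparison method.  Power is the fraction of replicates in
which a method reports any marker significant after multiple-testing
correction at the overall alpha; type-I error is the same fraction under the
null model (phenotypes independent of genotypes, ascertainment still
applied).  Mapping precision is the genetic distance in cM between the most
significant marker and the true risk locus.

Each replicate derives its own seeds from the experiment root seed, so
results are reproducible and independent of any replicate-level
parallelism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import fam_sim
from .fam_sim import (
    DiseaseMode,
    PenetranceModel,
    SimulatedDataset,
    StructureModel,
    prevalence,
    substream,
)
from .founder_score import pool_scores, score_deviation, score_relative_risk
from .hap_scan import DensityParams, ScanResult, SimilarityParams, scan
from .ped_model import (
    HaplotypeFrequencyTable,
    MarkerMap,
    Pedigree,
    Marker,
)
from .tdt_baseline import TdtScanResult, tdt_scan
from .zr_phase import PhaseConflictError, pick_config, solve

log = logging.getLogger(__name__)

#: MAF group boundaries: Low < 0.13 <= Medium < 0.30 <= High
MAF_CUTS: tuple[float, float] = (0.13, 0.30)


def maf_group(maf: float, cuts: tuple[float, float] = MAF_CUTS) -> str:
    if maf < cuts[0]:
        return "Low"
    if maf < cuts[1]:
        return "Medium"
    return "High"


def fhapminer_scan(
    pedigrees: Sequence[Pedigree],
    params: SimilarityParams | None = None,
    density: DensityParams | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    measure: str = "deviation",
    threshold: float = 0.5,
    permutations: int = 1000,
    qscore: str = "one-sample",
    rng: np.random.Generator | int | None = None,
) -> ScanResult:
    """Run the full pipeline on a set of phased-ready pedigrees.

    When a family admits several zero-recombination configurations one is
    drawn uniformly at random; a family whose genotypes admit none is
    excluded with a logged warning and the scan continues on the rest.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    per_family = []
    for ped in pedigrees:
        try:
            space = solve(ped)
        except PhaseConflictError as exc:
            log.warning("family %s excluded from scan: %s", ped.family_id, exc)
            continue
        config = pick_config(space, rng)
        phenotypes = {
            m.individual_id: m.phenotype
            for m in ped.members
            if not m.phenotype_missing
        }
        if measure == "deviation":
            scored = score_deviation(config, phenotypes)
        elif measure == "relative-risk":
            scored = score_relative_risk(config, phenotypes, threshold)
        else:
            raise ValueError(f"unknown measure {measure!r}")
        per_family.append(scored)
    pooled = pool_scores(per_family)
    if not pooled:
        raise ValueError("no families could be phased and scored")
    return scan(
        pooled,
        params=params,
        density=density,
        alpha=alpha,
        correction=correction,
        permutations=permutations,
        qscore=qscore,
        rng=rng,
    )


def mapping_precision(
    p_values: Sequence[float], marker_map: MarkerMap, true_marker: Marker
) -> tuple[float, bool]:
    """Genetic distance (cM) from the lowest-p marker to the true risk locus.

    Ties pick the lowest marker index.  Returns (distance, informative);
    ``informative`` is False when all p-values are identical.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) != len(marker_map):
        raise ValueError("p-value vector does not match the map")
    best = int(np.argmin(p))  # argmin takes the first minimum: lowest index
    informative = bool(np.any(p != p[0]))
    dist = abs(marker_map[best].genetic_pos_cm - true_marker.genetic_pos_cm)
    return dist, informative


@dataclass
class ExperimentConfig:
    """One experiment's knobs; every replicate seed derives from ``seed``."""

    freq_table: HaplotypeFrequencyTable
    penetrance: tuple[float, float, float] = fam_sim.PENETRANCE_SETS["C"]
    n_families: int = 50
    n_replicates: int = 100
    alpha: float = 0.05
    methods: tuple[str, ...] = ("fhapminer", "tdt")
    #: None = per-study convention (1 for single-locus studies, 10 for
    #: rare-haplotype studies)
    window: int | None = None
    correction: str = "bonferroni"
    measure: str = "deviation"
    qscore: str = "one-sample"
    density: DensityParams = field(default_factory=DensityParams)
    structure: StructureModel = field(default_factory=StructureModel)
    marker_map: MarkerMap | None = None
    null_prevalence: float | None = None  # default: prevalence of the
    # penetrance set at risk frequency 0.1
    seed: int = 0

    def similarity_params(self, default_window: int = 1) -> SimilarityParams:
        w = self.window if self.window is not None else default_window
        return SimilarityParams(window=w)

    def resolved_null_prevalence(self) -> float:
        if self.null_prevalence is not None:
            return self.null_prevalence
        return prevalence(self.penetrance, 0.1)


def _replicate_seed(root: int, *indices: int) -> int:
    ss = np.random.SeedSequence(root, spawn_key=tuple(indices))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _run_methods(
    config: ExperimentConfig,
    dataset: SimulatedDataset,
    analysis_rng: np.random.Generator,
    default_window: int = 1,
) -> dict[str, ScanResult | TdtScanResult]:
    out: dict[str, ScanResult | TdtScanResult] = {}
    for method in config.methods:
        if method == "fhapminer":
            out[method] = fhapminer_scan(
                dataset.pedigrees,
                params=config.similarity_params(default_window),
                density=config.density,
                alpha=config.alpha,
                correction=config.correction,
                measure=config.measure,
                qscore=config.qscore,
                rng=analysis_rng,
            )
        elif method == "tdt":
            out[method] = tdt_scan(dataset.pedigrees, alpha=config.alpha)
        else:
            raise ValueError(f"unknown method {method!r}")
    return out


def run_type1(config: ExperimentConfig) -> dict[str, float]:
    """Family-wise empirical type-I error rate per method under the null."""
    k = config.resolved_null_prevalence()
    log.info(
        "type-I run: %d replicates x %d families, null prevalence %.4f",
        config.n_replicates,
        config.n_families,
        k,
    )
    hits = {m: 0 for m in config.methods}
    for rep in range(config.n_replicates):
        dataset = fam_sim.simulate_dataset(
            config.freq_table,
            config.n_families,
            model=None,
            seed=_replicate_seed(config.seed, 0, rep),
            structure=config.structure,
            marker_map=config.marker_map,
            null_prevalence=k,
        )
        analysis_rng = substream(_replicate_seed(config.seed, 0, rep), "analysis")
        for method, res in _run_methods(config, dataset, analysis_rng).items():
            if res.any_significant:
                hits[method] += 1
    return {m: hits[m] / config.n_replicates for m in config.methods}


@dataclass
class PowerCell:
    key: str  # SNP label or risk-set size
    maf: float
    group: str
    method: str
    power: float
    mean_precision_cm: float | None = None


def _power_frame(cells: list[PowerCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "key": c.key,
                "maf": c.maf,
                "group": c.group,
                "method": c.method,
                "power": c.power,
                "mean_precision_cm": c.mean_precision_cm,
            }
            for c in cells
        ]
    )


def run_power_single_locus(
    config: ExperimentConfig,
    snps: Sequence[int] | None = None,
    collect_precision: bool = False,
) -> pd.DataFrame:
    """Power per risk SNP: each SNP in turn is the risk locus, is stripped
    from the data after phenotype assignment, and the methods must flag any
    remaining marker.  Monomorphic SNPs are skipped with a warning."""
    table = config.freq_table
    snps = list(snps) if snps is not None else list(range(table.n_markers))
    cells: list[PowerCell] = []
    for snp in snps:
        allele, maf = table.minor_allele(snp)
        if maf == 0.0 or maf == 1.0:
            log.warning("SNP %d monomorphic in the table; skipped", snp + 1)
            continue
        model = PenetranceModel(
            *config.penetrance,
            mode=DiseaseMode.SINGLE_LOCUS,
            risk_snp=snp,
            risk_allele=allele,
        )
        hits = {m: 0 for m in config.methods}
        dists: dict[str, list[float]] = {m: [] for m in config.methods}
        for rep in range(config.n_replicates):
            seed = _replicate_seed(config.seed, 1, snp, rep)
            dataset = fam_sim.simulate_dataset(
                table,
                config.n_families,
                model=model,
                seed=seed,
                structure=config.structure,
                marker_map=config.marker_map,
            )
            analysis_rng = substream(seed, "analysis")
            for method, res in _run_methods(config, dataset, analysis_rng).items():
                if res.any_significant:
                    hits[method] += 1
                if collect_precision:
                    d, _ = mapping_precision(
                        res.raw_p_values(), dataset.marker_map, dataset.removed_marker
                    )
                    dists[method].append(d)
        for method in config.methods:
            cells.append(
                PowerCell(
                    key=f"snp{snp + 1}",
                    maf=maf,
                    group=maf_group(maf),
                    method=method,
                    power=hits[method] / config.n_replicates,
                    mean_precision_cm=(
                        float(np.mean(dists[method])) if collect_precision else None
                    ),
                )
            )
    return _power_frame(cells)


def run_power_rare_hap(
    config: ExperimentConfig,
    k_values: Sequence[int] = (2, 3, 4, 5, 6),
    n_selections: int = 10,
    rare_threshold: float = 0.02,
) -> pd.DataFrame:
    """Power under the rare-haplotype model, averaged over random risk-set
    selections for each risk-set size k."""
    table = config.freq_table
    cells: list[PowerCell] = []
    for k in k_values:
        powers: dict[str, list[float]] = {m: [] for m in config.methods}
        for sel in range(n_selections):
            risk = fam_sim.pick_rare_haplotypes(
                table,
                k,
                threshold=rare_threshold,
                rng=substream(config.seed, "selection", _mix(k, sel)),
            )
            model = PenetranceModel(
                *config.penetrance,
                mode=DiseaseMode.RARE_HAPLOTYPE,
                risk_haplotypes=risk,
            )
            hits = {m: 0 for m in config.methods}
            for rep in range(config.n_replicates):
                seed = _replicate_seed(config.seed, 2, k, sel, rep)
                dataset = fam_sim.simulate_dataset(
                    table,
                    config.n_families,
                    model=model,
                    seed=seed,
                    structure=config.structure,
                    marker_map=config.marker_map,
                )
                analysis_rng = substream(seed, "analysis")
                results = _run_methods(config, dataset, analysis_rng, default_window=10)
                for method, res in results.items():
                    if res.any_significant:
                        hits[method] += 1
            for m in config.methods:
                powers[m].append(hits[m] / config.n_replicates)
        risk_freq = sum(
            f for h, f in zip(table.haplotypes, table.frequencies) if f < rare_threshold
        )
        for m in config.methods:
            cells.append(
                PowerCell(
                    key=f"k={k}",
                    maf=risk_freq,
                    group=f"{k} risk haplotypes",
                    method=m,
                    power=float(np.mean(powers[m])),
                )
            )
    return _power_frame(cells)


def _mix(*xs: int) -> int:
    out = 0
    for x in xs:
        out = out * 1_000_003 + x + 1
    return out & 0x7FFFFFFF
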