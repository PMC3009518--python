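"""Phenotype scores for founder haplotypes.

Each founder haplotype h_ik of family i receives a family-level score s_ik
accumulating the phenotypes of the members that carry it, so haplotypes
riding in affected / high-trait members score high.  Two measures are
offered:

* ``deviation`` (default): s_ik = sum_j c_ij * (Y_ij - Ybar_i), where c_ij
  in {0, 1, 2} counts the copies of h_ik carried by member j and Ybar_i is
  the family phenotype mean.  Copy counting (rather than a carrier
  indicator) makes the scores sum to zero exactly within every family: each
  member contributes its deviation once per haplotype slot.
* ``relative-risk``: a within-family high/low carrier ratio
  s_ik = (sum_j c_ij I(Y_ij >= t) + 1/2) / (sum_j c_ij I(Y_ij < t) + 1/2)
  with a half pseudocount in both tallies.  This is a reconstruction of the
  ratio-style measure from its described intent (relative risk with an
  indicator threshold t), selectable but non-default.

Binary traits are coded 1/0 affected/normal and treated as reals, so one
code path serves binary and quantitative phenotypes.  Members with missing
phenotypes are excluded from both the mean and the sums (the effective
family size shrinks accordingly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .zr_phase import FounderLabel, Haplotype, HaplotypeConfiguration


class ScoreError(ValueError):
    """Scores cannot be computed (e.g. no phenotyped members in a family)."""


@dataclass
class ScoredFounderHaplotype:
    family_id: str
    label: FounderLabel
    haplotype: Haplotype
    score: float
    carrier_copies: dict[str, int]  # member id -> copies in {0, 1, 2}


def _carrier_copies(
    config: HaplotypeConfiguration,
) -> dict[FounderLabel, dict[str, int]]:
    """Copy count c_ij of every founder haplotype in every member."""
    copies: dict[FounderLabel, dict[str, int]] = {}
    for iid, (lab_p, lab_m) in config.origins.items():
        for lab in (lab_p, lab_m):
            tab = copies.setdefault(lab, {})
            tab[iid] = tab.get(iid, 0) + 1
    return copies


def _founder_entries(
    config: HaplotypeConfiguration,
) -> list[tuple[FounderLabel, Haplotype]]:
    out = []
    for iid, labels in config.origins.items():
        if labels[0] == (iid, 0):
            out.append(((iid, 0), config.haplotypes[iid][0]))
            out.append(((iid, 1), config.haplotypes[iid][1]))
    return out


def score_deviation(
    config: HaplotypeConfiguration, phenotypes: dict[str, float]
) -> list[ScoredFounderHaplotype]:
    """Mean-deviation scores for every founder haplotype of one family.

    ``phenotypes`` maps member id to trait value; omitted members (and NaN /
    missing-sentinel values handled by the caller) take no part.
    """
    observed = {iid: y for iid, y in phenotypes.items() if iid in config.haplotypes}
    if not observed:
        raise ScoreError(
            f"family {config.family_id}: no phenotyped members, cannot score"
        )
    ybar = sum(observed.values()) / len(observed)
    copies = _carrier_copies(config)
    out = []
    for label, hap in _founder_entries(config):
        tab = copies.get(label, {})
        s = sum(c * (observed[iid] - ybar) for iid, c in tab.items() if iid in observed)
        out.append(
            ScoredFounderHaplotype(
                family_id=config.family_id,
                label=label,
                haplotype=hap,
                score=s,
                carrier_copies=tab,
            )
        )
    return out


def score_relative_risk(
    config: HaplotypeConfiguration,
    phenotypes: dict[str, float],
    t: float = 0.5,
) -> list[ScoredFounderHaplotype]:
    """Thresholded carrier-ratio scores (reconstruction; see module docs).

    For binary 1/0 traits any t in (0, 1] splits affected from normal;
    the default 0.5 does.
    """
    observed = {iid: y for iid, y in phenotypes.items() if iid in config.haplotypes}
    if not observed:
        raise ScoreError(
            f"family {config.family_id}: no phenotyped members, cannot score"
        )
    copies = _carrier_copies(config)
    out = []
    for label, hap in _founder_entries(config):
        tab = copies.get(label, {})
        high = sum(c for iid, c in tab.items() if iid in observed and observed[iid] >= t)
        low = sum(c for iid, c in tab.items() if iid in observed and observed[iid] < t)
        s = (high + 0.5) / (low + 0.5)
        out.append(
            ScoredFounderHaplotype(
                family_id=config.family_id,
                label=label,
                haplotype=hap,
                score=s,
                carrier_copies=tab,
            )
        )
    return out


def pool_scores(
    families: Iterable[Sequence[ScoredFounderHaplotype]],
) -> list[ScoredFounderHaplotype]:
    """Concatenate per-family score lists into the population-level sample.

    Founder haplotypes are treated as unrelated across families; identical
    allele strings from different families stay distinct records with their
    own scores.
    """
    out: list[ScoredFounderHaplotype] = []
    for fam in families:
        out.extend(fam)
    return out
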