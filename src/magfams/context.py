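"""Calibrated genomic-context ("guilt-by-association") functional predictor.

For every family member we take a window of up to three genes on each side
on the same contig and score the family against each candidate KEGG
pathway P with four conservation statistics:

* **synteny conservation** — fraction of members whose window contains at
  least one gene annotated to P;
* **functional relatedness** — pooled over members, the proportion of
  window genes annotated to P among all window genes (unannotated genes
  count in the denominator);
* **strand conservation** — among pooled P-annotated window genes, the
  fraction lying on the same strand as their focal member;
* **distance conservation** — among pooled P-annotated window genes, the
  fraction reachable from the focal gene through consecutive intergenic
  gaps of at most 100 nt each.

Score thresholds per pathway are calibrated on families of known function:
the level-c threshold of a score is the largest value that at least a
fraction c of known P-families reach (the empirical (1-c)-quantile, lower
interpolation). A family is associated with P at confidence c when all
four of its scores meet the level-c thresholds; the highest level met is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import ContextProfile, GeneRecord

WINDOW = 3
DEFAULT_LEVELS = (0.5, 0.9)
SCORE_NAMES = (
    "synteny_conservation",
    "functional_relatedness",
    "strand_conservation",
    "distance_conservation",
)


@dataclass
class Neighbor:
    rel_pos: int  # -3..-1, +1..+3
    gene: GeneRecord
    #: intergenic gap (nt) between this gene and its neighbour one step
    #: closer to the focal gene; negative for overlapping genes
    gap_toward_focal: int


@dataclass
class Neighborhood:
    """The +-``WINDOW``-gene context of one family member on its contig."""

    focal: GeneRecord
    neighbors: dict[int, Neighbor] = field(default_factory=dict)

    def genes(self) -> list[Neighbor]:
        return [self.neighbors[k] for k in sorted(self.neighbors)]

    def reachable(self, rel_pos: int, max_gap: int) -> bool:
        """True if every intergenic gap between the focal gene and the gene
        at ``rel_pos`` is <= ``max_gap`` nt."""
        step = 1 if rel_pos > 0 else -1
        for k in range(step, rel_pos + step, step):
            nb = self.neighbors.get(k)
            if nb is None or nb.gap_toward_focal > max_gap:
                return False
        return True


def extract_neighborhood(
    gene: GeneRecord,
    genes_on_contig: Sequence[GeneRecord],
    window: int = WINDOW,
) -> Neighborhood:
    """Window of up to ``window`` genes on each side of ``gene`` by
    ``rank_on_contig``; truncated at contig ends.

    Intergenic gaps are ``start(right) - end(left)`` in half-open
    coordinates and may be negative for overlapping genes.
    """
    ordered = sorted(genes_on_contig, key=lambda g: g.rank_on_contig)
    idx = next(
        i for i, g in enumerate(ordered) if g.gene_id == gene.gene_id
    )
    nbhd = Neighborhood(focal=gene)
    for off in range(-window, window + 1):
        if off == 0:
            continue
        j = idx + off
        if j < 0 or j >= len(ordered):
            continue
        inner = idx + off - 1 if off > 0 else idx + off + 1
        left, right = (ordered[inner], ordered[j]) if off > 0 else (ordered[j], ordered[inner])
        gap = right.start - left.end
        nbhd.neighbors[off] = Neighbor(rel_pos=off, gene=ordered[j], gap_toward_focal=gap)
    return nbhd


def _pathways_in_window(nbhd: Neighborhood) -> set[str]:
    out: set[str] = set()
    for nb in nbhd.genes():
        out |= nb.gene.pathways
    return out


def synteny_conservation(
    neighborhoods: Sequence[Neighborhood], pathway: str
) -> float:
    """Fraction of members whose window contains >=1 gene annotated to P."""
    if not neighborhoods:
        return 0.0
    hit = sum(
        1
        for nbhd in neighborhoods
        if any(pathway in nb.gene.pathways for nb in nbhd.genes())
    )
    return hit / len(neighborhoods)


def functional_relatedness(
    neighborhoods: Sequence[Neighborhood], pathway: str
) -> float:
    """Pooled proportion of window genes annotated to P (0 if no neighbours)."""
    total = 0
    in_p = 0
    for nbhd in neighborhoods:
        for nb in nbhd.genes():
            total += 1
            if pathway in nb.gene.pathways:
                in_p += 1
    return in_p / total if total else 0.0


def strand_conservation(
    neighborhoods: Sequence[Neighborhood], pathway: str
) -> float:
    """Among pooled P-annotated neighbours, fraction on the focal strand."""
    total = 0
    same = 0
    for nbhd in neighborhoods:
        for nb in nbhd.genes():
            if pathway in nb.gene.pathways:
                total += 1
                if nb.gene.strand == nbhd.focal.strand:
                    same += 1
    return same / total if total else 0.0


def distance_conservation(
    neighborhoods: Sequence[Neighborhood], pathway: str, max_gap: int = 100
) -> float:
    """Among pooled P-annotated neighbours, fraction reachable from the focal
    gene through consecutive intergenic gaps each <= ``max_gap`` nt."""
    total = 0
    reachable = 0
    for nbhd in neighborhoods:
        for nb in nbhd.genes():
            if pathway in nb.gene.pathways:
                total += 1
                if nbhd.reachable(nb.rel_pos, max_gap):
                    reachable += 1
    return reachable / total if total else 0.0


def compute_context_profiles(
    family_id: str,
    neighborhoods: Sequence[Neighborhood],
    max_gap: int = 100,
    pathways: Optional[Iterable[str]] = None,
) -> list[ContextProfile]:
    """All four scores against every pathway seen in any member window
    (or against an explicit pathway list)."""
    if pathways is None:
        seen: set[str] = set()
        for nbhd in neighborhoods:
            seen |= _pathways_in_window(nbhd)
        pathways = sorted(seen)
    out = []
    for p in pathways:
        out.append(
            ContextProfile(
                family_id=family_id,
                pathway_id=p,
                synteny_conservation=synteny_conservation(neighborhoods, p),
                functional_relatedness=functional_relatedness(neighborhoods, p),
                strand_conservation=strand_conservation(neighborhoods, p),
                distance_conservation=distance_conservation(neighborhoods, p),
                n_members_scored=len(neighborhoods),
            )
        )
    return out


@dataclass
class PathwayCalibration:
    """Minimum scores needed to recover a fraction c of known P-families."""

    pathway_id: str
    #: level -> (synteny, relatedness, strand, distance) thresholds
    thresholds: dict[float, tuple[float, float, float, float]]
    n_known_families: int


def calibrate_thresholds(
    known_profiles: Sequence[ContextProfile],
    levels: Sequence[float] = DEFAULT_LEVELS,
    n_min: int = 5,
) -> dict[str, PathwayCalibration]:
    """Per-pathway score thresholds from families of known function.

    ``known_profiles`` hold each known family's scores against its own true
    pathway. For each pathway with >= ``n_min`` known families, the level-c
    threshold of each score is the empirical (1-c)-quantile (lower
    interpolation) of the known families' scores: the largest value that a
    fraction >= c of them reach. Pathways with fewer known families get no
    calibration (predictions for them are impossible).
    """
    by_pathway: dict[str, list[ContextProfile]] = {}
    for prof in known_profiles:
        by_pathway.setdefault(prof.pathway_id, []).append(prof)
    out: dict[str, PathwayCalibration] = {}
    for pathway, profs in by_pathway.items():
        if len(profs) < n_min:
            continue
        thresholds: dict[float, tuple[float, float, float, float]] = {}
        for c in levels:
            thr = tuple(
                float(
                    np.quantile(
                        [getattr(p, s) for p in profs], 1.0 - c, method="lower"
                    )
                )
                for s in SCORE_NAMES
            )
            thresholds[c] = thr  # type: ignore[assignment]
        out[pathway] = PathwayCalibration(
            pathway_id=pathway, thresholds=thresholds, n_known_families=len(profs)
        )
    return out


def predict_pathway_associations(
    profiles: Sequence[ContextProfile],
    calibrations: Mapping[str, PathwayCalibration],
) -> list[tuple[str, float, ContextProfile]]:
    """Pathway associations for one family at the highest confidence met.

    A family is associated with P at level c iff all four of its scores
    against P are >= P's level-c thresholds. Returns
    ``(pathway, confidence, profile)`` sorted by confidence (descending)
    then synteny conservation (descending).
    """
    hits: list[tuple[str, float, ContextProfile]] = []
    for prof in profiles:
        cal = calibrations.get(prof.pathway_id)
        if cal is None:
            continue
        best: Optional[float] = None
        for c in sorted(cal.thresholds):
            thr = cal.thresholds[c]
            if all(s >= t for s, t in zip(prof.scores(), thr)):
                best = c
        if best is not None:
            hits.append((prof.pathway_id, best, prof))
    hits.sort(key=lambda h: (-h[1], -h[2].synteny_conservation, h[0]))
    return hits


class ContextPredictor:
    """Calibrate-then-predict wrapper around the four context scores.

    ``fit`` learns per-pathway thresholds from known families; ``predict``
    assigns pathway associations with discrete confidence levels to novel
    families.
    """

    def __init__(self, levels: Sequence[float] = DEFAULT_LEVELS, n_min: int = 5,
                 max_gap: int = 100):
        self.levels = tuple(levels)
        self.n_min = n_min
        self.max_gap = max_gap
        self.calibrations_: dict[str, PathwayCalibration] = {}

    def fit(self, known_profiles: Sequence[ContextProfile]) -> "ContextPredictor":
        self.calibrations_ = calibrate_thresholds(
            known_profiles, levels=self.levels, n_min=self.n_min
        )
        return self

    def predict(
        self, profiles: Sequence[ContextProfile]
    ) -> list[tuple[str, float, ContextProfile]]:
        return predict_pathway_associations(profiles, self.calibrations_)


def count_resistance_neighbors(
    neighborhoods: Sequence[Neighborhood],
    min_member_fraction: float = 0.8,
    window: int = WINDOW,
) -> int:
    """Number of window positions at which >= ``min_member_fraction`` of
    members have a resistance-flagged neighbour."""
    if not neighborhoods:
        return 0
    n = len(neighborhoods)
    count = 0
    for pos in list(range(-window, 0)) + list(range(1, window + 1)):
        hits = sum(
            1
            for nbhd in neighborhoods
            if pos in nbhd.neighbors and nbhd.neighbors[pos].gene.is_resistance
        )
        if hits / n >= min_member_fraction:
            count += 1
    return count


def positional_synteny(
    neighborhoods: Sequence[Neighborhood],
    positions: Sequence[int] = (-1, 1),
    label: str = "ko",
) -> float:
    """Mean conservation of the most frequent annotation label at the given
    window positions (adjacent genes by default).

    At each position the conservation is the fraction of members whose
    neighbour there carries the modal label; members lacking a neighbour or
    a label at that position dilute the fraction.
    """
    if not neighborhoods:
        return 0.0
    n = len(neighborhoods)
    per_pos = []
    for pos in positions:
        counts: dict[str, int] = {}
        for nbhd in neighborhoods:
            nb = nbhd.neighbors.get(pos)
            if nb is None:
                continue
            lab = getattr(nb.gene, label, None)
            if lab:
                counts[lab] = counts.get(lab, 0) + 1
        per_pos.append(max(counts.values()) / n if counts else 0.0)
    return float(np.mean(per_pos))
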