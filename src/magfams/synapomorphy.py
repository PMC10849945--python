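"""Clade-defining (synapomorphic) gene family detection.

A family is synapomorphic for a clade when it is nearly ubiquitous inside
the clade (high coverage) and essentially absent outside it (high
specificity). Two regimes are used: a strict one (more than 10 members,
coverage > 90%, specificity = 100%) for the final calls, and a broad
validation regime (coverage > 70%, specificity >= 90%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .model import GeneFamily, GeneRecord, TaxonomyTable

HIGH_RANKS = ("phylum", "class", "order")

#: (min_coverage strict >, min_specificity >=, min_members strict >)
STRICT_REGIME = dict(min_cov=0.9, min_spec=1.0, min_members=10)
BROAD_REGIME = dict(min_cov=0.7, min_spec=0.9, min_members=0)


@dataclass
class SynapomorphyHit:
    family_id: str
    rank: str
    clade: str
    coverage: float
    specificity: float
    n_members: int


def _member_genomes(
    family: GeneFamily, genes: Mapping[str, GeneRecord]
) -> list[str]:
    return [genes[g].genome_id for g in family.members]


def clade_coverage(
    family: GeneFamily,
    genes: Mapping[str, GeneRecord],
    taxonomy: TaxonomyTable,
    rank: str,
    clade: str,
) -> float:
    """Fraction of clade genomes containing >= 1 member of the family."""
    clade_genomes = taxonomy.genomes_in_clade(rank, clade)
    if not clade_genomes:
        raise ValueError(f"clade {clade} at rank {rank} has no genomes")
    present = set(_member_genomes(family, genes))
    return sum(1 for g in clade_genomes if g in present) / len(clade_genomes)


def clade_specificity(
    family: GeneFamily,
    genes: Mapping[str, GeneRecord],
    taxonomy: TaxonomyTable,
    rank: str,
    clade: str,
) -> float:
    """Fraction of family members whose genome lies inside the clade."""
    member_genomes = _member_genomes(family, genes)
    in_clade = sum(
        1 for g in member_genomes if taxonomy.rank_value(g, rank) == clade
    )
    return in_clade / len(member_genomes)


def scan_synapomorphies(
    families: Iterable[GeneFamily],
    genes: Mapping[str, GeneRecord],
    taxonomy: TaxonomyTable,
    min_cov: float = STRICT_REGIME["min_cov"],
    min_spec: float = STRICT_REGIME["min_spec"],
    min_members: int = STRICT_REGIME["min_members"],
    ranks: Sequence[str] = HIGH_RANKS,
    exclude: Optional[set[tuple[str, str]]] = None,
) -> list[SynapomorphyHit]:
    """Scan every family against every clade at the requested ranks.

    Emits a hit iff ``n_members > min_members``, ``coverage > min_cov`` and
    ``specificity >= min_spec`` (coverage and member-count boundaries are
    strict). ``exclude`` is an optional set of (family_id, clade) pairs
    purged by an external remapping screen. Clades with zero genomes are
    skipped with a warning.
    """
    exclude = exclude or set()
    hits: list[SynapomorphyHit] = []
    clades_by_rank = {rank: taxonomy.clades(rank) for rank in ranks}
    for fam in families:
        if fam.n_members <= min_members:
            continue
        member_genomes = _member_genomes(fam, genes)
        present = set(member_genomes)
        for rank in ranks:
            # only clades the family touches can satisfy coverage > 0
            touched = {taxonomy.rank_value(g, rank) for g in present}
            for clade in sorted(touched):
                clade_genomes = clades_by_rank[rank].get(clade, [])
                if not clade_genomes:
                    warnings.warn(f"clade {clade} at rank {rank} has no genomes")
                    continue
                if (fam.family_id, clade) in exclude:
                    continue
                cov = sum(1 for g in clade_genomes if g in present) / len(
                    clade_genomes
                )
                spec = sum(
                    1
                    for g in member_genomes
                    if taxonomy.rank_value(g, rank) == clade
                ) / len(member_genomes)
                if cov > min_cov and spec >= min_spec:
                    hits.append(
                        SynapomorphyHit(
                            family_id=fam.family_id,
                            rank=rank,
                            clade=clade,
                            coverage=cov,
                            specificity=spec,
                            n_members=fam.n_members,
                        )
                    )
    return hits
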