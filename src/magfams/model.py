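"""Core domain types shared across the pipeline.

Conventions fixed here and relied on everywhere else:

* gene coordinates are 0-based, half-open ``[start, end)`` on the contig;
  GFF3 I/O converts to/from the 1-based inclusive convention of the format;
* a genome's species identity is its GTDB species-rank string;
* taxonomy lineages are ordered 7-tuples
  (domain, phylum, class, order, family, genus, species) of GTDB-style
  prefixed strings, and clade membership is lineage-prefix consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: GTDB-style one-letter rank prefixes, in rank order.
RANK_PREFIXES: tuple[str, ...] = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass
class GeneRecord:
    """One gene call on a contig, with its external annotation flags.

    ``start``/``end`` are 0-based half-open nucleotide coordinates;
    ``rank_on_contig`` is the 0-based order of the gene along its contig
    when genes are sorted by ``start``.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    is_complete: bool = True
    rank_on_contig: int = -1
    protein_seq: Optional[str] = None
    cds_seq: Optional[str] = None
    pathways: set[str] = field(default_factory=set)
    ko: Optional[str] = None
    is_resistance: bool = False
    is_secreted: bool = False
    is_transmembrane: bool = False
    is_expressed: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentMatrix:
    """A rectangular multiple alignment (amino-acid or codon rows)."""

    ids: list[str]
    rows: list[str]
    alphabet: str = "aa"  # {"aa", "codon"}

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if self.rows:
            n = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != n:
                    raise ValueError(
                        f"ragged alignment: sequence {sid} has length {len(row)}, "
                        f"expected {n}"
                    )
            if self.alphabet == "codon" and n % 3 != 0:
                raise ValueError("codon alignment length must be divisible by 3")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column_occupancy(self, col: int) -> float:
        """Fraction of non-gap characters in one column."""
        n = self.n_seqs
        return sum(1 for r in self.rows if r[col] not in "-.") / n


@dataclass
class GeneFamily:
    """A cluster of homologous genes with its derived statistics."""

    family_id: str
    members: list[str]
    n_species: int = 0
    alignment: Optional[AlignmentMatrix] = None
    tree: Optional[str] = None  # Newick string
    dnds: Optional[float] = None
    conserved_domain: Optional[tuple[int, int]] = None
    mean_identity: Optional[float] = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id}: members must be non-empty")
        if self.dnds is not None and self.dnds < 0:
            raise ValueError(f"family {self.family_id}: dN/dS must be >= 0")

    @property
    def n_members(self) -> int:
        return len(self.members)


class TaxonomyTable:
    """genome_id -> ordered 7-rank GTDB-style lineage.

    Provides clade enumeration and lineage-prefix queries used by the
    synapomorphy scan, the LCA computation and duplication dating.
    """

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        self._lineages: dict[str, tuple[str, ...]] = {}
        for genome_id, lineage in lineages.items():
            lineage = tuple(lineage)
            if len(lineage) != len(RANKS) or any(not x for x in lineage):
                raise ValueError(
                    f"genome {genome_id}: lineage must have exactly "
                    f"{len(RANKS)} non-empty ranks, got {lineage!r}"
                )
            self._lineages[genome_id] = lineage

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    @property
    def genome_ids(self) -> list[str]:
        return list(self._lineages)

    def lineage(self, genome_id: str) -> tuple[str, ...]:
        return self._lineages[genome_id]

    def rank_value(self, genome_id: str, rank: str) -> str:
        return self._lineages[genome_id][RANKS.index(rank)]

    def species(self, genome_id: str) -> str:
        """Species identity of a genome = GTDB species-rank string."""
        return self._lineages[genome_id][-1]

    def clades(self, rank: str) -> dict[str, list[str]]:
        """All clades at ``rank`` -> list of genome_ids under each."""
        idx = RANKS.index(rank)
        out: dict[str, list[str]] = {}
        for genome_id, lineage in self._lineages.items():
            out.setdefault(lineage[idx], []).append(genome_id)
        return out

    def genomes_in_clade(self, rank: str, clade: str) -> list[str]:
        idx = RANKS.index(rank)
        return [g for g, lin in self._lineages.items() if lin[idx] == clade]

    def shared_prefix(self, genome_ids: Iterable[str]) -> tuple[str, ...]:
        """Deepest lineage prefix shared by all given genomes (may be empty)."""
        lineages = [self._lineages[g] for g in genome_ids]
        if not lineages:
            return ()
        prefix: list[str] = []
        for level in range(len(RANKS)):
            values = {lin[level] for lin in lineages}
            if len(values) == 1:
                prefix.append(values.pop())
            else:
                break
        return tuple(prefix)


@dataclass
class ContextProfile:
    """The four genomic-context conservation scores of a family vs one pathway."""

    family_id: str
    pathway_id: str
    synteny_conservation: float
    functional_relatedness: float
    strand_conservation: float
    distance_conservation: float
    n_members_scored: int = 0

    def __post_init__(self) -> None:
        for name in (
            "synteny_conservation",
            "functional_relatedness",
            "strand_conservation",
            "distance_conservation",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def scores(self) -> tuple[float, float, float, float]:
        return (
            self.synteny_conservation,
            self.functional_relatedness,
            self.strand_conservation,
            self.distance_conservation,
        )


@dataclass
class AbundanceMatrix:
    """family x sample relative abundances with case/control + block metadata."""

    values: "pandas.DataFrame"  # type: ignore[name-defined]  # families x samples
    condition: dict[str, str]  # sample -> {"case", "control"}
    block: dict[str, str]  # sample -> study block
    habitat: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import pandas as pd  # local import keeps model import light

        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (families x samples)")
        if (self.values.values < 0).any():
            raise ValueError("abundances must be non-negative")
        for s in self.values.columns:
            if s not in self.condition or s not in self.block:
                raise ValueError(f"sample {s} lacks condition or block metadata")
            if self.condition[s] not in ("case", "control"):
                raise ValueError(
                    f"sample {s}: condition must be 'case' or 'control', "
                    f"got {self.condition[s]!r}"
                )

    @property
    def family_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)
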