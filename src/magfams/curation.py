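"""Family-level candidacy filters and sequence-feature aggregation.

Turns raw sequence clusters into curated candidate families: drops orphans
(single-species clusters) and fragment-dominated clusters, requires a
conserved aligned block, screens external hit tables, and aggregates
per-gene feature predictions (secreted / transmembrane / small peptide) to
the family level. All filters are independent predicates over one family,
so their application order does not change the surviving set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import AlignmentMatrix, GeneFamily, GeneRecord, TaxonomyTable

#: machine-readable reason codes attached to dropped families
REASON_ORPHAN = "orphan_single_species"
REASON_TOO_FEW_COMPLETE = "too_few_complete_genes"
REASON_SHORT_DOMAIN = "conserved_domain_too_short"
REASON_NO_DOMAIN = "no_conserved_domain"
REASON_DB_HIT = "significant_database_hit"


@dataclass
class FilterReport:
    """Audit trail of the curation funnel: family -> reason it was dropped."""

    dropped: dict[str, str] = field(default_factory=dict)
    kept: list[str] = field(default_factory=list)

    def drop(self, family_id: str, reason: str) -> None:
        self.dropped[family_id] = reason


def select_candidate_families(
    clusters: Mapping[str, Sequence[str]],
    genes: Mapping[str, GeneRecord],
    taxonomy: TaxonomyTable,
    min_complete_genes: int = 3,
    min_species: int = 2,
    report: Optional[FilterReport] = None,
) -> list[GeneFamily]:
    """Keep clusters with >= ``min_complete_genes`` complete genes drawn from
    >= ``min_species`` distinct species.

    Completeness and species are evaluated on the same genes: a cluster
    qualifies when its complete members alone span enough species, which
    excludes both orphan families and clusters inferred from fragments.
    """
    out: list[GeneFamily] = []
    for family_id, member_ids in clusters.items():
        try:
            members = [genes[g] for g in member_ids]
        except KeyError as exc:
            raise KeyError(
                f"family {family_id}: member gene {exc.args[0]} not resolvable"
            ) from None
        complete = [m for m in members if m.is_complete]
        species = {taxonomy.species(m.genome_id) for m in complete}
        if len(complete) < min_complete_genes:
            if report is not None:
                report.drop(family_id, REASON_TOO_FEW_COMPLETE)
            continue
        if len(species) < min_species:
            if report is not None:
                report.drop(family_id, REASON_ORPHAN)
            continue
        all_species = {taxonomy.species(m.genome_id) for m in members}
        fam = GeneFamily(
            family_id=family_id,
            members=list(member_ids),
            n_species=len(all_species),
        )
        out.append(fam)
        if report is not None:
            report.kept.append(family_id)
    return out


def find_conserved_domain(
    alignment: AlignmentMatrix, min_occupancy: float = 0.8
) -> Optional[tuple[int, int]]:
    """Longest run of consecutive columns each with non-gap fraction >=
    ``min_occupancy``, as a 0-based half-open column interval.

    Ties are broken leftmost; returns ``None`` if no column qualifies.
    """
    best: Optional[tuple[int, int]] = None
    run_start: Optional[int] = None
    n = alignment.n_cols
    for col in range(n + 1):
        ok = col < n and alignment.column_occupancy(col) >= min_occupancy
        if ok and run_start is None:
            run_start = col
        elif not ok and run_start is not None:
            if best is None or (col - run_start) > (best[1] - best[0]):
                best = (run_start, col)
            run_start = None
    return best


def filter_by_domain(
    families: Iterable[GeneFamily],
    min_len: int = 20,
    min_occupancy: float = 0.8,
    report: Optional[FilterReport] = None,
) -> list[GeneFamily]:
    """Keep families whose most conserved aligned block spans >= ``min_len``
    residues; families without an alignment or without any qualifying block
    are dropped."""
    kept = []
    for fam in families:
        domain = fam.conserved_domain
        if domain is None and fam.alignment is not None:
            domain = find_conserved_domain(fam.alignment, min_occupancy)
            fam.conserved_domain = domain
        if domain is None:
            if report is not None:
                report.drop(fam.family_id, REASON_NO_DOMAIN)
            continue
        if domain[1] - domain[0] < min_len:
            if report is not None:
                report.drop(fam.family_id, REASON_SHORT_DOMAIN)
            continue
        kept.append(fam)
    return kept


#: default per-database significance rules: (max_evalue, min_coverage);
#: both boundaries strict (E < threshold, coverage > threshold)
DEFAULT_HIT_RULES: dict[str, tuple[float, Optional[float]]] = {
    "sequence": (1e-3, 0.5),
    "hmm": (1e-5, None),
}


def drop_flagged_families(
    families: Iterable[GeneFamily],
    hit_table: pd.DataFrame,
    rules: Optional[Mapping[str, tuple[float, Optional[float]]]] = None,
    report: Optional[FilterReport] = None,
) -> list[GeneFamily]:
    """Drop families with a significant external-database hit.

    ``hit_table`` columns: family_id, database, evalue, coverage. ``rules``
    maps a database class to (max_evalue, min_coverage); hits qualify with
    strict inequalities on both. Unknown database classes fall back to the
    'sequence' rule.
    """
    rules = dict(DEFAULT_HIT_RULES if rules is None else rules)
    flagged: set[str] = set()
    for row in hit_table.itertuples():
        max_e, min_cov = rules.get(str(row.database), rules["sequence"])
        if float(row.evalue) < max_e and (
            min_cov is None or float(row.coverage) > min_cov
        ):
            flagged.add(str(row.family_id))
    kept = []
    for fam in families:
        if fam.family_id in flagged:
            if report is not None:
                report.drop(fam.family_id, REASON_DB_HIT)
        else:
            kept.append(fam)
    return kept


def aggregate_member_flags(
    family: GeneFamily,
    genes: Mapping[str, GeneRecord],
    min_fraction: float = 0.8,
) -> set[str]:
    """Set the family-level secreted/transmembrane flags when at least
    ``min_fraction`` of members carry the per-gene prediction."""
    members = [genes[g] for g in family.members]
    n = len(members)
    for flag, attr in (("secreted", "is_secreted"), ("transmembrane", "is_transmembrane")):
        if sum(1 for m in members if getattr(m, attr)) / n >= min_fraction:
            family.flags.add(flag)
        else:
            family.flags.discard(flag)
    return family.flags


def family_length(family: GeneFamily, genes: Mapping[str, GeneRecord]) -> int:
    """Family length = residue length of the longest member protein."""
    lengths = []
    for g in family.members:
        rec = genes[g]
        if rec.protein_seq is not None:
            lengths.append(len(rec.protein_seq))
        else:
            lengths.append(rec.length_nt // 3 - 1)  # minus stop codon
    return max(lengths)


def flag_small_peptides(
    families: Iterable[GeneFamily],
    genes: Mapping[str, GeneRecord],
    max_len: int = 50,
) -> list[GeneFamily]:
    """Flag families whose longest member protein is shorter than ``max_len``
    residues as small peptides (strict inequality)."""
    out = []
    for fam in families:
        if family_length(fam, genes) < max_len:
            fam.flags.add("small_peptide")
        else:
            fam.flags.discard("small_peptide")
        out.append(fam)
    return out
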