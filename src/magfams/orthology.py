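"""Orthology calling on family gene trees.

A family represents a single basal orthologous group when its midpoint-
rooted gene tree contains no duplication event dated at a basal taxonomic
rank. Duplications are detected with the species-overlap rule: an internal
node is a duplication if the species sets of (any pair of) its child
subtrees intersect. Each event is dated at the deepest taxonomic rank
shared by all species below the node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import dendropy

from .model import RANKS, TaxonomyTable


@dataclass
class DuplicationEvent:
    node_id: str  # deterministic postorder index of the node
    overlapping_species: frozenset[str]
    dated_rank: str  # one of RANKS, or "root" when no rank is shared
    clade: str  # lineage value at dated_rank ("" for root)


def _as_tree(tree: Union[str, dendropy.Tree]) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)


def midpoint_root(tree: Union[str, dendropy.Tree]) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Trees whose branch lengths are all zero have no defined midpoint; the
    existing (deterministic) rooting is kept. Fewer than 2 leaves is an
    error.
    """
    from io import StringIO

    import skbio

    t = _as_tree(tree)
    leaves = t.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("midpoint rooting requires at least 2 leaves")
    for edge in t.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    nwk = t.as_string(schema="newick", suppress_rooting=True)
    sk = skbio.TreeNode.read(StringIO(nwk), convert_underscores=False)
    if sk.get_max_distance()[0] == 0:
        return t  # all-zero branch lengths: keep the existing rooting
    buf = StringIO()
    sk.root_at_midpoint().write(buf)
    return dendropy.Tree.get(
        data=buf.getvalue(), schema="newick", preserve_underscores=True
    )


def species_lineages_from_taxonomy(
    taxonomy: TaxonomyTable,
) -> dict[str, tuple[str, ...]]:
    """species-rank string -> full 7-rank lineage (from any genome carrying it)."""
    return {taxonomy.species(g): taxonomy.lineage(g) for g in taxonomy.genome_ids}


def _date_rank(
    species: frozenset[str],
    species_lineages: Optional[Mapping[str, Sequence[str]]],
) -> tuple[str, str]:
    """Deepest rank shared by all species in the set -> (rank name, clade)."""
    if species_lineages is None:
        # without a taxonomy every set of >1 species dates at the root
        if len(species) == 1:
            return "species", next(iter(species))
        return "root", ""
    lineages = [tuple(species_lineages[s]) for s in species]
    depth = 0
    clade = ""
    for level in range(len(RANKS)):
        values = {lin[level] for lin in lineages}
        if len(values) == 1:
            depth = level + 1
            clade = values.pop()
        else:
            break
    if depth == 0:
        return "root", ""
    return RANKS[depth - 1], clade


def detect_duplications(
    tree: Union[str, dendropy.Tree],
    gene_to_species: Mapping[str, str],
    species_lineages: Optional[Mapping[str, Sequence[str]]] = None,
) -> list[DuplicationEvent]:
    """Species-overlap duplication detection on a rooted gene tree.

    ``gene_to_species`` maps leaf labels to species identifiers; at
    multifurcations a node is a duplication if ANY pair of child subtrees
    shares a species. ``species_lineages`` (species -> 7-rank lineage)
    enables dating at taxonomic ranks; without it events date at the root
    (or at "species" for single-species overlaps).
    """
    t = _as_tree(tree)
    events: list[DuplicationEvent] = []
    species_below: dict[int, frozenset[str]] = {}
    for idx, node in enumerate(t.postorder_node_iter()):
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else ""
            if label not in gene_to_species:
                raise KeyError(f"leaf {label!r} missing from gene->species map")
            species_below[id(node)] = frozenset([gene_to_species[label]])
            continue
        child_sets = [species_below[id(c)] for c in node.child_nodes()]
        merged: frozenset[str] = frozenset().union(*child_sets)
        species_below[id(node)] = merged
        overlap: set[str] = set()
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                overlap |= child_sets[i] & child_sets[j]
        if overlap:
            rank, clade = _date_rank(merged, species_lineages)
            events.append(
                DuplicationEvent(
                    node_id=f"n{idx}",
                    overlapping_species=frozenset(overlap),
                    dated_rank=rank,
                    clade=clade,
                )
            )
    return events


def is_basal_orthologous_group(
    events: Sequence[DuplicationEvent],
    basal_ranks: frozenset[str] = frozenset({"domain"}),
) -> bool:
    """True iff no duplication event is dated at a basal rank.

    Events dated at "root" (species spanning both domains) are always
    treated as basal.
    """
    for ev in events:
        if ev.dated_rank in basal_ranks or ev.dated_rank == "root":
            return False
    return True
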