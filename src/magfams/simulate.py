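"""Seeded synthetic pangenome generator with planted ground truth.

Emulates every input the pipeline consumes — gene coordinate tables,
cluster memberships, functional annotations, taxonomy, contig mobility
flags, codon alignments, gene trees and case/control abundance matrices —
with the planted signal recorded in truth tables so each downstream stage
can be tested against known answers.

Design choices that keep the planted truth unambiguous:

* the taxonomy template is a balanced hierarchy with two children at every
  internal rank (2 domains x 2 phyla x 2 classes x 2 orders x ...), so no
  two clades at the scanned ranks contain identical genome sets and a
  family planted as synapomorphic for one clade cannot trivially qualify
  for another;
* operon (pathway-cassette) annotations and background annotations draw
  from disjoint pathway pools, so a planted context association can never
  be produced by background noise; context-shuffled null families instead
  receive sporadic, inconsistent operon-pathway neighbours;
* all randomness flows from one ``numpy`` Generator seeded by
  ``SimConfig.seed``; iteration orders are fixed, so identical
  configurations produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from . import io as mio
from .context import Neighborhood, extract_neighborhood
from .model import GeneRecord, TaxonomyTable

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


@dataclass
class SimConfig:
    """All knobs of the generator; the seed fully determines the output."""

    seed: int = 0

    # taxonomy template: balanced, two children per internal rank
    n_domains: int = 2
    n_phyla_per_domain: int = 2
    n_classes_per_phylum: int = 2
    n_orders_per_class: int = 2
    n_species_per_order: int = 4
    n_genomes_per_species: int = 3

    # genome layout
    genes_per_contig: int = 20
    gene_length_nt: int = 303  # 100 codons + stop
    background_gap_range: tuple[int, int] = (120, 300)

    # background annotation: pathways disjoint from the operon pool
    p_background_annotated: float = 0.3
    n_background_pathways: int = 10

    # planted operons (context module ground truth)
    n_operon_pathways: int = 10
    n_known_families_per_pathway: int = 10  # calibration set
    n_operon_families: int = 20  # novel families with a planted pathway
    n_null_families: int = 40  # context-shuffled negatives
    operon_members: int = 8
    operon_member_fraction: float = 0.9  # embedded members = round(f * n)
    cassette_size: int = 4
    operon_gap_range: tuple[int, int] = (10, 60)
    p_null_operon_neighbor: float = 0.5  # sporadic operon-pathway gene per null window

    # planted synapomorphies: (rank, coverage) per family, cycled over clades
    n_synapomorphy_families: int = 4
    synapomorphy_rank: str = "order"
    synapomorphy_coverage: float = 1.0

    # plain background clusters
    n_background_families: int = 30
    background_family_size_range: tuple[int, int] = (3, 6)

    # mobility
    plasmid_contig_fraction: float = 0.05
    viral_contig_fraction: float = 0.05

    # sequences (optional: curation/length tests)
    with_sequences: bool = False

    # abundance matrix (biomarker ground truth)
    ab_n_families: int = 500
    ab_n_samples: int = 200
    ab_n_blocks: int = 5
    ab_n_effect_families: int = 20
    ab_fold_change: float = 2.0
    ab_log_sigma: float = 0.6
    ab_block_sigma: float = 0.5
    ab_prevalence: float = 0.9


@dataclass
class Collection:
    """In-memory synthetic pangenome with planted ground truth."""

    config: SimConfig
    genes: dict[str, GeneRecord]
    clusters: dict[str, list[str]]
    taxonomy: TaxonomyTable
    contig_flags: dict[str, dict[str, bool]]
    uncultivated: dict[str, bool]
    truth: dict[str, pd.DataFrame]

    def genes_on_contig(self, genome_id: str, contig_id: str) -> list[GeneRecord]:
        return [
            g
            for g in self.genes.values()
            if g.genome_id == genome_id and g.contig_id == contig_id
        ]

    def _contig_index(self) -> dict[tuple[str, str], list[GeneRecord]]:
        cached = getattr(self, "_by_contig", None)
        if cached is None:
            cached = {}
            for g in self.genes.values():
                cached.setdefault((g.genome_id, g.contig_id), []).append(g)
            self._by_contig = cached
        return cached

    def family_neighborhoods(self, family_id: str, window: int = 3) -> list[Neighborhood]:
        by_contig = self._contig_index()
        out = []
        for gid in self.clusters[family_id]:
            g = self.genes[gid]
            out.append(
                extract_neighborhood(g, by_contig[(g.genome_id, g.contig_id)], window)
            )
        return out


def build_taxonomy(cfg: SimConfig) -> TaxonomyTable:
    """Balanced GTDB-style taxonomy; genus unique per species, two
    family-rank groups per order (so order-level clades are datable)."""
    lineages: dict[str, tuple[str, ...]] = {}
    gi = 0
    for d in range(cfg.n_domains):
        dn = f"d__D{d}"
        for p in range(cfg.n_phyla_per_domain):
            pn = f"p__D{d}P{p}"
            for c in range(cfg.n_classes_per_phylum):
                cn = f"c__D{d}P{p}C{c}"
                for o in range(cfg.n_orders_per_class):
                    on = f"o__D{d}P{p}C{c}O{o}"
                    for s in range(cfg.n_species_per_order):
                        fn = f"f__{on[3:]}F{s % 2}"
                        gn = f"g__{on[3:]}G{s}"
                        sn = f"s__{on[3:]}S{s}"
                        for _ in range(cfg.n_genomes_per_species):
                            gid = f"G{gi:05d}"
                            lineages[gid] = (dn, pn, cn, on, fn, gn, sn)
                            gi += 1
    return TaxonomyTable(lineages)


def _random_protein(rng: np.random.Generator, n_res: int) -> str:
    return "".join(
        AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), n_res)
    )


def random_codon_sequence(rng: np.random.Generator, n_codons: int) -> str:
    """Random stop-free coding sequence of ``n_codons`` codons."""
    idx = rng.integers(0, len(_NONSTOP_CODONS), n_codons)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


class _ContigBuilder:
    """Lays genes left-to-right on a fresh contig with chosen gaps."""

    def __init__(self, collection_genes: dict[str, GeneRecord], genome_id: str,
                 contig_id: str, gene_length: int):
        self.genes = collection_genes
        self.genome_id = genome_id
        self.contig_id = contig_id
        self.gene_length = gene_length
        self.cursor = 0
        self.rank = 0

    def add(
        self,
        gene_id: str,
        gap: int,
        strand: str,
        pathways: Optional[set[str]] = None,
        is_resistance: bool = False,
        is_complete: bool = True,
        ko: Optional[str] = None,
    ) -> GeneRecord:
        start = self.cursor + gap if self.rank > 0 else 0
        rec = GeneRecord(
            gene_id=gene_id,
            genome_id=self.genome_id,
            contig_id=self.contig_id,
            start=start,
            end=start + self.gene_length,
            strand=strand,
            is_complete=is_complete,
            rank_on_contig=self.rank,
            pathways=pathways or set(),
            ko=ko,
            is_resistance=is_resistance,
        )
        self.genes[gene_id] = rec
        self.cursor = rec.end
        self.rank += 1
        return rec


def generate_collection(cfg: SimConfig) -> Collection:
    """Build the full synthetic pangenome with planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    taxonomy = build_taxonomy(cfg)
    genomes = taxonomy.genome_ids
    genes: dict[str, GeneRecord] = {}
    clusters: dict[str, list[str]] = {}
    truth_rows: dict[str, list[dict]] = {
        "families": [],
        "operons": [],
        "synapomorphies": [],
    }
    bg_pathways = [f"bgP{i:03d}" for i in range(cfg.n_background_pathways)]
    op_pathways = [f"opP{i:03d}" for i in range(cfg.n_operon_pathways)]
    contig_counter: dict[str, int] = {g: 0 for g in genomes}

    def new_contig(genome_id: str) -> _ContigBuilder:
        n = contig_counter[genome_id]
        contig_counter[genome_id] += 1
        return _ContigBuilder(
            genes, genome_id, f"{genome_id}_c{n}", cfg.gene_length_nt
        )

    def bg_annotation() -> set[str]:
        if rng.random() < cfg.p_background_annotated:
            return {bg_pathways[rng.integers(0, len(bg_pathways))]}
        return set()

    def bg_gap() -> int:
        lo, hi = cfg.background_gap_range
        return int(rng.integers(lo, hi + 1))

    def strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    # --- background contigs: one per genome -------------------------------
    background_genes: list[str] = []
    for genome_id in genomes:
        cb = new_contig(genome_id)
        for j in range(cfg.genes_per_contig):
            gid = f"{cb.contig_id}_g{j:03d}"
            cb.add(gid, bg_gap(), strand(), bg_annotation())
            background_genes.append(gid)
    bg_pool = list(background_genes)
    rng.shuffle(bg_pool)
    bg_cursor = 0

    def take_background(n: int) -> list[str]:
        nonlocal bg_cursor
        if bg_cursor + n > len(bg_pool):
            raise ValueError("background gene pool exhausted; enlarge genomes")
        out = bg_pool[bg_cursor : bg_cursor + n]
        bg_cursor += n
        return out

    # --- planted operon-context families ----------------------------------
    def plant_context_family(
        family_id: str, pathway: Optional[str], kind: str
    ) -> None:
        """Members on dedicated contigs. With a pathway, round(f*n) members
        are embedded in a co-strand cassette of pathway genes; null members
        get sporadic, inconsistent operon-pathway neighbours instead."""
        member_genomes = rng.choice(genomes, size=cfg.operon_members, replace=False)
        n_embed = (
            int(math.floor(cfg.operon_member_fraction * cfg.operon_members + 0.5))
            if pathway is not None
            else 0
        )
        members: list[str] = []
        for mi, genome_id in enumerate(member_genomes):
            cb = new_contig(genome_id)
            focal_strand = strand()
            embedded = pathway is not None and mi < n_embed
            lo, hi = cfg.operon_gap_range
            # 11 genes, focal at index 5; cassette at offsets -2..-1, +1..+2
            for j in range(11):
                off = j - 5
                gid = f"{cb.contig_id}_g{j:03d}"
                if off == 0:
                    members.append(gid)
                    gap = int(rng.integers(lo, hi + 1)) if embedded else bg_gap()
                    cb.add(gid, gap, focal_strand)
                elif embedded and abs(off) <= cfg.cassette_size // 2:
                    gap = int(rng.integers(lo, hi + 1))
                    cb.add(gid, gap, focal_strand, {pathway})
                else:
                    ann = bg_annotation()
                    if (
                        pathway is None
                        and kind == "null"
                        and abs(off) <= 3
                        and rng.random() < cfg.p_null_operon_neighbor / 6.0
                    ):
                        ann = {op_pathways[rng.integers(0, len(op_pathways))]}
                    cb.add(gid, bg_gap(), strand(), ann)
        clusters[family_id] = members
        truth_rows["families"].append(
            {
                "family_id": family_id,
                "kind": kind,
                "pathway": pathway or "-",
                "n_members": len(members),
            }
        )
        if pathway is not None:
            truth_rows["operons"].append(
                {
                    "family_id": family_id,
                    "pathway": pathway,
                    "n_members": len(members),
                    "n_embedded": n_embed,
                }
            )

    for p_idx, pathway in enumerate(op_pathways):
        for k in range(cfg.n_known_families_per_pathway):
            plant_context_family(f"KNOWN{p_idx:02d}_{k:03d}", pathway, "known")
    for i in range(cfg.n_operon_families):
        pathway = op_pathways[i % len(op_pathways)]
        plant_context_family(f"OPFAM{i:04d}", pathway, "operon")
    for i in range(cfg.n_null_families):
        plant_context_family(f"NULLFAM{i:04d}", None, "null")

    # --- planted synapomorphies -------------------------------------------
    clades = sorted(taxonomy.clades(cfg.synapomorphy_rank))
    for i in range(cfg.n_synapomorphy_families):
        clade = clades[i % len(clades)]
        clade_genomes = sorted(taxonomy.genomes_in_clade(cfg.synapomorphy_rank, clade))
        n_cov = int(math.floor(cfg.synapomorphy_coverage * len(clade_genomes) + 0.5))
        chosen = list(
            rng.choice(clade_genomes, size=n_cov, replace=False)
        )
        family_id = f"SYNFAM{i:04d}"
        members = []
        for genome_id in sorted(chosen):
            cb = new_contig(genome_id)
            gid = f"{cb.contig_id}_g000"
            cb.add(gid, 0, strand(), bg_annotation())
            members.append(gid)
        clusters[family_id] = members
        truth_rows["families"].append(
            {
                "family_id": family_id,
                "kind": "synapomorphy",
                "pathway": "-",
                "n_members": len(members),
            }
        )
        truth_rows["synapomorphies"].append(
            {
                "family_id": family_id,
                "rank": cfg.synapomorphy_rank,
                "clade": clade,
                "coverage": n_cov / len(clade_genomes),
                "n_members": len(members),
            }
        )

    # --- plain background clusters ----------------------------------------
    lo, hi = cfg.background_family_size_range
    for i in range(cfg.n_background_families):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(take_background(size))
        family_id = f"BGFAM{i:04d}"
        clusters[family_id] = members
        truth_rows["families"].append(
            {
                "family_id": family_id,
                "kind": "background",
                "pathway": "-",
                "n_members": size,
            }
        )

    # --- mobility flags per contig ----------------------------------------
    contig_ids = sorted({(g.genome_id, g.contig_id) for g in genes.values()})
    contig_flags: dict[str, dict[str, bool]] = {}
    for _, contig_id in contig_ids:
        contig_flags[contig_id] = {
            "plasmid": bool(rng.random() < cfg.plasmid_contig_fraction),
            "viral": bool(rng.random() < cfg.viral_contig_fraction),
        }

    # --- optional sequences -------------------------------------------------
    if cfg.with_sequences:
        for gid in sorted(genes):
            rec = genes[gid]
            n_res = rec.length_nt // 3 - 1
            rec.protein_seq = _random_protein(rng, n_res)

    truth = {k: pd.DataFrame(v) for k, v in truth_rows.items()}
    uncultivated = {g: True for g in genomes}
    return Collection(
        config=cfg,
        genes=genes,
        clusters=clusters,
        taxonomy=taxonomy,
        contig_flags=contig_flags,
        uncultivated=uncultivated,
        truth=truth,
    )


def write_collection(collection: Collection, outdir) -> dict[str, Path]:
    """Write the collection in the pipeline's external formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff": outdir / "genes.gff",
        "clusters": outdir / "clusters.tsv",
        "annotations": outdir / "annotations.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "contig_flags": outdir / "contig_flags.tsv",
    }
    ordered = sorted(
        collection.genes.values(),
        key=lambda g: (g.genome_id, g.contig_id, g.start),
    )
    mio.write_gff(ordered, paths["gff"])
    mio.write_cluster_tsv(collection.clusters, paths["clusters"])
    with open(paths["annotations"], "w", encoding="utf-8") as fh:
        fh.write("gene_id\tpathways\tko\tis_resistance\n")
        for rec in ordered:
            pw = ",".join(sorted(rec.pathways)) if rec.pathways else "-"
            fh.write(
                f"{rec.gene_id}\t{pw}\t{rec.ko or '-'}\t"
                f"{1 if rec.is_resistance else 0}\n"
            )
    mio.write_taxonomy_tsv(collection.taxonomy, paths["taxonomy"])
    with open(paths["contig_flags"], "w", encoding="utf-8") as fh:
        fh.write("contig_id\tis_plasmid\tis_viral\n")
        for contig_id in sorted(collection.contig_flags):
            fl = collection.contig_flags[contig_id]
            fh.write(
                f"{contig_id}\t{1 if fl['plasmid'] else 0}\t"
                f"{1 if fl['viral'] else 0}\n"
            )
    for name, df in collection.truth.items():
        p = outdir / f"truth_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = p
    if collection.config.with_sequences:
        p = outdir / "proteins.faa"
        mio.write_fasta(
            {g.gene_id: g.protein_seq for g in ordered if g.protein_seq},
            p,
        )
        paths["proteins"] = p
    return paths


# --- gene trees for orthology ---------------------------------------------

@dataclass
class GeneTreeSim:
    newick: str
    gene_to_species: dict[str, str]
    species_lineages: dict[str, tuple[str, ...]]
    planted_rank: Optional[str]
    planted_clade: Optional[str]


def simulate_gene_tree(
    taxonomy: TaxonomyTable,
    rng: np.random.Generator,
    duplication_clade: Optional[tuple[str, str]] = None,
) -> GeneTreeSim:
    """Gene tree whose topology mirrors the balanced species hierarchy, one
    gene per species; optionally one planted duplication.

    The duplication duplicates the whole subtree of ``(rank, clade)``; the
    species sets of the two copies coincide, so species-overlap detection
    must report exactly one event, dated at the deepest rank shared by the
    clade's species (the clade's own rank in the balanced template).
    Deep backbone branches are long and within-clade branches short, so
    midpoint rooting stays on the inter-domain path.
    """
    from .model import RANKS

    species = sorted({taxonomy.species(g) for g in taxonomy.genome_ids})
    lineages = {
        taxonomy.species(g): taxonomy.lineage(g) for g in taxonomy.genome_ids
    }
    gene_to_species: dict[str, str] = {}

    def bl(level: int) -> float:
        # long near the root, short near the tips
        base = [1.0, 0.6, 0.4, 0.25, 0.15, 0.1, 0.05][min(level, 6)]
        return base * (0.8 + 0.4 * rng.random())

    def subtree(level: int, members: list[str], suffix: str) -> str:
        if level == len(RANKS):
            assert len(members) == 1
            sp = members[0]
            gene = f"gene_{sp[3:]}{suffix}"
            gene_to_species[gene] = sp
            return f"{gene}:{bl(level):.6f}"
        groups: dict[str, list[str]] = {}
        for sp in members:
            groups.setdefault(lineages[sp][level], []).append(sp)
        parts = [
            subtree(level + 1, grp, suffix) for _, grp in sorted(groups.items())
        ]
        if len(parts) == 1:
            return parts[0]
        inner = parts[0]
        for nxt in parts[1:]:  # resolve multifurcations caterpillar-style
            inner = f"({inner},{nxt}):{bl(level):.6f}"
        return inner

    if duplication_clade is None:
        nwk = subtree(0, species, "") + ";"
        return GeneTreeSim(nwk, gene_to_species, lineages, None, None)

    rank, clade = duplication_clade
    rank_idx = RANKS.index(rank)
    in_clade = [sp for sp in species if lineages[sp][rank_idx] == clade]
    out_clade = [sp for sp in species if lineages[sp][rank_idx] != clade]
    if not in_clade:
        raise ValueError(f"no species under clade {clade} at rank {rank}")
    copy_a = subtree(rank_idx + 1, in_clade, "_a")
    copy_b = subtree(rank_idx + 1, in_clade, "_b")
    dup_node = f"({copy_a},{copy_b}):{bl(rank_idx):.6f}"

    # attach the duplicated subtree among the remaining clades, preserving
    # the species hierarchy above the planted clade
    def subtree_with_dup(level: int, members: list[str]) -> str:
        groups: dict[str, list[str]] = {}
        for sp in members:
            groups.setdefault(lineages[sp][level], []).append(sp)
        parts = []
        for name, grp in sorted(groups.items()):
            if level == rank_idx and name == clade:
                parts.append(dup_node)
            elif level == rank_idx:
                parts.append(subtree(level + 1, grp, ""))
            else:
                parts.append(subtree_with_dup(level + 1, grp))
        if len(parts) == 1:
            return parts[0]
        inner = parts[0]
        for nxt in parts[1:]:
            inner = f"({inner},{nxt}):{bl(level):.6f}"
        return inner

    nwk = subtree_with_dup(0, species) + ";"
    return GeneTreeSim(nwk, gene_to_species, lineages, rank, clade)


# --- codon evolution --------------------------------------------------------

def _hky_weights(current: str, kappa: float) -> np.ndarray:
    """Proposal weights over ACGT for one site under HKY (no base-frequency
    bias): transitions weighted kappa, transversions 1, self 0."""
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    w = np.zeros(4)
    for i, b in enumerate(_BASES):
        if b == current:
            continue
        w[i] = kappa if transitions[current] == b else 1.0
    return w / w.sum()


def _evolve_branch(
    seq: str, length: float, omega: float, kappa: float, mu: float,
    rng: np.random.Generator, synonymous_only: bool = False,
) -> str:
    from Bio.Seq import Seq

    s = list(seq)
    n_events = rng.poisson(mu * length * len(s))
    for _ in range(n_events):
        pos = int(rng.integers(0, len(s)))
        if synonymous_only:
            pos = pos - pos % 3 + 2  # third codon positions only
        w = _hky_weights(s[pos], kappa)
        new_base = _BASES[rng.choice(4, p=w)]
        cstart = pos - pos % 3
        old_codon = "".join(s[cstart : cstart + 3])
        new_codon = (
            old_codon[: pos % 3] + new_base + old_codon[pos % 3 + 1 :]
        )
        if new_codon in _STOPS:
            continue
        syn = str(Seq(old_codon).translate()) == str(Seq(new_codon).translate())
        if synonymous_only and not syn:
            continue
        if syn or rng.random() < omega:
            s[pos] = new_base
    return "".join(s)


def evolve_codon_family(
    ancestral_cds: str,
    tree: str,
    omega: float,
    kappa: float = 2.0,
    seed: int = 0,
    mu: float = 1.0,
    synonymous_only: bool = False,
) -> dict[str, str]:
    """Markov codon substitution along a Newick tree.

    HKY-within-codon proposals with the non-synonymous rate scaled by
    ``omega``; substitutions creating stops are rejected. Returns a gap-free
    leaf-name -> sequence map (an implicit codon alignment, since no indels
    are generated).

    ``synonymous_only`` restricts substitutions to synonymous third-position
    changes. This is stronger than ``omega=0``: free evolution under
    ``omega=0`` can still connect codons that differ at several positions
    through chains of synonymous single steps (e.g. within the leucine
    codon network), and pathway-averaged counting then attributes
    fractional non-synonymous differences to such pairs. Restricting to the
    third position guarantees every observed codon difference is a single
    unambiguous synonymous change, so the estimated dN is exactly zero by
    construction.
    """
    if len(ancestral_cds) % 3 != 0:
        raise ValueError("ancestral CDS length must be divisible by 3")
    rng = np.random.default_rng(seed)
    t = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    seqs: dict[int, str] = {}
    out: dict[str, str] = {}
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            seqs[id(node)] = ancestral_cds.upper()
            continue
        parent_seq = seqs[id(node.parent_node)]
        length = node.edge.length or 0.0
        seqs[id(node)] = _evolve_branch(
            parent_seq, length, omega, kappa, mu, rng, synonymous_only
        )
        if node.is_leaf():
            label = node.taxon.label if node.taxon else f"leaf{id(node)}"
            out[label] = seqs[id(node)]
    return out


def random_balanced_tree(
    n_leaves: int, rng: np.random.Generator, mean_branch: float = 0.2
) -> str:
    """Random-length balanced Newick tree with leaves t0..t{n-1}."""

    def build(labels: list[str]) -> str:
        if len(labels) == 1:
            return f"{labels[0]}:{rng.exponential(mean_branch):.6f}"
        mid = len(labels) // 2
        return (
            f"({build(labels[:mid])},{build(labels[mid:])})"
            f":{rng.exponential(mean_branch):.6f}"
        )

    return build([f"t{i}" for i in range(n_leaves)]) + ";"


# --- abundance matrices -----------------------------------------------------

def generate_abundance(cfg: SimConfig):
    """Case/control abundance matrix with study-block structure.

    Log-normal baselines per family, multiplicative log-normal block
    offsets, a planted fold change on the effect families in case samples,
    and zero-inflation at rate ``1 - ab_prevalence``. Returns
    ``(AbundanceMatrix, truth DataFrame)``; with ``ab_fold_change == 1``
    the truth table is empty (a pure null matrix).
    """
    from .model import AbundanceMatrix

    rng = np.random.default_rng(cfg.seed + 1)
    families = [f"AB{i:04d}" for i in range(cfg.ab_n_families)]
    samples = [f"S{i:04d}" for i in range(cfg.ab_n_samples)]
    blocks = {
        s: f"study{(i * cfg.ab_n_blocks) // cfg.ab_n_samples}"
        for i, s in enumerate(samples)
    }
    condition = {s: ("case" if i % 2 == 0 else "control") for i, s in enumerate(samples)}
    effect = families[: cfg.ab_n_effect_families] if cfg.ab_fold_change != 1.0 else []
    base_mu = rng.normal(0.0, 1.0, size=cfg.ab_n_families)
    block_names = sorted(set(blocks.values()))
    block_offset = {
        (f, b): rng.normal(0.0, cfg.ab_block_sigma)
        for f in range(cfg.ab_n_families)
        for b in block_names
    }
    log_fc = math.log(cfg.ab_fold_change)
    mat = np.zeros((cfg.ab_n_families, cfg.ab_n_samples))
    for j, s in enumerate(samples):
        b = blocks[s]
        is_case = condition[s] == "case"
        noise = rng.normal(0.0, cfg.ab_log_sigma, size=cfg.ab_n_families)
        present = rng.random(cfg.ab_n_families) < cfg.ab_prevalence
        logv = base_mu + np.array(
            [block_offset[(f, b)] for f in range(cfg.ab_n_families)]
        ) + noise
        if is_case:
            for f in range(len(effect)):
                logv[f] += log_fc
        mat[:, j] = np.where(present, np.exp(logv), 0.0)
    values = pd.DataFrame(mat, index=families, columns=samples)
    truth = pd.DataFrame(
        [
            {"family_id": f, "fold_change": cfg.ab_fold_change, "direction": "over"}
            for f in effect
        ]
    )
    matrix = AbundanceMatrix(
        values=values, condition=condition, block=blocks, habitat={}
    )
    return matrix, truth
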