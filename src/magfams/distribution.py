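"""Taxonomic breadth, novelty density, habitat breadth and mobility.

Groups the per-family distribution summaries: last-common-ancestor lineage
of the member genomes (optionally with relaxed member support), counts of
families per genome within clades, habitat breadth over sample detections,
plasmid/viral mobility aggregation, and the breadth-mobility association.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import RANKS, GeneFamily, GeneRecord, TaxonomyTable


def family_lca(
    family: GeneFamily,
    genes: Mapping[str, GeneRecord],
    taxonomy: TaxonomyTable,
    support: float = 1.0,
) -> tuple[str, tuple[str, ...]]:
    """Deepest lineage prefix shared by >= ``support`` of the members.

    ``support=1.0`` is the strict LCA; lowering it (the relaxed 0.8 variant)
    tolerates a small fraction of misannotated members. Returns
    ``(rank_name, lineage_prefix)``; rank is ``"root"`` for an empty prefix.
    The extension chosen at each level is the most frequent one (ties by
    name), so raising ``support`` can only truncate the result.
    """
    lineages = [taxonomy.lineage(genes[g].genome_id) for g in family.members]
    n = len(lineages)
    prefix: list[str] = []
    matching = lineages
    for level in range(len(RANKS)):
        counts: dict[str, int] = {}
        for lin in matching:
            counts[lin[level]] = counts.get(lin[level], 0) + 1
        best = max(sorted(counts), key=lambda k: counts[k])
        if counts[best] / n >= support:
            prefix.append(best)
            matching = [lin for lin in matching if lin[level] == best]
        else:
            break
    rank = RANKS[len(prefix) - 1] if prefix else "root"
    return rank, tuple(prefix)


def novelty_density(
    families: Iterable[GeneFamily],
    genes: Mapping[str, GeneRecord],
    taxonomy: TaxonomyTable,
    uncultivated: Optional[Mapping[str, bool]] = None,
    rank: str = "order",
) -> pd.DataFrame:
    """Per-clade novelty density: mean +- sd of distinct families per genome.

    Every genome in the taxonomy contributes (with 0 for genomes carrying
    no family). Columns: clade, n_genomes, mean_families, sd_families,
    fraction_uncultivated.
    """
    per_genome: dict[str, set[str]] = {g: set() for g in taxonomy.genome_ids}
    for fam in families:
        for gid in fam.members:
            genome = genes[gid].genome_id
            if genome in per_genome:
                per_genome[genome].add(fam.family_id)
    rows = []
    for clade, genome_ids in sorted(taxonomy.clades(rank).items()):
        counts = np.array([len(per_genome[g]) for g in genome_ids], dtype=float)
        sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
        frac_unc = (
            sum(1 for g in genome_ids if uncultivated.get(g, False)) / len(genome_ids)
            if uncultivated is not None
            else np.nan
        )
        rows.append(
            {
                "clade": clade,
                "n_genomes": len(genome_ids),
                "mean_families": float(np.mean(counts)),
                "sd_families": sd,
                "fraction_uncultivated": frac_unc,
            }
        )
    return pd.DataFrame(rows)


def mobility_flags(
    family: GeneFamily,
    genes: Mapping[str, GeneRecord],
    contig_flags: Mapping[str, Mapping[str, bool]],
    member_fraction: float = 0.0,
) -> tuple[bool, bool]:
    """(plasmid, viral) family flags.

    A flag is set when the fraction of members on flagged contigs exceeds
    ``member_fraction`` (strictly); the default 0 therefore means "at least
    one member", and 0.3 gives the stricter variant.
    """
    n = len(family.members)
    out = []
    for kind in ("plasmid", "viral"):
        hits = sum(
            1
            for gid in family.members
            if contig_flags.get(genes[gid].contig_id, {}).get(kind, False)
        )
        out.append(hits / n > member_fraction)
    return out[0], out[1]


def habitat_breadth(
    detections: pd.DataFrame,
    sample_meta: pd.DataFrame,
    min_samples: int = 10,
    min_habitats: int = 2,
    habitat_groups: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-family ecological breadth over sample detections.

    ``detections``: columns (family_id, sample_id), duplicates ignored;
    ``sample_meta``: columns (sample_id, habitat). A family is broadly
    distributed when detected in more than ``min_samples`` samples (strict)
    from at least ``min_habitats`` distinct habitats. ``habitat_groups``
    optionally coarse-grains habitat labels (unmapped -> "Other"); group
    counts are reported alongside the raw ones.
    """
    det = detections[["family_id", "sample_id"]].drop_duplicates()
    meta = sample_meta.set_index("sample_id")["habitat"]
    det = det.assign(habitat=det["sample_id"].map(meta))
    if det["habitat"].isna().any():
        missing = det.loc[det["habitat"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"sample {missing} missing from sample metadata")
    if habitat_groups is not None:
        det = det.assign(
            habitat_group=det["habitat"].map(lambda h: habitat_groups.get(h, "Other"))
        )
    else:
        det = det.assign(habitat_group=det["habitat"])
    grouped = det.groupby("family_id").agg(
        n_samples=("sample_id", "nunique"),
        n_habitats=("habitat", "nunique"),
        n_habitat_groups=("habitat_group", "nunique"),
    )
    grouped["broad_flag"] = (grouped["n_samples"] > min_samples) & (
        grouped["n_habitats"] >= min_habitats
    )
    return grouped.reset_index()


@dataclass
class BreadthMobilityResult:
    rho: float
    p_value: float
    degenerate: bool
    bin_table: pd.DataFrame  # rareness bin -> (mean n_habitats, mobile fraction)


def breadth_mobility_association(
    table: pd.DataFrame,
    n_bins: int = 3,
) -> BreadthMobilityResult:
    """Association between ecological breadth and mobility.

    ``table`` columns: n_samples, n_habitats, is_mobile (bool). Families are
    binned into ``n_bins`` rareness levels (quantiles of n_samples) for the
    per-bin mobile-fraction summary; the Spearman correlation between
    n_habitats and mobility is computed over the unbinned families. A
    constant input (all-mobile, none-mobile or constant breadth) makes the
    correlation undefined: reported as 0 with ``degenerate=True``.
    """
    mob = table["is_mobile"].astype(float)
    try:
        bins = pd.qcut(table["n_samples"], q=n_bins, duplicates="drop")
        bin_table = (
            table.assign(_bin=bins)
            .groupby("_bin", observed=True)
            .agg(
                mean_n_habitats=("n_habitats", "mean"),
                mobile_fraction=("is_mobile", "mean"),
                n_families=("is_mobile", "size"),
            )
            .reset_index(names="rareness_bin")
        )
    except ValueError:
        bin_table = pd.DataFrame()
    if mob.nunique() < 2 or table["n_habitats"].nunique() < 2:
        return BreadthMobilityResult(0.0, 1.0, True, bin_table)
    rho, p = stats.spearmanr(table["n_habitats"], mob)
    return BreadthMobilityResult(float(rho), float(p), False, bin_table)
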