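"""LCA breadth, novelty density, habitat breadth and mobility."""

import numpy as np
import pandas as pd
import pytest

from magfams import distribution as dist
from magfams.model import GeneFamily, TaxonomyTable, RANKS
from conftest import make_gene


def _lineage(*parts):
    filled = list(parts) + [f"x__{i}" for i in range(7 - len(parts))]
    return tuple(filled[:7])


def _tax(spec):
    """spec: genome -> tuple of leading lineage parts (rest auto-filled
    uniquely per genome so deeper ranks never collide by accident)."""
    return TaxonomyTable(
        {
            g: tuple(
                list(parts) + [f"{RANKS[i][0]}__{g}{i}" for i in
                               range(len(parts), 7)]
            )
            for g, parts in spec.items()
        }
    )


def _family(member_genomes):
    genes = {
        f"m{i}": make_gene(gene_id=f"m{i}", genome_id=g, contig_id=f"{g}_c",
                           start=i * 1000, end=i * 1000 + 300)
        for i, g in enumerate(member_genomes)
    }
    return GeneFamily(family_id="f", members=list(genes)), genes


class TestFamilyLCA:
    def test_two_species_one_genus(self):
        tax = TaxonomyTable({
            "G1": ("d__B", "p__P", "c__C", "o__O", "f__F", "g__G", "s__S1"),
            "G2": ("d__B", "p__P", "c__C", "o__O", "f__F", "g__G", "s__S2"),
        })
        fam, genes = _family(["G1", "G2"])
        rank, lineage = dist.family_lca(fam, genes, tax)
        assert rank == "genus"
        assert lineage[-1] == "g__G"

    def test_relaxed_support_masks_minority(self):
        spec = {f"G{i}": ("d__B", "p__A") for i in range(9)}
        spec["G9"] = ("d__B", "p__B")
        tax = _tax(spec)
        fam, genes = _family(list(spec))
        rank_strict, lin_strict = dist.family_lca(fam, genes, tax, support=1.0)
        rank_relaxed, lin_relaxed = dist.family_lca(fam, genes, tax, support=0.8)
        assert (rank_strict, lin_strict[-1]) == ("domain", "d__B")
        assert (rank_relaxed, lin_relaxed[1]) == ("phylum", "p__A")

    def test_single_species_family(self):
        tax = TaxonomyTable({
            "G1": ("d__B", "p__P", "c__C", "o__O", "f__F", "g__G", "s__S1"),
        })
        fam, genes = _family(["G1", "G1"])
        rank, lineage = dist.family_lca(fam, genes, tax)
        assert rank == "species"

    def test_support_monotonicity(self, rng, default_collection):
        c = default_collection
        genome_ids = c.taxonomy.genome_ids
        for _ in range(100):
            members = rng.choice(genome_ids, size=int(rng.integers(2, 12)))
            fam, genes = _family(list(members))
            _, strict = dist.family_lca(fam, genes, c.taxonomy, support=1.0)
            _, relaxed = dist.family_lca(fam, genes, c.taxonomy, support=0.8)
            assert len(relaxed) >= len(strict)
            assert relaxed[: len(strict)] == strict


class TestNoveltyDensity:
    def test_mean_and_sd_by_hand(self):
        tax = _tax({"G1": ("d__B", "p__P", "c__C", "o__O"),
                    "G2": ("d__B", "p__P", "c__C", "o__O")})
        fams = []
        genes = {}
        # G1 carries 3 families, G2 carries 5
        for i, (g, n) in enumerate([("G1", 3), ("G2", 5)]):
            for j in range(n):
                gid = f"{g}_f{j}"
                genes[gid] = make_gene(gene_id=gid, genome_id=g,
                                       contig_id=f"{g}_c", start=j * 1000,
                                       end=j * 1000 + 300)
        for j in range(5):
            members = [f"G2_f{j}"] + ([f"G1_f{j}"] if j < 3 else [])
            fams.append(GeneFamily(family_id=f"fam{j}", members=members))
        out = dist.novelty_density(fams, genes, tax, rank="order")
        row = out[out.clade == "o__O"].iloc[0]
        assert row.mean_families == 4.0
        assert row.sd_families == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_empty_clade_zero(self):
        tax = _tax({"G1": ("d__B", "p__P", "c__C", "o__O1"),
                    "G2": ("d__B", "p__P", "c__C", "o__O2")})
        gid = "G1_f0"
        genes = {gid: make_gene(gene_id=gid, genome_id="G1", contig_id="c",
                                start=0, end=300)}
        fams = [GeneFamily(family_id="fam", members=[gid])]
        out = dist.novelty_density(fams, genes, tax, rank="order")
        row = out[out.clade == "o__O2"].iloc[0]
        assert (row.mean_families, row.sd_families) == (0.0, 0.0)

    def test_genome_totals_conserved(self, default_collection):
        c = default_collection
        out = dist.novelty_density([], c.genes, c.taxonomy, rank="order")
        assert out.n_genomes.sum() == len(c.taxonomy)


class TestMobility:
    def _fam(self, n, flagged_idx, kind="plasmid"):
        genes = {
            f"m{i}": make_gene(gene_id=f"m{i}", genome_id="G", contig_id=f"c{i}",
                               start=0, end=300)
            for i in range(n)
        }
        flags = {
            f"c{i}": {"plasmid": kind == "plasmid" and i in flagged_idx,
                      "viral": kind == "viral" and i in flagged_idx}
            for i in range(n)
        }
        return GeneFamily(family_id="f", members=list(genes)), genes, flags

    def test_single_member_triggers_default(self):
        fam, genes, flags = self._fam(10, {0})
        assert dist.mobility_flags(fam, genes, flags) == (True, False)

    def test_strict_fraction_not_met(self):
        fam, genes, flags = self._fam(10, {0})
        assert dist.mobility_flags(fam, genes, flags, member_fraction=0.3) == (
            False, False)

    def test_no_flagged_contigs(self):
        fam, genes, flags = self._fam(5, set())
        assert dist.mobility_flags(fam, genes, flags) == (False, False)


class TestHabitatBreadth:
    def _run(self, pairs, habitats, **kw):
        det = pd.DataFrame(pairs, columns=["family_id", "sample_id"])
        meta = pd.DataFrame(
            [{"sample_id": s, "habitat": h} for s, h in habitats.items()]
        )
        return dist.habitat_breadth(det, meta, **kw)

    def test_broad_eleven_samples_two_habitats(self):
        habitats = {f"s{i}": ("gut" if i < 6 else "soil") for i in range(11)}
        out = self._run([("f", f"s{i}") for i in range(11)], habitats)
        assert bool(out.broad_flag.iloc[0]) is True

    def test_single_habitat_not_broad(self):
        habitats = {f"s{i}": "gut" for i in range(11)}
        out = self._run([("f", f"s{i}") for i in range(11)], habitats)
        assert bool(out.broad_flag.iloc[0]) is False

    def test_ten_samples_boundary_strict(self):
        habitats = {f"s{i}": f"h{i % 3}" for i in range(10)}
        out = self._run([("f", f"s{i}") for i in range(10)], habitats)
        assert bool(out.broad_flag.iloc[0]) is False

    def test_duplicate_detections_ignored(self):
        habitats = {f"s{i}": f"h{i % 2}" for i in range(12)}
        pairs = [("f", f"s{i}") for i in range(12)] * 3
        out = self._run(pairs, habitats)
        assert out.n_samples.iloc[0] == 12

    def test_coarse_grouping(self):
        habitats = {"s0": "gut metagenome", "s1": "human gut", "s2": "soil"}
        out = self._run(
            [("f", "s0"), ("f", "s1"), ("f", "s2")], habitats,
            habitat_groups={"gut metagenome": "Human gut",
                            "human gut": "Human gut"},
        )
        assert out.n_habitats.iloc[0] == 3
        assert out.n_habitat_groups.iloc[0] == 2  # Human gut + Other


class TestBreadthMobility:
    def _table(self, n, mobile_fn, rng):
        n_samples = rng.integers(1, 100, size=n)
        n_habitats = 1 + (n_samples // 10)
        return pd.DataFrame({
            "n_samples": n_samples,
            "n_habitats": n_habitats,
            "is_mobile": [mobile_fn(h, rng) for h in n_habitats],
        })

    def test_null_association_near_zero(self, rng):
        table = self._table(1000, lambda h, r: bool(r.random() < 0.3), rng)
        res = dist.breadth_mobility_association(table)
        assert not res.degenerate
        assert abs(res.rho) < 0.1

    def test_planted_association_detected(self, rng):
        table = self._table(
            1000, lambda h, r: bool(r.random() < min(0.9, h / 10)), rng
        )
        res = dist.breadth_mobility_association(table)
        assert res.rho > 0.5
        assert len(res.bin_table) == 3

    def test_constant_mobility_degenerate(self, rng):
        table = self._table(100, lambda h, r: True, rng)
        res = dist.breadth_mobility_association(table)
        assert res.degenerate
        assert res.rho == 0.0
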