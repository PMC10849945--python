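import numpy as np
import pytest

from magfams import simulate as sim


@pytest.fixture(scope="session")
def default_collection():
    """One default synthetic pangenome shared by read-only tests."""
    return sim.generate_collection(sim.SimConfig(seed=101))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_gene(gene_id="g1", genome_id="G1", contig_id="c1", start=0, end=300,
              strand="+", **kw):
    from magfams.model import GeneRecord

    return GeneRecord(
        gene_id=gene_id, genome_id=genome_id, contig_id=contig_id,
        start=start, end=end, strand=strand, **kw,
    )


def toy_taxonomy(genome_species):
    """Taxonomy where each genome maps to a one-of-two-phyla lineage.

    ``genome_species``: genome_id -> species token; lineages are derived
    deterministically from the token's first letter (A* -> phylum pA,
    otherwise pB).
    """
    from magfams.model import TaxonomyTable

    lineages = {}
    for g, sp in genome_species.items():
        ph = "p__A" if sp.startswith("A") else "p__B"
        lineages[g] = (
            "d__Bacteria", ph, f"c__{ph[3:]}c", f"o__{ph[3:]}o",
            f"f__{sp}f", f"g__{sp}g", f"s__{sp}",
        )
    return TaxonomyTable(lineages)
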