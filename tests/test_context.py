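"""Genomic-context scores, calibration and prediction."""

import pytest

from magfams import context as ctx
from magfams.model import ContextProfile
from conftest import make_gene


def _contig(spec, contig="c1"):
    """spec: list of (gene_id, start, end, strand, pathways)."""
    genes = []
    for i, (gid, start, end, strand, pw) in enumerate(spec):
        genes.append(
            make_gene(gene_id=gid, contig_id=contig, start=start, end=end,
                      strand=strand, pathways=set(pw), rank_on_contig=i)
        )
    return genes


class TestNeighborhood:
    def test_edge_truncation_at_contig_start(self):
        genes = _contig([(f"g{i}", i * 400, i * 400 + 300, "+", []) for i in range(10)])
        nb = ctx.extract_neighborhood(genes[0], genes)
        assert sorted(nb.neighbors) == [1, 2, 3]

    def test_mid_contig_has_six_neighbors(self):
        genes = _contig([(f"g{i}", i * 400, i * 400 + 300, "+", []) for i in range(10)])
        nb = ctx.extract_neighborhood(genes[5], genes)
        assert sorted(nb.neighbors) == [-3, -2, -1, 1, 2, 3]

    def test_gaps_match_hand_computation(self):
        # starts/ends chosen so gaps are 50, -10 (overlap), 120
        genes = _contig([
            ("g0", 0, 300, "+", []),
            ("g1", 350, 650, "+", []),
            ("g2", 640, 940, "+", []),
            ("g3", 1060, 1360, "+", []),
        ])
        nb = ctx.extract_neighborhood(genes[0], genes)
        assert nb.neighbors[1].gap_toward_focal == 50
        assert nb.neighbors[2].gap_toward_focal == -10
        assert nb.neighbors[3].gap_toward_focal == 120
        assert nb.reachable(1, 100) and nb.reachable(2, 100)
        assert not nb.reachable(3, 100)


def _member(pathway_positions, strands=None, gaps=None, focal_strand="+",
            contig="c"):
    """One member neighbourhood: 7-gene contig, focal at rank 3."""
    spec = []
    cursor = 0
    gaps = gaps or {}
    for i in range(7):
        gap = gaps.get(i - 3, 50)
        start = cursor + gap if i else 0
        pw = pathway_positions.get(i - 3, [])
        strand = (strands or {}).get(i - 3, focal_strand)
        spec.append((f"{contig}_g{i}", start, start + 300, strand, pw))
        cursor = start + 300
    genes = _contig(spec, contig=contig)
    return ctx.extract_neighborhood(genes[3], genes)


class TestScores:
    def test_synteny_three_of_four_members(self):
        nbs = [_member({1: ["P"]}, contig=f"m{i}") for i in range(3)]
        nbs.append(_member({}, contig="m3"))
        assert ctx.synteny_conservation(nbs, "P") == 0.75

    def test_synteny_zero_without_annotations(self):
        nbs = [_member({}, contig=f"m{i}") for i in range(4)]
        assert ctx.synteny_conservation(nbs, "P") == 0.0

    def test_relatedness_pooled_denominator(self):
        # 2 members x 6 neighbours = 12 pooled, 6 in P
        nbs = [
            _member({-1: ["P"], 1: ["P"], 2: ["P"]}, contig=f"m{i}")
            for i in range(2)
        ]
        assert ctx.functional_relatedness(nbs, "P") == 0.5

    def test_strand_two_of_four_same(self):
        nbs = [
            _member({1: ["P"], -1: ["P"]},
                    strands={1: "+", -1: "-"}, contig=f"m{i}")
            for i in range(2)
        ]
        assert ctx.strand_conservation(nbs, "P") == 0.5

    def test_strand_zero_without_p_neighbors(self):
        nbs = [_member({}, contig="m0")]
        assert ctx.strand_conservation(nbs, "P") == 0.0

    def test_distance_chain_rule(self):
        # +1 at gap 30, +2 behind a 150 nt gap: chain broken for +2
        nb = _member({1: ["P"], 2: ["P"]}, gaps={1: 30, 2: 150})
        assert ctx.distance_conservation([nb], "P") == 0.5

    def test_overlapping_gene_counts(self):
        nb = _member({1: ["P"]}, gaps={1: -20})
        assert ctx.distance_conservation([nb], "P") == 1.0

    def test_scores_monotone_when_p_neighbor_added(self):
        base = [_member({1: ["P"]}, contig="m0"), _member({}, contig="m1")]
        more = [_member({1: ["P"]}, contig="m0"),
                _member({2: ["P"]}, contig="m1")]
        assert ctx.synteny_conservation(more, "P") >= ctx.synteny_conservation(base, "P")
        assert ctx.functional_relatedness(more, "P") >= ctx.functional_relatedness(base, "P")


class TestCalibration:
    def _profiles(self, scores, pathway="P"):
        return [
            ContextProfile(
                family_id=f"f{i}", pathway_id=pathway,
                synteny_conservation=s, functional_relatedness=s,
                strand_conservation=s, distance_conservation=s,
            )
            for i, s in enumerate(scores)
        ]

    def test_quantile_thresholds_from_worked_example(self):
        cal = ctx.calibrate_thresholds(
            self._profiles([1.0, 1.0, 0.8, 0.6]), n_min=4
        )["P"]
        assert cal.thresholds[0.5][0] == 0.8
        assert cal.thresholds[0.9][0] == 0.6

    def test_all_scores_one_gives_threshold_one(self):
        cal = ctx.calibrate_thresholds(self._profiles([1.0] * 5))["P"]
        assert cal.thresholds[0.5] == (1.0,) * 4
        assert cal.thresholds[0.9] == (1.0,) * 4

    def test_higher_level_never_stricter(self, rng):
        scores = list(rng.random(20))
        cal = ctx.calibrate_thresholds(self._profiles(scores))["P"]
        assert all(
            t9 <= t5 for t9, t5 in zip(cal.thresholds[0.9], cal.thresholds[0.5])
        )

    def test_pathway_below_n_min_not_calibrated(self):
        assert ctx.calibrate_thresholds(self._profiles([1.0] * 4), n_min=5) == {}


class TestPrediction:
    def _cal(self, thr05, thr09):
        return {
            "P": ctx.PathwayCalibration(
                "P", {0.5: (thr05,) * 4, 0.9: (thr09,) * 4}, 10
            )
        }

    def _prof(self, s):
        return [ContextProfile("f", "P", s, s, s, s)]

    def test_meets_both_levels_reports_highest(self):
        hits = ctx.predict_pathway_associations(self._prof(0.9),
                                                self._cal(0.5, 0.8))
        assert [(h[0], h[1]) for h in hits] == [("P", 0.9)]

    def test_meets_only_lower_level(self):
        hits = ctx.predict_pathway_associations(self._prof(0.6),
                                                self._cal(0.5, 0.8))
        assert [(h[0], h[1]) for h in hits] == [("P", 0.5)]

    def test_below_all_thresholds_is_empty(self):
        assert ctx.predict_pathway_associations(self._prof(0.3),
                                                self._cal(0.5, 0.8)) == []


class TestResistanceNeighbors:
    def _nb(self, res_positions, contig):
        nb = _member({}, contig=contig)
        for pos in res_positions:
            nb.neighbors[pos].gene.is_resistance = True
        return nb

    def test_conserved_position_counted(self):
        nbs = [self._nb([1], f"m{i}") for i in range(5)]
        assert ctx.count_resistance_neighbors(nbs, 0.8) == 1

    def test_no_resistance_flags(self):
        nbs = [self._nb([], f"m{i}") for i in range(5)]
        assert ctx.count_resistance_neighbors(nbs, 0.8) == 0

    def test_two_conserved_positions(self):
        nbs = [self._nb([1, -2], f"m{i}") for i in range(5)]
        assert ctx.count_resistance_neighbors(nbs, 0.8) == 2

    def test_fraction_threshold(self):
        nbs = [self._nb([1], f"m{i}") for i in range(3)]
        nbs += [self._nb([], f"m{i+3}") for i in range(2)]
        assert ctx.count_resistance_neighbors(nbs, 0.8) == 0
        assert ctx.count_resistance_neighbors(nbs, 0.6) == 1


class TestPositionalSynteny:
    def _nb(self, ko_map, contig):
        nb = _member({}, contig=contig)
        for pos, ko in ko_map.items():
            nb.neighbors[pos].gene.ko = ko
        return nb

    def test_identical_adjacent_neighbors(self):
        nbs = [self._nb({1: "K1", -1: "K2"}, f"m{i}") for i in range(4)]
        assert ctx.positional_synteny(nbs) == 1.0

    def test_half_shared_plus_one_unlabeled_minus_one(self):
        nbs = [self._nb({1: "K1"}, "m0"), self._nb({1: "K1"}, "m1"),
               self._nb({1: "K9"}, "m2"), self._nb({1: "K8"}, "m3")]
        # +1 modal label covers 2/4 members -> 0.5; -1 unlabeled -> 0
        assert ctx.positional_synteny(nbs) == 0.25

    def test_random_labels_approach_uniform_expectation(self, rng):
        n_labels = 5
        nbs = [
            self._nb({1: f"K{rng.integers(n_labels)}",
                      -1: f"K{rng.integers(n_labels)}"}, f"m{i}")
            for i in range(500)
        ]
        val = ctx.positional_synteny(nbs)
        # modal share of 500 uniform draws over 5 labels is near 1/5
        assert 0.15 < val < 0.3


class TestEndToEnd:
    def test_planted_families_recovered_nulls_rejected(self, default_collection):
        c = default_collection
        truth = c.truth["families"]
        known = truth[truth.kind == "known"]
        profiles = []
        for fam_id, pw in zip(known.family_id, known.pathway):
            nbs = c.family_neighborhoods(fam_id)
            profiles.extend(ctx.compute_context_profiles(fam_id, nbs, pathways=[pw]))
        predictor = ctx.ContextPredictor().fit(profiles)
        ops = truth[truth.kind == "operon"]
        recovered = 0
        for fam_id, pw in zip(ops.family_id, ops.pathway):
            prof = ctx.compute_context_profiles(
                fam_id, c.family_neighborhoods(fam_id)
            )
            hits = predictor.predict(prof)
            if any(h[0] == pw and h[1] == 0.9 for h in hits):
                recovered += 1
        assert recovered >= 0.95 * len(ops)
        nulls = truth[truth.kind == "null"]
        fp = sum(
            bool(
                predictor.predict(
                    ctx.compute_context_profiles(f, c.family_neighborhoods(f))
                )
            )
            for f in nulls.family_id
        )
        assert fp <= 0.05 * len(nulls)
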