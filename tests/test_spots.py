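import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from snpsom.annotation import AssociationCatalog
from snpsom.portrayal import Portrait
from snpsom.som import SomConfig, SomModel
from snpsom.spots import (
    SummaryMap,
    background_distribution,
    enrich_terms,
    fisher_greater,
    segment_spots,
    spot_profile,
    summary_map,
)
from snpsom.synthetic import leaf_terms, make_ontology_fixture

from .conftest import matrix_from_scores
from .oracles import hypergeom_upper_tail_exact
from .test_portrayal import manual_model


def mean_p(grid):
    return Portrait(grid=np.asarray(grid, dtype=float), subject="g", kind="mean")


def mapped_catalog(pairs, graph=None):
    """Catalog from (snp, leaf_term) pairs, mapped through a fixture ontology."""
    graph = graph or make_ontology_fixture()
    records = pd.DataFrame(
        [(s, t, None, "t") for s, t in pairs],
        columns=["snp_id", "term_id", "gene", "source"],
    )
    return AssociationCatalog(records=records).map_terms(graph)


class TestSummaryMap:
    def test_single_portrait_identity(self):
        p = mean_p([[0.5, 1.5]])
        np.testing.assert_allclose(summary_map([p]).grid, p.grid)

    def test_elementwise_max(self):
        out = summary_map([mean_p([[0.0, 2.0]]), mean_p([[2.0, 0.0]])])
        np.testing.assert_allclose(out.grid, [[2.0, 2.0]])

    def test_dominates_inputs(self):
        rng = np.random.default_rng(0)
        ps = [mean_p(rng.uniform(0, 2, (5, 5))) for _ in range(4)]
        out = summary_map(ps)
        for p in ps:
            assert (out.grid >= p.grid).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            summary_map([mean_p([[0.0]]), mean_p([[0.0, 1.0]])])


class TestSegmentSpots:
    def grid_model(self, rows, cols, n_snps, rng=None):
        rng = rng or np.random.default_rng(0)
        assignment = rng.integers(0, rows * cols, size=n_snps)
        return manual_model(rows, cols, assignment, 2), [f"rs{i}" for i in range(n_snps)]

    def test_uniform_map_yields_no_spots(self):
        model, ids = self.grid_model(4, 4, 30)
        spots = segment_spots(SummaryMap(np.ones((4, 4))), model, ids)
        assert len(spots) == 0

    def test_two_plateaus_two_spots(self):
        grid = np.zeros((10, 10))
        grid[1:3, 1:4] = 2.0  # 6 units
        grid[7:9, 6:9] = 1.8  # 6 units
        model = manual_model(10, 10, np.arange(100), 2)
        ids = [f"rs{i}" for i in range(100)]
        spots = segment_spots(SummaryMap(grid), model, ids, threshold_quantile=0.8, min_units=5)
        assert len(spots) == 2
        assert spots.spots[0].peak == 2.0  # A = highest peak
        assert spots.spots[1].peak == 1.8
        assert {len(s.units) for s in spots} == {6}

    def test_min_units_filters_small_plateau(self):
        grid = np.zeros((6, 6))
        grid[0, :3] = 2.0  # 3 units only
        model = manual_model(6, 6, np.arange(36), 2)
        spots = segment_spots(
            SummaryMap(grid), model, [f"rs{i}" for i in range(36)], 0.8, min_units=5
        )
        assert len(spots) == 0

    def test_member_snps_from_assignment(self):
        grid = np.zeros((4, 4))
        grid[0, 0:3] = 2.0
        grid[1, 0:3] = 2.0
        # 5 SNPs in unit 0 (=cell 0,0), 1 in unit 5 (=cell 1,1), rest far away
        assignment = [0, 0, 0, 0, 0, 5, 15, 15, 15]
        model = manual_model(4, 4, assignment, 2)
        ids = [f"rs{i}" for i in range(9)]
        spots = segment_spots(SummaryMap(grid), model, ids, 0.6, min_units=5)
        assert len(spots) == 1
        assert sorted(spots.spots[0].member_snps) == ["rs0", "rs1", "rs2", "rs3", "rs4", "rs5"]

    def test_disjoint_units_and_members(self):
        rng = np.random.default_rng(5)
        grid = rng.uniform(0, 2, (12, 12))
        model, ids = self.grid_model(12, 12, 400, rng)
        spots = segment_spots(SummaryMap(grid), model, ids, 0.7, min_units=2)
        seen_units, seen_snps = set(), set()
        for s in spots:
            assert not (s.units & seen_units)
            assert not (set(s.member_snps) & seen_snps)
            seen_units |= s.units
            seen_snps |= set(s.member_snps)

    def test_param_validation(self):
        model, ids = self.grid_model(3, 3, 5)
        with pytest.raises(ValueError):
            segment_spots(SummaryMap(np.zeros((3, 3))), model, ids, 1.5)
        with pytest.raises(ValueError):
            segment_spots(SummaryMap(np.zeros((3, 3))), model, ids, 0.5, min_units=0)


class TestSpotProfile:
    def make_spot(self, members):
        from snpsom.spots import Spot

        return Spot(label="A", units={(0, 0)}, member_snps=members, peak=2.0)

    def test_all_two_in_group(self):
        matrix = matrix_from_scores([[2, 2, 0], [2, 2, 0]], populations=["G", "G", "H"])
        spot = self.make_spot(["rs1", "rs2"])
        group, sample = spot_profile(spot, matrix, "population")
        assert group["G"] == 2.0
        assert group["H"] == 0.0

    def test_single_member_equals_row(self):
        matrix = matrix_from_scores([[0, 1, 2], [2, 2, 2]])
        spot = self.make_spot(["rs1"])
        _, sample = spot_profile(spot, matrix, "population")
        np.testing.assert_allclose(sample.to_numpy(), [0, 1, 2])

    def test_complementary_pair(self):
        matrix = matrix_from_scores([[0, 2], [2, 0]])
        spot = self.make_spot(["rs1", "rs2"])
        _, sample = spot_profile(spot, matrix, "population")
        np.testing.assert_allclose(sample.to_numpy(), [1.0, 1.0])

    def test_missing_member_errors(self):
        matrix = matrix_from_scores([[0, 1]])
        with pytest.raises(KeyError):
            spot_profile(self.make_spot(["zzz"]), matrix, "population")


class TestFisherGreater:
    def test_example_table_matches_exact_enumeration(self):
        p = float(fisher_greater(8, 12, 20, 160))
        exact = float(hypergeom_upper_tail_exact(8, 12, 20, 160))
        assert p == pytest.approx(exact, abs=1e-12)

    def test_matches_scipy_fisher_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 30, size=4)
            ours = float(fisher_greater(a, b, c, d))
            theirs = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_extreme_table_is_minimal_for_margins(self):
        # all annotated SNPs inside the spot: smallest p over all same-margin tables
        n_total, n_annot, n_spot = 12, 4, 5
        ps = []
        for a in range(max(0, n_annot + n_spot - n_total), min(n_annot, n_spot) + 1):
            ps.append(
                float(fisher_greater(a, n_spot - a, n_annot - a, n_total - n_spot - n_annot + a))
            )
        assert ps[-1] == min(ps)
        exact = hypergeom_upper_tail_exact(4, 1, 0, 7)
        assert ps[-1] == pytest.approx(float(exact), abs=1e-12)

    def test_zero_annotated_in_spot_gives_one(self):
        assert float(fisher_greater(0, 10, 5, 85)) == pytest.approx(1.0)

    def test_monotone_in_overlap(self):
        # moving one annotated SNP into the spot never increases p
        prev = 1.1
        for a in range(0, 10):
            p = float(fisher_greater(a, 10 - a, 10 - a, 80 + a))
            assert p <= prev + 1e-15
            prev = p


class TestEnrichTerms:
    def build(self, spot_members, annotations, universe):
        from snpsom.spots import Spot, SpotSet

        spots = SpotSet(
            spots=[
                Spot(label=l, units={(i, 0)}, member_snps=m, peak=2.0)
                for i, (l, m) in enumerate(spot_members.items())
            ],
            threshold=0.0,
            quantile=0.9,
        )
        return spots, mapped_catalog(annotations), universe

    def test_contingency_counts_sum_to_universe(self):
        graph = make_ontology_fixture()
        leaves = leaf_terms(graph)
        universe = [f"rs{i}" for i in range(40)]
        annotations = [(f"rs{i}", leaves[i % 3]) for i in range(0, 40, 2)]
        spots, catalog, universe = self.build(
            {"A": universe[:10], "B": universe[10:18]}, annotations, universe
        )
        result = enrich_terms(spots, catalog, universe)
        assert len(result)
        totals = result[["in_annot", "in_other", "out_annot", "out_other"]].sum(axis=1)
        assert (totals == 40).all()
        assert result["p_value"].between(0, 1).all()
        assert result["p_bh"].between(0, 1).all()

    def test_planted_term_is_top_hit(self):
        graph = make_ontology_fixture()
        leaves = leaf_terms(graph)
        universe = [f"rs{i}" for i in range(60)]
        # spot A holds all 12 SNPs of leaves[0]; background annotated elsewhere
        annotations = [(f"rs{i}", leaves[0]) for i in range(12)]
        annotations += [(f"rs{i}", leaves[5]) for i in range(12, 60, 3)]
        spots, catalog, universe = self.build({"A": universe[:12]}, annotations, universe)
        result = enrich_terms(spots, catalog, universe)
        top = result.iloc[0]
        want = sorted(graph.ancestors_at_depth(leaves[0], 3))[0]
        assert top["term"] == want
        assert top["p_value"] < 1e-6

    def test_snp_counted_once_per_term(self):
        graph = make_ontology_fixture()
        leaf = leaf_terms(graph)[0]
        universe = [f"rs{i}" for i in range(10)]
        annotations = [("rs0", leaf), ("rs0", leaf)]
        spots, catalog, universe = self.build({"A": universe[:3]}, annotations, universe)
        result = enrich_terms(spots, catalog, universe)
        assert result["in_annot"].max() == 1
        assert (result["in_annot"] + result["out_annot"]).max() == 1

    def test_term_without_universe_snps_skipped(self):
        graph = make_ontology_fixture()
        leaves = leaf_terms(graph)
        universe = [f"rs{i}" for i in range(5)]
        annotations = [("rs0", leaves[0]), ("absent_snp", leaves[-1])]
        spots, catalog, universe = self.build({"A": universe[:2]}, annotations, universe)
        result = enrich_terms(spots, catalog, universe)
        mapped_absent = {
            sorted(graph.ancestors_at_depth(leaves[-1], 3))[0],
        }
        assert not set(result["term"]) & mapped_absent


class TestBackgroundDistribution:
    def test_empty_universe(self):
        catalog = mapped_catalog([("rs1", leaf_terms(make_ontology_fixture())[0])])
        assert background_distribution(catalog, []).sum() == 0

    def test_one_snp_two_terms(self):
        graph = make_ontology_fixture()
        leaves = leaf_terms(graph)
        catalog = mapped_catalog([("rs1", leaves[0]), ("rs1", leaves[-1])], graph)
        counts = background_distribution(catalog, ["rs1"])
        assert (counts == 1).all()
        assert len(counts) == 2

    def test_duplicate_rows_do_not_inflate(self):
        graph = make_ontology_fixture()
        leaf = leaf_terms(graph)[0]
        catalog = mapped_catalog([("rs1", leaf), ("rs1", leaf)], graph)
        counts = background_distribution(catalog, ["rs1", "rs2"])
        assert counts.max() == 1
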