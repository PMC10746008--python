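import numpy as np
import pytest

from ecotyping.binning import DEFAULT_CRITERIA, BinningCurve, binning_curve
from ecotyping.ecosim import MatchRule
from ecotyping.fit_demarcate import (
    CI_THRESHOLD,
    DemarcationConfig,
    NewickParseError,
    default_depth,
    demarcate,
    fit_parameters,
    nj_tree,
    parse_newick,
    profile_ci,
    write_newick,
)
from ecotyping.seq_core import (
    Alignment,
    DistanceMatrix,
    SequenceRecord,
    distance_matrix,
)
from ecotyping.synthetic_data import SynthConfig, simulate_ecotype_alignment


def tip_distances(tree):
    """Leaf-to-leaf path lengths through the rooted tree."""
    tips = list(tree.tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            out[frozenset((a.name, b.name))] = a.distance(b)
    return out


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        d = np.array([[0, 0.2, 0.3], [0.2, 0, 0.3], [0.3, 0.3, 0]])
        dm = DistanceMatrix(ids=list("ABC"), data=d, kind="jc_corrected")
        tree = nj_tree(dm)
        dists = tip_distances(tree)
        assert dists[frozenset("AB")] == pytest.approx(0.2)
        assert dists[frozenset("AC")] == pytest.approx(0.3)
        assert dists[frozenset("BC")] == pytest.approx(0.3)

    def test_four_taxon_additive_matrix_reconstructed(self):
        # tree ((A:1,B:2):1,(C:3,D:4):1) scaled by 0.01
        d = 0.01 * np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(ids=list("ABCD"), data=d, kind="jc_corrected")
        dists = tip_distances(nj_tree(dm))
        for pair, value in dists.items():
            a, b = sorted(pair)
            i, j = "ABCD".index(a), "ABCD".index(b)
            assert value == pytest.approx(d[i, j], abs=1e-12)

    def test_star_matrix_equal_pendants(self):
        n = 5
        d = np.full((n, n), 0.1)
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(ids=[f"t{i}" for i in range(n)], data=d)
        tree = nj_tree(dm)
        dists = tip_distances(tree)
        assert all(v == pytest.approx(0.1) for v in dists.values())

    def test_two_taxa_returned_as_cherry(self):
        dm = DistanceMatrix(ids=["a", "b"], data=np.array([[0, 0.04], [0.04, 0]]))
        tree = nj_tree(dm)
        assert sorted(tree.leaf_labels()) == ["a", "b"]
        assert tip_distances(tree)[frozenset(("a", "b"))] == pytest.approx(0.04)


class TestNewickIO:
    def test_parse_simple_tree(self):
        tree = parse_newick("((A:0.1,B:0.1):0.05,C:0.15);")
        assert sorted(tree.leaf_labels()) == ["A", "B", "C"]

    def test_roundtrip_preserves_topology_and_lengths(self):
        text = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.07);"
        once = write_newick(parse_newick(text))
        twice = write_newick(parse_newick(once))
        assert once == twice
        d1 = tip_distances(parse_newick(once))
        d2 = tip_distances(parse_newick(text))
        for k in d2:
            assert d1[k] == pytest.approx(d2[k])

    def test_missing_branch_lengths_read_as_zero(self):
        tree = parse_newick("((A,B),C);")
        assert all(
            node.length == 0.0 for node in tree.tree.traverse() if node.parent
        )

    def test_duplicate_labels_rejected(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A:1,B:1):1,A:2);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A:1,B:1):1;")


class TestFitParameters:
    def test_degenerate_curve_fits_single_ecotype(self):
        observed = BinningCurve(DEFAULT_CRITERIA, tuple(1 for _ in DEFAULT_CRITERIA))
        fit = fit_parameters(observed, n=10, depth=0.01, L=300, R=40, restarts=1, seed=0)
        assert fit.best.npop == 1
        assert fit.likelihood > 0.5

    def test_seeded_fit_is_reproducible(self):
        observed = BinningCurve(DEFAULT_CRITERIA, (6, 2, 2, 2, 2, 2, 2, 1, 1, 1))
        fits = [
            fit_parameters(observed, n=12, depth=0.02, L=300, R=40, restarts=1, seed=9)
            for _ in range(2)
        ]
        assert fits[0].best == fits[1].best
        assert fits[0].likelihood == fits[1].likelihood

    def test_more_replicates_do_not_collapse_likelihood(self):
        # doubling R changes the estimate by at most a couple of MC errors
        observed = BinningCurve(DEFAULT_CRITERIA, (6, 2, 2, 2, 2, 2, 2, 1, 1, 1))
        f1 = fit_parameters(observed, n=12, depth=0.02, L=300, R=60, restarts=1, seed=4)
        f2 = fit_parameters(observed, n=12, depth=0.02, L=300, R=120, restarts=1, seed=4)
        se = np.sqrt(max(f1.likelihood, 1e-3) * 1.0 / 60)
        assert f2.likelihood >= f1.likelihood - 3 * se


class TestProfileCI:
    def test_flat_likelihood_spans_grid(self):
        observed = BinningCurve(DEFAULT_CRITERIA, tuple(1 for _ in DEFAULT_CRITERIA))
        from ecotyping.ecosim import EcosimParams

        best = EcosimParams(omega=1.0, sigma=1e9, npop=1)
        lo, hi = profile_ci(
            best, "sigma", observed, R=30, n=6, depth=0.01, L=200,
            rule=MatchRule(tolerance=float("inf")), seed=0,
        )
        assert lo == pytest.approx(1e8)
        assert hi == pytest.approx(1e10)

    def test_interval_contains_best_and_widens_with_threshold(self):
        from ecotyping.ecosim import EcosimParams

        observed = BinningCurve(DEFAULT_CRITERIA, (4, 2, 2, 2, 2, 2, 2, 1, 1, 1))
        best = EcosimParams(omega=0.01, sigma=800.0, npop=2)
        kwargs = dict(observed=observed, R=60, n=8, depth=0.02, L=300, seed=3)
        strict = profile_ci(best, "npop", threshold=0.5, **kwargs)
        loose = profile_ci(best, "npop", threshold=0.05, **kwargs)
        assert strict[0] <= 2 <= strict[1]
        assert loose[0] <= strict[0] and loose[1] >= strict[1]


class TestDemarcation:
    def test_identical_sequences_single_ecotype(self):
        aln = Alignment([SequenceRecord(f"s{i}", "ACGT" * 50) for i in range(6)])
        d = np.zeros((6, 6))
        dm = DistanceMatrix(ids=aln.ids, data=d, kind="jc_corrected")
        tree = nj_tree(
            DistanceMatrix(ids=aln.ids, data=d + 1e-9 * (1 - np.eye(6)), kind="jc_corrected")
        )
        from ecotyping.fit_demarcate import FitResult
        from ecotyping.ecosim import EcosimParams

        fit = FitResult(best=EcosimParams(0.1, 1000.0, 1), likelihood=0.5)
        dem = demarcate(tree, aln, fit, DemarcationConfig(R=30, seed=0))
        assert dem.n_ecotypes() == 1
        assert set(dem.assignments) == set(aln.ids)

    def test_recovers_generated_ecotypes(self, four_ecotype_data):
        aln, labels = four_ecotype_data
        dm_jc = distance_matrix(aln, kind="jc_corrected")
        curve = binning_curve(distance_matrix(aln))
        fit = fit_parameters(
            curve, n=len(aln), depth=default_depth(dm_jc.data), L=aln.length,
            R=100, restarts=1, seed=2,
        )
        dem = demarcate(nj_tree(dm_jc), aln, fit, DemarcationConfig(R=150, seed=2))
        assert dem.n_ecotypes() == 4
        # each demarcated clade coincides with one generated ecotype
        for clade in dem.clades:
            assert len({labels[m] for m in clade.members}) == 1

    def test_well_separated_clades_never_merge(self, four_ecotype_data):
        aln, labels = four_ecotype_data
        dm_jc = distance_matrix(aln, kind="jc_corrected")
        curve = binning_curve(distance_matrix(aln))
        fit = fit_parameters(
            curve, n=len(aln), depth=default_depth(dm_jc.data), L=aln.length,
            R=100, restarts=1, seed=5,
        )
        dem = demarcate(nj_tree(dm_jc), aln, fit, DemarcationConfig(R=150, seed=5))
        for clade in dem.clades:
            assert len({labels[m] for m in clade.members}) == 1

    def test_partition_and_hierarchy_invariants(self, four_ecotype_data):
        aln, _ = four_ecotype_data
        dm_jc = distance_matrix(aln, kind="jc_corrected")
        tree = nj_tree(dm_jc)
        from ecotyping.fit_demarcate import FitResult
        from ecotyping.ecosim import EcosimParams

        fit = FitResult(best=EcosimParams(0.5, 1300.0, 4), likelihood=0.1)
        dem = demarcate(tree, aln, fit, DemarcationConfig(R=100, seed=1))
        # partition: every leaf exactly once
        members = [m for c in dem.clades for m in c.members]
        assert sorted(members) == sorted(tree.leaf_labels())
        # hierarchical consistency: each ecotype is the leaf set of one node
        node_leafsets = {
            frozenset(t.name for t in node.tips()) or frozenset((node.name,))
            for node in tree.tree.traverse()
        }
        for clade in dem.clades:
            assert frozenset(clade.members) in node_leafsets

    def test_seeded_demarcation_reproducible(self, four_ecotype_data):
        aln, _ = four_ecotype_data
        dm_jc = distance_matrix(aln, kind="jc_corrected")
        tree = nj_tree(dm_jc)
        from ecotyping.fit_demarcate import FitResult
        from ecotyping.ecosim import EcosimParams

        fit = FitResult(best=EcosimParams(0.5, 1300.0, 4), likelihood=0.1)
        runs = [
            demarcate(tree, aln, fit, DemarcationConfig(R=100, seed=8))
            for _ in range(2)
        ]
        assert runs[0].assignments == runs[1].assignments

    def test_missing_leaf_rejected(self, four_ecotype_data):
        aln, _ = four_ecotype_data
        sub = aln.subset(aln.ids[:-1])
        dm_jc = distance_matrix(aln, kind="jc_corrected")
        tree = nj_tree(dm_jc)
        from ecotyping.fit_demarcate import FitResult
        from ecotyping.ecosim import EcosimParams

        fit = FitResult(best=EcosimParams(0.5, 1300.0, 4), likelihood=0.1)
        with pytest.raises(ValueError):
            demarcate(tree, sub, fit, DemarcationConfig(R=20, seed=0))
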