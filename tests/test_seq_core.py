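import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecotyping.seq_core import (
    Alignment,
    AlignmentShapeError,
    DegenerateComparisonError,
    SaturationError,
    SequenceRecord,
    clone_tally,
    dilution_density_bound,
    distance_matrix,
    group_divergence,
    hamming_differences,
    jc_distance,
    pairwise_identity,
    read_fasta,
    write_fasta,
)

from conftest import random_seq


def naive_hamming(a: str, b: str):
    """Column-by-column brute-force oracle under pairwise deletion."""
    n_diff = n_comp = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            n_comp += 1
            n_diff += x != y
    return n_diff, n_comp


class TestFastaIO:
    def test_roundtrip_preserves_records(self, tmp_path, rng):
        records = [
            SequenceRecord(f"r{i}", random_seq(rng, 60), description=f"r{i} site X")
            for i in range(5)
        ]
        path = tmp_path / "x.fasta"
        write_fasta(records, path)
        back = read_fasta(path)
        assert [r.id for r in back] == [r.id for r in records]
        assert [r.seq for r in back] == [r.seq for r in records]

    def test_u_normalised_to_t(self, tmp_path):
        (tmp_path / "u.fasta").write_text(">a\nacgu\n")
        rec = read_fasta(tmp_path / "u.fasta")[0]
        assert rec.seq == "ACGT"

    def test_aligned_read_checks_shape(self, tmp_path):
        (tmp_path / "bad.fasta").write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(AlignmentShapeError):
            read_fasta(tmp_path / "bad.fasta", aligned=True)
        (tmp_path / "ok.fasta").write_text(">a\nACGTACGTAC\n>b\nACGTACGTAG\n")
        aln = read_fasta(tmp_path / "ok.fasta", aligned=True)
        assert aln.length == 10 and len(aln) == 2


class TestPairwiseComparison:
    def test_self_comparison_is_zero(self, rng):
        s = random_seq(rng, 120)
        assert hamming_differences(s, s) == (0, 120)
        assert pairwise_identity(s, s) == 1.0

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_naive_oracle(self, rng, trial):
        a = random_seq(rng, 200, "ACGT-N")
        b = random_seq(rng, 200, "ACGT-N")
        assert hamming_differences(a, b) == naive_hamming(a, b)

    def test_identity_complements_p_distance(self, rng):
        a, b = random_seq(rng, 300), random_seq(rng, 300)
        nd, nc = hamming_differences(a, b)
        assert pairwise_identity(a, b) == pytest.approx(1 - nd / nc)

    def test_one_difference_over_741(self):
        # two clones of the same 16S gene differing at a single position
        base = random_seq(np.random.default_rng(7), 741)
        variant = base[:100] + ("A" if base[100] != "A" else "C") + base[101:]
        assert hamming_differences(base, variant) == (1, 741)
        assert pairwise_identity(base, variant) == pytest.approx(0.9986504723346828)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentShapeError):
            hamming_differences("ACGT", "ACG")

    def test_all_gap_comparison_is_degenerate(self):
        with pytest.raises(DegenerateComparisonError):
            hamming_differences("A---", "-CGT")

    def test_strict_policy_rejects_ambiguity(self):
        with pytest.raises(ValueError):
            hamming_differences("ACGN", "ACGT", policy="strict")


class TestJukesCantor:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.0, 0.0),
            (0.01, 0.010067265249105515),
            (0.10, 0.107325632730505),
        ],
    )
    def test_closed_form_values(self, p, expected):
        assert jc_distance(p) == pytest.approx(expected, rel=1e-12)

    def test_saturation(self):
        with pytest.raises(SaturationError):
            jc_distance(0.75)
        assert jc_distance(0.8, saturated=math.inf) == math.inf

    @given(st.floats(min_value=1e-6, max_value=0.74))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_exceeds_p_and_increases(self, p):
        d = jc_distance(p)
        assert d > p
        assert jc_distance(p * 0.5) < d


class TestDistanceMatrix:
    def test_identical_records_zero_matrix(self):
        aln = Alignment([SequenceRecord(f"s{i}", "ACGTACGT") for i in range(3)])
        assert np.all(distance_matrix(aln).data == 0)

    def test_matches_pairwise_brute_force(self, toy_alignment):
        dm = distance_matrix(toy_alignment)
        for i, a in enumerate(toy_alignment.records):
            for j, b in enumerate(toy_alignment.records):
                if i == j:
                    continue
                nd, nc = naive_hamming(a.seq, b.seq)
                assert dm.data[i, j] == pytest.approx(nd / nc)

    def test_symmetry_and_kinds(self, rng):
        # related sequences (~10% divergence) so the JC correction is defined
        base = random_seq(rng, 150)
        seqs = []
        for _ in range(6):
            s = list(base)
            for pos in rng.choice(150, size=15, replace=False):
                s[pos] = "ACGT"[rng.integers(4)]
            seqs.append("".join(s))
        aln = Alignment([SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)])
        p = distance_matrix(aln, "p_distance")
        jc = distance_matrix(aln, "jc_corrected")
        ident = distance_matrix(aln, "identity")
        assert np.allclose(p.data, p.data.T)
        assert np.all(np.diag(p.data) == 0)
        assert np.all(jc.data >= p.data)  # correction only inflates
        assert np.allclose(ident.data, 1 - p.data)


class TestGroupDivergence:
    def test_identical_group_zero_divergence(self):
        aln = Alignment([SequenceRecord(f"s{i}", "ACGTACGTAC") for i in range(3)])
        (summary,) = group_divergence(aln, {f"s{i}": "g" for i in range(3)})
        assert (summary.min_pct, summary.max_pct) == (0.0, 0.0)
        assert summary.n_pairs == 3

    def test_matches_brute_force(self, rng):
        aln = Alignment(
            [SequenceRecord(f"s{i}", random_seq(rng, 90)) for i in range(6)]
        )
        groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        out = {(s.group_a, s.group_b): s for s in group_divergence(aln, groups)}
        dm = distance_matrix(aln).data * 100
        within_a = [dm[i, j] for i in range(3) for j in range(i + 1, 3)]
        among = [dm[i, j] for i in range(3) for j in range(3, 6)]
        assert out[("a", "a")].min_pct == pytest.approx(min(within_a))
        assert out[("a", "b")].max_pct == pytest.approx(max(among))
        assert out[("a", "b")].n_pairs == 9

    def test_one_group_partition_equals_global_range(self, rng):
        aln = Alignment(
            [SequenceRecord(f"s{i}", random_seq(rng, 80)) for i in range(5)]
        )
        (summary,) = group_divergence(aln, {i: "all" for i in aln.ids})
        dm = distance_matrix(aln).data * 100
        off = dm[np.triu_indices(5, 1)]
        assert summary.min_pct == pytest.approx(off.min())
        assert summary.max_pct == pytest.approx(off.max())


class TestCloneTally:
    def test_copy_number_structure(self, rng):
        variants = [random_seq(rng, 50) for _ in range(3)]
        records = [
            SequenceRecord(f"c{k}", seq)
            for k, seq in enumerate(
                [variants[0]] * 10 + [variants[1]] * 10 + [variants[2]] * 3
            )
        ]
        tally, singletons = clone_tally(records)
        assert [c for _, c in tally] == [10, 10, 3]
        assert singletons == 0

    def test_all_distinct_all_singletons(self, rng):
        records = [SequenceRecord(f"c{k}", random_seq(rng, 40)) for k in range(8)]
        tally, singletons = clone_tally(records)
        assert singletons == 8
        assert sum(c for _, c in tally) == 8

    def test_counts_conserved_and_gaps_ignored(self, rng):
        seq = random_seq(rng, 30)
        records = [
            SequenceRecord("a", seq),
            SequenceRecord("b", seq[:10] + "-" + seq[10:]),
            SequenceRecord("c", random_seq(rng, 30)),
        ]
        tally, _ = clone_tally(records)
        assert sum(c for _, c in tally) == 3
        assert tally[0][1] == 2  # gapped copy collapses onto the degapped one


class TestDilutionBound:
    def test_exact_published_style_value(self):
        assert dilution_density_bound(5e-7, 0.1) == pytest.approx(2e7)

    @pytest.mark.parametrize("d,v,expected", [(1.0, 1.0, 1.0), (1e-3, 1.0, 1e3)])
    def test_arithmetic(self, d, v, expected):
        assert dilution_density_bound(d, v) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            dilution_density_bound(0, 0.1)
        with pytest.raises(ValueError):
            dilution_density_bound(1e-3, -1)
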