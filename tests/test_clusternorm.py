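"""Greedy clustering against a brute-force rule checker, and the TMM
recipe against a literal straight-line transcription."""

import numpy as np
import pandas as pd
import pytest

from faecalomics import (
    apply_factors,
    cluster_count_table,
    greedy_cluster,
    sequences_match,
    tmm_factors,
)
from faecalomics.clusternorm import mean_intersample_correlation
from faecalomics.containers import CountTable
from oracles import oracle_greedy_partition, oracle_match, oracle_tmm

BASES = list("ACGT")


def random_seq(rng, length):
    return "".join(rng.choice(BASES, size=length))


# ----------------------------------------------------------------- tests

class TestSequencesMatch:
    def test_identical(self):
        assert sequences_match("ACGTACGT", "ACGTACGT")

    def test_hamming_four_rejected(self):
        # spread-out substitutions in a period-4 sequence: shifted overlaps
        # only get worse, so the distance-4 pair must split
        a = "ACGTACGTACGTACGTACGT"
        b = "ACTTACGAACGTATGTACGA"  # distance 4 at positions 2, 7, 13, 19
        assert not sequences_match(a, b)
        assert sequences_match(a, "ACTTACGAACGTATGTACGT")  # distance 3

    def test_overhang_with_mismatches(self):
        centre = "ACGTACGTACGTACGTACGTACGT"  # 24 nt
        member = list(centre[:21])           # 3 nt total overhang
        member[2], member[7], member[12] = "T", "A", "T"  # 3 mismatches
        assert sequences_match("".join(member), centre)

    @pytest.mark.parametrize("seed", range(8))
    def test_rule_agrees_with_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            la, lb = rng.integers(15, 30, size=2)
            if rng.random() < 0.5:
                a, b = random_seq(rng, la), random_seq(rng, lb)
            else:  # correlated pair: mutated/truncated copy
                b = random_seq(rng, lb)
                a = list(b)
                for pos in rng.choice(lb, size=rng.integers(0, 5), replace=False):
                    a[pos] = str(rng.choice(BASES))
                a = "".join(a)[: max(10, lb - rng.integers(0, 5))]
            assert sequences_match(a, b) == oracle_match(a, b)


class TestGreedyCluster:
    def test_identical_sequences_single_cluster(self):
        tbl = pd.DataFrame({"S1": [5.0]}, index=["ACGTACGTACGTACGT"])
        cs = greedy_cluster(tbl)
        assert len(cs) == 1
        assert cs.clusters[0].cardinality["S1"] == 5.0

    def test_partition_matches_bruteforce(self):
        """Greedy partition equals the all-pairs rule checker on random sets."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            seqs = set()
            while len(seqs) < 40:
                if rng.random() < 0.5 or not seqs:
                    seqs.add(random_seq(rng, int(rng.integers(18, 30))))
                else:  # near-duplicate of an existing sequence
                    base = list(sorted(seqs)[rng.integers(len(seqs))])
                    for pos in rng.choice(len(base), size=rng.integers(1, 4),
                                          replace=False):
                        base[pos] = str(rng.choice(BASES))
                    seqs.add("".join(base))
            tbl = pd.DataFrame(
                {"S1": rng.integers(1, 50, size=len(seqs)).astype(float)},
                index=sorted(seqs),
            )
            expected = oracle_greedy_partition(tbl)
            got = greedy_cluster(tbl).membership()
            assert got == expected

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        seqs = [random_seq(rng, 20) for _ in range(25)]
        tbl = pd.DataFrame(
            {"S1": rng.integers(1, 9, len(seqs)).astype(float)},
            index=pd.Index(seqs),
        )
        shuffled = tbl.sample(frac=1.0, random_state=1)
        assert greedy_cluster(tbl).membership() == greedy_cluster(shuffled).membership()

    def test_cardinalities_conserve_totals(self):
        rng = np.random.default_rng(5)
        seqs = [random_seq(rng, 22) for _ in range(30)]
        tbl = pd.DataFrame(
            rng.integers(0, 20, size=(30, 3)).astype(float),
            index=pd.Index(seqs), columns=["S1", "S2", "S3"],
        )
        cs = greedy_cluster(tbl)
        table, _ = cluster_count_table(cs)
        assert np.allclose(table.values.sum(axis=0), tbl.sum(axis=0))

    def test_singleton_clusters_reproduce_raw_table(self):
        # far-apart sequences cluster alone
        seqs = ["A" * 20, "C" * 20, "G" * 20, "T" * 20]
        tbl = pd.DataFrame(
            {"S1": [4.0, 3.0, 2.0, 1.0], "S2": [1.0, 2.0, 3.0, 4.0]},
            index=pd.Index(seqs),
        )
        cs = greedy_cluster(tbl)
        assert len(cs) == 4
        table, corr = cluster_count_table(cs)
        assert sorted(table.values.sum(axis=1)) == [5.0, 5.0, 5.0, 5.0]
        assert corr.shape == (2, 2)

    def test_cluster_counts_more_stable_than_sequence_counts(self):
        """Variant-split noise cancels in cluster cardinalities."""
        rng = np.random.default_rng(11)
        n_samples, n_backbone = 6, 20
        shared = rng.gamma(3.0, 60.0, size=n_backbone)
        rows: dict[str, np.ndarray] = {}
        for i in range(n_backbone):
            centre = random_seq(rng, 26)
            variants = [centre]
            for _ in range(2):
                v = list(centre)
                for pos in rng.choice(26, size=2, replace=False):
                    v[pos] = str(rng.choice(BASES))
                variants.append("".join(v))
            for j in range(n_samples):
                total = shared[i] * rng.lognormal(0, 0.1)
                split = rng.dirichlet([0.35] * len(variants))
                for v, frac in zip(variants, split):
                    rows.setdefault(v, np.zeros(n_samples))[j] += total * frac
        for j in range(n_samples):  # sample-private sequences
            for _ in range(4):
                seq = random_seq(rng, 30)
                rows.setdefault(seq, np.zeros(n_samples))[j] = rng.gamma(3.0, 80.0)
        tbl = pd.DataFrame.from_dict(rows, orient="index",
                                     columns=[f"S{j}" for j in range(n_samples)])
        cs = greedy_cluster(tbl)
        cluster_table, _ = cluster_count_table(cs)
        assert (
            mean_intersample_correlation(cluster_table.values)
            >= mean_intersample_correlation(tbl)
        )


class TestTmmFactors:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(80, size=30).astype(float) + 1
        table = CountTable(pd.DataFrame({"S1": col, "S2": col, "S3": col}))
        f = tmm_factors(table)
        assert np.allclose(f.factors, 1.0, atol=1e-12)

    def test_single_column_scaling_invariance(self):
        """Scaling a column leaves factors (asymptotically) unchanged.

        M, A and the trim are exactly depth-invariant; the inverse-binomial
        precision weights retain a weak absolute-depth dependence, so
        invariance is exact only in the large-depth limit — hence the small
        tolerance here rather than machine precision.
        """
        rng = np.random.default_rng(1)
        vals = rng.poisson(60, size=(40, 3)).astype(float) + 1
        t1 = CountTable(pd.DataFrame(vals, columns=["S1", "S2", "S3"]))
        vals2 = vals.copy()
        vals2[:, 1] *= 7.5
        t2 = CountTable(pd.DataFrame(vals2, columns=["S1", "S2", "S3"]))
        f1, f2 = tmm_factors(t1), tmm_factors(t2)
        assert np.allclose(f1.factors, f2.factors, rtol=0.02)

    def test_doubled_column_gives_unit_factors(self):
        rng = np.random.default_rng(2)
        col = rng.poisson(100, size=25).astype(float) + 1
        table = CountTable(pd.DataFrame({"S1": col, "S2": 2 * col}))
        assert np.allclose(tmm_factors(table).factors, 1.0, atol=1e-12)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        vals = rng.poisson(50, size=(50, 4)).astype(float) + 1
        vals[:5, 0] *= 6
        f = tmm_factors(CountTable(pd.DataFrame(vals)))
        assert abs(np.log(f.factors.to_numpy()).mean()) < 1e-9

    def _perturbed_fixture(self):
        rng = np.random.default_rng(7)
        vals = rng.poisson(100, size=(20, 3)).astype(float) + 1
        vals[:4, 1] *= 8.0  # 4 of 20 features perturbed 8-fold in one sample
        return CountTable(pd.DataFrame(vals, columns=["S1", "S2", "S3"]))

    def test_matches_straightline_oracle(self):
        table = self._perturbed_fixture()
        got = tmm_factors(table)
        exp, r = oracle_tmm(
            table.values.to_numpy(), table.library_sizes.to_numpy()
        )
        assert np.allclose(got.factors.to_numpy(), exp, atol=1e-9)
        assert got.reference_sample == table.values.columns[r]

    def test_apply_factors_recovers_unperturbed_ratios(self):
        table = self._perturbed_fixture()
        norm = apply_factors(table, tmm_factors(table))
        ratios = norm.values.iloc[4:, 1] / norm.values.iloc[4:, 0]
        assert abs(np.median(ratios) - 1.0) < 0.1


class TestApplyFactors:
    def test_identity_when_factors_and_depths_equal(self):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(rng.poisson(50, size=(10, 2)).astype(float) + 1,
                            columns=["S1", "S2"])
        vals["S2"] = vals["S1"]
        table = CountTable(vals)
        f = tmm_factors(table)
        norm = apply_factors(table, f)
        pd.testing.assert_frame_equal(norm.values, table.values)

    def test_doubling_a_factor_halves_values(self):
        rng = np.random.default_rng(6)
        vals = pd.DataFrame(rng.poisson(50, size=(10, 2)).astype(float) + 1,
                            columns=["S1", "S2"])
        table = CountTable(vals)
        from faecalomics.containers import NormalizationFactors

        base = NormalizationFactors(
            pd.Series({"S1": 1.0, "S2": 1.0}), reference_sample="S1"
        )
        k = np.sqrt(2.0)  # {1/k, k} has geometric mean 1
        doubled = NormalizationFactors(
            pd.Series({"S1": 1.0 / k, "S2": k}), reference_sample="S1"
        )
        n1 = apply_factors(table, base)
        n2 = apply_factors(table, doubled)
        scale = (n2.values["S2"] / n1.values["S2"]).iloc[0]
        ratio = (n2.values["S2"] / n2.values["S1"]) / (n1.values["S2"] / n1.values["S1"])
        assert np.allclose(ratio, 0.5)

    def test_missing_sample_named_in_error(self):
        from faecalomics.containers import NormalizationFactors

        table = CountTable(pd.DataFrame({"S1": [1.0], "S2": [2.0]}))
        f = NormalizationFactors(pd.Series({"S1": 1.0}), reference_sample="S1")
        with pytest.raises(ValueError, match="S2"):
            apply_factors(table, f)
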