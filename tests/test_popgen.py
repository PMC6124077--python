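"""AMOVA Phi_ST and chi-square homogeneity against exhaustive oracles."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from flukeprint.errors import AlignmentError
from flukeprint.popgen import (
    StrataDataset,
    _phi_from_labels,
    chi2_test,
    differentiation_tests,
    pairwise_distance_matrix,
    phi_st,
)


def _dataset(obs, seqs):
    return StrataDataset(observations=obs, seqs=seqs)


def distinct_label_permutations(codes):
    return {p for p in permutations(codes)}


class TestDistances:
    def test_identical_and_known_differences(self):
        ds = _dataset(
            [("a", "H1", "N"), ("b", "H1", "N"), ("c", "H2", "S")],
            {"H1": "AAAAAA", "H2": "TTAAAT"},
        )
        D = pairwise_distance_matrix(ds)
        assert D[0, 1] == 0
        assert D[0, 2] == 3
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_matrix_matches_site_loop_oracle(self, rng):
        haps = {f"H{i}": "".join(rng.choice(list("ACGT"), 25)) for i in range(4)}
        obs = [(f"s{i}", rng.choice(list(haps)), "N") for i in range(7)]
        ds = _dataset(obs, haps)
        D = pairwise_distance_matrix(ds)
        for i, (_, hi, _) in enumerate(obs):
            for j, (_, hj, _) in enumerate(obs):
                expect = sum(a != b for a, b in zip(haps[hi], haps[hj]))
                assert D[i, j] == expect

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            _dataset([("a", "H1", "N")], {"H1": "AAAA", "H2": "AA"})


class TestPhiSt:
    def test_fixed_distinct_strata_give_phi_one(self):
        ds = _dataset(
            [("a", "H1", "N"), ("b", "H1", "N"), ("c", "H2", "S"), ("d", "H2", "S")],
            {"H1": "AAAAAA", "H2": "TTTAAA"},
        )
        r = phi_st(ds, n_perm=99, seed=0)
        assert r.phi_st == pytest.approx(1.0, abs=1e-12)
        assert r.sigma2_among == pytest.approx(4.5, abs=1e-12)
        assert r.sigma2_within == 0.0

    def test_monomorphic_dataset_reports_status(self):
        ds = _dataset(
            [("a", "H1", "N"), ("b", "H1", "N"), ("c", "H1", "S"), ("d", "H1", "S")],
            {"H1": "AAAA"},
        )
        r = phi_st(ds, n_perm=9, seed=0)
        assert (r.status, r.phi_st, r.phi_p) == ("monomorphic", 0.0, 1.0)

    def test_identical_compositions_never_positive(self, rng):
        haps = {h: "".join(rng.choice(list("ACGT"), 30)) for h in "ABC"}
        comp = ["A", "A", "B", "C"]
        obs = [(f"n{i}", h, "N") for i, h in enumerate(comp)]
        obs += [(f"s{i}", h, "S") for i, h in enumerate(comp)]
        r = phi_st(_dataset(obs, haps), n_perm=9, seed=0)
        assert r.phi_st <= 1e-12

    def test_permutation_p_matches_exhaustive_enumeration(self, rng):
        haps = {h: "".join(rng.choice(list("ACGT"), 12)) for h in "ABCD"}
        obs = [
            (f"s{i}", h, lab)
            for i, (h, lab) in enumerate(
                zip(["A", "B", "A", "C", "D", "C", "D", "B"],
                    ["N", "N", "N", "N", "S", "S", "S", "S"])
            )
        ]
        ds = _dataset(obs, haps)
        d2 = pairwise_distance_matrix(ds) ** 2
        codes = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        obs_phi = _phi_from_labels(d2, codes, 2)
        null = [
            _phi_from_labels(d2, np.array(p), 2)
            for p in distinct_label_permutations(codes.tolist())
        ]
        exact = sum(v >= obs_phi - 1e-12 for v in null) / len(null)
        mc = phi_st(ds, n_perm=4000, seed=11)
        sigma = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(mc.phi_p - exact) <= 3 * sigma + 1 / 4001

    def test_divergence_increases_phi(self, rng):
        """Median Phi_ST rises monotonically over a 3-point divergence grid."""
        haps = {h: "".join(rng.choice(list("ACGT"), 40)) for h in "AB"}
        grids = [0.1, 0.3, 0.5]  # |freq(A in N) - freq(A in S)| / 2-ish
        medians = []
        for d in grids:
            vals = []
            for rep in range(40):
                pN, pS = 0.5 + d, 0.5 - d
                obs = [
                    (f"n{i}", "A" if rng.random() < pN else "B", "N")
                    for i in range(12)
                ] + [
                    (f"s{i}", "A" if rng.random() < pS else "B", "S")
                    for i in range(12)
                ]
                try:
                    vals.append(phi_st(_dataset(obs, haps), n_perm=0, seed=0).phi_st)
                except ValueError:
                    continue
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]

    def test_single_stratum_rejected(self):
        ds = _dataset([("a", "H1", "N"), ("b", "H2", "N"), ("c", "H1", "N")],
                      {"H1": "AAAA", "H2": "AATT"})
        with pytest.raises(ValueError):
            phi_st(ds)


class TestChi2:
    def test_diagonal_table_closed_form(self):
        seqs = {"A": "AAAA", "B": "AAAT"}
        obs = [(f"a{i}", "A", "N") for i in range(10)]
        obs += [(f"b{i}", "B", "S") for i in range(10)]
        r = chi2_test(_dataset(obs, seqs), n_perm=99, seed=0)
        assert r.chi2 == pytest.approx(20.0, abs=1e-12)
        assert r.chi2_df == 1

    def test_identical_rows_give_zero(self):
        seqs = {"A": "AAAA", "B": "AAAT"}
        obs = [(f"n{i}", h, "N") for i, h in enumerate(["A", "A", "B", "B"])]
        obs += [(f"s{i}", h, "S") for i, h in enumerate(["A", "A", "B", "B"])]
        r = chi2_test(_dataset(obs, seqs), n_perm=9, seed=0)
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.chi2_p_asymptotic == pytest.approx(1.0)

    def test_statistic_matches_scipy_contingency(self, rng):
        seqs = {h: "".join(rng.choice(list("ACGT"), 10)) for h in "ABC"}
        obs = [
            (f"s{i}", rng.choice(list("ABC")), rng.choice(["N", "S"]))
            for i in range(30)
        ]
        ds = _dataset(obs, seqs)
        r = chi2_test(ds, n_perm=9, seed=0)
        table = pd.crosstab(
            pd.Series([h for _, h, _ in obs]), pd.Series([s for _, _, s in obs])
        )
        expect = sps.chi2_contingency(table, correction=False)
        assert r.chi2 == pytest.approx(expect.statistic)
        assert r.chi2_p_asymptotic == pytest.approx(expect.pvalue)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        seqs = {"A": "AAAA", "B": "AATT"}
        obs = [("s1", "A", "N"), ("s2", "A", "N"), ("s3", "B", "N"),
               ("s4", "B", "S"), ("s5", "B", "S"), ("s6", "A", "S")]
        ds = _dataset(obs, seqs)
        r = chi2_test(ds, n_perm=4000, seed=3)
        haps = [h for _, h, _ in obs]
        labels = [s for _, _, s in obs]
        null = []
        for p in distinct_label_permutations(labels):
            t = pd.crosstab(pd.Series(haps), pd.Series(list(p)))
            null.append(sps.chi2_contingency(t, correction=False).statistic)
        exact = sum(v >= r.chi2 - 1e-12 for v in null) / len(null)
        sigma = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(r.chi2_p_perm - exact) <= 3 * sigma + 1 / 4001

    def test_single_haplotype_rejected(self):
        ds = _dataset([("a", "H1", "N"), ("b", "H1", "S")], {"H1": "AAAA"})
        with pytest.raises(ValueError):
            chi2_test(ds)


class TestFromCalls:
    def test_dataset_built_from_call_table(self, rng):
        refs = {"CR01": "A" * 20, "CR02": "A" * 10 + "T" * 10}
        calls = pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S2", "S3", "S4"],
                "haplotype_id": ["CR01", "CR01", "novel-1", "CR02", None],
                "status": ["known", "known", "novel", "known", "failed_sample"],
                "rank": ["primary", "primary", "secondary", "primary", None],
                "seq": [None, None, "A" * 9 + "C" + "T" * 10, None, None],
            }
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3", "S4"],
                "stratum": ["N", "N", "S", "S"],
            }
        )
        ds = StrataDataset.from_calls(calls, meta, refs)
        assert len(ds.observations) == 4  # failed sample contributes nothing
        assert ds.seqs["novel-1"].startswith("A")
        primary_only = StrataDataset.from_calls(calls, meta, refs,
                                                include_secondary=False)
        assert len(primary_only.observations) == 3

    def test_summary_renders(self):
        seqs = {"A": "AAAA", "B": "AATT"}
        obs = [("s1", "A", "N"), ("s2", "A", "N"), ("s3", "B", "S"),
               ("s4", "B", "S"), ("s5", "A", "S")]
        res = differentiation_tests(_dataset(obs, seqs), n_perm=99, seed=0)
        text = res.summary()
        assert "Phi_ST" in text and "chi2" in text
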