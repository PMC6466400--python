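"""K-mer counting and correspondence analysis against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from characlock.kmer import (
    correspondence_analysis,
    count_kmers,
    group_cohesion,
    kmer_order,
    profile_table,
)
from characlock.simulate import gc_biased_profile, random_genome, simulate_biased_cds


def _brute_counts(seq, k):
    counts = {}
    for i in range(len(seq) - k + 1):
        word = seq[i:i + k]
        if set(word) <= set("ACGT"):
            counts[word] = counts.get(word, 0) + 1
    return counts


class TestCountKmers:
    def test_homopolymer_dinucleotides(self):
        p = count_kmers("AAAA", 2)
        assert p.counts[kmer_order(2).index("AA")] == 3
        assert p.total == 3

    @given(st.text(alphabet="ACGT", min_size=7, max_size=60),
           st.integers(2, 7))
    def test_total_is_window_count(self, seq, k):
        assert count_kmers(seq, k).total == len(seq) - k + 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_substring_enumeration_oracle(self, seed):
        seq = random_genome(1000, seed=seed).seq
        profile = count_kmers(seq, 4).as_series()
        brute = _brute_counts(seq, 4)
        for word in kmer_order(4):
            assert profile[word] == brute.get(word, 0)

    def test_ambiguous_windows_skipped(self):
        p = count_kmers("AANAA", 2)
        assert p.total == 2  # AA, AA; the two N-containing windows skipped

    def test_invalid_k_or_short_sequence(self):
        with pytest.raises(ValueError):
            count_kmers("ACGT", 1)
        with pytest.raises(ValueError):
            count_kmers("ACGT", 8)
        with pytest.raises(ValueError):
            count_kmers("AC", 3)

    def test_concatenation_boundary_identity(self):
        """counts(A+B) equals counts(A)+counts(B) plus the k-1 windows
        spanning the junction, checked exactly by enumeration."""
        a = random_genome(200, seed=1).seq
        b = random_genome(150, seed=2).seq
        k = 4
        cat = count_kmers(a + b, k).as_series()
        sep = count_kmers(a, k).as_series() + count_kmers(b, k).as_series()
        boundary = _brute_counts(a[-(k - 1):] + b[:k - 1], k)
        for word in kmer_order(k):
            assert cat[word] == sep[word] + boundary.get(word, 0)


def _oracle_ca(N):
    """Brute-force CA via the eigendecomposition of S S^T / S^T S."""
    n = N.sum()
    P = N / n
    r, c = P.sum(axis=1), P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    evals, U = np.linalg.eigh(S @ S.T)
    order = np.argsort(evals)[::-1]
    evals, U = evals[order], U[:, order]
    keep = evals > 1e-12
    sv = np.sqrt(evals[keep])
    U = U[:, keep]
    rowc = (U / np.sqrt(r)[:, None]) * sv[None, :]
    return rowc, sv, float((S ** 2).sum())


class TestCorrespondenceAnalysis:
    def test_rank_one_table_has_zero_inertia(self):
        N = np.outer([1, 2, 3], [4, 5, 6, 7]).astype(float)
        res = correspondence_analysis(pd.DataFrame(N))
        assert res.n_axes == 0
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_toy_table_matches_eigendecomposition_oracle(self):
        N = np.array([[10, 3, 5, 7], [2, 9, 4, 1], [6, 6, 8, 3]], float)
        res = correspondence_analysis(pd.DataFrame(N))
        rowc, sv, inertia = _oracle_ca(N)
        assert res.total_inertia == pytest.approx(inertia, abs=1e-12)
        np.testing.assert_allclose(res.singular_values, sv, atol=1e-9)
        for a in range(res.n_axes):  # compare up to sign
            ours, theirs = res.row_coords[:, a], rowc[:, a]
            assert (np.allclose(ours, theirs, atol=1e-9)
                    or np.allclose(ours, -theirs, atol=1e-9))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = rng.integers(1, 40, size=(6, 16)).astype(float)
        res = correspondence_analysis(pd.DataFrame(N))
        rowc, sv, inertia = _oracle_ca(N)
        np.testing.assert_allclose(res.singular_values, sv, atol=1e-9)
        for a in range(res.n_axes):
            ours, theirs = res.row_coords[:, a], rowc[:, a]
            assert (np.allclose(ours, theirs, atol=1e-9)
                    or np.allclose(ours, -theirs, atol=1e-9))
        assert res.total_inertia == pytest.approx(inertia, abs=1e-12)

    def test_inertia_times_total_is_pearson_chi_square(self):
        rng = np.random.default_rng(11)
        N = rng.integers(1, 30, size=(5, 8))
        res = correspondence_analysis(pd.DataFrame(N))
        chi2 = chi2_contingency(N, correction=False).statistic
        assert res.total_inertia * N.sum() == pytest.approx(chi2, rel=1e-10)

    def test_inertia_fractions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(13)
        N = rng.integers(1, 25, size=(7, 10))
        res = correspondence_analysis(pd.DataFrame(N))
        f = res.inertia_fractions
        assert ((f[:-1] - f[1:]) > -1e-12).all()
        assert 0 <= f.sum() <= 1 + 1e-9

    def test_row_permutation_permutes_coordinates(self):
        rng = np.random.default_rng(17)
        N = pd.DataFrame(rng.integers(1, 30, size=(5, 9)),
                         index=list("abcde"))
        res = correspondence_analysis(N)
        perm = ["d", "a", "e", "b", "c"]
        res_p = correspondence_analysis(N.loc[perm])
        for i, row in enumerate(perm):
            np.testing.assert_allclose(
                res_p.row_coords[i],
                res.row_coords[res.row_ids.index(row)], atol=1e-9)

    def test_duplicating_a_column_leaves_row_coords_unchanged(self):
        rng = np.random.default_rng(19)
        N = pd.DataFrame(rng.integers(1, 30, size=(5, 6)))
        dup = pd.concat([N, N[[0]].rename(columns={0: "dup"})], axis=1)
        # halve the duplicated mass so column margins are preserved
        dup[0] = dup[0] / 2
        dup["dup"] = dup["dup"] / 2
        res = correspondence_analysis(N.astype(float))
        res_d = correspondence_analysis(dup.astype(float))
        np.testing.assert_allclose(
            np.abs(res_d.row_coords[:, :res.n_axes]),
            np.abs(res.row_coords), atol=1e-9)

    def test_all_zero_row_pruned_with_warning(self):
        N = pd.DataFrame([[1, 2, 3], [0, 0, 0], [3, 1, 2]],
                         index=list("abc"))
        with pytest.warns(UserWarning, match="pruned"):
            res = correspondence_analysis(N)
        assert res.row_ids == ["a", "c"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            correspondence_analysis(pd.DataFrame([[1, -1], [2, 3]]))

    def test_principal_inertias_match_vegan(self, tmp_path):
        """Cross-check against the R vegan package's CA eigenvalues."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not on PATH; vegan cross-check cannot run")
        rng = np.random.default_rng(0)
        N = rng.integers(1, 40, size=(6, 16))
        path = tmp_path / "table.tsv"
        np.savetxt(path, N, fmt="%d", delimiter="\t")
        script = (
            f'x <- as.matrix(read.table("{path}")); '
            "suppressMessages(library(vegan)); "
            'cat(sprintf("%.12g\\n", cca(x)$CA$eig))'
        )
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True, check=True)
        vegan_eig = np.array([float(v) for v in proc.stdout.split()])
        res = correspondence_analysis(pd.DataFrame(N))
        np.testing.assert_allclose(res.inertia, vegan_eig, atol=1e-10)


class TestGroupCohesion:
    def _mock_result(self, coords, ids):
        from characlock.kmer import CaResult

        coords = np.asarray(coords, float)
        return CaResult(row_ids=ids, col_ids=[], row_coords=coords,
                        col_coords=np.zeros((0, coords.shape[1])),
                        singular_values=np.ones(coords.shape[1]),
                        total_inertia=1.0)

    def test_mirrored_far_groups_score_near_one(self):
        coords = [[-10, 0], [-10.1, 0.1], [10, 0], [10.1, -0.1]]
        res = self._mock_result(coords, ["a1", "a2", "b1", "b2"])
        scores = group_cohesion(res, {"a1": "A", "a2": "A",
                                      "b1": "B", "b2": "B"})
        assert all(s > 0.95 for s in scores.values())

    def test_shuffled_labels_average_near_zero(self, rng):
        coords = rng.normal(size=(40, 2))
        ids = [f"s{i}" for i in range(40)]
        res = self._mock_result(coords, ids)
        means = []
        for _ in range(30):
            labels = rng.permutation(["A"] * 20 + ["B"] * 20)
            scores = group_cohesion(res, dict(zip(ids, labels)))
            means.append(np.mean(list(scores.values())))
        assert abs(np.mean(means)) < 0.1

    def test_unknown_ids_rejected(self):
        res = self._mock_result([[0, 0], [1, 1]], ["a", "b"])
        with pytest.raises(KeyError):
            group_cohesion(res, {"a": "A", "zzz": "B"})

    def test_host_biased_cds_cluster_by_host(self):
        """Strongly tilted tetranucleotide profiles must separate on
        the first CA axes with cohesion > 0.5."""
        seqs = {}
        seqs.update(simulate_biased_cds(
            gc_biased_profile("hostA", 1.2), 6, 900, seed=5))
        seqs.update(simulate_biased_cds(
            gc_biased_profile("hostB", -1.2), 6, 900, seed=6))
        res = correspondence_analysis(profile_table(seqs, k=4))
        groups = {sid: sid.split("_")[0] for sid in seqs}
        scores = group_cohesion(res, groups)
        assert all(s > 0.5 for s in scores.values())
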