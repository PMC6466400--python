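"""Rarefaction, abundance normalization, SNV calling and classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from characlock.genome import GenomeRecord, OrfAnnotation
from characlock.virome import (
    CountTable,
    PileupColumn,
    RarefactionConfig,
    SNVRecord,
    call_snvs,
    classify_all,
    classify_snv,
    normalize_abundance,
    rarefy,
    read_pileup_tsv,
    snv_summary,
    write_pileup_tsv,
)
from characlock.simulate import random_genome, simulate_pileup

# Codon-table oracle (NCBI standard code, bases in TCAG order),
# independent of the Bio.Seq translation used by the implementation.
_CODON_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    "".join(c): aa for c, aa in zip(itertools.product("TCAG", repeat=3),
                                    _CODON_AA)
}


def _table():
    counts = pd.DataFrame({"s1": [900, 100], "s2": [500, 500]},
                          index=["c1", "c2"])
    return CountTable(counts, pd.Series([1000, 2000], index=["c1", "c2"]))


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self):
        table = _table()
        cfg = RarefactionConfig(depth=1000, iterations=5, seed=1)
        out = rarefy(table, cfg)
        pd.testing.assert_frame_equal(out, table.counts.astype(float))

    def test_every_iteration_sums_to_depth(self):
        table = _table()
        cfg = RarefactionConfig(depth=137, iterations=200, seed=2)
        _, draws = rarefy(table, cfg, return_iterations=True)
        assert (draws.sum(axis=1) == 137).all()

    def test_means_match_hypergeometric_expectation(self):
        """Mean rarefied count of a 10%-abundance contig at depth 100
        must sit within 3 Monte-Carlo SE of the hypergeometric mean 10."""
        table = _table()
        cfg = RarefactionConfig(depth=100, iterations=1000, seed=3)
        mean, draws = rarefy(table, cfg, return_iterations=True)
        # sample s1: N=1000, K=100 (c2), n=100 -> mean 10
        expected = 100 * 100 / 1000
        var = (100 * (100 / 1000) * (900 / 1000) * (1000 - 100) / (1000 - 1))
        se = np.sqrt(var / cfg.iterations)
        assert abs(mean.loc["c2", "s1"] - expected) < 3 * se

    def test_single_contig_sample_always_returns_depth(self):
        counts = pd.DataFrame({"s": [800]}, index=["c"])
        table = CountTable(counts, pd.Series([500], index=["c"]))
        out = rarefy(table, RarefactionConfig(depth=123, iterations=50, seed=4))
        assert out.loc["c", "s"] == 123.0

    def test_strict_mode_rejects_shallow_samples(self):
        counts = pd.DataFrame({"s1": [900, 100], "s2": [300, 200]},
                              index=["c1", "c2"])
        table = CountTable(counts, pd.Series([1000, 2000],
                                             index=["c1", "c2"]))
        with pytest.raises(ValueError, match="below rarefaction depth"):
            rarefy(table, RarefactionConfig(depth=800, iterations=2, seed=0))
        with pytest.warns(UserWarning, match="dropping"):
            out = rarefy(table, RarefactionConfig(
                depth=800, iterations=2, seed=0, strict=False))
        assert list(out.columns) == ["s1"]

    def test_seed_reproducibility(self):
        table = _table()
        cfg = RarefactionConfig(depth=300, iterations=20, seed=42)
        pd.testing.assert_frame_equal(rarefy(table, cfg), rarefy(table, cfg))


class TestNormalizeAbundance:
    def test_equal_lengths_is_identity(self):
        counts = pd.DataFrame({"s": [10.0, 20.0]}, index=["c1", "c2"])
        lengths = pd.Series([700, 700], index=["c1", "c2"])
        pd.testing.assert_frame_equal(
            normalize_abundance(counts, lengths), counts)

    def test_double_length_contig_halves_abundance(self):
        counts = pd.DataFrame({"s": [30.0, 30.0]}, index=["c1", "c2"])
        lengths = pd.Series([1000, 2000], index=["c1", "c2"])
        out = normalize_abundance(counts, lengths)
        # mean length 1500: c1 -> 30/(1000/1500)=45, c2 -> 30/(2000/1500)=22.5
        assert out.loc["c1", "s"] == pytest.approx(2 * out.loc["c2", "s"])

    def test_generative_rates_rank_recovered(self, rng):
        """Reads drawn proportional to rate x length: normalized
        abundance must rank-correlate perfectly with the true rates."""
        n = 8
        lengths = pd.Series(rng.integers(500, 5000, n),
                            index=[f"c{i}" for i in range(n)])
        rates = pd.Series(np.sort(rng.uniform(0.5, 10.0, n))[::-1],
                          index=lengths.index)
        lam = 3000 * rates * lengths / lengths.mean()
        counts = pd.DataFrame({"s": rng.poisson(lam)}, index=lengths.index)
        table = CountTable(counts, lengths)
        rare = rarefy(table, RarefactionConfig(
            depth=int(counts["s"].sum()), iterations=1, seed=1))
        norm = normalize_abundance(rare, lengths)
        rho = spearmanr(norm["s"], rates).statistic
        assert rho == pytest.approx(1.0)

    def test_zero_length_rejected(self):
        counts = pd.DataFrame({"s": [1.0]}, index=["c"])
        with pytest.raises(ValueError):
            normalize_abundance(counts, pd.Series([0], index=["c"]))


class TestCallSnvs:
    def test_no_mismatches_yields_empty_list(self):
        cols = [PileupColumn("c", i + 1, "A", a=50) for i in range(10)]
        assert call_snvs(cols) == []

    def test_minimum_count_threshold(self):
        col = PileupColumn("c", 1, "A", a=97, g=1, t=2)
        records = call_snvs([col], min_count=2)
        assert [(r.alt, r.alt_count) for r in records] == [("T", 2)]

    def test_multiple_alts_yield_multiple_records(self):
        col = PileupColumn("c", 5, "C", c=90, a=4, t=6)
        records = call_snvs([col], min_count=2)
        assert {(r.alt, r.alt_count) for r in records} == {("A", 4), ("T", 6)}

    def test_deletions_reported_unclassified(self):
        col = PileupColumn("c", 2, "G", g=80, deletion=20)
        records = call_snvs([col])
        assert records[0].alt == "-"
        classified = classify_all(records, [OrfAnnotation("c", "o", 1, 9)],
                                  GenomeRecord("c", "AGAAAATAA"))
        assert classified[0].effect is None

    def test_zero_depth_column_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-depth"):
            assert call_snvs([PileupColumn("c", 1, "A")]) == []

    def test_pileup_tsv_round_trip(self, tmp_path):
        cols = [PileupColumn("c", 1, "A", a=10, g=2),
                PileupColumn("c", 2, "T", t=11, deletion=1)]
        path = tmp_path / "pileup.tsv"
        write_pileup_tsv(cols, path)
        assert read_pileup_tsv(path) == cols


class TestClassifySnv:
    def _record(self, pos, ref, alt):
        return SNVRecord("g", pos, ref, alt, alt_count=5, depth=10)

    def test_third_position_gly_to_gly_synonymous(self):
        genome = GenomeRecord("g", "GGAAAA")
        orfs = [OrfAnnotation("g", "o", 1, 6)]
        out = classify_snv(self._record(3, "A", "G"), orfs, genome)
        assert out.effect == "synonymous"
        assert out.codon_index == 0

    def test_first_position_lys_to_glu_nonsynonymous(self):
        genome = GenomeRecord("g", "AAAGGG")
        orfs = [OrfAnnotation("g", "o", 1, 6)]
        out = classify_snv(self._record(1, "A", "G"), orfs, genome)
        assert out.effect == "nonsynonymous"

    def test_outside_all_orfs_is_noncoding(self):
        genome = GenomeRecord("g", "TTTAAAGGG")
        orfs = [OrfAnnotation("g", "o", 4, 9)]
        assert classify_snv(self._record(2, "T", "A"), orfs,
                            genome).effect == "noncoding"

    def test_position_beyond_genome_rejected(self):
        genome = GenomeRecord("g", "AAA")
        with pytest.raises(ValueError):
            classify_snv(self._record(7, "A", "G"), [], genome)

    def test_all_576_single_base_changes_match_codon_oracle(self):
        """Exhaustive: every codon x position x alternative base agrees
        with the standard-code lookup (synonymous iff same residue)."""
        orf = [OrfAnnotation("g", "o", 1, 3)]
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            genome = GenomeRecord("g", codon)
            for pos, alt in itertools.product(range(3), "ACGT"):
                if codon[pos] == alt:
                    continue
                mutated = codon[:pos] + alt + codon[pos + 1:]
                expected = ("synonymous"
                            if CODON_TABLE[codon] == CODON_TABLE[mutated]
                            else "nonsynonymous")
                out = classify_snv(self._record(pos + 1, codon[pos], alt),
                                   orf, genome)
                assert out.effect == expected, (codon, pos, alt)


class TestSnvSummary:
    def _orfs(self):
        return [OrfAnnotation("g", "o", 1, 300)]

    def test_empty_input_yields_empty_table(self):
        summary = snv_summary([], self._orfs())
        assert summary.per_orf.empty
        assert summary.fraction_nonsynonymous is None
        assert summary.spectrum["count"].sum() == 0

    def test_planted_composition_recovered_exactly(self):
        records = []
        for i in range(10):
            effect = "nonsynonymous" if i < 7 else "synonymous"
            records.append(SNVRecord("g", i + 1, "A", "G", alt_count=3,
                                     depth=10, effect=effect, orf_name="o",
                                     codon_index=i // 3))
        summary = snv_summary(records, self._orfs())
        assert summary.fraction_nonsynonymous == pytest.approx(0.70)
        assert summary.per_orf.loc["o", "n_snvs"] == 10

    def test_low_frequency_records_flagged_infrequent(self):
        records = [
            SNVRecord("g", i + 1, "A", "G", alt_count=1 + i, depth=100,
                      effect="nonsynonymous", orf_name="o")
            for i in range(5)
        ]
        summary = snv_summary(records, self._orfs())
        assert summary.median_frequency < 0.5
        assert summary.infrequent is True

    def test_frequency_spectrum_bins(self):
        records = [
            SNVRecord("g", 1, "A", "G", alt_count=5, depth=100,
                      effect="synonymous", orf_name="o"),      # 0.05
            SNVRecord("g", 2, "A", "G", alt_count=95, depth=100,
                      effect="synonymous", orf_name="o"),      # 0.95
            SNVRecord("g", 3, "A", "G", alt_count=100, depth=100,
                      effect="nonsynonymous", orf_name="o"),   # 1.0
        ]
        spectrum = snv_summary(records, self._orfs()).spectrum
        assert spectrum["count"].iloc[0] == 1
        assert spectrum["count"].iloc[9] == 2  # last bin closed at 1.0


class TestPipelineDeterminism:
    def test_identical_seeds_identical_bytes(self, tmp_path):
        genome = random_genome(400, seed=5, genome_id="ctg")
        orfs = [OrfAnnotation("ctg", "o", 10, 399, incomplete=True)]
        variants = [(50, "A" if genome.seq[49] != "A" else "C", 0.3)]
        outputs = []
        for run in range(2):
            cols, _ = simulate_pileup(genome, orfs, variants, depth=150,
                                      seed=77)
            records = classify_all(call_snvs(cols), orfs, genome)
            table = CountTable(
                pd.DataFrame({"s": [1000, 500]}, index=["c1", "c2"]),
                pd.Series([400, 800], index=["c1", "c2"]))
            rare = rarefy(table, RarefactionConfig(depth=400, iterations=50,
                                                   seed=77))
            norm = normalize_abundance(rare, table.lengths)
            path = tmp_path / f"out{run}.tsv"
            with open(path, "w") as fh:
                for r in records:
                    fh.write(f"{r.pos}\t{r.alt}\t{r.alt_count}\t{r.effect}\n")
                norm.to_csv(fh, sep="\t")
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]
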