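import math
import random

import numpy as np
import pytest

from srnakit import rasirna as ras
from srnakit._intervals import Interval
from srnakit.annotate import AnnotatedRead, Hit
from srnakit.preprocess import UniqueRead


def _cand(seq, hits, category="unannotated", count=1):
    return AnnotatedRead(UniqueRead(seq, {"t": count}), hits, category)


def _hits(n, chrom="c", strand="+", length=27, start=100):
    return [Hit(chrom, start + 50 * i, strand, length) for i in range(n)]


class TestCandidateFilter:
    def test_boundary_five_loci_retained(self):
        ar = _cand("A" * 27, _hits(5))
        assert ras.select_rasirna_candidates([ar]) == [ar]

    def test_six_loci_excluded(self):
        ar = _cand("A" * 27, _hits(6))
        assert ras.select_rasirna_candidates([ar]) == []

    def test_length_boundaries(self):
        keep23 = _cand("A" * 23, _hits(1, length=23))
        keep32 = _cand("A" * 32, _hits(1, length=32))
        drop22 = _cand("A" * 22, _hits(1, length=22))
        drop33 = _cand("A" * 33, _hits(1, length=33))
        got = ras.select_rasirna_candidates([keep23, keep32, drop22, drop33])
        assert got == [keep23, keep32]

    def test_annotated_excluded(self):
        ar = _cand("A" * 27, _hits(1), category="repeat:LINE")
        assert ras.select_rasirna_candidates([ar]) == []

    def test_predicate_oracle_on_random_reads(self):
        rng = random.Random(9)
        reads = []
        for _ in range(10_000):
            n = rng.randint(18, 35)
            cat = rng.choice(["unannotated", "exon", "miRNA", "repeat:LINE"])
            loci = rng.randint(0, 8)
            reads.append(_cand("A" * n, _hits(loci, length=n) if loci else [], cat))
        got = ras.select_rasirna_candidates(reads)
        oracle = [
            r
            for r in reads
            if r.category == "unannotated"
            and 23 <= len(r.sequence) <= 32
            and 1 <= r.n_loci <= 5
        ]
        assert got == oracle

    def test_idempotent_and_order_independent(self):
        rng = random.Random(10)
        reads = [
            _cand("A" * rng.randint(20, 34), _hits(rng.randint(1, 7)))
            for _ in range(200)
        ]
        once = ras.select_rasirna_candidates(reads)
        assert ras.select_rasirna_candidates(once) == once
        shuffled = list(reads)
        rng.shuffle(shuffled)
        assert sorted(map(id, ras.select_rasirna_candidates(shuffled))) == sorted(
            map(id, once)
        )


class TestFivepBias:
    def test_all_u_start(self):
        cands = [_cand("T" + "A" * 25, _hits(1, length=26)) for _ in range(5)]
        matrix, u = ras.fivep_bias(cands)
        assert u == 1.0
        assert matrix.iloc[0]["U"] == 1.0

    def test_empty_set(self):
        matrix, u = ras.fivep_bias([])
        assert u is None and matrix.empty

    def test_rows_sum_to_one(self):
        rng = random.Random(2)
        cands = [
            _cand(
                "".join(rng.choice("ACGT") for _ in range(rng.randint(23, 32))),
                _hits(1),
            )
            for _ in range(300)
        ]
        matrix, _ = ras.fivep_bias(cands)
        assert np.allclose(matrix.sum(axis=1), 1.0)

    def test_planted_bias_binomial_oracle(self):
        rng = random.Random(3)
        bias, n = 0.8, 4_000
        cands = []
        for _ in range(n):
            first = "T" if rng.random() < bias else rng.choice("ACG")
            cands.append(_cand(first + "".join(rng.choice("ACGT") for _ in range(26)), _hits(1)))
        _, u = ras.fivep_bias(cands)
        assert abs(u - bias) <= 3 * math.sqrt(bias * (1 - bias) / n)

    def test_uniform_reads_near_quarter(self):
        rng = random.Random(4)
        n = 4_000
        cands = [
            _cand("".join(rng.choice("ACGT") for _ in range(25)), _hits(1))
            for _ in range(n)
        ]
        matrix, _ = ras.fivep_bias(cands)
        sd = math.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(matrix.iloc[0] - 0.25) <= 3 * sd)


class TestChromDistribution:
    def test_density_normalization_ratio(self):
        genome = {"small": "A" * 1_000, "big": "A" * 2_000}
        cands = [_cand("A" * 25, [Hit("small", i, "+", 25)]) for i in range(10)]
        cands += [_cand("A" * 25, [Hit("big", i, "+", 25)]) for i in range(10)]
        df = ras.chrom_distribution(cands, genome).set_index("chrom")
        ratio = df.loc["small", "density_unique_per_mb"] / df.loc["big", "density_unique_per_mb"]
        assert ratio == pytest.approx(2.0)

    def test_fractional_multilocus_attribution(self):
        genome = {"a": "A" * 1_000, "b": "A" * 1_000}
        ar = _cand("A" * 25, [Hit("a", 0, "+", 25), Hit("b", 0, "+", 25)])
        df = ras.chrom_distribution([ar], genome).set_index("chrom")
        assert df.loc["a", "n_unique"] == pytest.approx(0.5)
        assert df.n_unique.sum() == pytest.approx(1.0)

    def test_no_candidates_all_zero(self):
        df = ras.chrom_distribution([], {"c": "A" * 100})
        assert (df.n_unique == 0).all() and (df.density_unique_per_mb == 0).all()

    def test_missing_chromosome_errors(self):
        ar = _cand("A" * 25, [Hit("nope", 0, "+", 25)])
        with pytest.raises(KeyError, match="nope"):
            ras.chrom_distribution([ar], {"c": "A" * 100})

    def test_feature_base_fractions(self):
        genome = {"c": "A" * 1_000}
        tracks = [
            Interval("c", 0, 100, "e1", "+", "exon"),
            Interval("c", 50, 150, "e2", "+", "exon"),  # overlaps e1; merged
            Interval("c", 500, 600, "L", "+", "LINE"),
        ]
        df = ras.chrom_distribution([], genome, tracks).set_index("chrom")
        assert df.loc["c", "exon_base_fraction"] == pytest.approx(0.15)
        assert df.loc["c", "repeat_base_fraction"] == pytest.approx(0.10)


def naive_feature_density(spans, chrom_len, window, step):
    """Per-base recount oracle."""
    covered = np.zeros(chrom_len, dtype=bool)
    for s, e in spans:
        covered[s:e] = True
    values = []
    for s in range(0, max(chrom_len, 1), step):
        e = min(s + window, chrom_len)
        values.append(covered[s:e].mean() if e > s else 0.0)
    return np.array(values)


class TestFeatureDensity:
    def test_no_features_all_zero(self):
        tr = ras.feature_density([], "c", 10_000, 1_000, 100)
        assert np.all(tr.values == 0)

    def test_full_window_is_one(self):
        ivs = [Interval("c", 0, 2_000, "x", "+", "exon")]
        tr = ras.feature_density(ivs, "c", 10_000, 1_000, 1_000)
        assert tr.values[0] == 1.0 and tr.values[1] == 1.0

    def test_matches_per_base_oracle(self):
        rng = random.Random(6)
        chrom_len = 30_000
        ivs = []
        for i in range(60):
            s = rng.randint(0, chrom_len - 500)
            ivs.append(Interval("c", s, s + rng.randint(50, 500), f"f{i}", "+", "exon"))
        tr = ras.feature_density(ivs, "c", chrom_len, 5_000, 500)
        oracle = naive_feature_density([(iv.start, iv.end) for iv in ivs], chrom_len, 5_000, 500)
        np.testing.assert_allclose(tr.values, oracle, atol=1e-12)

    def test_split_invariance(self):
        whole = [Interval("c", 100, 700, "w", "+", "exon")]
        parts = [
            Interval("c", 100, 300, "p1", "+", "exon"),
            Interval("c", 300, 700, "p2", "+", "exon"),
        ]
        t1 = ras.feature_density(whole, "c", 5_000, 1_000, 100)
        t2 = ras.feature_density(parts, "c", 5_000, 1_000, 100)
        np.testing.assert_allclose(t1.values, t2.values)

    def test_invalid_window_step(self):
        with pytest.raises(ValueError):
            ras.feature_density([], "c", 1_000, 100, 200)


class TestReadDensity:
    def test_single_read_windows(self):
        ar = _cand("A" * 25, [Hit("c", 2_500, "+", 25)])
        tr = ras.read_density([ar], "c", 10_000, "+", 1_000, 500)
        # 5' end at 2500 falls in windows starting at 1500..2500
        expect = np.zeros(len(tr.starts))
        for i, s in enumerate(tr.starts):
            if s <= 2_500 < min(s + 1_000, 10_000):
                expect[i] = 1.0
        np.testing.assert_allclose(tr.values, expect)
        assert tr.values.max() == 1.0

    def test_minus_strand_five_prime_end(self):
        ar = _cand("A" * 25, [Hit("c", 100, "-", 25)])
        tr = ras.read_density([ar], "c", 1_000, "-", 100, 100)
        # 5' end of a minus-strand read is its rightmost base: 124
        assert tr.values[1] == 1.0 and tr.values[0] == 0.0

    def test_strand_swap_symmetry(self):
        cands = [
            _cand("A" * 25, [Hit("c", 100, "+", 25)]),
            _cand("C" * 25, [Hit("c", 300, "-", 25)]),
        ]
        flipped = [
            _cand("A" * 25, [Hit("c", 100, "-", 25)]),
            _cand("C" * 25, [Hit("c", 300, "+", 25)]),
        ]
        plus = ras.read_density(cands, "c", 1_000, "+", 200, 100)
        minus_f = ras.read_density(flipped, "c", 1_000, "-", 200, 100)
        # positions differ by the 5'-end convention; totals must swap
        assert plus.values.sum() > 0
        assert ras.read_density(cands, "c", 1_000, "-", 200, 100).values.sum() == pytest.approx(
            ras.read_density(flipped, "c", 1_000, "+", 200, 100).values.sum()
        )
        assert plus.values.sum() == pytest.approx(minus_f.values.sum())

    def test_matches_naive_recount(self):
        rng = random.Random(8)
        chrom_len = 20_000
        cands = []
        for _ in range(1_000):
            n_loci = rng.randint(1, 5)
            hits = [
                Hit("c", rng.randint(0, chrom_len - 30), rng.choice("+-"), 27)
                for _ in range(n_loci)
            ]
            cands.append(_cand("A" * 27, hits))
        tr = ras.read_density(cands, "c", chrom_len, "+", 2_000, 250)
        values = np.zeros(len(tr.starts))
        for ar in cands:
            for h in ar.hits:
                if h.strand != "+" or h.chrom != "c":
                    continue
                p = h.five_prime()
                for i, s in enumerate(tr.starts):
                    if s <= p < min(s + 2_000, chrom_len):
                        values[i] += 1.0 / ar.n_loci
        np.testing.assert_allclose(tr.values, values, atol=1e-9)

    def test_density_conservation_tiling(self):
        rng = random.Random(11)
        chrom_len = 10_000
        cands = []
        total = 0.0
        for _ in range(300):
            n_loci = rng.randint(1, 5)
            hits = [
                Hit("c", rng.randint(0, chrom_len - 30), "+", 25) for _ in range(n_loci)
            ]
            cands.append(_cand("A" * 25, hits))
            total += len(hits) / n_loci
        tr = ras.read_density(cands, "c", chrom_len, "+", 1_000, 1_000)
        assert tr.values.sum() == pytest.approx(total)

    def test_invalid_strand(self):
        with pytest.raises(ValueError, match="strand"):
            ras.read_density([], "c", 1_000, "x")

    def test_upstream_filter_asserted(self):
        ar = _cand("A" * 27, _hits(7))
        with pytest.raises(AssertionError):
            ras.read_density([ar], "c", 10_000, "+")

    def test_bedgraph_output(self, tmp_path):
        ar = _cand("A" * 25, [Hit("c", 100, "+", 25)])
        tr = ras.read_density([ar], "c", 1_000, "+", 500, 100)
        path = tmp_path / "t.bedgraph"
        ras.write_bedgraph(tr, str(path), 1_000)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("track type=bedGraph")
        assert len(lines) == len(tr.starts) + 1
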