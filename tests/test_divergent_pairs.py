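"""Divergent-pair identification, overlap classes, and chromosome stats."""

import numpy as np
import pytest

from bdpscan.annotation_io import GenomeAnnotation
from bdpscan.divergent_pairs import (
    NON_OVERLAPPING,
    OVERLAPPING,
    ChromosomeStats,
    DivergentPair,
    chromosome_stats,
    classify_overlap,
    density_pair_correlation,
    find_divergent_pairs,
)
from conftest import brute_force_pairs, make_gene, random_annotation


def annotation_of(*genes):
    return GenomeAnnotation(genes=list(genes))


class TestFindPairs:
    def test_basic_divergent_pair(self):
        ann = annotation_of(make_gene("m", 2000, "-"), make_gene("p", 2500, "+"))
        pairs = find_divergent_pairs(ann)
        assert len(pairs) == 1
        assert pairs[0].tss_distance == 500
        assert pairs[0].overlap_class == NON_OVERLAPPING

    def test_distance_beyond_threshold_excluded(self):
        ann = annotation_of(make_gene("m", 2000, "-"), make_gene("p", 3200, "+"))
        assert find_divergent_pairs(ann) == []

    def test_threshold_is_strict(self):
        near = annotation_of(make_gene("m", 2000, "-"), make_gene("p", 2999, "+"))
        at = annotation_of(make_gene("m", 2000, "-"), make_gene("p", 3000, "+"))
        assert len(find_divergent_pairs(near)) == 1
        assert find_divergent_pairs(at) == []

    def test_same_strand_never_pairs(self):
        ann = annotation_of(
            make_gene("a", 2000, "+"), make_gene("b", 2300, "+", chrom="chr1")
        )
        assert find_divergent_pairs(ann) == []

    def test_overlapping_five_prime_pair(self):
        ann = annotation_of(make_gene("p", 1000, "+"), make_gene("m", 1200, "-"))
        pairs = find_divergent_pairs(ann)
        assert len(pairs) == 1
        assert pairs[0].tss_distance == 200
        assert pairs[0].overlap_class == OVERLAPPING

    def test_different_chromosomes_never_pair(self):
        ann = annotation_of(
            make_gene("m", 2000, "-", chrom="chr1"),
            make_gene("p", 2500, "+", chrom="chr2"),
        )
        assert find_divergent_pairs(ann) == []

    def test_intervening_tss_blocks_pair(self):
        # a third gene whose TSS sits inside the inter-TSS window breaks
        # adjacency, whatever its strand
        ann = annotation_of(
            make_gene("m", 2000, "-"),
            make_gene("p", 2900, "+"),
            make_gene("x", 2400, "+", length=100),
        )
        pairs = find_divergent_pairs(ann)
        # m cannot pair with p; but x itself pairs with m (distance 400)
        assert [(p.gene_minus.gene_id, p.gene_plus.gene_id) for p in pairs] == [
            ("m", "x")
        ]

    def test_third_gene_tss_outside_window_does_not_block(self):
        ann = annotation_of(
            make_gene("m", 2000, "-"),
            make_gene("p", 2500, "+"),
            make_gene("x", 9000, "+"),
        )
        assert len(find_divergent_pairs(ann)) == 1

    def test_nearest_partner_wins(self):
        ann = annotation_of(
            make_gene("m1", 2000, "-", length=300),
            make_gene("p", 2500, "+"),
            make_gene("m2", 2800, "-", length=100),
        )
        pairs = find_divergent_pairs(ann)
        assert len(pairs) == 1
        # m2 is 300 bp from p, m1 is 500 bp: nearest TSS distance wins
        assert pairs[0].gene_minus.gene_id == "m2"

    def test_empty_annotation(self):
        assert find_divergent_pairs(GenomeAnnotation()) == []

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            ann = random_annotation(rng)
            small = {
                (p.gene_minus.gene_id, p.gene_plus.gene_id)
                for p in find_divergent_pairs(ann, max_tss_distance=300)
            }
            large = {
                (p.gene_minus.gene_id, p.gene_plus.gene_id)
                for p in find_divergent_pairs(ann, max_tss_distance=1000)
            }
            # every candidate added by a wider threshold has a larger
            # distance, so earlier selections are preserved verbatim
            assert small <= large

    def test_matches_exhaustive_oracle_on_small_annotations(self):
        rng = np.random.default_rng(123)
        for _ in range(40):
            ann = random_annotation(rng)
            got = {
                (p.gene_minus.gene_id, p.gene_plus.gene_id)
                for p in find_divergent_pairs(ann)
            }
            assert got == brute_force_pairs(ann)

    def test_planted_pairs_recovered_exactly(self, small_genome):
        out, spec = small_genome
        from bdpscan.annotation_io import parse_annotation

        ann = parse_annotation(out.gff_path)
        pairs = find_divergent_pairs(ann)
        got = {
            p.pair_id: (p.tss_distance, p.overlap_class) for p in pairs
        }
        want = {
            row.pair_id: (row.tss_distance, row.overlap_class)
            for row in out.pairs_truth.itertuples()
        }
        assert got == want


class TestOverlapClass:
    @pytest.mark.parametrize(
        "tss_minus,tss_plus,expected",
        [
            (500, 900, NON_OVERLAPPING),
            (900, 500, OVERLAPPING),
            (700, 700, OVERLAPPING),  # zero-length spacer cannot separate
        ],
    )
    def test_classification(self, tss_minus, tss_plus, expected):
        pair = DivergentPair(
            make_gene("m", tss_minus, "-", length=400),
            make_gene("p", tss_plus, "+", length=400),
        )
        assert classify_overlap(pair) == expected

    def test_every_pair_classified(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pairs = find_divergent_pairs(random_annotation(rng))
            assert all(
                p.overlap_class in (OVERLAPPING, NON_OVERLAPPING) for p in pairs
            )


class TestChromosomeStats:
    def test_toy_arithmetic(self):
        genes = [make_gene(f"g{i}", 3000 * (i + 1), "+", chrom="chrA") for i in range(6)]
        genes += [
            make_gene("m1", 50_000, "-", chrom="chrA"),
            make_gene("p1", 50_400, "+", chrom="chrA"),
            make_gene("m2", 60_000, "-", chrom="chrA"),
            make_gene("p2", 60_300, "+", chrom="chrA"),
        ]
        ann = GenomeAnnotation(genes=genes, chrom_sizes={"chrA": 2_000_000})
        pairs = find_divergent_pairs(ann)
        assert len(pairs) == 2
        rows = chromosome_stats(ann, pairs)
        row = rows[0]
        assert row.total_genes == 10
        assert row.gene_density == pytest.approx(5.0)
        assert row.divergent_gene_count == 4
        assert row.divergent_ratio == pytest.approx(0.40)
        total = rows[-1]
        assert total.chrom == "Total"
        assert total.pair_count == 2

    def test_chromosome_without_pairs(self):
        ann = GenomeAnnotation(
            genes=[make_gene("g1", 5000, "+")], chrom_sizes={"chr1": 1_000_000}
        )
        rows = chromosome_stats(ann, [])
        assert rows[0].pair_count == 0
        assert rows[0].divergent_ratio == 0.0


def _stats_row(chrom, density, pairs, ratio=0.1):
    return ChromosomeStats(
        chrom=chrom,
        size_mb=10.0,
        total_genes=int(density * 10),
        gene_density=density,
        pair_count=pairs,
        divergent_gene_count=2 * pairs,
        divergent_ratio=ratio,
    )


class TestDensityCorrelation:
    def test_perfect_linearity(self):
        rows = [_stats_row(f"c{i}", d, int(2 * d)) for i, d in enumerate([10, 20, 30, 40])]
        res = density_pair_correlation(rows, "pair_count")
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(11)
        rows = [
            _stats_row(f"c{i}", float(rng.uniform(10, 50)), int(rng.integers(5, 100)))
            for i in range(24)
        ]
        res = density_pair_correlation(rows, "pair_count")
        x = np.array([r.gene_density for r in rows])
        y = np.array([r.pair_count for r in rows], dtype=float)
        xc, yc = x - x.mean(), y - y.mean()
        r_manual = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert res["pearson_r"] == pytest.approx(r_manual, abs=1e-12)

    def test_independent_variables_weakly_correlated(self):
        rng = np.random.default_rng(2024)
        rows = [
            _stats_row(f"c{i}", float(rng.uniform(10, 50)), int(rng.integers(5, 100)))
            for i in range(24)
        ]
        res = density_pair_correlation(rows, "pair_count")
        assert abs(res["pearson_r"]) < 0.5

    def test_zero_variance_is_undefined(self):
        rows = [_stats_row(f"c{i}", 25.0, i + 1) for i in range(4)]
        with pytest.raises(ValueError, match="undefined"):
            density_pair_correlation(rows, "pair_count")

    def test_ratio_variant_supported(self):
        rng = np.random.default_rng(3)
        rows = [
            _stats_row(f"c{i}", float(rng.uniform(10, 50)), 5, ratio=float(rng.uniform(0.05, 0.2)))
            for i in range(10)
        ]
        res = density_pair_correlation(rows, "divergent_ratio")
        assert -1.0 <= res["pearson_r"] <= 1.0
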