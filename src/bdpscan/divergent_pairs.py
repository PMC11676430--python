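"""Head-to-head (divergent) gene pair detection and genome-wide statistics.

A divergent gene pair is two adjacent genes on opposite strands whose TSSs
are separated by less than a threshold (1000 bp by default). The inter-TSS
region is the candidate bidirectional promoter (BDP). Pairs whose plus-strand
TSS lies at or upstream of the minus-strand TSS have overlapping 5' ends.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .annotation_io import GeneModel, GenomeAnnotation, GenomicInterval

__all__ = [
    "OVERLAPPING",
    "NON_OVERLAPPING",
    "DivergentPair",
    "ChromosomeStats",
    "find_divergent_pairs",
    "classify_overlap",
    "chromosome_stats",
    "stats_to_frame",
    "density_pair_correlation",
    "pairs_to_frame",
]

OVERLAPPING = "overlapping_5prime"
NON_OVERLAPPING = "non_overlapping"


@dataclass(frozen=True)
class DivergentPair:
    """Two opposite-strand genes whose TSSs face each other within threshold."""

    gene_minus: GeneModel
    gene_plus: GeneModel

    def __post_init__(self) -> None:
        if self.gene_minus.strand != "-" or self.gene_plus.strand != "+":
            raise ValueError("DivergentPair requires a (minus, plus) gene pair")
        if self.gene_minus.chrom != self.gene_plus.chrom:
            raise ValueError("pair genes must share a chromosome")

    @property
    def pair_id(self) -> str:
        return f"{self.gene_minus.gene_id}|{self.gene_plus.gene_id}"

    @property
    def chrom(self) -> str:
        return self.gene_plus.chrom

    @property
    def tss_distance(self) -> int:
        return abs(self.gene_plus.tss - self.gene_minus.tss)

    @property
    def overlap_class(self) -> str:
        return classify_overlap(self)

    @property
    def bdp_interval(self) -> GenomicInterval:
        lo = min(self.gene_minus.tss, self.gene_plus.tss)
        hi = max(self.gene_minus.tss, self.gene_plus.tss)
        return GenomicInterval(self.chrom, lo, hi, name=self.pair_id)


def classify_overlap(pair: DivergentPair) -> str:
    """Overlap class of a pair: 5' ends overlap iff tss_plus <= tss_minus.

    When the plus-strand TSS is not downstream of the minus-strand TSS the
    two transcribed regions share the inter-TSS interval; equality (a shared
    TSS position) is a zero-length spacer and counts as overlapping.
    """
    return OVERLAPPING if pair.gene_plus.tss <= pair.gene_minus.tss else NON_OVERLAPPING


def find_divergent_pairs(
    annotation: GenomeAnnotation, max_tss_distance: int = 1000
) -> list[DivergentPair]:
    """Identify divergent gene pairs with TSS distance strictly below threshold.

    Rules, applied per chromosome:

    * candidate pairs are one minus-strand and one plus-strand gene with
      ``|tss_plus - tss_minus| < max_tss_distance``;
    * the two genes must be adjacent: no third gene's TSS strictly between
      the pair's TSSs;
    * each gene joins at most one pair — when a gene has several candidate
      partners the smallest TSS distance wins, ties broken by the
      lexicographically smaller partner gene_id.

    Output is sorted by (chrom, leftmost TSS).
    """
    selected: list[DivergentPair] = []
    for chrom, genes in sorted(annotation.by_chrom().items()):
        all_tss = sorted(g.tss for g in genes)
        plus = sorted((g for g in genes if g.strand == "+"), key=lambda g: g.tss)
        plus_tss = [g.tss for g in plus]
        candidates: list[tuple[int, str, str, DivergentPair]] = []
        for gm in (g for g in genes if g.strand == "-"):
            lo_i = bisect.bisect_left(plus_tss, gm.tss - max_tss_distance + 1)
            hi_i = bisect.bisect_right(plus_tss, gm.tss + max_tss_distance - 1)
            for gp in plus[lo_i:hi_i]:
                dist = abs(gp.tss - gm.tss)
                lo, hi = min(gm.tss, gp.tss), max(gm.tss, gp.tss)
                # adjacency: no third gene's TSS strictly inside (lo, hi);
                # the pair's own TSSs sit at the endpoints, never inside
                if bisect.bisect_left(all_tss, hi) > bisect.bisect_right(all_tss, lo):
                    continue
                candidates.append(
                    (dist, gm.gene_id, gp.gene_id, DivergentPair(gm, gp))
                )
        used: set[str] = set()
        for dist, mid, pid, pair in sorted(candidates, key=lambda c: c[:3]):
            if mid in used or pid in used:
                continue
            used.update((mid, pid))
            selected.append(pair)
    selected.sort(key=lambda p: (p.chrom, p.bdp_interval.start))
    return selected


@dataclass(frozen=True)
class ChromosomeStats:
    """Per-chromosome gene density and divergent-pair summary."""

    chrom: str
    size_mb: float
    total_genes: int
    gene_density: float
    pair_count: int
    divergent_gene_count: int
    divergent_ratio: float


def chromosome_stats(
    annotation: GenomeAnnotation, pairs: list[DivergentPair]
) -> list[ChromosomeStats]:
    """One stats row per chromosome plus a genome-total row (chrom='Total').

    Gene density is total genes / chromosome length in Mb; the divergent
    ratio is the fraction of the chromosome's genes found in divergent pairs.
    """
    by_chrom = annotation.by_chrom()
    pair_by_chrom: dict[str, list[DivergentPair]] = {}
    for p in pairs:
        pair_by_chrom.setdefault(p.chrom, []).append(p)

    rows: list[ChromosomeStats] = []
    for chrom in sorted(by_chrom):
        genes = by_chrom[chrom]
        cpairs = pair_by_chrom.get(chrom, [])
        div_genes = {g.gene_id for p in cpairs for g in (p.gene_minus, p.gene_plus)}
        size = annotation.chrom_sizes.get(chrom)
        size_mb = size / 1e6 if size else float("nan")
        rows.append(
            ChromosomeStats(
                chrom=chrom,
                size_mb=size_mb,
                total_genes=len(genes),
                gene_density=len(genes) / size_mb if size else float("nan"),
                pair_count=len(cpairs),
                divergent_gene_count=len(div_genes),
                divergent_ratio=len(div_genes) / len(genes) if genes else 0.0,
            )
        )
    total_genes = sum(r.total_genes for r in rows)
    total_div = sum(r.divergent_gene_count for r in rows)
    total_size = sum(r.size_mb for r in rows if r.size_mb == r.size_mb)
    rows.append(
        ChromosomeStats(
            chrom="Total",
            size_mb=total_size,
            total_genes=total_genes,
            gene_density=total_genes / total_size if total_size else float("nan"),
            pair_count=len(pairs),
            divergent_gene_count=total_div,
            divergent_ratio=total_div / total_genes if total_genes else 0.0,
        )
    )
    return rows


def stats_to_frame(rows: list[ChromosomeStats]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def density_pair_correlation(
    rows: list[ChromosomeStats], y_variable: str = "pair_count"
) -> dict[str, float]:
    """Pearson correlation (and regression line) of gene density vs pairs.

    ``y_variable`` selects the response: per-chromosome pair count or the
    divergent ratio. Genome-total rows are excluded. Raises ValueError when
    either variable has zero variance (correlation undefined).
    """
    if y_variable not in ("pair_count", "divergent_ratio"):
        raise ValueError(f"unsupported y_variable '{y_variable}'")
    data = [r for r in rows if r.chrom != "Total" and r.gene_density == r.gene_density]
    if len(data) < 3:
        raise ValueError("need at least 3 chromosomes with finite density")
    x = [r.gene_density for r in data]
    y = [getattr(r, y_variable) for r in data]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("zero variance in density or response: correlation undefined")
    r, pvalue = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return {
        "pearson_r": float(r),
        "p_value": float(pvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n": len(data),
    }


def pairs_to_frame(pairs: list[DivergentPair]) -> pd.DataFrame:
    """Tidy table of pairs: ids, strands, TSSs, distance, overlap class."""
    return pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "chrom": p.chrom,
                "gene_minus": p.gene_minus.gene_id,
                "gene_plus": p.gene_plus.gene_id,
                "tss_minus": p.gene_minus.tss,
                "tss_plus": p.gene_plus.tss,
                "tss_distance": p.tss_distance,
                "overlap_class": p.overlap_class,
                "bdp_start": p.bdp_interval.start,
                "bdp_end": p.bdp_interval.end,
            }
            for p in pairs
        ],
        columns=[
            "pair_id",
            "chrom",
            "gene_minus",
            "gene_plus",
            "tss_minus",
            "tss_plus",
            "tss_distance",
            "overlap_class",
            "bdp_start",
            "bdp_end",
        ],
    )
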