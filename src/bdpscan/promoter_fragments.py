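"""Extraction and characterization of promoter fragments.

BDP fragments are the inter-TSS regions of divergent gene pairs (or, for the
between-ATG variant used when TSSs sit very close together, the span between
the two annotated start codons). Control fragments are fixed-length windows
upstream of randomly sampled genes that belong to no divergent pair. Both
kinds are summarized by length and GC content.

Fragment spans are inclusive of both boundary coordinates, so a
non-overlapping pair with TSS distance d yields a fragment of d + 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import GenomeAccessor, GenomeAnnotation, GenomicInterval
from .divergent_pairs import DivergentPair

__all__ = [
    "PromoterFragment",
    "FragmentSummary",
    "extract_bdp_fragment",
    "sample_control_promoters",
    "gc_content",
    "summarize_fragments",
    "fragments_to_frame",
    "write_fragments_fasta",
]

LENGTH_BIN_BP = 100
GC_BAND_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)


@dataclass(frozen=True)
class PromoterFragment:
    """A promoter sequence slice with its length and GC content."""

    fragment_id: str
    source: str  # "bdp" | "control"
    interval: GenomicInterval
    sequence: str
    pair_overlap_class: str | None = None

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        return gc_content(self.sequence)


def gc_content(sequence: str) -> float:
    """GC fraction (#G + #C) / (#A + #C + #G + #T); ambiguity codes excluded.

    Returns NaN for sequences with no unambiguous base.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def extract_bdp_fragment(
    pair: DivergentPair, genome: GenomeAccessor, mode: str = "between_tss"
) -> PromoterFragment:
    """Extract the pair's promoter fragment from the reference plus strand.

    ``between_tss`` takes the inclusive span of the two TSSs; ``between_atg``
    the inclusive span of the two start-codon A positions (requires an
    annotated CDS on both genes).
    """
    if mode == "between_tss":
        a, b = pair.gene_minus.tss, pair.gene_plus.tss
    elif mode == "between_atg":
        for g in (pair.gene_minus, pair.gene_plus):
            if g.cds_start is None:
                raise ValueError(
                    f"between_atg mode: gene {g.gene_id} has no annotated CDS"
                )
        a, b = pair.gene_minus.cds_start, pair.gene_plus.cds_start
    else:
        raise ValueError(f"unknown fragment mode '{mode}'")
    lo, hi = min(a, b), max(a, b)
    interval = GenomicInterval(pair.chrom, lo, hi, name=pair.pair_id)
    seq = genome.fetch(pair.chrom, lo, hi)
    return PromoterFragment(
        fragment_id=f"bdp|{pair.pair_id}|{mode}",
        source="bdp",
        interval=interval,
        sequence=seq,
        pair_overlap_class=pair.overlap_class,
    )


def sample_control_promoters(
    annotation: GenomeAnnotation,
    genome: GenomeAccessor,
    pairs: list[DivergentPair],
    n: int = 3000,
    upstream_bp: int = 1000,
    seed: int = 0,
) -> list[PromoterFragment]:
    """Sample unidirectional-promoter controls: upstream windows of non-pair genes.

    ``n`` genes outside every divergent pair are drawn without replacement
    (reproducibly under ``seed``) and the ``upstream_bp`` bases upstream of
    each TSS extracted, strand-aware: upstream of a minus-strand gene extends
    rightward on the reference and is reverse-complemented so every control
    reads promoter-proximal 3' end last. Genes whose upstream window would
    run off the contig are ineligible.
    """
    paired = {
        g.gene_id for p in pairs for g in (p.gene_minus, p.gene_plus)
    }
    sizes = annotation.chrom_sizes or genome.chrom_sizes()
    eligible = []
    for g in annotation.genes:
        if g.gene_id in paired:
            continue
        if g.strand == "+":
            lo, hi = g.tss - upstream_bp, g.tss - 1
        else:
            lo, hi = g.tss + 1, g.tss + upstream_bp
        if lo < 1:
            continue
        size = sizes.get(g.chrom)
        if size is None or hi > size:
            continue
        eligible.append((g, lo, hi))
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} genes eligible as controls, need {n}"
        )
    eligible.sort(key=lambda t: t[0].gene_id)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n, replace=False)
    fragments = []
    for i in sorted(chosen):
        g, lo, hi = eligible[i]
        seq = genome.fetch(g.chrom, lo, hi, revcomp=(g.strand == "-"))
        fragments.append(
            PromoterFragment(
                fragment_id=f"control|{g.gene_id}|up{upstream_bp}",
                source="control",
                interval=GenomicInterval(g.chrom, lo, hi, name=g.gene_id, strand=g.strand),
                sequence=seq,
            )
        )
    return fragments


@dataclass(frozen=True)
class FragmentSummary:
    """Length/GC summary of a fragment set."""

    n: int
    mean_gc_percent: float
    median_gc_percent: float
    length_histogram: dict[str, int]
    gc_histogram: dict[str, int]
    fraction_shorter_than_400: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_gc_percent": self.mean_gc_percent,
            "median_gc_percent": self.median_gc_percent,
            "length_histogram_bp_bins": self.length_histogram,
            "gc_histogram_percent_bands": self.gc_histogram,
            "fraction_shorter_than_400": self.fraction_shorter_than_400,
            "binning": "left-closed right-open; lengths in 100-bp bins, GC in 20-point bands",
        }


def summarize_fragments(fragments: list[PromoterFragment]) -> FragmentSummary:
    """Mean/median GC (percent) and length/GC histograms of a fragment set.

    Length bins are 100 bp wide, [0,100), [100,200), ...; GC bands are
    20-percentage-point wide with the last band closed at 100. Fragments
    with undefined GC (all ambiguous) are excluded from GC statistics but
    kept in the length histogram.
    """
    if not fragments:
        raise ValueError("no fragments to summarize")
    lengths = np.array([f.length_bp for f in fragments])
    gcs = np.array([f.gc_fraction for f in fragments]) * 100.0
    gc_valid = gcs[~np.isnan(gcs)]

    length_hist: dict[str, int] = {}
    for length in lengths:
        lo = (int(length) // LENGTH_BIN_BP) * LENGTH_BIN_BP
        key = f"[{lo},{lo + LENGTH_BIN_BP})"
        length_hist[key] = length_hist.get(key, 0) + 1

    gc_hist: dict[str, int] = {}
    for gc in gc_valid:
        for lo, hi in zip(GC_BAND_EDGES[:-1], GC_BAND_EDGES[1:]):
            if lo <= gc < hi or (hi == 100.0 and gc == 100.0):
                key = f"[{lo:.0f},{hi:.0f})" if hi < 100 else f"[{lo:.0f},{hi:.0f}]"
                gc_hist[key] = gc_hist.get(key, 0) + 1
                break

    return FragmentSummary(
        n=len(fragments),
        mean_gc_percent=float(np.mean(gc_valid)) if gc_valid.size else float("nan"),
        median_gc_percent=float(np.median(gc_valid)) if gc_valid.size else float("nan"),
        length_histogram=dict(sorted(length_hist.items(), key=lambda kv: int(kv[0][1:].split(",")[0]))),
        gc_histogram=gc_hist,
        fraction_shorter_than_400=float(np.mean(lengths < 400)),
    )


def fragments_to_frame(fragments: list[PromoterFragment]) -> pd.DataFrame:
    """Per-fragment table of coordinates, length, and GC."""
    return pd.DataFrame(
        [
            {
                "fragment_id": f.fragment_id,
                "source": f.source,
                "chrom": f.interval.chrom,
                "start": f.interval.start,
                "end": f.interval.end,
                "length_bp": f.length_bp,
                "gc_fraction": f.gc_fraction,
                "pair_overlap_class": f.pair_overlap_class,
            }
            for f in fragments
        ],
        columns=[
            "fragment_id",
            "source",
            "chrom",
            "start",
            "end",
            "length_bp",
            "gc_fraction",
            "pair_overlap_class",
        ],
    )


def write_fragments_fasta(fragments: list[PromoterFragment], path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f">{f.fragment_id} {f.interval.chrom}:{f.interval.start}-{f.interval.end}\n")
            for i in range(0, len(f.sequence), 60):
                fh.write(f.sequence[i : i + 60] + "\n")
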