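"""Synthetic genomes, annotations, expression tables, and motif plants.

Every pipeline stage is testable against known ground truth: the generator
emits a multi-chromosome FASTA + GFF3 containing planted head-to-head gene
pairs at controlled TSS distances (including 5'-overlapping pairs) among
isolated background genes, FPKM tables with planted per-tissue state
proportions, and promoter sequences with planted motif instances. All
outputs are deterministic functions of their spec and seed.

Planted loci are separated by at least ``min_locus_gap`` (2 kb by default,
comfortably above the 1 kb pairing threshold), so the planted pairs are
exactly the divergent pairs present in the annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .divergent_pairs import NON_OVERLAPPING, OVERLAPPING

__all__ = [
    "GenomeSpec",
    "ExpressionSpec",
    "SyntheticGenome",
    "default_tss_distance_sampler",
    "generate_genome",
    "generate_expression",
    "plant_motifs",
    "DEFAULT_TISSUE_PROPORTIONS",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Per-tissue (co_expressed, unidirectional, co_silent) proportions observed
#: in medaka gonads, brain, and liver; used as generator defaults.
DEFAULT_TISSUE_PROPORTIONS: dict[str, tuple[float, float, float]] = {
    "ovary": (0.502, 0.459, 0.039),
    "testis": (0.508, 0.451, 0.041),
    "brain_F": (0.522, 0.456, 0.022),
    "brain_M": (0.510, 0.460, 0.030),
    "liver_F": (0.402, 0.582, 0.016),
    "liver_M": (0.368, 0.612, 0.020),
}


def default_tss_distance_sampler(rng: np.random.Generator) -> int:
    """Draw an inter-TSS distance in [1, 999], skewed toward short spacers.

    A Beta(1, 1.357) rescaled to [1, 999] puts about half of the mass below
    400 bp, matching the compactness of fish bidirectional promoters.
    """
    return 1 + int(998 * rng.beta(1.0, 1.357))


@dataclass
class GenomeSpec:
    """Parameters of a synthetic genome with planted divergent pairs."""

    n_chromosomes: int = 4
    chrom_length_bp: int = 600_000
    n_divergent_pairs: int = 40
    fraction_overlapping: float = 0.20
    n_background_genes: int = 120
    bdp_gc_target: float = 0.42
    background_gc_target: float = 0.38
    #: (consensus, pair index, 1-based offset within the pair's inter-TSS
    #: fragment, strand)
    planted_motifs: list[tuple[str, int, int, str]] = field(default_factory=list)
    tss_distance_sampler: Callable[[np.random.Generator], int] | None = None
    min_locus_gap: int = 2000
    margin_bp: int = 3000
    gene_length_range: tuple[int, int] = (500, 2000)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chrom_length_bp, self.n_divergent_pairs) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.fraction_overlapping <= 1:
            raise ValueError("fraction_overlapping must be in [0, 1]")
        for gc in (self.bdp_gc_target, self.background_gc_target):
            if not 0 < gc < 1:
                raise ValueError("GC targets must be in (0, 1)")


@dataclass
class SyntheticGenome:
    """Generator output: file paths plus in-memory truth tables."""

    fasta_path: Path
    gff_path: Path
    pairs_truth: pd.DataFrame
    motifs_truth: pd.DataFrame
    chrom_sizes: dict[str, int]
    manifest_path: Path


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_start: int
    cds_end: int


def _sample_pair_geometry(spec: GenomeSpec, rng: np.random.Generator, overlapping: bool):
    """Relative coordinates (0-based within the locus) of one planted pair."""
    sampler = spec.tss_distance_sampler or default_tss_distance_sampler
    d = sampler(rng)
    if not 1 <= d < 1000:
        raise ValueError(f"tss_distance_sampler returned {d}, outside [1, 999]")
    lo_len, hi_len = spec.gene_length_range
    lm = int(rng.integers(lo_len, hi_len + 1))
    lp = int(rng.integers(lo_len, hi_len + 1))
    if overlapping:
        # minus gene [0, lm-1] with tss at its right end; the plus gene's
        # TSS sits d bp inside the minus gene body, bodies overlapping
        lm = max(lm, d + 100)
        lp = max(lp, d + 100)
        tss_m = lm - 1
        tss_p = tss_m - d
        minus = (0, lm - 1)
        plus = (tss_p, tss_p + lp - 1)
    else:
        tss_m = lm - 1
        tss_p = tss_m + d
        minus = (0, lm - 1)
        plus = (tss_p, tss_p + lp - 1)
    span = max(minus[1], plus[1]) + 1
    return d, minus, plus, tss_m, tss_p, span


def generate_genome(spec: GenomeSpec, out_dir: str | Path) -> SyntheticGenome:
    """Write a synthetic FASTA + GFF3 with planted pairs and truth tables.

    Exactly ``round(n_divergent_pairs * fraction_overlapping)`` planted
    pairs have overlapping 5' ends. Raises ValueError naming the required
    minimum chromosome length when the spec does not fit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    n_overlap = round(spec.n_divergent_pairs * spec.fraction_overlapping)
    overlap_flags = np.zeros(spec.n_divergent_pairs, dtype=bool)
    overlap_flags[:n_overlap] = True
    rng.shuffle(overlap_flags)

    # sample all locus geometries first, then check the spec fits
    pair_geoms = [
        _sample_pair_geometry(spec, rng, bool(flag)) for flag in overlap_flags
    ]
    lo_len, hi_len = spec.gene_length_range
    bg_lengths = rng.integers(lo_len, hi_len + 1, size=spec.n_background_genes)
    bg_strands = rng.choice(["+", "-"], size=spec.n_background_genes)

    loci: list[tuple[str, int]] = [("pair", i) for i in range(spec.n_divergent_pairs)]
    loci += [("background", i) for i in range(spec.n_background_genes)]

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    per_chrom: dict[str, list[tuple[str, int]]] = {c: [] for c in chrom_names}
    for i, locus in enumerate(loci):
        per_chrom[chrom_names[i % spec.n_chromosomes]].append(locus)

    def _span(locus: tuple[str, int]) -> int:
        kind, i = locus
        return pair_geoms[i][5] if kind == "pair" else int(bg_lengths[i])

    required = max(
        2 * spec.margin_bp
        + sum(_span(l) for l in chrom_loci)
        + spec.min_locus_gap * max(len(chrom_loci) - 1, 0)
        for chrom_loci in per_chrom.values()
    )
    if required > spec.chrom_length_bp:
        raise ValueError(
            f"spec does not fit: chrom_length_bp must be at least {required}"
        )

    genes: list[_Gene] = []
    pair_rows: list[dict] = []
    for chrom, chrom_loci in per_chrom.items():
        cursor = spec.margin_bp + 1  # 1-based
        for kind, i in chrom_loci:
            if kind == "pair":
                d, minus, plus, tss_m, tss_p, span = pair_geoms[i]
                gm_id, gp_id = f"gM{i:05d}", f"gP{i:05d}"
                gm = _Gene(
                    gene_id=gm_id,
                    chrom=chrom,
                    start=cursor + minus[0],
                    end=cursor + minus[1],
                    strand="-",
                    cds_start=0,
                    cds_end=0,
                )
                gp = _Gene(
                    gene_id=gp_id,
                    chrom=chrom,
                    start=cursor + plus[0],
                    end=cursor + plus[1],
                    strand="+",
                    cds_start=0,
                    cds_end=0,
                )
                utr_m = int(rng.integers(20, 61))
                utr_p = int(rng.integers(20, 61))
                # minus gene: start-codon A sits utr_m bp downstream (leftward) of its TSS
                gm.cds_end = gm.end - utr_m
                gm.cds_start = gm.cds_end - 299
                gp.cds_start = gp.start + utr_p
                gp.cds_end = gp.cds_start + 299
                genes.extend([gm, gp])
                abs_tss_m = cursor + tss_m
                abs_tss_p = cursor + tss_p
                pair_rows.append(
                    {
                        "pair_index": i,
                        "pair_id": f"{gm_id}|{gp_id}",
                        "chrom": chrom,
                        "gene_minus": gm_id,
                        "gene_plus": gp_id,
                        "tss_minus": abs_tss_m,
                        "tss_plus": abs_tss_p,
                        "tss_distance": d,
                        "overlap_class": OVERLAPPING if abs_tss_p <= abs_tss_m else NON_OVERLAPPING,
                        "bdp_start": min(abs_tss_m, abs_tss_p),
                        "bdp_end": max(abs_tss_m, abs_tss_p),
                    }
                )
                cursor += span + spec.min_locus_gap
            else:
                length = int(bg_lengths[i])
                strand = str(bg_strands[i])
                gid = f"gB{i:05d}"
                g = _Gene(
                    gene_id=gid,
                    chrom=chrom,
                    start=cursor,
                    end=cursor + length - 1,
                    strand=strand,
                    cds_start=0,
                    cds_end=0,
                )
                utr = int(rng.integers(20, 61))
                if strand == "+":
                    g.cds_start = g.start + utr
                    g.cds_end = g.cds_start + 299
                else:
                    g.cds_end = g.end - utr
                    g.cds_start = g.cds_end - 299
                genes.append(g)
                cursor += length + spec.min_locus_gap

    pairs_truth = pd.DataFrame(pair_rows).sort_values(
        ["chrom", "bdp_start"], ignore_index=True
    )

    # chromosome sequences: background composition everywhere, BDP
    # composition inside the planted inter-TSS fragments
    def _probs(gc: float) -> np.ndarray:
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    seqs: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        seqs[chrom] = rng.choice(
            BASES, size=spec.chrom_length_bp, p=_probs(spec.background_gc_target)
        )
    for row in pair_rows:
        lo, hi = row["bdp_start"], row["bdp_end"]
        seqs[row["chrom"]][lo - 1 : hi] = rng.choice(
            BASES, size=hi - lo + 1, p=_probs(spec.bdp_gc_target)
        )

    # plant motif consensus sequences inside BDP fragments
    motif_rows: list[dict] = []
    truth_by_index = {row["pair_index"]: row for row in pair_rows}
    for consensus, pair_index, offset, strand in spec.planted_motifs:
        if pair_index not in truth_by_index:
            raise ValueError(f"planted motif references unknown pair {pair_index}")
        row = truth_by_index[pair_index]
        frag_len = row["bdp_end"] - row["bdp_start"] + 1
        if offset < 1 or offset + len(consensus) - 1 > frag_len:
            raise ValueError(
                f"motif '{consensus}' at offset {offset} does not fit in "
                f"fragment of pair {pair_index} (length {frag_len})"
            )
        seq = consensus.upper()
        if strand == "-":
            seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        pos = row["bdp_start"] + offset - 1
        seqs[row["chrom"]][pos - 1 : pos - 1 + len(seq)] = np.frombuffer(
            seq.encode(), dtype="S1"
        )
        motif_rows.append(
            {
                "pair_index": pair_index,
                "pair_id": row["pair_id"],
                "consensus": consensus.upper(),
                "fragment_offset": offset,
                "strand": strand,
                "chrom": row["chrom"],
                "genome_start": pos,
                "genome_end": pos + len(seq) - 1,
            }
        )
    motifs_truth = pd.DataFrame(
        motif_rows,
        columns=[
            "pair_index",
            "pair_id",
            "consensus",
            "fragment_offset",
            "strand",
            "chrom",
            "genome_start",
            "genome_end",
        ],
    )

    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom in chrom_names:
            fh.write(f">{chrom}\n")
            s = seqs[chrom].tobytes().decode()
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")

    gff_path = out_dir / "annotation.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in chrom_names:
            fh.write(f"##sequence-region {chrom} 1 {spec.chrom_length_bp}\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tbdpscan_synth\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tbdpscan_synth\tmRNA\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            lo, hi = min(g.cds_start, g.cds_end), max(g.cds_start, g.cds_end)
            fh.write(
                f"{g.chrom}\tbdpscan_synth\tCDS\t{lo}\t{hi}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
            )

    chrom_sizes = {c: spec.chrom_length_bp for c in chrom_names}
    pairs_truth.to_csv(out_dir / "pairs_truth.tsv", sep="\t", index=False)
    motifs_truth.to_csv(out_dir / "motifs_truth.tsv", sep="\t", index=False)
    manifest_path = out_dir / "manifest.json"
    manifest = {
        "generator": "bdpscan.synthetic_data.generate_genome",
        "seed": spec.seed,
        "n_chromosomes": spec.n_chromosomes,
        "chrom_length_bp": spec.chrom_length_bp,
        "n_divergent_pairs": spec.n_divergent_pairs,
        "n_overlapping": int(n_overlap),
        "fraction_overlapping": spec.fraction_overlapping,
        "n_background_genes": spec.n_background_genes,
        "bdp_gc_target": spec.bdp_gc_target,
        "background_gc_target": spec.background_gc_target,
        "n_planted_motifs": len(spec.planted_motifs),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    return SyntheticGenome(
        fasta_path=fasta_path,
        gff_path=gff_path,
        pairs_truth=pairs_truth,
        motifs_truth=motifs_truth,
        chrom_sizes=chrom_sizes,
        manifest_path=manifest_path,
    )


@dataclass
class ExpressionSpec:
    """Parameters of a synthetic FPKM table with planted pair states."""

    tissues: list[str] = field(
        default_factory=lambda: list(DEFAULT_TISSUE_PROPORTIONS)
    )
    replicates: int = 3
    #: tissue -> (co_expressed, unidirectional, co_silent); tissues missing
    #: from the map fall back to the ovary proportions
    proportions: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_PROPORTIONS)
    )
    fpkm_scale: float = 20.0
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        for tissue, props in self.proportions.items():
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(f"proportions for {tissue} do not sum to 1")


def _allocate_counts(n: int, props: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of n items to the given proportions."""
    raw = [p * n for p in props]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(props)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def generate_expression(
    pairs_truth: pd.DataFrame,
    spec: ExpressionSpec,
    extra_gene_ids: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an FPKM table realizing planted per-tissue pair states.

    Returns ``(fpkm, truth)``: an FPKM matrix indexed by gene_id with
    columns ``{tissue}_r{i}``, and a truth table (pair_id, tissue, state).
    Planted states sit away from the decision boundaries (co-expressed
    ratios inside [0.4, 2.5], unidirectional ratios >= 6, silent FPKMs
    <= 0.7), so mean-of-replicates classification recovers them at
    moderate replicate noise; with ``noise_cv = 0`` recovery is exact.
    """
    rng = np.random.default_rng(spec.seed)
    pair_ids = list(pairs_truth["pair_id"])
    gene_a = list(pairs_truth["gene_minus"])
    gene_b = list(pairs_truth["gene_plus"])
    n = len(pair_ids)

    states_order = ("co_expressed", "unidirectional", "co_silent")
    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))

    columns: dict[str, np.ndarray] = {}
    truth_rows: list[dict] = []
    all_genes = list(dict.fromkeys(gene_a + gene_b + list(extra_gene_ids)))
    gene_index = {g: i for i, g in enumerate(all_genes)}

    for tissue in spec.tissues:
        props = spec.proportions.get(tissue, DEFAULT_TISSUE_PROPORTIONS["ovary"])
        counts = _allocate_counts(n, props)
        states = np.repeat(states_order, counts)
        rng.shuffle(states)
        base_means = np.zeros((len(all_genes),), dtype=float)
        # background/extra genes: plain lognormal expression
        for g in extra_gene_ids:
            base_means[gene_index[g]] = rng.lognormal(np.log(spec.fpkm_scale), 1.0)
        for pid, ga, gb, state in zip(pair_ids, gene_a, gene_b, states):
            if state == "co_expressed":
                base = max(rng.lognormal(np.log(spec.fpkm_scale), 0.8), 4.0)
                ratio = np.exp(rng.uniform(np.log(0.4), np.log(2.5)))
                a, b = base * np.sqrt(ratio), base / np.sqrt(ratio)
            elif state == "co_silent":
                a = rng.uniform(0.02, 0.7)
                b = rng.uniform(0.02, 0.7)
            else:
                high = max(rng.lognormal(np.log(spec.fpkm_scale), 0.8), 5.0)
                low = high / np.exp(rng.uniform(np.log(6.0), np.log(50.0)))
                if rng.random() < 0.5:
                    a, b = high, low
                else:
                    a, b = low, high
            base_means[gene_index[ga]] = a
            base_means[gene_index[gb]] = b
            truth_rows.append({"pair_id": pid, "tissue": tissue, "state": state})
        for r in range(1, spec.replicates + 1):
            if spec.noise_cv == 0:
                vals = base_means.copy()
            else:
                noise = rng.lognormal(-(sigma**2) / 2, sigma, size=len(all_genes))
                vals = base_means * noise
            columns[f"{tissue}_r{r}"] = vals

    fpkm = pd.DataFrame(columns, index=pd.Index(all_genes, name="gene_id"))
    truth = pd.DataFrame(truth_rows, columns=["pair_id", "tissue", "state"])
    return fpkm, truth


def plant_motifs(
    sequences: dict[str, str],
    planted: list[tuple[str, str, int, str]],
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write motif consensus strings into fragment sequences.

    ``planted`` holds (consensus, fragment_id, 1-based offset, strand); a
    minus-strand plant writes the reverse complement so a double-stranded
    scan reports the motif on '-' at the stated position. Returns the
    modified sequences and a truth table.
    """
    out = dict(sequences)
    rows = []
    for consensus, frag_id, offset, strand in planted:
        if frag_id not in out:
            raise KeyError(f"unknown fragment '{frag_id}'")
        seq = out[frag_id]
        ins = consensus.upper()
        if strand == "-":
            ins = ins.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        if offset < 1 or offset + len(ins) - 1 > len(seq):
            raise ValueError(
                f"motif '{consensus}' at offset {offset} does not fit fragment "
                f"'{frag_id}' (length {len(seq)})"
            )
        out[frag_id] = seq[: offset - 1] + ins + seq[offset - 1 + len(ins) :]
        rows.append(
            {
                "fragment_id": frag_id,
                "consensus": consensus.upper(),
                "start": offset,
                "end": offset + len(ins) - 1,
                "strand": strand,
            }
        )
    truth = pd.DataFrame(
        rows, columns=["fragment_id", "consensus", "start", "end", "strand"]
    )
    return out, truth
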