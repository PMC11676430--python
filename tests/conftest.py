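"""Shared fixtures and independent reference oracles for the test suite.

The oracles here deliberately re-derive results by the most naive route
available (exhaustive enumeration, plain regex, per-window loops) so the
package implementations are checked against logic that shares no code with
them.
"""

from __future__ import annotations

import itertools
import re

import numpy as np
import pytest
from hypothesis import settings

from bdpscan.annotation_io import GeneModel, GenomeAnnotation, reverse_complement
from bdpscan.synthetic_data import GenomeSpec, generate_genome

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_genome(tmp_path_factory):
    """A small planted genome shared by read-only tests."""
    spec = GenomeSpec(
        n_chromosomes=3,
        chrom_length_bp=250_000,
        n_divergent_pairs=12,
        n_background_genes=30,
        seed=42,
    )
    out = generate_genome(spec, tmp_path_factory.mktemp("synth"))
    return out, spec


@pytest.fixture()
def jaspar_file(tmp_path):
    path = tmp_path / "motifs.jaspar"
    path.write_text(
        ">MA0001.1 ALPHA\n"
        "A [ 90  1  1  1  1 ]\n"
        "C [  1 90  1  1 90 ]\n"
        "G [  1  1 90  1  1 ]\n"
        "T [  1  1  1 90  1 ]\n"
        ">MA0002.1 BETA\n"
        "A [ 4.5 0.5 ]\n"
        "C [ 0.5 4.5 ]\n"
        "G [ 2.0 2.0 ]\n"
        "T [ 1.0 1.0 ]\n"
    )
    return path


def make_gene(
    gene_id: str,
    tss: int,
    strand: str,
    length: int = 500,
    chrom: str = "chr1",
    cds_offset: int | None = None,
) -> GeneModel:
    """Build a gene from its TSS (the natural handle in pairing tests)."""
    if strand == "+":
        start, end = tss, tss + length - 1
        cds = tss + cds_offset if cds_offset is not None else None
    else:
        start, end = tss - length + 1, tss
        cds = tss - cds_offset if cds_offset is not None else None
    return GeneModel(
        gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand, cds_start=cds
    )


def brute_force_pairs(annotation: GenomeAnnotation, max_tss_distance: int = 1000):
    """Exhaustive reference for divergent-pair finding on small inputs.

    Enumerates every (minus, plus) gene combination, applies the strand /
    distance / adjacency rules directly, then assigns one pair per gene by
    repeatedly taking the candidate with the smallest
    (distance, minus_id, plus_id) whose genes are both still free.
    Returns a set of (minus_id, plus_id) tuples.
    """
    genes = list(annotation.genes)
    candidates = []
    for gm, gp in itertools.product(genes, genes):
        if gm.strand != "-" or gp.strand != "+" or gm.chrom != gp.chrom:
            continue
        dist = abs(gp.tss - gm.tss)
        if dist >= max_tss_distance:
            continue
        lo, hi = sorted((gm.tss, gp.tss))
        if any(
            lo < other.tss < hi
            for other in genes
            if other.chrom == gm.chrom
            and other.gene_id not in (gm.gene_id, gp.gene_id)
        ):
            continue
        candidates.append((dist, gm.gene_id, gp.gene_id))
    chosen = set()
    used: set[str] = set()
    for dist, mid, pid in sorted(candidates):
        if mid not in used and pid not in used:
            used.update((mid, pid))
            chosen.add((mid, pid))
    return chosen


def regex_core_hits(sequence: str, name: str, pattern: str, both_strands: bool = True):
    """Plain-regex reference for core-element scanning (overlaps allowed).

    Returns a set of (name, start, end, strand, matched) tuples with
    1-based plus-strand coordinates.
    """
    seq = sequence.upper()
    # expand {k} repeats so the match length is fixed and window-like
    rx = re.compile(f"(?=({pattern}))")
    length = len(
        re.sub(r"\[[A-Z]+\]", "N", re.sub(r"\[([A-Z]+)\]\{(\d+)\}", lambda m: "N" * int(m.group(2)), pattern))
    )
    hits = set()
    for m in rx.finditer(seq):
        if "N" in m.group(1):
            continue
        start = m.start() + 1
        hits.add((name, start, start + length - 1, "+", m.group(1)))
    if both_strands:
        rc = reverse_complement(seq)
        for m in rx.finditer(rc):
            if "N" in m.group(1):
                continue
            start = len(seq) - (m.start() + length) + 1
            hits.add((name, start, start + length - 1, "-", m.group(1)))
    return hits


def naive_pwm_hits(sequence: str, pwm, rel_threshold: float, both_strands: bool = True):
    """Per-window loop reference for PWM scanning.

    Returns a set of (start, end, strand) with 1-based plus-strand coords.
    """
    weights = {b: pwm.weights[i] for i, b in enumerate("ACGT")}
    L = pwm.length
    span = pwm.score_max - pwm.score_min

    def _scan(seq: str, strand: str, n: int):
        found = set()
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            if "N" in window:
                continue
            score = sum(weights[c][j] for j, c in enumerate(window))
            if (score - pwm.score_min) / span >= rel_threshold:
                start = i + 1 if strand == "+" else n - (i + L) + 1
                found.add((start, start + L - 1, strand))
        return found

    seq = sequence.upper()
    hits = _scan(seq, "+", len(seq))
    if both_strands:
        hits |= _scan(reverse_complement(seq), "-", len(seq))
    return hits


def random_annotation(rng: np.random.Generator, max_genes: int = 20) -> GenomeAnnotation:
    """A random small annotation for oracle-equivalence tests."""
    n = int(rng.integers(2, max_genes + 1))
    genes = []
    for i in range(n):
        chrom = f"chr{int(rng.integers(1, 3))}"
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(rng.integers(1000, 8000))
        length = int(rng.integers(100, 800))
        genes.append(make_gene(f"g{i:03d}", tss, strand, length=length, chrom=chrom))
    return GenomeAnnotation(genes=genes)


def write_fasta(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
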