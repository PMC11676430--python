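"""Annotation and sequence I/O: GFF3/GTF genes, FASTA access, BED output.

All internal coordinates are 1-based inclusive, matching GFF; conversion to
0-based half-open happens only when writing BED. The transcription start
site (TSS) of a gene is its strand-dependent 5' end: ``start`` on the plus
strand, ``end`` on the minus strand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "GenomicInterval",
    "AnnotationParseError",
    "parse_annotation",
    "load_genome",
    "GenomeAccessor",
    "write_intervals",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationParseError(ValueError):
    """Raised for a structurally malformed annotation record."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene with its strand-aware TSS.

    ``tss`` is the gene-level 5' end: equal to ``start`` for plus-strand
    genes and ``end`` for minus-strand genes. ``cds_start`` is the genomic
    position of the A of the annotated start codon, when a CDS is present.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_start: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class GenomeAnnotation:
    """A collection of genes grouped by chromosome, with optional sizes."""

    genes: list[GeneModel] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    n_rejected: int = 0

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        for g in self.genes:
            size = self.chrom_sizes.get(g.chrom)
            if size is not None and g.end > size:
                raise ValueError(
                    f"gene {g.gene_id} ends at {g.end}, beyond {g.chrom} "
                    f"length {size}"
                )

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: (g.start, g.gene_id))
        return out

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)


def _prevalidate(path: Path) -> None:
    """Cheap structural pass so malformed lines fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}, line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}, line {lineno}: non-integer coordinates"
                ) from exc
            if start > end:
                raise AnnotationParseError(
                    f"{path}, line {lineno}: start {start} > end {end}"
                )


def _gene_id_of(feature: gffutils.Feature) -> str:
    for key in ("ID", "gene_id", "Name", "gene_name"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return feature.id


def parse_annotation(
    path: str | Path,
    feature_type: str = "gene",
    chrom_sizes: dict[str, int] | None = None,
) -> GenomeAnnotation:
    """Read a GFF3 or GTF file into a :class:`GenomeAnnotation`.

    One :class:`GeneModel` is built per feature of ``feature_type``; the TSS
    is derived from the strand, and ``cds_start`` is taken from the gene's
    CDS children when present. Records with a strand other than ``+``/``-``
    are rejected with a warning and counted in ``n_rejected``. Both GFF3 and
    GTF attribute dialects are accepted (sniffed by gffutils).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate(path)

    has_gene_features = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if line.split("\t")[2] == feature_type:
                has_gene_features = True
                break

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=has_gene_features,
        disable_infer_transcripts=has_gene_features,
    )

    genes: list[GeneModel] = []
    n_rejected = 0
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            n_rejected += 1
            warnings.warn(
                f"gene {_gene_id_of(feat)} on {feat.seqid}: strand "
                f"'{feat.strand}' not in {{+,-}}, record rejected",
                stacklevel=2,
            )
            continue
        cds_start: int | None = None
        cds = list(db.children(feat, featuretype="CDS"))
        if cds:
            # A of the start codon: 5'-most CDS base, strand-dependent.
            if feat.strand == "+":
                cds_start = min(c.start for c in cds)
            else:
                cds_start = max(c.end for c in cds)
        genes.append(
            GeneModel(
                gene_id=_gene_id_of(feat),
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                cds_start=cds_start,
            )
        )
    logger.info("parsed %d genes from %s (%d rejected)", len(genes), path, n_rejected)
    return GenomeAnnotation(
        genes=genes, chrom_sizes=chrom_sizes or {}, n_rejected=n_rejected
    )


class GenomeAccessor:
    """Random access to an indexed FASTA with 1-based inclusive slicing."""

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), sequence_always_upper=True)

    def chroms(self) -> list[str]:
        return list(self._fasta.keys())

    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(rec) for name, rec in self._fasta.items()}

    def fetch(self, chrom: str, start: int, end: int, revcomp: bool = False) -> str:
        """Return the sequence of ``chrom[start..end]`` (1-based inclusive)."""
        if chrom not in self._fasta:
            raise KeyError(f"unknown sequence '{chrom}'")
        size = len(self._fasta[chrom])
        if start < 1 or end > size:
            raise IndexError(
                f"interval {chrom}:{start}-{end} outside sequence of length {size}"
            )
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        seq = str(self._fasta[chrom][start - 1 : end])
        return reverse_complement(seq) if revcomp else seq

    def close(self) -> None:
        self._fasta.close()


def load_genome(path: str | Path) -> GenomeAccessor:
    """Open a FASTA file for 1-based inclusive slicing (uppercase output)."""
    return GenomeAccessor(path)


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (0-based half-open), sorted by (chrom, start)."""
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        fh.write("# BED6: chrom, chromStart (0-based), chromEnd, name, score, strand\n")
        for iv in rows:
            name = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file back into 1-based inclusive intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                GenomicInterval(
                    chrom=f[0],
                    start=int(f[1]) + 1,
                    end=int(f[2]),
                    name=f[3] if len(f) > 3 else "",
                    strand=f[5] if len(f) > 5 else ".",
                )
            )
    return out
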