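"""Core promoter element and PWM transcription-factor binding-site scanning.

Two scanners over promoter fragments:

* fixed-length character-class patterns for the classical core promoter
  elements (TATA box, initiator, BRE, DPE, CCAAT box), matched window by
  window on both strands;
* position weight matrix (PWM) scanning of JASPAR motifs, reporting every
  window whose score, rescaled between the matrix's minimum and maximum
  attainable scores, reaches a relative threshold (70% by default).

Minus-strand hits are located by scanning the reverse complement and mapped
back to plus-strand coordinates, so all reported positions are 1-based
inclusive within the scanned fragment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .annotation_io import reverse_complement
from .promoter_fragments import PromoterFragment

__all__ = [
    "CoreElementPattern",
    "CORE_ELEMENTS",
    "PositionFrequencyMatrix",
    "PositionWeightMatrix",
    "MotifHit",
    "scan_core_elements",
    "read_jaspar",
    "pfm_to_pwm",
    "scan_pwm",
    "motif_map",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class CoreElementPattern:
    """A fixed-length promoter element pattern: one allowed base set per position."""

    name: str
    pattern: str
    positions: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.positions)


def _compile_pattern(name: str, pattern: str) -> CoreElementPattern:
    """Expand a character-class string like ``T[AT]A[AT]A[AGT]`` or
    ``[CT]{2}A[CT][AT][CT]{2}`` into per-position base sets."""
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            charset = frozenset(pattern[i + 1 : j])
            i = j + 1
        elif ch in BASES:
            charset = frozenset(ch)
            i += 1
        else:
            raise ValueError(f"pattern {name}: unexpected character '{ch}'")
        repeat = 1
        if i < len(pattern) and pattern[i] == "{":
            j = pattern.index("}", i)
            repeat = int(pattern[i + 1 : j])
            i = j + 1
        positions.extend([charset] * repeat)
    if not all(s <= set(BASES) for s in positions):
        raise ValueError(f"pattern {name}: non-ACGT characters in class")
    return CoreElementPattern(name=name, pattern=pattern, positions=tuple(positions))


#: The five classical core promoter element patterns.
CORE_ELEMENTS: tuple[CoreElementPattern, ...] = (
    _compile_pattern("TATA", "T[AT]A[AT]A[AGT]"),
    _compile_pattern("INR", "[CT]{2}A[CT][AT][CT]{2}"),
    _compile_pattern("BRE", "[GC]{2}[GA]CGCC"),
    _compile_pattern("DPE", "[AG][CG][AT][CT][ACG][CT]"),
    _compile_pattern("CCAAT", "[AG][AG]CCAAT[ACG][AG]"),
)


@dataclass(frozen=True)
class MotifHit:
    """A located element or PWM match within a scanned fragment.

    Coordinates are 1-based inclusive positions on the fragment's plus
    strand; for minus-strand hits ``matched_seq`` is the minus-strand
    sequence that matched.
    """

    source: str  # "core_element" | "pwm"
    name: str
    start: int
    end: int
    strand: str
    matched_seq: str
    score: float | None = None
    relative_score: float | None = None


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return seq


def _scan_one_strand_core(
    seq: str, pat: CoreElementPattern, strand: str, seq_len: int
) -> list[MotifHit]:
    L = len(pat)
    hits = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if all(c in allowed for c, allowed in zip(window, pat.positions)):
            if strand == "+":
                start = i + 1
            else:
                start = seq_len - (i + L) + 1
            hits.append(
                MotifHit(
                    source="core_element",
                    name=pat.name,
                    start=start,
                    end=start + L - 1,
                    strand=strand,
                    matched_seq=window,
                )
            )
    return hits


def scan_core_elements(
    sequence: str,
    patterns: tuple[CoreElementPattern, ...] = CORE_ELEMENTS,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Report every window matching a core element pattern; overlaps allowed.

    Windows containing N never match. Minus-strand hits come from scanning
    the reverse complement, with coordinates reflected back to the plus
    strand. Hits are sorted by (start, name, strand).
    """
    seq = _check_sequence(sequence)
    n = len(seq)
    hits: list[MotifHit] = []
    for pat in patterns:
        hits.extend(_scan_one_strand_core(seq, pat, "+", n))
        if both_strands:
            hits.extend(_scan_one_strand_core(reverse_complement(seq), pat, "-", n))
    hits.sort(key=lambda h: (h.start, h.name, h.strand))
    return hits


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Base counts per motif column (rows A, C, G, T)."""

    motif_id: str
    motif_name: str
    counts: np.ndarray  # shape (4, L)

    def __post_init__(self) -> None:
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError(f"motif {self.motif_id}: counts must be 4 x L, L >= 1")
        if (self.counts < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative counts")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError(f"motif {self.motif_id}: all-zero column")

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log-odds scores per base and column, with attainable score extrema."""

    motif_id: str
    motif_name: str
    weights: np.ndarray  # shape (4, L)
    score_min: float
    score_max: float

    @property
    def length(self) -> int:
        return int(self.weights.shape[1])


class JasparParseError(ValueError):
    """Raised for a structurally invalid JASPAR PFM file."""


def _prevalidate_jaspar(path: Path) -> None:
    """Check every '>' block has exactly 4 rows labelled A/C/G/T of equal length."""
    motif_id = None
    rows: list[tuple[str, int]] = []

    def _flush() -> None:
        if motif_id is None:
            return
        letters = [r[0] for r in rows]
        if letters != ["A", "C", "G", "T"]:
            raise JasparParseError(
                f"motif {motif_id}: expected rows A,C,G,T, got {letters}"
            )
        if len({r[1] for r in rows}) != 1:
            raise JasparParseError(f"motif {motif_id}: rows have unequal lengths")

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                motif_id = line[1:].split()[0] if len(line) > 1 else "?"
                rows = []
            else:
                letter = line[0].upper()
                body = line[1:].strip().lstrip("[").rstrip("]")
                values = body.split()
                try:
                    [float(v) for v in values]
                except ValueError as exc:
                    raise JasparParseError(
                        f"motif {motif_id}: non-numeric count in row {letter}"
                    ) from exc
                rows.append((letter, len(values)))
        _flush()


def read_jaspar(path: str | Path) -> list[PositionFrequencyMatrix]:
    """Read a JASPAR-format PFM text file (">ID NAME" + 4 bracketed rows)."""
    path = Path(path)
    _prevalidate_jaspar(path)
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    pfms = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        pfms.append(
            PositionFrequencyMatrix(
                motif_id=m.matrix_id or m.name,
                motif_name=m.name or m.matrix_id,
                counts=counts,
            )
        )
    return pfms


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    pseudocount: float = 0.8,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> PositionWeightMatrix:
    """Convert counts to a log2-odds PWM with a background-split pseudocount.

    weight[b][i] = log2( (count[b][i] + pseudocount * bg[b])
                        / (colsum[i] + pseudocount) / bg[b] ).

    The attainable score extrema are the sums of per-column minima and
    maxima; they anchor the relative-score rescaling used by the scanner.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = np.asarray(background, dtype=float)
    if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background must sum to 1")
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    weights = np.log2(probs / bg[:, None])
    return PositionWeightMatrix(
        motif_id=pfm.motif_id,
        motif_name=pfm.motif_name,
        weights=weights,
        score_min=float(weights.min(axis=0).sum()),
        score_max=float(weights.max(axis=0).sum()),
    )


def _scan_one_strand_pwm(
    seq: str, pwm: PositionWeightMatrix, rel_threshold: float, strand: str, seq_len: int
) -> list[MotifHit]:
    L = pwm.length
    n = len(seq)
    if n < L:
        return []
    codes = np.full(n, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    # window score = sum of per-position weights; windows containing N skipped
    idx = np.arange(n - L + 1)[:, None] + np.arange(L)[None, :]
    win_codes = codes[idx]
    valid = (win_codes >= 0).all(axis=1)
    contrib = pwm.weights[np.clip(win_codes, 0, 3), np.arange(L)[None, :]]
    scores = np.where(valid, contrib.sum(axis=1), -np.inf)
    span = pwm.score_max - pwm.score_min
    rel = (scores - pwm.score_min) / span
    hits = []
    for i in np.nonzero(valid & (rel >= rel_threshold))[0]:
        if strand == "+":
            start = int(i) + 1
        else:
            start = seq_len - (int(i) + L) + 1
        hits.append(
            MotifHit(
                source="pwm",
                name=pwm.motif_name,
                start=start,
                end=start + L - 1,
                strand=strand,
                matched_seq=seq[i : i + L],
                score=float(scores[i]),
                relative_score=float(rel[i]),
            )
        )
    return hits


def scan_pwm(
    sequence: str,
    pwm: PositionWeightMatrix,
    rel_threshold: float = 0.70,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Report every window with relative PWM score >= ``rel_threshold``.

    The relative score is (S - score_min) / (score_max - score_min), i.e.
    the window score rescaled between the matrix's attainable extremes,
    so a threshold of 0.70 corresponds to a 70% match score. Windows
    containing N are skipped; both strands are scanned by default.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")
    seq = _check_sequence(sequence)
    if len(seq) < pwm.length:
        raise ValueError("sequence shorter than motif")
    n = len(seq)
    hits = _scan_one_strand_pwm(seq, pwm, rel_threshold, "+", n)
    if both_strands:
        hits.extend(
            _scan_one_strand_pwm(reverse_complement(seq), pwm, rel_threshold, "-", n)
        )
    hits.sort(key=lambda h: (h.start, h.name, h.strand))
    return hits


def motif_map(fragment: PromoterFragment, hits: list[MotifHit]) -> pd.DataFrame:
    """Tidy per-fragment hit table (sorted by start) for plotting or export."""
    for h in hits:
        if h.start < 1 or h.end > fragment.length_bp:
            raise ValueError(
                f"hit {h.name} at {h.start}-{h.end} outside fragment "
                f"{fragment.fragment_id} (length {fragment.length_bp})"
            )
    rows = [
        {
            "fragment_id": fragment.fragment_id,
            "source": h.source,
            "name": h.name,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "matched_seq": h.matched_seq,
            "score": h.score,
            "relative_score": h.relative_score,
        }
        for h in sorted(hits, key=lambda h: (h.start, h.end, h.name, h.strand))
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "fragment_id",
            "source",
            "name",
            "start",
            "end",
            "strand",
            "matched_seq",
            "score",
            "relative_score",
        ],
    )
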