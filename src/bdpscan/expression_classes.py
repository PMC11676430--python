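"""Expression-state classification of divergent gene pairs from FPKM tables.

A pair's state in one sample group follows an ordered rule on the two genes'
FPKM values: if both fall below the expression threshold (1 FPKM) the pair
is co-silent; otherwise the expression ratio decides — within the four-fold
band [0.25, 4] the pair is co-expressed, outside it unidirectionally
expressed. The module also provides cross-tissue overlap (three-set Venn)
counts and the 2^-ddCt relative-expression helper for qPCR validation data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .divergent_pairs import DivergentPair

logger = logging.getLogger(__name__)

__all__ = [
    "CO_EXPRESSED",
    "UNIDIRECTIONAL",
    "CO_SILENT",
    "STATES",
    "PairExpressionState",
    "ClassificationResult",
    "classify_pair",
    "classify_all",
    "overlap_sets",
    "delta_delta_ct",
    "DdCtInput",
    "read_expression_table",
    "read_sample_sheet",
]

CO_EXPRESSED = "co_expressed"
UNIDIRECTIONAL = "unidirectional"
CO_SILENT = "co_silent"
STATES = (CO_EXPRESSED, UNIDIRECTIONAL, CO_SILENT)


def classify_pair(
    fpkm_a: float,
    fpkm_b: float,
    expressed_min: float = 1.0,
    ratio_low: float = 0.25,
    ratio_high: float = 4.0,
) -> str:
    """Classify one pair from two FPKM values.

    Ordered rule: both below ``expressed_min`` -> co_silent; otherwise the
    ratio fpkm_a / fpkm_b decides, with the band endpoints inclusive. A
    single zero FPKM makes the ratio infinite (or zero) and hence
    unidirectional; both zero is caught by the co-silent rule first.
    """
    if fpkm_a < 0 or fpkm_b < 0:
        raise ValueError("FPKM values must be non-negative")
    if fpkm_a < expressed_min and fpkm_b < expressed_min:
        return CO_SILENT
    if fpkm_b == 0:
        return UNIDIRECTIONAL
    ratio = fpkm_a / fpkm_b
    return CO_EXPRESSED if ratio_low <= ratio <= ratio_high else UNIDIRECTIONAL


@dataclass(frozen=True)
class PairExpressionState:
    """One pair's state in one tissue, with the FPKMs that produced it."""

    pair_id: str
    tissue: str
    state: str
    fpkm_a: float
    fpkm_b: float

    @property
    def ratio(self) -> float | None:
        if self.fpkm_b == 0:
            return None
        return self.fpkm_a / self.fpkm_b


@dataclass
class ClassificationResult:
    states: list[PairExpressionState]
    proportions: dict[str, float]
    n_skipped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pair_id": s.pair_id,
                    "tissue": s.tissue,
                    "state": s.state,
                    "fpkm_minus": s.fpkm_a,
                    "fpkm_plus": s.fpkm_b,
                }
                for s in self.states
            ]
        )


def classify_all(
    pairs: list[DivergentPair],
    table: pd.DataFrame,
    tissue: str,
    sample_columns: list[str] | None = None,
    expressed_min: float = 1.0,
    ratio_low: float = 0.25,
    ratio_high: float = 4.0,
) -> ClassificationResult:
    """Classify every pair in one tissue from an FPKM matrix.

    ``table`` is gene_id-indexed with sample columns. Replicates (the
    ``sample_columns``, or every column whose name starts with the tissue
    label) are combined by mean FPKM per gene before classification. Pairs
    with a gene absent from the table are skipped with a warning count.
    """
    if sample_columns is None:
        sample_columns = [c for c in table.columns if str(c).startswith(tissue)]
    if not sample_columns:
        raise ValueError(f"no sample columns found for tissue '{tissue}'")
    if (table[sample_columns] < 0).any().any():
        raise ValueError("negative FPKM values in expression table")
    mean_fpkm = table[sample_columns].mean(axis=1)

    states: list[PairExpressionState] = []
    n_skipped = 0
    for p in pairs:
        ga, gb = p.gene_minus.gene_id, p.gene_plus.gene_id
        if ga not in mean_fpkm.index or gb not in mean_fpkm.index:
            n_skipped += 1
            logger.warning("pair %s skipped: gene missing from table", p.pair_id)
            continue
        a, b = float(mean_fpkm[ga]), float(mean_fpkm[gb])
        states.append(
            PairExpressionState(
                pair_id=p.pair_id,
                tissue=tissue,
                state=classify_pair(a, b, expressed_min, ratio_low, ratio_high),
                fpkm_a=a,
                fpkm_b=b,
            )
        )
    n = len(states)
    proportions = {
        s: (sum(1 for st in states if st.state == s) / n if n else 0.0) for s in STATES
    }
    return ClassificationResult(states=states, proportions=proportions, n_skipped=n_skipped)


def overlap_sets(states_by_tissue: dict[str, set[str]]) -> dict[str, int]:
    """Disjoint three-set Venn region counts of pair-id sets across tissues.

    Keys name the region by the tissues it is exclusive to, joined by '&'
    (e.g. ``brain``, ``brain&liver``, ``brain&liver&testis``). The seven
    region counts partition the union of the three sets.
    """
    if len(states_by_tissue) != 3:
        raise ValueError("overlap_sets expects exactly 3 tissues")
    tissues = sorted(states_by_tissue)
    sets = [states_by_tissue[t] for t in tissues]
    regions: dict[str, int] = {}
    union = set().union(*sets)
    for mask in range(1, 8):
        members = [tissues[i] for i in range(3) if mask >> i & 1]
        inside = set(union)
        for i in range(3):
            if mask >> i & 1:
                inside &= sets[i]
            else:
                inside -= sets[i]
        regions["&".join(members)] = len(inside)
    return regions


@dataclass(frozen=True)
class DdCtInput:
    """Cycle thresholds for target and reference genes, treated vs control."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float


def delta_delta_ct(inp: DdCtInput) -> float:
    """Relative expression by the 2^-ddCt method."""
    for v in (
        inp.ct_target_treated,
        inp.ct_reference_treated,
        inp.ct_target_control,
        inp.ct_reference_control,
    ):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (inp.ct_target_treated - inp.ct_reference_treated) - (
        inp.ct_target_control - inp.ct_reference_control
    )
    return 2.0 ** (-ddct)


def read_expression_table(path) -> pd.DataFrame:
    """Read a gene_id x sample FPKM TSV (first column = gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression table")
    return df


def read_sample_sheet(path) -> dict[str, list[str]]:
    """Read a sample->tissue TSV (columns: sample, tissue) into tissue groups."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "tissue"} <= set(df.columns):
        raise ValueError("sample sheet needs 'sample' and 'tissue' columns")
    groups: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        groups.setdefault(str(row["tissue"]), []).append(str(row["sample"]))
    return groups
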