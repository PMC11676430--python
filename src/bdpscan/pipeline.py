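"""End-to-end pipeline orchestration with a validated run configuration.

Stages (each toggleable): pair finding -> fragment extraction and controls
-> expression classification -> motif scanning. Every run writes TSV/JSON
reports plus a manifest recording parameters, seed, and input checksums, so
identical configs reproduce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotation_io, divergent_pairs, expression_classes, motif_scan
from . import promoter_fragments as frag

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline"]

DATA_DICTIONARY = {
    "pairs.tsv": {
        "pair_id": "minus-gene id | plus-gene id",
        "chrom": "chromosome of both genes",
        "gene_minus": "minus-strand gene id",
        "gene_plus": "plus-strand gene id",
        "tss_minus": "1-based TSS of the minus-strand gene (its end)",
        "tss_plus": "1-based TSS of the plus-strand gene (its start)",
        "tss_distance": "|tss_plus - tss_minus| in bp",
        "overlap_class": "overlapping_5prime when tss_plus <= tss_minus, else non_overlapping",
        "bdp_start": "1-based inclusive start of the inter-TSS BDP interval",
        "bdp_end": "1-based inclusive end of the inter-TSS BDP interval",
    },
    "chromosome_stats.tsv": {
        "chrom": "chromosome name ('Total' = genome-wide row)",
        "size_mb": "chromosome length in megabases",
        "total_genes": "annotated genes on the chromosome",
        "gene_density": "total_genes / size_mb",
        "pair_count": "divergent pairs on the chromosome",
        "divergent_gene_count": "distinct genes inside those pairs",
        "divergent_ratio": "divergent_gene_count / total_genes",
    },
    "fragments.tsv": {
        "fragment_id": "bdp|<pair_id>|<mode> or control|<gene_id>|up<N>",
        "source": "bdp or control",
        "length_bp": "fragment length (inclusive span)",
        "gc_fraction": "(G+C)/(A+C+G+T), ambiguity codes excluded",
        "pair_overlap_class": "overlap class of the source pair (bdp only)",
    },
    "expression_states.tsv": {
        "pair_id": "pair identifier",
        "tissue": "tissue/sample-group label",
        "state": "co_expressed | unidirectional | co_silent",
        "fpkm_minus": "mean FPKM of the minus-strand gene over replicates",
        "fpkm_plus": "mean FPKM of the plus-strand gene over replicates",
    },
    "motif_hits.tsv": {
        "fragment_id": "scanned fragment",
        "source": "core_element or pwm",
        "name": "element or motif name",
        "start,end": "1-based inclusive hit coordinates on the fragment plus strand",
        "strand": "+ or - (minus hits mapped back to plus coordinates)",
        "relative_score": "(S - score_min) / (score_max - score_min), PWM hits only",
    },
}


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 at the CLI)."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: Path
    annotation: Path | None = None
    genome: Path | None = None
    expression: Path | None = None
    sample_sheet: Path | None = None
    jaspar: Path | None = None
    max_tss_distance: int = 1000
    expressed_min: float = 1.0
    ratio_low: float = 0.25
    ratio_high: float = 4.0
    control_n: int = 3000
    upstream_bp: int = 1000
    rel_threshold: float = 0.70
    fragment_mode: str = "between_tss"
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["pairs", "fragments", "expression", "motifs"]
    )

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("annotation", "genome", "expression", "sample_sheet", "jaspar"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, Path(val))
        self.validate()

    def validate(self) -> None:
        if self.max_tss_distance < 1:
            raise ConfigError("max_tss_distance must be positive")
        if self.ratio_low > self.ratio_high:
            raise ConfigError(
                f"ratio band invalid: low {self.ratio_low} > high {self.ratio_high}"
            )
        if not 0 < self.rel_threshold <= 1:
            raise ConfigError("rel_threshold must be in (0, 1]")
        if self.fragment_mode not in ("between_tss", "between_atg"):
            raise ConfigError(f"unknown fragment_mode '{self.fragment_mode}'")
        unknown = set(self.stages) - {"pairs", "fragments", "expression", "motifs"}
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if "pairs" not in self.stages:
            raise ConfigError("the 'pairs' stage is required by all others")
        for name in ("annotation", "genome", "expression", "sample_sheet", "jaspar"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                raise ConfigError(f"{name} path does not exist: {val}")
        if self.annotation is None:
            raise ConfigError("an annotation file is required")
        if "fragments" in self.stages and self.genome is None:
            raise ConfigError("the fragments stage requires a genome FASTA")
        if "expression" in self.stages and self.expression is None:
            raise ConfigError("the expression stage requires an FPKM table")
        if "motifs" in self.stages and self.genome is None:
            raise ConfigError("the motifs stage requires a genome FASTA")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; returns the output directory.

    On stage failure, partial outputs are kept alongside a ``FAILED``
    marker naming the stage, and :class:`StageError` is raised.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stage = "setup"
    try:
        genome = annotation_io.load_genome(config.genome) if config.genome else None
        chrom_sizes = genome.chrom_sizes() if genome else None
        annotation = annotation_io.parse_annotation(
            config.annotation, chrom_sizes=chrom_sizes
        )
        counts["genes_parsed"] = len(annotation)
        counts["gene_records_rejected"] = annotation.n_rejected

        stage = "pairs"
        pairs = divergent_pairs.find_divergent_pairs(
            annotation, max_tss_distance=config.max_tss_distance
        )
        counts["pairs_found"] = len(pairs)
        divergent_pairs.pairs_to_frame(pairs).to_csv(
            out / "pairs.tsv", sep="\t", index=False
        )
        stats = divergent_pairs.chromosome_stats(annotation, pairs)
        divergent_pairs.stats_to_frame(stats).to_csv(
            out / "chromosome_stats.tsv", sep="\t", index=False, float_format="%.4f"
        )
        annotation_io.write_intervals(
            [p.bdp_interval for p in pairs], out / "bdp_intervals.bed"
        )
        corr = {}
        if chrom_sizes and len([s for s in stats if s.chrom != "Total"]) >= 3:
            for y in ("pair_count", "divergent_ratio"):
                try:
                    corr[y] = divergent_pairs.density_pair_correlation(stats, y)
                except ValueError as exc:
                    corr[y] = {"error": str(exc)}
            (out / "density_correlation.json").write_text(
                json.dumps(corr, indent=2) + "\n"
            )

        fragments = []
        if "fragments" in config.stages:
            stage = "fragments"
            fragments = [
                frag.extract_bdp_fragment(p, genome, mode=config.fragment_mode)
                for p in pairs
            ]
            controls = []
            try:
                controls = frag.sample_control_promoters(
                    annotation,
                    genome,
                    pairs,
                    n=config.control_n,
                    upstream_bp=config.upstream_bp,
                    seed=config.seed,
                )
            except ValueError as exc:
                logger.warning("control sampling skipped: %s", exc)
                counts["control_sampling_skipped"] = 1
            counts["bdp_fragments"] = len(fragments)
            counts["control_fragments"] = len(controls)
            frag.write_fragments_fasta(fragments + controls, out / "fragments.fa")
            frag.fragments_to_frame(fragments + controls).to_csv(
                out / "fragments.tsv", sep="\t", index=False, float_format="%.6f"
            )
            summary = {"bdp": frag.summarize_fragments(fragments).to_dict()}
            if controls:
                summary["control"] = frag.summarize_fragments(controls).to_dict()
            (out / "fragment_summary.json").write_text(
                json.dumps(summary, indent=2) + "\n"
            )

        if "expression" in config.stages:
            stage = "expression"
            table = expression_classes.read_expression_table(config.expression)
            if config.sample_sheet:
                groups = expression_classes.read_sample_sheet(config.sample_sheet)
            else:
                groups = {}
                for col in table.columns:
                    tissue = str(col).rsplit("_r", 1)[0]
                    groups.setdefault(tissue, []).append(str(col))
            frames = []
            proportions: dict[str, dict[str, float]] = {}
            states_by_tissue: dict[str, dict[str, set]] = {}
            for tissue, samples in sorted(groups.items()):
                res = expression_classes.classify_all(
                    pairs,
                    table,
                    tissue,
                    sample_columns=samples,
                    expressed_min=config.expressed_min,
                    ratio_low=config.ratio_low,
                    ratio_high=config.ratio_high,
                )
                counts[f"pairs_skipped_{tissue}"] = res.n_skipped
                frames.append(res.to_frame())
                proportions[tissue] = res.proportions
                for state in expression_classes.STATES:
                    states_by_tissue.setdefault(state, {})[tissue] = {
                        s.pair_id for s in res.states if s.state == state
                    }
            if frames:
                import pandas as pd

                pd.concat(frames, ignore_index=True).to_csv(
                    out / "expression_states.tsv", sep="\t", index=False,
                    float_format="%.4f",
                )
            (out / "expression_proportions.json").write_text(
                json.dumps(proportions, indent=2) + "\n"
            )
            venn = {}
            for state, by_tissue in states_by_tissue.items():
                if len(by_tissue) == 3:
                    venn[state] = expression_classes.overlap_sets(by_tissue)
            if venn:
                (out / "venn_regions.json").write_text(json.dumps(venn, indent=2) + "\n")

        if "motifs" in config.stages:
            stage = "motifs"
            if not fragments:
                fragments = [
                    frag.extract_bdp_fragment(p, genome, mode=config.fragment_mode)
                    for p in pairs
                ]
            pwms = []
            if config.jaspar:
                pwms = [
                    motif_scan.pfm_to_pwm(pfm)
                    for pfm in motif_scan.read_jaspar(config.jaspar)
                ]
            import pandas as pd

            maps = []
            n_hits = 0
            for f in fragments:
                hits = motif_scan.scan_core_elements(f.sequence)
                for pwm in pwms:
                    if len(f.sequence) >= pwm.length:
                        hits.extend(
                            motif_scan.scan_pwm(
                                f.sequence, pwm, rel_threshold=config.rel_threshold
                            )
                        )
                n_hits += len(hits)
                maps.append(motif_scan.motif_map(f, hits))
            counts["motif_hits"] = n_hits
            pd.concat(maps, ignore_index=True).to_csv(
                out / "motif_hits.tsv", sep="\t", index=False, float_format="%.6f"
            )
    except (ConfigError, StageError):
        raise
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(f"stage '{stage}' failed: {exc}") from exc

    manifest = {
        "parameters": {
            "max_tss_distance": config.max_tss_distance,
            "expressed_min": config.expressed_min,
            "ratio_band": [config.ratio_low, config.ratio_high],
            "control_n": config.control_n,
            "upstream_bp": config.upstream_bp,
            "rel_threshold": config.rel_threshold,
            "fragment_mode": config.fragment_mode,
            "seed": config.seed,
            "stages": config.stages,
        },
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name in ("annotation", "genome", "expression", "sample_sheet", "jaspar")
            if (p := getattr(config, name)) is not None
        },
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out / "data_dictionary.json").write_text(
        json.dumps(DATA_DICTIONARY, indent=2) + "\n"
    )
    logger.info("pipeline complete: %s", counts)
    return out
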