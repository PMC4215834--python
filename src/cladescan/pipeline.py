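"""End-to-end analysis: filter → profiles → signatures → scores → mapping
→ helix summary → (optional) proximity → cross-reference.

One :class:`RunConfig` collects every input path and threshold; the run
writes a TSV per stage plus a manifest recording the package version,
the configuration hash and the seed, so identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignment_io import (
    build_coordinate_map,
    column_gap_fractions,
    filter_gap_columns,
    read_labeled_alignment,
)
from .conservation import (
    call_signature_sites,
    score_sites,
    signature_calls_to_frame,
    site_profiles,
)
from .proximity import (
    DEFAULT_PROXIMITY_ANGSTROM,
    cross_reference,
    nearest_protein_distances,
    parse_structure,
    proximal_helices,
    records_to_frame,
)
from .structure_map import (
    annotations_to_frame,
    map_scores_to_reference,
    read_helix_table,
    summarize_by_helix,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    alignment: str
    labels: str
    reference_id: str
    outdir: str
    helix_table: str | None = None
    structure: str | None = None
    rna_chain: str = "A"
    protein_chain: str = "B"
    max_gap: float = 0.5
    in_min: float = 0.90
    out_max: float = 0.10
    proximity_angstrom: float = DEFAULT_PROXIMITY_ANGSTROM
    top_k_helices: int = 5
    rounding: int = 3
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v, lo, hi in (
            ("max_gap", self.max_gap, 0.0, 1.0),
            ("in_min", self.in_min, 0.0, 1.0),
            ("out_max", self.out_max, 0.0, 1.0),
        ):
            if not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {v}")
        if self.proximity_angstrom <= 0:
            raise ValueError("proximity_angstrom must be positive")
        if self.top_k_helices < 1:
            raise ValueError("top_k_helices must be at least 1")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class StageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df, path: Path, rounding: int) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{rounding}f")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return a report of output paths.

    Stage errors propagate as :class:`StageError` naming the stage; the
    manifest written alongside the outputs flags whether the run
    completed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    manifest = {
        "package": "cladescan",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "complete": False,
        "stage_seconds": {},
    }
    manifest_path = outdir / "manifest.json"

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                manifest["stage_seconds"][name] = round(dt, 3)
                if exc is not None:
                    manifest_path.write_text(json.dumps(manifest, indent=1))
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.3fs", name, dt)

        return _Timer()

    for field_name in ("alignment", "labels"):
        path = getattr(config, field_name)
        if not path or not Path(path).exists():
            raise ValueError(f"config field {field_name!r}: missing input {path!r}")

    with stage("read"):
        aln = read_labeled_alignment(config.alignment, config.labels)
    with stage("filter"):
        filt = filter_gap_columns(aln, config.max_gap)
    with stage("profiles"):
        profiles = site_profiles(filt.filtered, filt.kept_columns)
    with stage("signatures"):
        calls = call_signature_sites(profiles, config.in_min, config.out_max)
        df_calls = signature_calls_to_frame(calls)
        _write_tsv(df_calls, outdir / "signatures.tsv", config.rounding)
        outputs["signatures"] = str(outdir / "signatures.tsv")
    with stage("scores"):
        table = score_sites(filt.filtered, filt.kept_columns)
        _write_tsv(table.scores, outdir / "scores.tsv", config.rounding)
        outputs["scores"] = str(outdir / "scores.tsv")
        manifest["t_avg_in"] = round(table.t_avg_in, 6)
        manifest["t_avg_out"] = round(table.t_avg_out, 6)
    with stage("mapping"):
        cmap = build_coordinate_map(aln, config.reference_id)
        pooled_gap = {
            c + 1: float(g) for c, g in enumerate(column_gap_fractions(aln))
        }
        annotations = map_scores_to_reference(
            table.scores, cmap, pooled_gap, config.max_gap
        )
        _write_tsv(
            annotations_to_frame(annotations), outdir / "annotations.tsv", config.rounding
        )
        outputs["annotations"] = str(outdir / "annotations.tsv")

    helix_summary = None
    if config.helix_table:
        with stage("helix_summary"):
            helices = read_helix_table(config.helix_table)
            helix_summary = summarize_by_helix(annotations, helices)
            _write_tsv(helix_summary, outdir / "helix_summary.tsv", config.rounding)
            outputs["helix_summary"] = str(outdir / "helix_summary.tsv")

    if config.structure and config.helix_table:
        with stage("proximity"):
            model = parse_structure(
                config.structure, config.rna_chain, config.protein_chain
            )
            records = nearest_protein_distances(
                model, config.rna_chain, config.protein_chain
            )
            _write_tsv(records_to_frame(records), outdir / "distances.tsv", config.rounding)
            outputs["distances"] = str(outdir / "distances.tsv")
            prox = proximal_helices(records, helices, config.proximity_angstrom)
            _write_tsv(prox, outdir / "proximal_helices.tsv", config.rounding)
            outputs["proximal_helices"] = str(outdir / "proximal_helices.tsv")
        with stage("cross_reference"):
            hits = cross_reference(helix_summary, prox, config.top_k_helices)
            _write_tsv(hits, outdir / "cross_reference.tsv", config.rounding)
            outputs["cross_reference"] = str(outdir / "cross_reference.tsv")
            manifest["cross_reference_hits"] = hits["helix_id"].tolist()

    manifest["outputs"] = outputs
    manifest["complete"] = True
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    outputs["manifest"] = str(manifest_path)
    return {"outputs": outputs, "manifest": manifest}
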