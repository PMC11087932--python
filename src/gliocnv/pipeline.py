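"""End-to-end orchestration: input → corrected profile → segmentation →
marker calls → classification → report.

Every run is keyed by a digest of its configuration; the digest is embedded
in each output file's sidecar metadata and mixed-digest output directories
are refused. The expensive counting stage is cached: a rerun with the same
digest reuses the counts on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .classification import ClinicalContext, classify_glioma
from .cnv_hmm import HMMConfig, estimate_tumor_fraction
from .deletion_baseline import (DeletionBaseline, load_default_baseline)
from .errors import GlioCNVError, PipelineStageError
from .genome_model import (DEFAULT_BIN_SIZE, GenomeBuild, MarkerCatalog,
                           build_bin_grid, exclusion_mask, locate_marker_bins)
from .marker_calls import call_all_markers
from .normalization import correct_bias, normalize_against_panel
from .readcount_io import (BinCounts, annotate_gc_mappability,
                           count_reads_in_bins, read_wig, write_wig)
from .reporting import ReportBundle, render_genome_plot, render_html_report

log = logging.getLogger("gliocnv")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults reproduce the intended
    analysis parameters (500-kb windows, MAPQ >= 20, secondary reads
    dropped)."""

    input_path: str
    out_dir: str
    input_type: str = "wig"                  # wig | alignment
    build: str = "hg38"
    bin_size: int = DEFAULT_BIN_SIZE
    min_mapq: int = 20
    drop_secondary: bool = True
    gc_track: str | None = None
    map_track: str | None = None
    skip_gc_correction: bool = False
    panel_paths: tuple = ()
    baseline_path: str | None = None
    tf_min: float = 0.05
    tf_max: float = 1.0
    tf_step: float = 0.01
    switch_prob: float = 1e-4
    neutral_state_bias: float = 0.1
    arm_call_threshold: float = 0.8
    mappability_threshold: float = 0.75
    amplification_state: int = 5
    centromere_padding: int = 1
    context_path: str | None = None
    sample_id: str | None = None
    seed: int = 0
    suppress_timestamp: bool = True
    log_level: str = "INFO"

    def digest(self) -> str:
        d = asdict(self)
        d.pop("out_dir")
        d.pop("log_level")
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "panel_paths" in data:
            data["panel_paths"] = tuple(data["panel_paths"])
        return cls(**data)


def _load_context(path: str | None) -> ClinicalContext:
    if path is None:
        return ClinicalContext()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {k: data.pop(k) for k in ("idh_status", "histology_note", "sample_id")
             if k in data}
    return ClinicalContext(extra=data, **known)


def _check_digest(out_dir: Path, digest: str) -> None:
    marker = out_dir / "run_config.json"
    if marker.exists():
        previous = json.loads(marker.read_text()).get("digest")
        if previous is not None and previous != digest:
            raise GlioCNVError(
                f"output directory {out_dir} holds results for digest "
                f"{previous}, refusing to mix with {digest}"
            )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage and write all exports into ``config.out_dir``.

    On failure, a ``FAILED`` marker file naming the stage is left in the
    output directory and a :class:`PipelineStageError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    _check_digest(out, digest)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    stage = "setup"
    try:
        build = GenomeBuild.load(config.build)
        grid = build_bin_grid(build, config.bin_size)
        catalog = MarkerCatalog.default(build)
        mask = exclusion_mask(grid, config.centromere_padding)
        context = _load_context(config.context_path)
        (out / "run_config.json").write_text(json.dumps(
            {"digest": digest, "tool_version": __version__,
             "config": asdict(config)}, indent=2, default=str) + "\n")

        stage = "read_counting"
        counts_cache = out / "counts.wig"
        if config.input_type == "alignment":
            if counts_cache.exists():
                log.info("reusing cached counts (%s)", counts_cache)
                counts = read_wig(str(counts_cache), grid,
                                  sample_id=config.sample_id)
            else:
                counts = count_reads_in_bins(
                    config.input_path, grid, min_mapq=config.min_mapq,
                    drop_secondary=config.drop_secondary,
                    sample_id=config.sample_id)
                write_wig(counts, str(counts_cache))
                log.info("counting: %s", counts.filter_stats)
        elif config.input_type == "wig":
            counts = read_wig(config.input_path, grid,
                              sample_id=config.sample_id)
        else:
            raise GlioCNVError(f"unknown input_type {config.input_type!r}")
        counts = annotate_gc_mappability(counts, config.gc_track,
                                         config.map_track)

        stage = "bias_correction"
        profile = correct_bias(
            counts, mask, mappability_threshold=config.mappability_threshold,
            skip_gc=config.skip_gc_correction)

        stage = "panel_normalization"
        panel = []
        for path in config.panel_paths:
            member = read_wig(str(path), grid, sample_id=str(path))
            member = annotate_gc_mappability(member, config.gc_track,
                                             config.map_track)
            panel.append(correct_bias(
                member, mask,
                mappability_threshold=config.mappability_threshold,
                skip_gc=config.skip_gc_correction))
        if panel:
            profile = normalize_against_panel(profile, panel)
        profile.to_tsv(str(out / "corrected.tsv"))

        stage = "segmentation"
        hmm = HMMConfig(
            switch_prob=config.switch_prob,
            neutral_state_bias=config.neutral_state_bias,
            tf_grid=np.round(np.arange(config.tf_min,
                                       config.tf_max + config.tf_step / 2,
                                       config.tf_step), 6),
            seed=config.seed,
        )
        seg = estimate_tumor_fraction(profile, hmm)
        seg.to_seg(str(out / "segments.seg"))
        seg.to_bed(str(out / "segments.bed"))
        log.info("tumor fraction %.2f (informative=%s)",
                 seg.tumor_fraction, seg.tf_informative)

        stage = "marker_calls"
        if config.baseline_path:
            baseline = DeletionBaseline.from_json(config.baseline_path)
        else:
            baseline = load_default_baseline()
        table = call_all_markers(
            seg, profile, catalog, grid, baseline,
            arm_call_threshold=config.arm_call_threshold,
            amplification_state=config.amplification_state)
        table.to_tsv(str(out / "markers.tsv"))
        table.to_json(str(out / "markers.json"))

        stage = "classification"
        result = classify_glioma(table, context)
        result.to_json(str(out / "classification.json"))

        stage = "reporting"
        marker_bins = {e.marker_id: locate_marker_bins(catalog, grid, e.marker_id)
                       for e in catalog.entries}
        render_genome_plot(seg, profile, table, str(out / "plot.svg"),
                           str(out / "plot.png"), marker_bins=marker_bins)
        header = {"sample_id": config.sample_id or counts.sample_id,
                  "build": config.build, "bin_size": config.bin_size,
                  "input": str(config.input_path),
                  "tumor_fraction": f"{seg.tumor_fraction:.2f}"
                  + ("" if seg.tf_informative else " (non-informative)"),
                  "idh_status": context.idh_status}
        if context.histology_note:
            header["histology_note"] = context.histology_note
        header.update(context.extra)
        timestamp = None
        if not config.suppress_timestamp:
            from datetime import datetime, timezone
            timestamp = datetime.now(timezone.utc).isoformat()
        bundle = ReportBundle(
            sample_header=header,
            plot_svg=(out / "plot.svg").read_text(),
            marker_table=table,
            classification=result,
            tool_version=__version__,
            run_config_digest=digest,
            timestamp=timestamp,
        )
        render_html_report(bundle, str(out / "report.html"))
        return bundle
    except GlioCNVError:
        failed_marker.write_text(stage + "\n")
        raise
    except Exception as exc:
        failed_marker.write_text(stage + "\n")
        raise PipelineStageError(stage, str(exc)) from exc
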