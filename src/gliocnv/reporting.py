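"""Genome-wide CNV plot and the single-file HTML report.

The report is one self-contained HTML document in four sections: a sample
information header, the visualization (the genome plot inlined as SVG), the
marker status table (altered markers carry an alert style), and the
classification summary with its fired rules and disclaimer. Rendering is
deterministic: timestamps can be suppressed and the SVG hash salt is
pinned, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classification import ClassificationResult
from .cnv_hmm import SegmentationResult
from .marker_calls import (AMPLIFICATION, GAIN, HEMIZYGOUS_LOSS,
                           HOMOZYGOUS_LOSS, INDETERMINATE, MarkerTable,
                           NEUTRAL)
from .normalization import CorrectedProfile

STATUS_COLORS = {
    AMPLIFICATION: "#c62828",
    GAIN: "#ef6c00",
    HEMIZYGOUS_LOSS: "#1565c0",
    HOMOZYGOUS_LOSS: "#4a148c",
}

ALTERED_STATUSES = tuple(STATUS_COLORS)


@dataclass
class ReportBundle:
    sample_header: dict
    plot_svg: str                      # SVG text, inlined into the report
    marker_table: MarkerTable
    classification: ClassificationResult
    tool_version: str = "0"
    run_config_digest: str = ""
    timestamp: str | None = None       # None suppresses the footer timestamp


def render_genome_plot(seg: SegmentationResult, profile: CorrectedProfile,
                       table: MarkerTable, out_svg: str,
                       out_png: str | None = None,
                       marker_bins: dict | None = None) -> None:
    """Scatter the per-bin log2 ratios in genome order with segment means
    overlaid and marker regions highlighted by their called status.

    ``marker_bins`` maps marker_id -> bin ordinals; highlighted spans carry
    SVG ids ``marker-<id>-<status>`` so the rendering can be audited.
    """
    plt.rcParams["svg.hashsalt"] = "gliocnv"
    grid = profile.grid
    x = np.arange(grid.n_bins)
    fig, ax = plt.subplots(figsize=(14, 4))

    valid = profile.valid
    ax.scatter(x[valid], profile.log2_ratio[valid], s=4, c="#607d8b",
               alpha=0.6, linewidths=0, rasterized=False)

    # chromosome boundaries and labels
    ticks, labels = [], []
    for chrom, sl in grid.chrom_slices.items():
        if sl.start > 0:
            ax.axvline(sl.start - 0.5, color="#bdbdbd", lw=0.6)
        ticks.append((sl.start + sl.stop - 1) / 2)
        labels.append(chrom.replace("chr", ""))
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)

    # segment means
    pos = {(c, s): i for i, (c, s) in
           enumerate(zip(grid.chrom, grid.start))}
    for s in seg.segments:
        i0 = pos[(s.chrom, s.start)]
        i1 = i0 + s.n_bins  # approximate extent in bin ordinals
        ax.hlines(s.mean_log2, i0 - 0.5, i1 - 0.5, colors="#d32f2f", lw=1.5)

    # marker highlights
    if marker_bins:
        for marker_id, bins in marker_bins.items():
            call = table.calls.get(marker_id)
            if call is None or call.status not in ALTERED_STATUSES:
                continue
            bins = np.asarray(bins)
            span = ax.axvspan(bins.min() - 0.5, bins.max() + 0.5,
                              color=STATUS_COLORS[call.status], alpha=0.25)
            span.set_gid(f"marker-{marker_id}-{call.status}")
            ax.text(float(bins.mean()), ax.get_ylim()[1] * 0.9, marker_id,
                    ha="center", fontsize=7, color=STATUS_COLORS[call.status])

    ax.axhline(0.0, color="#9e9e9e", lw=0.8, ls="--")
    ax.set_ylabel("log2 copy ratio")
    ax.set_xlabel("chromosome")
    ax.set_title(
        f"{profile.sample_id} — tumor fraction "
        f"{seg.tumor_fraction:.2f}" + ("" if seg.tf_informative
                                       else " (non-informative)")
    )
    ax.set_xlim(-0.5, grid.n_bins - 0.5)
    fig.tight_layout()
    fig.savefig(out_svg, format="svg", metadata={"Date": None})
    if out_png:
        fig.savefig(out_png, format="png", dpi=150)
    plt.close(fig)


def _esc(x) -> str:
    return html.escape(str(x))


def _header_section(bundle: ReportBundle) -> str:
    rows = "\n".join(
        f"<tr><th>{_esc(k)}</th><td>{_esc(v)}</td></tr>"
        for k, v in bundle.sample_header.items()
    ) or "<tr><td colspan='2'>no sample metadata supplied</td></tr>"
    return (f"<section id=\"sample-information\">\n"
            f"<h2>Sample Information</h2>\n<table>{rows}</table>\n</section>")


def _visualization_section(bundle: ReportBundle) -> str:
    svg = bundle.plot_svg
    # strip the XML prolog/doctype so the SVG nests inside the HTML body
    start = svg.find("<svg")
    svg = svg[start:] if start >= 0 else svg
    return (f"<section id=\"visualization\">\n<h2>Genome-wide CNV Profile</h2>\n"
            f"<figure>{svg}</figure>\n</section>")


def _marker_section(bundle: ReportBundle) -> str:
    rows = []
    for call in bundle.marker_table.calls.values():
        cls = " class=\"alert\"" if call.status in ALTERED_STATUSES else ""
        mean_copy = "n/a" if not np.isfinite(call.mean_copy) \
            else f"{call.mean_copy:.2f}"
        rows.append(
            f"<tr{cls}><td>{_esc(call.marker_id)}</td>"
            f"<td>{_esc(call.status)}</td><td>{mean_copy}</td>"
            f"<td>{call.fraction_of_bins_altered:.0%}</td>"
            f"<td>{call.bins_used}</td><td>{_esc(call.evidence_note)}</td></tr>"
        )

    def flag(v):
        return "indeterminate" if v is None else ("yes" if v else "no")

    composites = (
        f"<p>1p/19q codeletion: <b>{flag(bundle.marker_table.codeletion_1p19q)}</b>"
        f" · +7/−10 signature: "
        f"<b>{flag(bundle.marker_table.plus7_minus10)}</b></p>"
    )
    return ("<section id=\"marker-status\">\n<h2>Glioma Marker Status</h2>\n"
            "<table><tr><th>marker</th><th>status</th><th>mean copy</th>"
            "<th>fraction altered</th><th>bins</th><th>evidence</th></tr>\n"
            + "\n".join(rows) + "</table>\n" + composites + "</section>")


def _classification_section(bundle: ReportBundle) -> str:
    result = bundle.classification
    rules = "\n".join(
        f"<li><b>{_esc(r['id'])}</b>: {_esc(r['evidence'])}</li>"
        for r in result.rules_fired
    )
    return (f"<section id=\"classification\">\n"
            f"<h2>Classification and Grading Summary</h2>\n"
            f"<p>CNV pattern consistent with: <b>{_esc(result.suggestion)}</b></p>\n"
            f"<p>Grade hint: <b>{_esc(result.grade_hint)}</b></p>\n"
            f"<ul>{rules}</ul>\n"
            f"<p class=\"disclaimer\">{_esc(result.disclaimer)}</p>\n</section>")


_CSS = """
body { font-family: sans-serif; margin: 2em auto; max-width: 1100px; }
h1 { border-bottom: 2px solid #333; }
section { margin-bottom: 2em; }
table { border-collapse: collapse; }
th, td { border: 1px solid #ccc; padding: 4px 10px; text-align: left; }
tr.alert { background: #ffebee; color: #b71c1c; font-weight: bold; }
.disclaimer { font-size: 0.85em; color: #555; font-style: italic; }
footer { font-size: 0.8em; color: #888; border-top: 1px solid #ccc; }
figure { margin: 0; }
figure svg { max-width: 100%; height: auto; }
"""


def render_html_report(bundle: ReportBundle, out_path: str) -> None:
    """Write the four-section, self-contained HTML report."""
    missing = [name for name in ("sample_header", "plot_svg", "marker_table",
                                 "classification")
               if getattr(bundle, name) is None]
    if missing:
        raise ValueError(f"report bundle is missing fields: {missing}")
    footer_bits = [f"tool version {_esc(bundle.tool_version)}"]
    if bundle.run_config_digest:
        footer_bits.append(f"config digest {_esc(bundle.run_config_digest)}")
    if bundle.timestamp:
        footer_bits.append(f"generated {_esc(bundle.timestamp)}")
    doc = f"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8"/>
<title>CNV marker report — {_esc(bundle.sample_header.get('sample_id', 'sample'))}</title>
<style>{_CSS}</style>
</head>
<body>
<h1>Glioma CNV Marker Report</h1>
{_header_section(bundle)}
{_visualization_section(bundle)}
{_marker_section(bundle)}
{_classification_section(bundle)}
<footer>{' · '.join(footer_bits)}</footer>
</body>
</html>
"""
    with open(out_path, "w") as fh:
        fh.write(doc)
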