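"""Serialization of screen results: JSON document, CSV top table, HTML report.

The JSON *screen document* bundles everything a downstream viewer needs —
the run configuration (thresholds, reference cohort, cohort display colors),
the top table with its metrics and fitted-line geometry, and per-row
sample-level arrays (post-transform x/y values, cohort labels, optional
per-observation |DFFITS|).  Serialization is canonical (sorted keys, fixed
indentation, trailing newline) so that parse(serialize(doc)) round-trips to
identical bytes.

The HTML report is a single self-contained file: a node-link network
rendered from a seeded force-directed layout, the top table with one inline
microplot per row, and a detail scatter plot per row with per-cohort fitted
lines and point radii proportional to influence.  No external resources are
referenced.
"""

from __future__ import annotations

import io
import json
import re
from importlib import resources

import numpy as np
import networkx as nx

from .errors import IntegrityError, ValidationError
from .regress import glyph_segments
from .screen import NetworkSummary, TopTable, network_summary
from .tables import MergedTable, RunConfig

_DEFAULT_PALETTE = (
    "#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#ff7f0e",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)
_OME_COLORS = {"microbe": "#2ca02c", "immune": "#9467bd"}


def _cohort_colors(config: RunConfig, labels: list[str]) -> dict[str, str]:
    colors = dict(config.cohort_colors or {})
    for i, lab in enumerate(labels):
        colors.setdefault(lab, _DEFAULT_PALETTE[i % len(_DEFAULT_PALETTE)])
    return colors


# ---------------------------------------------------------------------------
# document construction
# ---------------------------------------------------------------------------

def to_document(table: TopTable, merged: MergedTable, config: RunConfig) -> dict:
    """Build the export document for a top table.

    Sample-level x/y arrays come from the fitted pairs, i.e. post-transform
    values restricted to the pairwise-complete samples actually used, so the
    viewer's plots match the fitted models.
    """
    feature_names = set(merged.feature_names())
    cohort_labels: list[str] = []
    for r in table.rows:
        for lab in r.fit.cohort_labels:
            if lab not in cohort_labels:
                cohort_labels.append(lab)
    if not cohort_labels:
        cohort_labels = [str(c) for c in merged.cohort_labels]
    colors = _cohort_colors(config, cohort_labels)

    top_rows = []
    data: dict[str, dict] = {}
    for r in table.rows:
        for analyte in (r.microbe, r.immune):
            if analyte not in feature_names:
                raise IntegrityError(
                    f"top-table analyte {analyte!r} missing from merged table"
                )
        fit = r.fit
        row: dict = {
            "key": r.key,
            "microbe": r.microbe,
            "immune": r.immune,
            "F": float(r.F),
            "p": float(r.p),
            "pAdj": float(r.pAdj),
            "cohortLines": [
                {"cohort": ln.cohort, "intercept": ln.intercept,
                 "slope": ln.slope, "xMin": ln.x_min, "xMax": ln.x_max}
                for ln in fit.cohort_lines
            ],
            "glyph": [
                {"cohort": g.cohort, "x0": g.x0, "y0": g.y0,
                 "x1": g.x1, "y1": g.y1}
                for g in glyph_segments(fit.cohort_lines)
            ],
        }
        if r.interaction_p is not None:
            row["interactionP"] = {c: float(v) for c, v in r.interaction_p.items()}
        if "max_influence" in config.metric_columns:
            row["maxInfluence"] = (None if r.max_influence is None
                                   else float(r.max_influence))
        top_rows.append(row)

        rec = {
            "x": [float(v) for v in fit.x],
            "y": [float(v) for v in fit.y],
            "cohort": [str(c) for c in fit.cohorts],
            "xUnits": merged.meta(r.immune).units,
            "yUnits": merged.meta(r.microbe).units,
        }
        if fit.dffits is not None:
            rec["dffits"] = [float(abs(v)) for v in fit.dffits]
        data[str(r.key)] = rec

    doc = {
        "config": {
            "referenceCohort": config.reference_cohort,
            "thresholdType": config.threshold_type,
            "thresholdValue": float(config.threshold_value),
            "minNonzero": int(config.min_nonzero),
            "immuneTransform": config.immune_transform,
            "metricColumns": list(config.metric_columns),
            "cohortColors": colors,
            "m": int(table.m),
            "seed": int(config.seed),
        },
        "topTable": top_rows,
        "data": data,
    }
    validate_document(doc)
    return doc


def serialize_document(doc: dict) -> str:
    """Canonical UTF-8 JSON text: sorted keys, 2-space indent, newline-terminated."""
    return json.dumps(doc, sort_keys=True, indent=2, ensure_ascii=False,
                      allow_nan=False) + "\n"


def parse_document(text: str) -> dict:
    doc = json.loads(text)
    validate_document(doc)
    return doc


def load_schema() -> dict:
    """The machine-readable document schema shipped with the package."""
    with resources.files("omescreen").joinpath(
            "schema/document.schema.json").open(encoding="utf-8") as fh:
        return json.load(fh)


# -- minimal schema interpreter (type/required/properties/items/enum/bounds) --

def _check_node(value, schema: dict, path: str, errors: list[str]) -> None:
    types = schema.get("type")
    if types is not None:
        if isinstance(types, str):
            types = [types]
        ok = False
        for t in types:
            if t == "object" and isinstance(value, dict):
                ok = True
            elif t == "array" and isinstance(value, list):
                ok = True
            elif t == "string" and isinstance(value, str):
                ok = True
            elif t == "integer" and isinstance(value, int) and not isinstance(value, bool):
                ok = True
            elif t == "number" and isinstance(value, (int, float)) and not isinstance(value, bool):
                ok = True
            elif t == "null" and value is None:
                ok = True
        if not ok:
            errors.append(f"{path}: expected {types}, got {type(value).__name__}")
            return
    if value is None:
        return
    if "enum" in schema and value not in schema["enum"]:
        errors.append(f"{path}: {value!r} not in {schema['enum']}")
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if "minimum" in schema and value < schema["minimum"]:
            errors.append(f"{path}: {value} < minimum {schema['minimum']}")
        if "exclusiveMinimum" in schema and value <= schema["exclusiveMinimum"]:
            errors.append(f"{path}: {value} <= exclusiveMinimum")
        if "maximum" in schema and value > schema["maximum"]:
            errors.append(f"{path}: {value} > maximum {schema['maximum']}")
    if isinstance(value, dict):
        props = schema.get("properties", {})
        patterns = schema.get("patternProperties", {})
        for req in schema.get("required", []):
            if req not in value:
                errors.append(f"{path}: missing required key {req!r}")
        for k, v in value.items():
            if k in props:
                _check_node(v, props[k], f"{path}.{k}", errors)
                continue
            matched = False
            for pat, sub in patterns.items():
                if re.search(pat, k):
                    _check_node(v, sub, f"{path}.{k}", errors)
                    matched = True
                    break
            if not matched and schema.get("additionalProperties") is False:
                errors.append(f"{path}: unexpected key {k!r}")
    if isinstance(value, list) and "items" in schema:
        for i, v in enumerate(value):
            _check_node(v, schema["items"], f"{path}[{i}]", errors)


def validate_document(doc: dict) -> None:
    """Validate a document against the shipped schema plus cross-references.

    Cross-reference invariants beyond the per-node schema: top-table keys and
    data records are 1:1, and array lengths within a data record are equal.
    """
    errors: list[str] = []
    _check_node(doc, load_schema(), "$", errors)
    if errors:
        raise ValidationError("document schema violations: " + "; ".join(errors[:5]))

    keys = [str(row["key"]) for row in doc["topTable"]]
    if sorted(keys) != sorted(doc["data"].keys()):
        raise ValidationError("top-table keys and data records are not 1:1")
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate top-table keys")
    for k, rec in doc["data"].items():
        lengths = {name: len(rec[name]) for name in ("x", "y", "cohort")}
        if "dffits" in rec:
            lengths["dffits"] = len(rec["dffits"])
        if len(set(lengths.values())) > 1:
            raise ValidationError(f"data record {k}: unequal array lengths {lengths}")


# ---------------------------------------------------------------------------
# CSV top table
# ---------------------------------------------------------------------------

def write_top_table_csv(table: TopTable, path) -> None:
    """One row per top-table entry, configured metric columns, full precision."""
    df = table.to_dataframe()
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# HTML report
# ---------------------------------------------------------------------------

_MICROPLOT_W, _MICROPLOT_H, _MICROPLOT_PAD = 72, 36, 4


def _microplot_svg(glyph_rows: list[dict], colors: dict[str, str]) -> str:
    """Sparkline-sized glyph: each cohort's fitted segment in a fixed frame."""
    w, h, pad = _MICROPLOT_W, _MICROPLOT_H, _MICROPLOT_PAD
    parts = [
        f'<svg width="{w}" height="{h}" viewBox="0 0 {w} {h}" role="img">',
        f'<rect x="0" y="0" width="{w}" height="{h}" fill="#fafafa" '
        'stroke="#cccccc"/>',
    ]
    for g in glyph_rows:
        x0 = pad + g["x0"] * (w - 2 * pad)
        x1 = pad + g["x1"] * (w - 2 * pad)
        # SVG y grows downward
        y0 = h - pad - g["y0"] * (h - 2 * pad)
        y1 = h - pad - g["y1"] * (h - 2 * pad)
        col = colors.get(g["cohort"], "#333333")
        parts.append(
            f'<line x1="{x0:.2f}" y1="{y0:.2f}" x2="{x1:.2f}" y2="{y1:.2f}" '
            f'stroke="{col}" stroke-width="2"/>'
        )
    parts.append("</svg>")
    return "".join(parts)


def _network_svg(net: NetworkSummary, seed: int, size: int = 420) -> str:
    """Node-link view with a deterministic seeded force-directed layout."""
    if not net.nodes:
        return (f'<svg width="{size}" height="120"><text x="10" y="60" '
                'font-size="13">empty network</text></svg>')
    g = nx.Graph()
    for node in net.nodes:
        g.add_node(node.name, ome=node.ome, degree=node.degree)
    for mb, ir, _key in net.edges:
        g.add_edge(mb, ir)
    pos = nx.spring_layout(g, seed=seed, iterations=60)
    xs = np.array([p[0] for p in pos.values()])
    ys = np.array([p[1] for p in pos.values()])
    span_x = max(xs.max() - xs.min(), 1e-9)
    span_y = max(ys.max() - ys.min(), 1e-9)
    pad = 30

    def sx(v):
        return pad + (v - xs.min()) / span_x * (size - 2 * pad)

    def sy(v):
        return pad + (v - ys.min()) / span_y * (size - 2 * pad)

    parts = [f'<svg width="{size}" height="{size}" '
             f'viewBox="0 0 {size} {size}" role="img">']
    for mb, ir, _key in net.edges:
        parts.append(
            f'<line x1="{sx(pos[mb][0]):.1f}" y1="{sy(pos[mb][1]):.1f}" '
            f'x2="{sx(pos[ir][0]):.1f}" y2="{sy(pos[ir][1]):.1f}" '
            'stroke="#999999" stroke-width="1"/>'
        )
    for node in net.nodes:
        x, y = sx(pos[node.name][0]), sy(pos[node.name][1])
        r = 4 + 1.5 * np.sqrt(node.degree)
        parts.append(
            f'<circle cx="{x:.1f}" cy="{y:.1f}" r="{r:.1f}" '
            f'fill="{_OME_COLORS[node.ome]}" fill-opacity="0.85">'
            f'<title>{_esc(node.name)} (degree {node.degree})</title></circle>'
        )
        parts.append(
            f'<text x="{x + r + 2:.1f}" y="{y + 3:.1f}" font-size="9" '
            f'fill="#444444">{_esc(node.name)}</text>'
        )
    parts.append("</svg>")
    return "".join(parts)


def _detail_plot_svg(row: dict, rec: dict, colors: dict[str, str]) -> str:
    """Matplotlib scatter + fitted lines for one pair, as an inline SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(rec["x"], dtype=float)
    y = np.asarray(rec["y"], dtype=float)
    coh = np.asarray(rec["cohort"], dtype=object)
    infl = np.asarray(rec.get("dffits", []), dtype=float)

    fig, ax = plt.subplots(figsize=(3.6, 2.8), dpi=90)
    for lab in dict.fromkeys(coh):
        mask = coh == lab
        if infl.size:
            # radius proportional to |DFFITS|; floor keeps points visible
            sizes = 15 + 120 * (infl[mask] / max(infl.max(), 1e-12))
        else:
            sizes = 25
        ax.scatter(x[mask], y[mask], s=sizes, alpha=0.75,
                   color=colors.get(str(lab), "#333333"), label=str(lab),
                   edgecolors="none")
    for ln in row["cohortLines"]:
        gx = np.array([ln["xMin"], ln["xMax"]])
        ax.plot(gx, ln["intercept"] + ln["slope"] * gx,
                color=colors.get(ln["cohort"], "#333333"), lw=1.5)
    xlabel = row["immune"] + (f' ({rec["xUnits"]})' if rec["xUnits"] else "")
    ylabel = row["microbe"] + (f' ({rec["yUnits"]})' if rec["yUnits"] else "")
    ax.set_xlabel(xlabel, fontsize=8)
    ax.set_ylabel(ylabel, fontsize=8)
    ax.tick_params(labelsize=7)
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    svg = buf.getvalue()
    return svg[svg.index("<svg"):]


def _esc(s: str) -> str:
    return (str(s).replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;").replace('"', "&quot;"))


def render_report(doc: dict, path, *, max_detail_plots: int | None = None) -> None:
    """Write a single self-contained HTML report for a screen document.

    Layout: network summary on top, the top table with inline microplots,
    then one detail plot per row (capped at ``max_detail_plots`` if given).
    Rows lacking influence data render constant-radius points.
    """
    validate_document(doc)
    cfg = doc["config"]
    colors = cfg.get("cohortColors", {})
    rows = doc["topTable"]

    # reconstruct the network from the document rows
    from .screen import NetworkNode
    degree: dict[str, int] = {}
    ome: dict[str, str] = {}
    edges = []
    for row in rows:
        degree[row["microbe"]] = degree.get(row["microbe"], 0) + 1
        degree[row["immune"]] = degree.get(row["immune"], 0) + 1
        ome.setdefault(row["microbe"], "microbe")
        ome.setdefault(row["immune"], "immune")
        edges.append((row["microbe"], row["immune"], row["key"]))
    net = NetworkSummary(
        nodes=[NetworkNode(n, ome[n], degree[n]) for n in degree],
        edges=edges,
    )

    has_interactions = any("interactionP" in r for r in rows)
    has_influence = any(r.get("maxInfluence") is not None for r in rows)

    head = [
        "<!DOCTYPE html>",
        '<html lang="en"><head><meta charset="utf-8">',
        "<title>Cross-ome screen report</title>",
        "<style>",
        "body{font-family:sans-serif;margin:24px;color:#222}",
        "table{border-collapse:collapse;margin:12px 0}",
        "th,td{border:1px solid #ddd;padding:4px 8px;font-size:12px;"
        "text-align:left}",
        "th{background:#f0f0f0}",
        ".legend span{margin-right:14px;font-size:12px}",
        ".plots{display:flex;flex-wrap:wrap;gap:12px}",
        ".plot{border:1px solid #eee;padding:6px}",
        "</style></head><body>",
        "<h1>Cross-ome association screen</h1>",
    ]
    n_rows = len(rows)
    summary = (
        f"<p>{n_rows} relationship{'s' if n_rows != 1 else ''} at "
        f"{_esc(cfg['thresholdType'])} &lt; {cfg['thresholdValue']:g} "
        f"(reference cohort {_esc(cfg['referenceCohort'])}, "
        f"{cfg['m']} tests adjusted).</p>"
    )
    if n_rows == 0:
        summary += "<p><em>0 relationships surfaced; nothing to plot.</em></p>"
    legend = ['<p class="legend">'] + [
        f'<span style="color:{col}">&#9632; {_esc(lab)}</span>'
        for lab, col in colors.items()
    ] + [
        f'<span style="color:{_OME_COLORS["microbe"]}">&#9679; microbe</span>',
        f'<span style="color:{_OME_COLORS["immune"]}">&#9679; immune</span>',
        "</p>",
    ]

    parts = head + [summary] + legend
    parts.append("<h2>Network</h2>")
    parts.append(_network_svg(net, seed=int(cfg.get("seed", 0))))

    parts.append("<h2>Top table</h2>")
    header = ["key", "microbe", "immune", "F", "p", "pAdj"]
    if has_interactions:
        header.append("interaction p")
    if has_influence:
        header.append("maxInfluence")
    header.append("mPlot")
    parts.append("<table><thead><tr>"
                 + "".join(f"<th>{h}</th>" for h in header)
                 + "</tr></thead><tbody>")
    for row in rows:
        cells = [
            str(row["key"]), _esc(row["microbe"]), _esc(row["immune"]),
            f"{row['F']:.3f}", f"{row['p']:.3g}", f"{row['pAdj']:.3g}",
        ]
        if has_interactions:
            ip = row.get("interactionP", {})
            cells.append(", ".join(f"{_esc(c)}: {v:.3g}"
                                   for c, v in sorted(ip.items())))
        if has_influence:
            mi = row.get("maxInfluence")
            cells.append("" if mi is None else f"{mi:.3f}")
        cells.append(_microplot_svg(row["glyph"], colors))
        parts.append("<tr>" + "".join(f"<td>{c}</td>" for c in cells) + "</tr>")
    parts.append("</tbody></table>")

    parts.append("<h2>Detail plots</h2>")
    parts.append('<div class="plots">')
    plot_rows = rows if max_detail_plots is None else rows[:max_detail_plots]
    for row in plot_rows:
        rec = doc["data"][str(row["key"])]
        parts.append(f'<div class="plot"><p>key = {row["key"]}: '
                     f'{_esc(row["microbe"])} ~ {_esc(row["immune"])}</p>')
        parts.append(_detail_plot_svg(row, rec, colors))
        parts.append("</div>")
    parts.append("</div></body></html>")

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(parts))


# convenience: document straight from a top table + merged table
def export_all(table: TopTable, merged: MergedTable, config: RunConfig,
               json_path=None, csv_path=None, html_path=None,
               max_detail_plots: int | None = None) -> dict:
    """Build the document and write any of the three artifacts."""
    doc = to_document(table, merged, config)
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            fh.write(serialize_document(doc))
    if csv_path is not None:
        write_top_table_csv(table, csv_path)
    if html_path is not None:
        render_report(doc, html_path, max_detail_plots=max_detail_plots)
    return doc


__all__ = [
    "to_document", "serialize_document", "parse_document", "load_schema",
    "validate_document", "write_top_table_csv", "render_report", "export_all",
    "network_summary",
]
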