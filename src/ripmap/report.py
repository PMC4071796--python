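"""Static HTML report: sortable index, per-protein peptide maps, zip bundle.

The report is plain HTML5 + CSS3 with a small vanilla-JS sorter/filter —
no server required.  Each valid protein gets a page drawing its sequence
as a horizontal bar with feature tracks (signal peptide, transmembrane
segments, topological domains) and the mapped peptides as boxes colored
on a red–green scale: decreases (log2 below the no-change zone) in red,
increases in green, the zone itself in neutral gray.  The whole output
directory is zipped with fixed timestamps so that identical inputs give
identical archives.
"""

from __future__ import annotations

import html
import zipfile
from pathlib import Path
from typing import Optional, Sequence, Union

from .mapping import ProteinResult
from .quantify import DiscardedProtein, RunConfig
from .screen import RunSummary

#: bundle member names; the browser note keeps its original (misspelled)
#: published filename by default for fidelity
BROWSER_NOTE_MISSPELLED = "suppoted_browsers_and_os.txt"
BROWSER_NOTE_CORRECTED = "supported_browsers_and_os.txt"

_CHANNEL_FLOOR = 64  # faintest non-gray intensity at the zone boundary

_FEATURE_COLORS = {
    "signal": "#e6a23c",
    "transmembrane": "#444444",
    "cytoplasmic": "#4a7fb5",
    "extra_cytoplasmic": "#c9b458",
    "unclassified": "#bbbbbb",
}


def color_for_ratio(value: float, config: Optional[RunConfig] = None) -> str:
    """Hex RGB color of one clamped log2 ratio on the red–green scale.

    The no-change zone [zn, zp] is neutral gray ``#808080``.  Above zp the
    green channel grows linearly from 64 to 255 at rmax; below zn the red
    channel grows from 64 to 255 at rmin (more negative = more intense).
    Endpoints are exact: rmax → ``#00FF00``, rmin → ``#FF0000``.
    """
    config = config or RunConfig()
    if not (config.rmin <= value <= config.rmax):
        raise ValueError(
            f"value {value} outside clamped range [{config.rmin}, {config.rmax}]"
        )
    if config.zn <= value <= config.zp:
        return "#808080"
    if value > config.zp:
        frac = (value - config.zp) / (config.rmax - config.zp)
        green = round(_CHANNEL_FLOOR + frac * (255 - _CHANNEL_FLOOR))
        return f"#00{green:02X}00"
    frac = (config.zn - value) / (config.zn - config.rmin)
    red = round(_CHANNEL_FLOOR + frac * (255 - _CHANNEL_FLOOR))
    return f"#{red:02X}0000"


# ---------------------------------------------------------------------------
# SVG peptide maps

def _protein_svg(result: ProteinResult, width: int = 960) -> str:
    """Horizontal sequence bar with feature track and colored peptide boxes."""
    from .annotation import classify_feature

    height = 150
    bar_y, bar_h = 60, 24
    margin = 20
    ann = result.annotation
    length = ann.length if ann is not None else max(
        (max((e for _, e in m.positions), default=1) for m in result.mapped_peptides),
        default=1,
    )
    scale = (width - 2 * margin) / max(length, 1)

    def x(pos: int) -> float:
        return margin + (pos - 1) * scale

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<rect x="{margin}" y="{bar_y}" width="{(width - 2 * margin):.1f}" '
        f'height="{bar_h}" fill="#dddddd" stroke="#999999"/>',
    ]
    if ann is not None:
        for feat in ann.features:
            cat = classify_feature(feat)
            color = _FEATURE_COLORS.get(cat, "#bbbbbb")
            w = (feat.end - feat.start + 1) * scale
            parts.append(
                f'<rect x="{x(feat.start):.1f}" y="{bar_y}" width="{w:.1f}" '
                f'height="{bar_h}" fill="{color}">'
                f"<title>{feat.category} {feat.start}..{feat.end} "
                f"{html.escape(feat.subtype)}</title></rect>"
            )
    for m in result.mapped_peptides:
        if not m.positions:
            continue
        start, end = m.positions[0]
        w = max((end - start + 1) * scale, 1.0)
        label = (
            f"{m.peptide.sequence} {start}..{end} {m.region_class}"
            + (f" log2={m.log2_ratio:.2f}" if m.log2_ratio is not None else "")
        )
        parts.append(
            f'<rect x="{x(start):.1f}" y="{bar_y - 26}" width="{w:.1f}" height="18" '
            f'fill="{m.color}" stroke="#333333" stroke-width="0.5">'
            f"<title>{html.escape(label)}</title></rect>"
        )
    parts.append(
        f'<text x="{margin}" y="{bar_y + bar_h + 30}" font-size="12" '
        f'font-family="sans-serif">1</text>'
    )
    parts.append(
        f'<text x="{width - margin}" y="{bar_y + bar_h + 30}" font-size="12" '
        f'text-anchor="end" font-family="sans-serif">{length}</text>'
    )
    parts.append("</svg>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# HTML documents

_CSS = """\
body { font-family: sans-serif; margin: 1.5em; color: #222; }
table.index { border-collapse: collapse; width: 100%; }
table.index th, table.index td { border: 1px solid #ccc; padding: 4px 8px; }
table.index th { background: #f0f0f0; cursor: pointer; }
tr.hidden { display: none; }
.badge { background: #b33; color: white; border-radius: 4px; padding: 1px 6px; font-size: 85%; }
.updown-up { color: #070; } .updown-down { color: #b00; }
.controls { margin: 0.8em 0; }
"""

_SORT_JS = """\
function sortTable(col) {
  var table = document.getElementById('proteins');
  var rows = Array.prototype.slice.call(table.tBodies[0].rows);
  var dir = table.getAttribute('data-dir') === 'asc' ? -1 : 1;
  rows.sort(function (a, b) {
    var x = a.cells[col].getAttribute('data-v') || a.cells[col].textContent;
    var y = b.cells[col].getAttribute('data-v') || b.cells[col].textContent;
    var nx = parseFloat(x), ny = parseFloat(y);
    if (!isNaN(nx) && !isNaN(ny)) { return dir * (nx - ny); }
    return dir * x.localeCompare(y);
  });
  rows.forEach(function (r) { table.tBodies[0].appendChild(r); });
  table.setAttribute('data-dir', dir === 1 ? 'asc' : 'desc');
}
function applyFilters() {
  var needTM = document.getElementById('f-tm').checked;
  var needSig = document.getElementById('f-signal').checked;
  var rows = document.getElementById('proteins').tBodies[0].rows;
  for (var i = 0; i < rows.length; i++) {
    var ok = (!needTM || rows[i].getAttribute('data-tm') === '1') &&
             (!needSig || rows[i].getAttribute('data-signal') === '1');
    rows[i].className = ok ? '' : 'hidden';
  }
}
"""


def _fmt(value: Optional[float], digits: int = 2) -> str:
    return "NA" if value is None else f"{value:.{digits}f}"


def _protein_page(result: ProteinResult, config: RunConfig) -> str:
    rec = result.record
    ann = result.annotation
    title = html.escape(rec.accession)
    rows = []
    for m in result.mapped_peptides:
        pos = (
            f"{m.positions[0][0]}..{m.positions[0][1]}" if m.positions else "NA"
        )
        extra = f" (+{len(m.positions) - 1} more)" if len(m.positions) > 1 else ""
        rows.append(
            "<tr>"
            f"<td style='font-family:monospace'>{html.escape(m.peptide.sequence)}</td>"
            f"<td>{m.peptide.probability:.3f}</td><td>{pos}{extra}</td>"
            f"<td>{html.escape(m.region_class)}</td>"
            f"<td>{_fmt(m.raw_ratio)}</td><td>{_fmt(m.log2_ratio)}</td>"
            f"<td style='background:{m.color}'>{html.escape(m.change_class)}</td>"
            f"<td>{html.escape(m.validation_flag)}</td>"
            "</tr>"
        )
    badge = "" if ann is not None else ' <span class="badge">unannotated</span>'
    name = html.escape(ann.recommended_name) if ann is not None else "(no annotation)"
    cyto = result.cytoplasmic
    extra_q = result.extra_cytoplasmic
    quant_line = (
        f"<p>Protein log2 L:H: <b>{_fmt(result.protein_log2)}</b> &middot; "
        f"cytoplasmic mean: <b>{_fmt(cyto.mean_log2 if cyto else None)}</b>"
        f" (n={cyto.n_peptides if cyto else 0}) &middot; "
        f"extra-cytoplasmic mean: "
        f"<b>{_fmt(extra_q.mean_log2 if extra_q else None)}</b>"
        f" (n={extra_q.n_peptides if extra_q else 0})</p>"
    )
    img = (
        f'<p><img src="../images/{rec.accession}.svg" alt="peptide map" '
        f'width="960"/></p>'
        if ann is not None
        else "<p>No sequence available; peptides listed without positions.</p>"
    )
    return f"""<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8"/>
<title>{title}</title><link rel="stylesheet" href="style.css"/></head>
<body>
<p><a href="../index.html">&larr; index</a></p>
<h1>{title}{badge}</h1>
<p>{name} &middot; ProteinProphet probability {rec.probability:.3f}</p>
{quant_line}
{img}
<table class="index"><thead><tr>
<th>Peptide</th><th>Probability</th><th>Position</th><th>Region</th>
<th>L:H</th><th>log2</th><th>Change</th><th>Validation</th>
</tr></thead><tbody>
{''.join(rows)}
</tbody></table>
</body></html>
"""


def _index_page(
    results: Sequence[ProteinResult],
    summary: RunSummary,
    config: RunConfig,
) -> str:
    rows = []
    for res in results:
        rec = res.record
        ann = res.annotation
        has_tm = int(ann is not None and ann.has_transmembrane())
        has_sig = int(ann is not None and ann.has_signal())
        name = html.escape(ann.recommended_name) if ann is not None else "NA"
        cyto = res.cytoplasmic
        extra = res.extra_cytoplasmic
        link = (
            f'<a href="https://www.uniprot.org/uniprotkb/{rec.accession}">'
            f"{html.escape(rec.accession)}</a>"
            if rec.namespace == "uniprot"
            else html.escape(rec.accession)
        )
        rows.append(
            f'<tr data-tm="{has_tm}" data-signal="{has_sig}">'
            f'<td><a href="index_files/{rec.accession}.html">{html.escape(rec.accession)}</a></td>'
            f"<td>{link}</td><td>{name}</td>"
            f"<td>{rec.probability:.3f}</td>"
            f"<td>{_fmt(res.protein_log2)}</td>"
            f"<td>{_fmt(cyto.mean_log2 if cyto else None)}</td>"
            f"<td>{_fmt(extra.mean_log2 if extra else None)}</td>"
            f"<td>{'yes' if has_tm else 'no'}</td>"
            f"<td>{'yes' if has_sig else 'no'}</td>"
            f'<td><img src="small_images/{rec.accession}.svg" alt="" height="30"/></td>'
            "</tr>"
        )
    return f"""<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8"/>
<title>Peptide-mapping report</title>
<link rel="stylesheet" href="index_files/style.css"/>
<script src="index_files/sorter.js"></script></head>
<body>
<h1>Peptide-mapping report</h1>
<p>{summary.n_total} quantified proteins &middot; {summary.n_tm} with a
transmembrane domain ({summary.pct_tm}%) &middot; {summary.n_tm_no_signal}
TM proteins without a signal peptide ({summary.pct_tm_no_signal}% of TM).</p>
<div class="controls">
<label><input type="checkbox" id="f-tm" onchange="applyFilters()"/> has transmembrane</label>
<label><input type="checkbox" id="f-signal" onchange="applyFilters()"/> has signal peptide</label>
</div>
<table class="index" id="proteins"><thead><tr>
<th onclick="sortTable(0)">Accession</th>
<th onclick="sortTable(1)">UniProt</th>
<th onclick="sortTable(2)">Name</th>
<th onclick="sortTable(3)">Probability</th>
<th onclick="sortTable(4)">Protein log2</th>
<th onclick="sortTable(5)">Cytoplasmic mean</th>
<th onclick="sortTable(6)">Extra-cytoplasmic mean</th>
<th onclick="sortTable(7)">TM</th>
<th onclick="sortTable(8)">Signal</th>
<th>Map</th>
</tr></thead><tbody>
{''.join(rows)}
</tbody></table>
</body></html>
"""


_BROWSER_NOTE = """\
Viewing requirements
--------------------
The report is static HTML5 + CSS3 with inline SVG graphics and a small
amount of JavaScript for table sorting and filtering.  Any CSS3-capable
browser renders it as intended (current Firefox, Chrome/Chromium, Edge,
Safari) on Linux, macOS or Windows.  No network connection or server is
required; open index.html from the unpacked folder.
"""


def render_html(
    results: Sequence[ProteinResult],
    summary: RunSummary,
    config: Optional[RunConfig] = None,
) -> dict[str, str]:
    """Render the report as a mapping of relative path → document text.

    Keys include ``index.html``, one ``index_files/<acc>.html`` per
    protein, full-size and thumbnail SVGs under ``images/`` and
    ``small_images/``, and the shared CSS/JS assets under
    ``index_files/``.
    """
    config = config or RunConfig()
    docs: dict[str, str] = {}
    docs["index.html"] = _index_page(results, summary, config)
    docs["index_files/style.css"] = _CSS
    docs["index_files/sorter.js"] = _SORT_JS
    for res in results:
        acc = res.record.accession
        docs[f"index_files/{acc}.html"] = _protein_page(res, config)
        if res.annotation is not None:
            docs[f"images/{acc}.svg"] = _protein_svg(res, width=960)
            docs[f"small_images/{acc}.svg"] = _protein_svg(res, width=200)
        else:
            placeholder = (
                '<svg xmlns="http://www.w3.org/2000/svg" width="200" height="30">'
                '<text x="4" y="20" font-size="12">unannotated</text></svg>'
            )
            docs[f"images/{acc}.svg"] = placeholder
            docs[f"small_images/{acc}.svg"] = placeholder
    return docs


def _run_stats(discarded: Sequence[DiscardedProtein]) -> str:
    lines = [f"{d.record.protein_name}\t{d.reason}" for d in discarded]
    return "\n".join(lines) + ("\n" if lines else "")


def _average_mw(results: Sequence[ProteinResult]) -> str:
    weights = [
        r.annotation.molecular_weight for r in results if r.annotation is not None
    ]
    mean = sum(weights) / len(weights) if weights else 0.0
    return (
        f"average_molecular_weight_Da\t{mean:.1f}\n"
        f"n_proteins\t{len(weights)}\n"
    )


def write_bundle(
    results: Sequence[ProteinResult],
    summary: RunSummary,
    discarded: Sequence[DiscardedProtein],
    output_dir: Union[str, Path],
    config: Optional[RunConfig] = None,
    corrected_browser_note_name: bool = False,
) -> Path:
    """Write the report directory and its zip archive; return the zip path.

    The directory holds exactly the published inventory: ``index.html``,
    ``run_stats.out`` (one line per discarded protein),
    ``average_molecular_weight.txt``, the browser-support note, and the
    ``images``, ``small_images`` and ``index_files`` directories.  Zip
    members are sorted and carry a fixed timestamp, so the archive is
    byte-stable for identical inputs.
    """
    config = config or RunConfig()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    docs = render_html(results, summary, config)
    docs["run_stats.out"] = _run_stats(discarded)
    docs["average_molecular_weight.txt"] = _average_mw(results)
    note_name = (
        BROWSER_NOTE_CORRECTED if corrected_browser_note_name else BROWSER_NOTE_MISSPELLED
    )
    docs[note_name] = _BROWSER_NOTE
    for dirname in ("images", "small_images", "index_files"):
        (out / dirname).mkdir(exist_ok=True)
    for rel, text in docs.items():
        target = out / rel
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_text(text, encoding="utf-8")

    zip_path = out.parent / (out.name + ".zip")
    fixed_date = (1980, 1, 1, 0, 0, 0)
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for dirname in ("images", "small_images", "index_files"):
            info = zipfile.ZipInfo(dirname + "/", date_time=fixed_date)
            info.external_attr = 0o755 << 16 | 0x10
            zf.writestr(info, b"")
        for rel in sorted(docs):
            info = zipfile.ZipInfo(rel, date_time=fixed_date)
            info.external_attr = 0o644 << 16
            zf.writestr(info, docs[rel].encode("utf-8"))
    return zip_path
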