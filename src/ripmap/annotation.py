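"""Per-accession protein annotation: sequence, names and topology.

Region assignment needs, for every protein, its full precursor sequence
and the 1-based inclusive coordinates of its signal peptide, transmembrane
segments and topological domains (UniProt's FT SIGNAL / TRANSMEM /
TOPO_DOM features).  Two local sources are supported — UniProt flat text
and the package's own one-row-per-entry tabular format — plus an optional
online fetcher for single UniProt entries, kept out of the test suite.

Coordinates stay 1-based inclusive throughout (UniProt convention), and
the precursor sequence (signal peptide included) is the mapping frame.
"""

from __future__ import annotations

import logging
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Union

logger = logging.getLogger(__name__)

FEATURE_CATEGORIES = ("SIGNAL", "TRANSMEM", "TOPO_DOM")

#: TOPO_DOM descriptions counted as extra-cytoplasmic besides the two
#: canonical ones; configurable via classify_feature(extra_synonyms=...)
EXTRA_CYTOPLASMIC_SYNONYMS = ("Extracellular", "Lumenal", "Periplasmic", "Vesicular")

_TOPO_CANONICAL = {
    "cytoplasmic": "Cytoplasmic",
    "extracellular": "Extracellular",
    "lumenal": "Lumenal",
    "luminal": "Lumenal",
}


@dataclass(frozen=True)
class TopoFeature:
    """One topological feature on a protein, 1-based inclusive."""

    category: str  # SIGNAL | TRANSMEM | TOPO_DOM
    start: int
    end: int
    subtype: str = ""  # for TOPO_DOM: Cytoplasmic, Extracellular, Lumenal, Other...

    def __post_init__(self) -> None:
        if self.category not in FEATURE_CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid feature span {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinAnnotation:
    """Sequence plus topology for one accession."""

    accession: str
    recommended_name: str
    sequence: str
    molecular_weight: float
    features: list[TopoFeature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        kept = []
        for feat in self.features:
            if feat.end > self.length:
                logger.warning(
                    "%s: feature %s %d..%d exceeds length %d; dropped",
                    self.accession, feat.category, feat.start, feat.end, self.length,
                )
                continue
            kept.append(feat)
        self.features = kept
        self._warn_overlaps()

    def _warn_overlaps(self) -> None:
        spans = sorted((f.start, f.end, f.category) for f in self.features)
        for (s1, e1, c1), (s2, e2, c2) in zip(spans, spans[1:]):
            if s2 <= e1:
                logger.warning(
                    "%s: overlapping features %s %d..%d and %s %d..%d "
                    "(resolved by priority at mapping time)",
                    self.accession, c1, s1, e1, c2, s2, e2,
                )

    def has_transmembrane(self) -> bool:
        return any(f.category == "TRANSMEM" for f in self.features)

    def has_signal(self) -> bool:
        return any(f.category == "SIGNAL" for f in self.features)


def classify_feature(
    feature: TopoFeature,
    extra_synonyms: Sequence[str] = EXTRA_CYTOPLASMIC_SYNONYMS,
) -> str:
    """Map a feature to its region category.

    Returns one of ``cytoplasmic``, ``extra_cytoplasmic``, ``transmembrane``,
    ``signal`` or ``unclassified``.  A TOPO_DOM whose subtype is neither
    Cytoplasmic nor a known extra-cytoplasmic synonym is unclassified and
    contributes no region.
    """
    if feature.category == "TRANSMEM":
        return "transmembrane"
    if feature.category == "SIGNAL":
        return "signal"
    subtype = feature.subtype.strip()
    canonical = _TOPO_CANONICAL.get(subtype.lower(), subtype)
    if canonical == "Cytoplasmic":
        return "cytoplasmic"
    if canonical in ("Extracellular", "Lumenal"):
        return "extra_cytoplasmic"
    lowered = {s.lower() for s in extra_synonyms}
    if subtype.lower() in lowered or any(
        subtype.lower().startswith(s.lower()) for s in extra_synonyms
    ):
        return "extra_cytoplasmic"
    return "unclassified"


# ---------------------------------------------------------------------------
# tabular annotation format
#
# One row per entry, tab-separated:
#   accession  name  molecular_weight  length  features  sequence
# features: semicolon-separated "CATEGORY start..end[ subtype]" items, or "-".

_FEATURE_ITEM_RE = re.compile(
    r"^\s*(SIGNAL|TRANSMEM|TOPO_DOM)\s+(\d+)\.\.(\d+)(?:\s+(.+?))?\s*$"
)

_TABLE_HEADER = "accession\tname\tmolecular_weight\tlength\tfeatures\tsequence"


def _parse_feature_list(text: str, accession: str) -> list[TopoFeature]:
    features: list[TopoFeature] = []
    if not text or text.strip() in ("-", "NA", ""):
        return features
    for item in text.split(";"):
        if not item.strip():
            continue
        m = _FEATURE_ITEM_RE.match(item)
        if not m:
            logger.warning("%s: unparsable feature %r skipped", accession, item.strip())
            continue
        category, start, end, subtype = m.groups()
        try:
            features.append(
                TopoFeature(
                    category=category,
                    start=int(start),
                    end=int(end),
                    subtype=(subtype or "").strip(),
                )
            )
        except ValueError as exc:
            logger.warning("%s: feature %r skipped: %s", accession, item.strip(), exc)
    return features


def _load_tabular(path: Path) -> Dict[str, ProteinAnnotation]:
    annotations: Dict[str, ProteinAnnotation] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("accession\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                logger.warning("%s:%d: expected 6 columns, got %d; skipped",
                               path, lineno, len(parts))
                continue
            acc, name, mw, length, feats, seq = parts
            seq = seq.strip().upper()
            try:
                ann = ProteinAnnotation(
                    accession=acc,
                    recommended_name=name,
                    sequence=seq,
                    molecular_weight=float(mw),
                    features=_parse_feature_list(feats, acc),
                )
            except ValueError as exc:
                logger.warning("%s:%d: entry %s skipped: %s", path, lineno, acc, exc)
                continue
            if int(length) != ann.length:
                logger.warning(
                    "%s: declared length %s != sequence length %d",
                    acc, length, ann.length,
                )
            annotations[acc] = ann
    return annotations


def save_annotations(
    annotations: Dict[str, ProteinAnnotation], path: Union[str, Path]
) -> None:
    """Write annotations in the tabular format (round-trips with load)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(_TABLE_HEADER + "\n")
        for acc in sorted(annotations):
            ann = annotations[acc]
            feats = "; ".join(
                f"{f.category} {f.start}..{f.end}" + (f" {f.subtype}" if f.subtype else "")
                for f in ann.features
            ) or "-"
            handle.write(
                f"{ann.accession}\t{ann.recommended_name}\t{ann.molecular_weight:g}"
                f"\t{ann.length}\t{feats}\t{ann.sequence}\n"
            )


# ---------------------------------------------------------------------------
# UniProt flat text (DE / SQ / FT lines)

def _load_flat(path: Path) -> Dict[str, ProteinAnnotation]:
    annotations: Dict[str, ProteinAnnotation] = {}
    acc = name = ""
    mw = 0.0
    seq_lines: list[str] = []
    in_sq = False
    raw_features: list[dict] = []
    current_feature: Optional[dict] = None

    def flush() -> None:
        nonlocal acc, name, mw, seq_lines, raw_features, current_feature, in_sq
        if acc and seq_lines:
            sequence = "".join(seq_lines).replace(" ", "").upper()
            feats = []
            for f in raw_features:
                try:
                    feats.append(
                        TopoFeature(
                            category=f["category"],
                            start=f["start"],
                            end=f["end"],
                            subtype=f.get("subtype", ""),
                        )
                    )
                except ValueError as exc:
                    logger.warning("%s: flat-file feature skipped: %s", acc, exc)
            try:
                annotations[acc] = ProteinAnnotation(
                    accession=acc,
                    recommended_name=name or acc,
                    sequence=sequence,
                    molecular_weight=mw if mw > 0 else max(len(sequence) * 110.0, 1.0),
                    features=feats,
                )
            except ValueError as exc:
                logger.warning("flat-file entry %s skipped: %s", acc, exc)
        acc, name, mw = "", "", 0.0
        seq_lines, raw_features, current_feature = [], [], None
        in_sq = False

    ft_re = re.compile(r"^FT\s{3}(\w+)\s+(\d+)(?:\.\.(\d+))?")
    note_re = re.compile(r"/note=\"([^\"]*)\"")

    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("AC"):
                if not acc:
                    acc = line[5:].split(";")[0].strip()
            elif line.startswith("DE   RecName: Full="):
                if not name:
                    name = line.split("Full=", 1)[1].split(";")[0].split("{")[0].strip()
            elif line.startswith("SQ"):
                in_sq = True
                m = re.search(r"(\d+)\s+MW", line)
                if m:
                    mw = float(m.group(1))
            elif line.startswith("FT"):
                m = ft_re.match(line)
                if m and m.group(1) in FEATURE_CATEGORIES:
                    current_feature = {
                        "category": m.group(1),
                        "start": int(m.group(2)),
                        "end": int(m.group(3) or m.group(2)),
                    }
                    raw_features.append(current_feature)
                elif current_feature is not None and "/note=" in line:
                    nm = note_re.search(line)
                    if nm and current_feature["category"] == "TOPO_DOM":
                        current_feature["subtype"] = nm.group(1).split(";")[0].strip()
            elif line.startswith("//"):
                flush()
            elif in_sq:
                seq_lines.append(re.sub(r"[\s\d]", "", line))
    flush()
    return annotations


def load_annotations(source: Union[str, Path]) -> Dict[str, ProteinAnnotation]:
    """Load a local annotation file (tabular or UniProt flat text).

    The format is sniffed from the first non-empty line: UniProt flat
    files start with two-letter line codes (ID/AC), the tabular format
    with the header or a tab-separated row.  Raises ``FileNotFoundError``
    for a missing file and ``ValueError`` when no entry parses.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"annotation source not found: {path}")
    with open(path, encoding="utf-8") as handle:
        first = ""
        for line in handle:
            if line.strip():
                first = line
                break
    if first.startswith(("ID ", "AC ")):
        annotations = _load_flat(path)
    else:
        annotations = _load_tabular(path)
    if not annotations:
        raise ValueError(f"no annotation entries parsed from {path}")
    return annotations


# ---------------------------------------------------------------------------
# optional online fetcher (not exercised by the hermetic test suite)

UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{accession}.txt"


class AnnotationLookupError(RuntimeError):
    """Raised when an accession cannot be resolved to an annotation."""


def fetch_annotation(accession: str, timeout: float = 30.0) -> ProteinAnnotation:
    """Fetch one UniProt entry's annotation over HTTPS (flat-text endpoint).

    IPI identifiers cannot be fetched (the IPI service is retired); supply
    a local mapping table instead.  Network or lookup failures raise
    :class:`AnnotationLookupError`; the pipeline records such proteins as
    unannotated and continues.
    """
    if accession.upper().startswith("IPI"):
        raise AnnotationLookupError(
            f"{accession}: IPI identifiers have no live annotation service; "
            "provide a local annotation file"
        )
    url = UNIPROT_URL.format(accession=accession)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode("utf-8")
    except Exception as exc:  # noqa: BLE001 - network errors are environmental
        raise AnnotationLookupError(f"{accession}: fetch failed ({exc})") from exc
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".txt", delete=False) as tmp:
        tmp.write(text)
        tmp_path = tmp.name
    try:
        entries = _load_flat(Path(tmp_path))
    finally:
        Path(tmp_path).unlink(missing_ok=True)
    if not entries:
        raise AnnotationLookupError(f"{accession}: no parsable entry in response")
    return next(iter(entries.values()))
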