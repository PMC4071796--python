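"""Placing peptides on protein sequences and classifying them by region.

Each deduplicated peptide is located by exact substring search on the
precursor sequence (all occurrences, 1-based inclusive spans) and assigned
the topological region its residues fall into.  Residues covered by
overlapping features resolve by priority signal > transmembrane >
cytoplasmic > extra-cytoplasmic; peptides straddling a region boundary
are classed ``spanning`` and excluded from region averages, as are
peptides matching at loci that disagree in category (``ambiguous``).
Isoleucine and leucine are distinct residues here: the upstream database
search already fixed the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .annotation import ProteinAnnotation, TopoFeature, classify_feature
from .protxml_io import PeptideRecord, ProteinRecord
from .quantify import (
    RegionQuant,
    RunConfig,
    clamp,
    classify_change,
    dedupe_peptides,
    region_average,
    select_ratio,
    to_log2,
)

REGION_CLASSES = (
    "cytoplasmic",
    "extra_cytoplasmic",
    "transmembrane",
    "signal",
    "spanning",
    "ambiguous",
    "unannotated",
    "unmapped",
)

#: residue-level precedence for overlapping features (first wins)
_CATEGORY_PRIORITY = ("signal", "transmembrane", "cytoplasmic", "extra_cytoplasmic")


@dataclass
class MappedPeptide:
    """A peptide placed (or not) on its protein, with its quantitation."""

    peptide: PeptideRecord
    positions: list[tuple[int, int]] = field(default_factory=list)
    region_class: str = "unmapped"
    raw_ratio: Optional[float] = None
    log2_ratio: Optional[float] = None
    change_class: str = "unquantified"
    validation_flag: str = "untestable"
    color: str = "#808080"


@dataclass
class ProteinResult:
    """Everything computed for one valid protein."""

    record: ProteinRecord
    annotation: Optional[ProteinAnnotation]
    mapped_peptides: list[MappedPeptide] = field(default_factory=list)
    region_quants: list[RegionQuant] = field(default_factory=list)
    protein_log2: Optional[float] = None

    @property
    def cytoplasmic(self) -> Optional[RegionQuant]:
        return next((q for q in self.region_quants if q.region == "cytoplasmic"), None)

    @property
    def extra_cytoplasmic(self) -> Optional[RegionQuant]:
        return next(
            (q for q in self.region_quants if q.region == "extra_cytoplasmic"), None
        )


def locate_peptide(peptide_seq: str, protein_seq: str) -> list[tuple[int, int]]:
    """All exact (possibly overlapping) occurrences, 1-based inclusive."""
    if not peptide_seq or not protein_seq:
        raise ValueError("peptide and protein sequences must be non-empty")
    spans: list[tuple[int, int]] = []
    start = protein_seq.find(peptide_seq)
    while start != -1:
        spans.append((start + 1, start + len(peptide_seq)))
        start = protein_seq.find(peptide_seq, start + 1)
    return spans


def _residue_categories(
    length: int, features: Sequence[TopoFeature]
) -> list[Optional[str]]:
    """Per-residue region category (index 0 = residue 1), None = uncovered."""
    cats: list[Optional[str]] = [None] * length
    rank = {c: i for i, c in enumerate(_CATEGORY_PRIORITY)}
    for feat in features:
        category = classify_feature(feat)
        if category == "unclassified":
            continue
        for i in range(feat.start - 1, min(feat.end, length)):
            if cats[i] is None or rank[category] < rank[cats[i]]:
                cats[i] = category
    return cats


def assign_region(
    span: tuple[int, int], features: Sequence[TopoFeature], length: Optional[int] = None
) -> str:
    """Region class of one span given the protein's classified features.

    Order-independent in the feature list: residue categories are resolved
    by priority first, then the span's distinct categories are inspected.
    Uncovered residues count as a category of their own, so a peptide half
    in an annotated domain and half outside it is ``spanning``.
    """
    start, end = span
    if length is None:
        length = max((f.end for f in features), default=end)
        length = max(length, end)
    if not (1 <= start <= end <= length):
        raise ValueError(f"span {span} outside protein bounds 1..{length}")
    cats = _residue_categories(length, features)
    seen = {cats[i] if cats[i] is not None else "unannotated" for i in range(start - 1, end)}
    if len(seen) > 1:
        return "spanning"
    return seen.pop()


def map_protein(
    record: ProteinRecord,
    annotation: Optional[ProteinAnnotation],
    config: Optional[RunConfig] = None,
) -> ProteinResult:
    """Map one valid protein's peptides and compute its region averages.

    Without annotation every peptide is ``unannotated`` and no region
    average exists.  With annotation, each deduplicated peptide takes the
    region of its first occurrence unless occurrences disagree in
    category (``ambiguous``); peptides absent from the sequence are
    ``unmapped``.  Quantified ratios run through selection → log2 →
    clamping → change classification; the cytoplasmic and
    extra-cytoplasmic averages use only single-region, validation-passing
    peptides.  In elaborate mode all peptide occurrences are displayed
    but averages still use the best-per-sequence subset.
    """
    from .report import color_for_ratio  # local import: report depends on mapping

    config = config or RunConfig()
    result = ProteinResult(record=record, annotation=annotation)

    display = dedupe_peptides(record.peptides, elaborate=config.elaborate)
    averaging = (
        dedupe_peptides(record.peptides, elaborate=False)
        if config.elaborate
        else display
    )
    averaging_ids = {id(p) for p in averaging}

    for pep in display:
        mapped = MappedPeptide(peptide=pep)
        raw, flag = select_ratio(pep, config)
        mapped.raw_ratio = raw
        mapped.validation_flag = flag
        if raw is not None:
            log2 = clamp(to_log2(raw, invert=config.invert), config.rmin, config.rmax)
            mapped.log2_ratio = log2
            mapped.change_class = classify_change(log2, config.zn, config.zp)
            mapped.color = color_for_ratio(log2, config)
        if annotation is None:
            mapped.region_class = "unannotated"
        else:
            mapped.positions = locate_peptide(pep.sequence, annotation.sequence)
            if not mapped.positions:
                mapped.region_class = "unmapped"
            else:
                regions = [
                    assign_region(span, annotation.features, annotation.length)
                    for span in mapped.positions
                ]
                mapped.region_class = (
                    regions[0] if len(set(regions)) == 1 else "ambiguous"
                )
        result.mapped_peptides.append(mapped)

    contributing = [
        m for m in result.mapped_peptides if id(m.peptide) in averaging_ids
    ]
    for region in ("cytoplasmic", "extra_cytoplasmic"):
        quant = region_average(contributing, region)
        if quant is not None:
            result.region_quants.append(quant)

    if record.protein_asap is not None:
        result.protein_log2 = clamp(
            to_log2(record.protein_asap.ratio_mean, invert=config.invert),
            config.rmin,
            config.rmax,
        )
    return result
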