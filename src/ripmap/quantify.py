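"""Ratio selection, transformation and per-region averaging.

Peptide-level light:heavy (L:H) isotope ratios from ASAPRatio are the
primary quantitative signal.  They are log2-transformed (optionally
inverted to H:L), clamped to a user-set ``[rmin, rmax]`` window that also
defines the color scale, and classified as up / down / no-change against
the no-change zone ``[zn, zp]``.  Per topological region the tool computes
the arithmetic mean of the clamped log2 ratios of the peptides that fall
entirely inside that region — the per-domain fold change that drives the
substrate screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .mapping import MappedPeptide
    from .protxml_io import PeptideRecord, ProteinRecord

#: linear-ratio value at or above which XPRESS means "infinite" (all light)
XPRESS_INFINITY = 9999.0

#: markers used between to_log2 and clamp for degenerate linear ratios
NEG_INF = float("-inf")
POS_INF = float("inf")


@dataclass(frozen=True)
class RunConfig:
    """User-adjustable options of a run.

    Defaults mirror the tool's published option table: probability cutoff
    0.90, log2 window [-3, 3], no-change zone [-0.25, 0.25].
    """

    invert: bool = False
    validate: bool = False
    elaborate: bool = False
    threshold: float = 0.90
    rmin: float = -3.0
    rmax: float = 3.0
    zn: float = -0.25
    zp: float = 0.25
    validation_tolerance: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if not (self.rmin < self.zn <= 0.0 <= self.zp < self.rmax):
            raise ValueError(
                "bounds must satisfy rmin < zn <= 0 <= zp < rmax, got "
                f"rmin={self.rmin}, zn={self.zn}, zp={self.zp}, rmax={self.rmax}"
            )
        if self.validation_tolerance <= 0:
            raise ValueError("validation_tolerance must be positive")


@dataclass(frozen=True)
class RegionQuant:
    """Average fold change of one topological region of one protein."""

    region: str  # "cytoplasmic" or "extra_cytoplasmic"
    n_peptides: int
    mean_log2: float

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ValueError("RegionQuant requires at least one contributing peptide")


@dataclass
class DiscardedProtein:
    """A protein rejected by the validity filter, with the reason."""

    record: "ProteinRecord"
    reason: str


def filter_proteins(
    records: Sequence["ProteinRecord"], threshold: float = 0.90
) -> tuple[list["ProteinRecord"], list[DiscardedProtein]]:
    """Split records into valid (probability >= threshold) and discarded.

    The published rule rejects entries with a ProteinProphet probability
    *strictly below* the cutoff, so a protein sitting exactly at the
    threshold is kept.  Document order is preserved in both lists.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    valid: list["ProteinRecord"] = []
    discarded: list[DiscardedProtein] = []
    for rec in records:
        if rec.probability >= threshold:
            valid.append(rec)
        else:
            discarded.append(
                DiscardedProtein(
                    rec,
                    f"ProteinProphet probability {rec.probability:.4f} "
                    f"< threshold {threshold:.4f}",
                )
            )
    return valid, discarded


def select_ratio(
    peptide: "PeptideRecord", config: RunConfig
) -> tuple[Optional[float], str]:
    """Pick the peptide's quantitative ratio and its validation verdict.

    ASAPRatio is the reported quantitation.  With ``config.validate`` on,
    the XPRESS ratio cross-checks it: the peptide *passes* iff
    ``|log2(asap) - log2(xpress)| <= validation_tolerance``.  Returns
    ``(linear ratio or None, flag)`` with flag in ``{"pass", "fail",
    "untestable"}``; validation off always yields ``"pass"`` for
    quantified peptides.  Failing peptides stay visible per peptide but
    are excluded from region averages downstream.
    """
    asap = peptide.asap.ratio_mean if peptide.asap is not None else None
    if asap is None:
        return None, "untestable"
    if not config.validate:
        return asap, "pass"
    xpress = peptide.xpress.ratio_mean if peptide.xpress is not None else None
    if xpress is None:
        return asap, "untestable"
    if asap <= 0 or xpress <= 0 or xpress >= XPRESS_INFINITY:
        # degenerate ratios cannot be compared on the log scale
        return asap, "untestable"
    if abs(math.log2(asap) - math.log2(xpress)) <= config.validation_tolerance:
        return asap, "pass"
    return asap, "fail"


def to_log2(ratio: float, invert: bool = False) -> float:
    """log2-transform a linear L:H ratio; ``invert`` flips to H:L.

    Degenerate inputs map to infinity markers that :func:`clamp` later
    saturates: a ratio of 0 becomes -inf, and the XPRESS all-light
    convention (ratio >= 9999) becomes +inf.
    """
    if ratio < 0:
        raise ValueError(
            f"negative linear ratio {ratio}: 'not computed' sentinels must be "
            "mapped to absent before transformation"
        )
    if ratio == 0.0:
        value = NEG_INF
    elif ratio >= XPRESS_INFINITY:
        value = POS_INF
    else:
        value = math.log2(ratio)
    return -value if invert else value


def clamp(value: float, rmin: float = -3.0, rmax: float = 3.0) -> float:
    """Saturate a log2 value into [rmin, rmax]; infinities hit the bounds."""
    if rmin >= rmax:
        raise ValueError(f"rmin ({rmin}) must be below rmax ({rmax})")
    return min(max(value, rmin), rmax)


def classify_change(value: float, zn: float = -0.25, zp: float = 0.25) -> str:
    """Classify a clamped log2 ratio against the inclusive no-change zone."""
    if zn > zp:
        raise ValueError(f"zn ({zn}) must not exceed zp ({zp})")
    if value > zp:
        return "up"
    if value < zn:
        return "down"
    return "no_change"


def dedupe_peptides(
    peptides: Iterable["PeptideRecord"], elaborate: bool = False
) -> list["PeptideRecord"]:
    """Collapse repeated identifications of the same peptide sequence.

    Default behaviour keeps, per stripped sequence (charge-agnostic), the
    occurrence with the highest PeptideProphet probability; ties prefer
    more quantified spectra, then first occurrence.  ``elaborate`` keeps
    every occurrence, grouped by sequence in first-seen order.
    """
    groups: dict[str, list["PeptideRecord"]] = {}
    for pep in peptides:
        groups.setdefault(pep.sequence, []).append(pep)
    if elaborate:
        return [p for seq_group in groups.values() for p in seq_group]

    def rank(p: "PeptideRecord") -> tuple[float, float]:
        n = p.asap.n_spectra if p.asap is not None and p.asap.n_spectra else 0
        return (p.probability, n)

    best: list["PeptideRecord"] = []
    for seq_group in groups.values():
        winner = seq_group[0]
        for cand in seq_group[1:]:
            if rank(cand) > rank(winner):
                winner = cand
        best.append(winner)
    return best


def region_average(
    mapped: Iterable["MappedPeptide"], region: str
) -> Optional[RegionQuant]:
    """Arithmetic mean of clamped log2 ratios over one region's peptides.

    Only quantified, validation-passing peptides whose region class equals
    ``region`` contribute; returns None when no peptide qualifies.
    """
    if region not in ("cytoplasmic", "extra_cytoplasmic"):
        raise ValueError(f"region must be cytoplasmic or extra_cytoplasmic, got {region!r}")
    values = [
        m.log2_ratio
        for m in mapped
        if m.region_class == region
        and m.log2_ratio is not None
        and m.validation_flag != "fail"
    ]
    if not values:
        return None
    return RegionQuant(region=region, n_peptides=len(values), mean_log2=sum(values) / len(values))
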