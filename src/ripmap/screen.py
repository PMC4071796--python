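"""Run-level summaries, fold-change distributions and the substrate screen.

Loss of the intramembrane proteases SPPL2a/b leaves the membrane-bound
N-terminal fragments of their substrates uncleaved, so in a
knockout-vs-wild-type comparison a substrate's cytoplasmic tail
accumulates (log2 L:H > 1, i.e. more than 2-fold) while its shed
ectodomain need not.  Known substrates are type 2 single-pass membrane
proteins — cytoplasmic N-terminus, one transmembrane segment, large
extra-cytoplasmic C-terminal ectodomain — and the screen encodes exactly
that: single TM, type-2 topology, cytoplasmic domain mean above the
fold-change cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .mapping import ProteinResult
from .quantify import RunConfig

FC_CATEGORIES = ("all", "tm", "cytoplasmic_domains", "extra_cytoplasmic_domains")

#: histogram bin width (log2 units) for fold-change distributions
FC_BIN_WIDTH = 0.25


def _pct(numerator: int, denominator: int) -> int:
    """Whole-number percentage, 0 when the denominator is 0."""
    if denominator == 0:
        return 0
    return round(100.0 * numerator / denominator)


@dataclass(frozen=True)
class RunSummary:
    """Headline counts of a run, with derived whole-number percentages."""

    n_total: int = 0
    n_tm: int = 0
    n_signal: int = 0
    n_tm_no_signal: int = 0
    n_tm_cyto_quant: int = 0
    n_tm_extra_quant: int = 0

    def __post_init__(self) -> None:
        if self.n_tm > self.n_total:
            raise ValueError("n_tm cannot exceed n_total")
        for name in ("n_tm_no_signal", "n_tm_cyto_quant", "n_tm_extra_quant"):
            if getattr(self, name) > self.n_tm:
                raise ValueError(f"{name} cannot exceed n_tm")

    @property
    def pct_tm(self) -> int:
        """Percentage of quantified proteins with a transmembrane domain."""
        return _pct(self.n_tm, self.n_total)

    @property
    def pct_signal(self) -> int:
        return _pct(self.n_signal, self.n_total)

    @property
    def pct_tm_no_signal(self) -> int:
        """Percentage of TM proteins lacking an annotated signal peptide."""
        return _pct(self.n_tm_no_signal, self.n_tm)

    @property
    def pct_tm_cyto_quant(self) -> int:
        return _pct(self.n_tm_cyto_quant, self.n_tm)

    @property
    def pct_tm_extra_quant(self) -> int:
        return _pct(self.n_tm_extra_quant, self.n_tm)


def _is_quantified(result: ProteinResult) -> bool:
    return result.protein_log2 is not None or any(
        m.log2_ratio is not None for m in result.mapped_peptides
    )


def summarize_run(results: Iterable[ProteinResult]) -> RunSummary:
    """Count quantified proteins by topology and per-domain quantitation.

    A protein counts as quantified when it carries a protein-level ratio
    or at least one quantified peptide.  An empty input yields the
    all-zero summary.
    """
    n_total = n_tm = n_signal = n_tm_no_signal = 0
    n_tm_cyto = n_tm_extra = 0
    for res in results:
        if not _is_quantified(res):
            continue
        n_total += 1
        ann = res.annotation
        if ann is None:
            continue
        has_tm = ann.has_transmembrane()
        has_sig = ann.has_signal()
        if has_sig:
            n_signal += 1
        if has_tm:
            n_tm += 1
            if not has_sig:
                n_tm_no_signal += 1
            if res.cytoplasmic is not None:
                n_tm_cyto += 1
            if res.extra_cytoplasmic is not None:
                n_tm_extra += 1
    return RunSummary(
        n_total=n_total,
        n_tm=n_tm,
        n_signal=n_signal,
        n_tm_no_signal=n_tm_no_signal,
        n_tm_cyto_quant=n_tm_cyto,
        n_tm_extra_quant=n_tm_extra,
    )


def fc_distribution(
    results: Iterable[ProteinResult],
    category: str = "all",
    config: Optional[RunConfig] = None,
) -> tuple[list[float], np.ndarray, np.ndarray]:
    """Fold-change values of one category plus their histogram.

    Categories: ``all`` — protein-level log2 ratios of all valid proteins;
    ``tm`` — the same restricted to TM proteins; ``cytoplasmic_domains`` /
    ``extra_cytoplasmic_domains`` — per-protein domain means of TM
    proteins.  Returns ``(values, counts, bin_edges)`` with fixed
    0.25-wide bins spanning [rmin, rmax]; counts always sum to
    ``len(values)`` because values are clamped into that window.
    """
    if category not in FC_CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {FC_CATEGORIES}")
    config = config or RunConfig()
    values: list[float] = []
    for res in results:
        if category in ("all", "tm"):
            if category == "tm" and (
                res.annotation is None or not res.annotation.has_transmembrane()
            ):
                continue
            if res.protein_log2 is not None:
                values.append(res.protein_log2)
        else:
            if res.annotation is None or not res.annotation.has_transmembrane():
                continue
            quant = (
                res.cytoplasmic
                if category == "cytoplasmic_domains"
                else res.extra_cytoplasmic
            )
            if quant is not None:
                values.append(quant.mean_log2)
    n_bins = int(round((config.rmax - config.rmin) / FC_BIN_WIDTH))
    edges = config.rmin + FC_BIN_WIDTH * np.arange(n_bins + 1)
    counts, edges = np.histogram(values, bins=edges)
    return values, counts, edges


@dataclass(frozen=True)
class SubstrateCandidate:
    """A protein passing the intramembrane-protease substrate screen."""

    result: ProteinResult
    cytoplasmic_mean: float
    extra_cytoplasmic_mean: Optional[float]
    tail_length: int
    reasons: tuple[str, ...]

    @property
    def accession(self) -> str:
        return self.result.record.accession


def _single_tm_type2(ann) -> Optional[tuple[int, int]]:
    """(TM start, cytoplasmic tail length) if type-2 single-pass, else None."""
    tms = [f for f in ann.features if f.category == "TRANSMEM"]
    if len(tms) != 1:
        return None
    tm = tms[0]
    from .annotation import classify_feature

    cyto_before = [
        f
        for f in ann.features
        if f.category == "TOPO_DOM"
        and classify_feature(f) == "cytoplasmic"
        and f.start < tm.start
    ]
    extra_after = [
        f
        for f in ann.features
        if f.category == "TOPO_DOM"
        and classify_feature(f) == "extra_cytoplasmic"
        and f.start > tm.start
    ]
    if not cyto_before or not extra_after:
        return None
    tail_length = max(f.end - f.start + 1 for f in cyto_before)
    return tm.start, tail_length


def screen_sppl_candidates(
    results: Iterable[ProteinResult],
    fc_cutoff: float = 1.0,
    max_tail_length: Optional[int] = None,
) -> list[SubstrateCandidate]:
    """Select putative SPPL2a/b substrates.

    A protein qualifies iff it (a) has exactly one transmembrane segment,
    (b) shows type-2 orientation — an annotated cytoplasmic domain before
    the TM and an extra-cytoplasmic domain after it — and (c) its
    cytoplasmic domain mean log2 ratio exceeds ``fc_cutoff`` (default 1.0,
    i.e. more than 2-fold accumulation of the tail).  ``max_tail_length``
    optionally restricts to short cytoplasmic tails; it is off by default
    because tail brevity describes known substrates rather than defining
    the screen.
    """
    candidates: list[SubstrateCandidate] = []
    for res in results:
        ann = res.annotation
        if ann is None:
            continue
        topo = _single_tm_type2(ann)
        if topo is None:
            continue
        _, tail_length = topo
        if max_tail_length is not None and tail_length > max_tail_length:
            continue
        cyto = res.cytoplasmic
        if cyto is None or not (cyto.mean_log2 > fc_cutoff):
            continue
        extra = res.extra_cytoplasmic
        reasons = (
            "single transmembrane segment",
            "type-2 orientation (cytoplasmic N-terminus, extra-cytoplasmic C-terminus)",
            f"cytoplasmic mean log2 {cyto.mean_log2:.2f} > {fc_cutoff:g}",
        )
        candidates.append(
            SubstrateCandidate(
                result=res,
                cytoplasmic_mean=cyto.mean_log2,
                extra_cytoplasmic_mean=extra.mean_log2 if extra is not None else None,
                tail_length=tail_length,
                reasons=reasons,
            )
        )
    return candidates
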