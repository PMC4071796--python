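"""End-to-end run: parse → filter → annotate → map → summarize → report."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

from .annotation import (
    AnnotationLookupError,
    ProteinAnnotation,
    fetch_annotation,
    load_annotations,
)
from .mapping import ProteinResult, map_protein
from .protxml_io import ProteinRecord, RunMetadata, parse_protxml, write_table
from .quantify import DiscardedProtein, RunConfig, filter_proteins
from .report import write_bundle
from .screen import RunSummary, SubstrateCandidate, screen_sppl_candidates, summarize_run

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    """Everything a completed run produced."""

    config: RunConfig
    metadata: RunMetadata
    results: list[ProteinResult]
    discarded: list[DiscardedProtein]
    summary: RunSummary
    candidates: list[SubstrateCandidate]


def run_pipeline(
    protxml_source: Union[str, Path],
    annotations: Union[str, Path, Dict[str, ProteinAnnotation], None],
    config: Optional[RunConfig] = None,
    fetch_missing: bool = False,
    fc_cutoff: float = 1.0,
) -> RunResult:
    """Run the full analysis on one protXML file.

    ``annotations`` may be a path to a local annotation file, an already
    loaded accession → annotation mapping, or None (all proteins treated
    as unannotated unless ``fetch_missing`` pulls entries from UniProt).
    Proteins whose accession has no annotation are mapped in degraded
    mode, never dropped.
    """
    config = config or RunConfig()
    records, metadata = parse_protxml(protxml_source)
    valid, discarded = filter_proteins(records, config.threshold)

    if annotations is None:
        ann_map: Dict[str, ProteinAnnotation] = {}
    elif isinstance(annotations, (str, Path)):
        ann_map = load_annotations(annotations)
    else:
        ann_map = dict(annotations)

    results: list[ProteinResult] = []
    for record in valid:
        ann = ann_map.get(record.accession)
        if ann is None and fetch_missing and record.namespace == "uniprot":
            try:
                ann = fetch_annotation(record.accession)
                ann_map[record.accession] = ann
            except AnnotationLookupError as exc:
                logger.warning("%s", exc)
        results.append(map_protein(record, ann, config))

    summary = summarize_run(results)
    candidates = screen_sppl_candidates(results, fc_cutoff=fc_cutoff)
    return RunResult(
        config=config,
        metadata=metadata,
        results=results,
        discarded=discarded,
        summary=summary,
        candidates=candidates,
    )


def write_outputs(run: RunResult, out_dir: Union[str, Path]) -> Path:
    """Write the TSV peptide table and the HTML bundle; return the zip path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(r.mapped_peptides for r in run.results):
        write_table(run.results, out / "peptides.tsv")
    return write_bundle(
        run.results, run.summary, run.discarded, out / "report", run.config
    )
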