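"""protXML input and flat tabular output.

protXML is the protein-level report of the Trans Proteomic Pipeline:
ProteinProphet groups with posterior probabilities, member peptides with
PeptideProphet probabilities, and (when the data are isotope-labeled)
ASAPRatio / XPRESS light:heavy quantitation attached as analysis results
at both the protein and the peptide level.  Parsing is delegated to
:mod:`pyteomics.protxml`; this module normalizes its output into the
package's record types.

Conventions handled here:

* a negative ``ratio_mean`` is the format's "not computed" sentinel and
  becomes an absent :class:`QuantResult`;
* when a protein carries both a plain ASAPRatio and the recomputed
  ("adjusted") ASAPRatio_pvalue result, the adjusted values win;
* peptide sequences are stripped of modification annotations so that they
  can be located on plain database sequences.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Union

from lxml import etree
from pyteomics import protxml as _protxml

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYBXZU")

_UNIPROT_ACC_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})"
    r"(?:-\d+)?$"
)
_IPI_RE = re.compile(r"^IPI:?(IPI\d{8})(?:\.\d+)?$|^(IPI\d{8})(?:\.\d+)?$")


@dataclass(frozen=True)
class QuantResult:
    """One quantitation result (ASAPRatio or XPRESS), linear L:H scale."""

    ratio_mean: float
    ratio_stdev: Optional[float] = None
    n_spectra: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ratio_mean < 0:
            raise ValueError("ratio_mean must be >= 0; negative sentinels map to absent")


@dataclass
class PeptideRecord:
    """One identified peptide under a protein entry."""

    sequence: str
    charge: int
    probability: float
    asap: Optional[QuantResult] = None
    xpress: Optional[QuantResult] = None
    is_nondegenerate: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residues in peptide sequence: {sorted(bad)}")
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"peptide probability out of [0,1]: {self.probability}")


@dataclass
class ProteinRecord:
    """One protein entry of a protXML protein group."""

    group_index: int
    protein_name: str
    accession: str
    namespace: str  # "uniprot" | "ipi" | "unknown"
    probability: float
    percent_coverage: Optional[float] = None
    total_peptides: int = 0
    protein_asap: Optional[QuantResult] = None
    protein_xpress: Optional[QuantResult] = None
    peptides: list[PeptideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"protein probability out of [0,1]: {self.probability}")
        if self.total_peptides < 0:
            raise ValueError("total_peptides must be >= 0")


@dataclass
class RunMetadata:
    source_name: str
    n_groups: int
    n_proteins: int
    n_peptides: int


def extract_accession(protein_name: str) -> tuple[str, str]:
    """Normalize a protXML protein name to (accession, namespace).

    Handles pipe-delimited UniProt names (``sp|P12345|TEST_MOUSE``), IPI
    identifiers with or without version suffix, and bare accession-shaped
    tokens; anything else passes through with namespace ``unknown``.
    """
    if not protein_name:
        raise ValueError("protein_name must be non-empty")
    name = protein_name.strip()
    parts = name.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1], "uniprot"
    m = _IPI_RE.match(name)
    if m:
        return m.group(1) or m.group(2), "ipi"
    if _UNIPROT_ACC_RE.match(name):
        return name, "uniprot"
    return name, "unknown"


def _as_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _quant_from_attrs(attrs: dict, prefix: str = "") -> Optional[QuantResult]:
    mean = _as_float(attrs.get(prefix + "ratio_mean"))
    if mean is None or mean < 0:  # negative mean: "not computed" sentinel
        return None
    stdev = _as_float(attrs.get(prefix + "ratio_standard_dev"))
    n = attrs.get(prefix + "ratio_number_peptides")
    try:
        n = int(n) if n is not None else None
    except (TypeError, ValueError):
        n = None
    return QuantResult(
        ratio_mean=mean,
        ratio_stdev=stdev if stdev is None or stdev >= 0 else None,
        n_spectra=n,
    )


def _extract_quant(analysis_results) -> tuple[Optional[QuantResult], Optional[QuantResult]]:
    """Pull (asap, xpress) from a list of analysis_result dicts.

    The recomputed ASAPRatio_pvalue result (``adj_ratio_*`` attributes)
    takes precedence over the plain ASAPRatio when both are present.
    """
    asap = adj_asap = xpress = None
    for res in analysis_results or []:
        kind = res.get("analysis")
        if kind == "asapratio" and "ASAPRatio" in res:
            asap = _quant_from_attrs(res["ASAPRatio"])
        elif kind == "asapratio_pvalue" and "ASAPRatio_pvalue" in res:
            adj_asap = _quant_from_attrs(res["ASAPRatio_pvalue"], prefix="adj_")
        elif kind == "xpress" and "XPressRatio" in res:
            xpress = _quant_from_attrs(res["XPressRatio"])
    return (adj_asap if adj_asap is not None else asap), xpress


def strip_modifications(sequence: str) -> str:
    """Reduce a possibly modified peptide string to plain residues.

    Removes bracketed mass annotations (``M[147]``), the lowercase
    terminal-modification markers ``n``/``c``, and any non-letter
    characters, and uppercases the rest.
    """
    plain = re.sub(r"\[[^\]]*\]", "", sequence)
    plain = re.sub(r"^n", "", plain)
    plain = re.sub(r"c$", "", plain)
    plain = re.sub(r"[^A-Za-z]", "", plain)
    return plain.upper()


def _build_peptide(pep: dict) -> Optional[PeptideRecord]:
    raw_seq = pep.get("peptide_sequence", "")
    sequence = strip_modifications(raw_seq)
    if not sequence:
        logger.warning("peptide with empty sequence skipped")
        return None
    asap, xpress = _extract_quant(pep.get("analysis_result"))
    prob = pep.get("nsp_adjusted_probability")
    if prob is None:
        prob = pep.get("initial_probability", 0.0)
    nondeg = pep.get("is_nondegenerate_evidence", True)
    if isinstance(nondeg, str):
        nondeg = nondeg.upper().startswith("Y")
    try:
        return PeptideRecord(
            sequence=sequence,
            charge=int(pep.get("charge", 1) or 1),
            probability=float(prob),
            asap=asap,
            xpress=xpress,
            is_nondegenerate=bool(nondeg),
        )
    except ValueError as exc:
        logger.warning("peptide %s skipped: %s", raw_seq, exc)
        return None


def parse_protxml(
    source: Union[str, Path, IO[bytes]],
) -> tuple[list[ProteinRecord], RunMetadata]:
    """Read a protXML document into :class:`ProteinRecord` objects.

    Records preserve document order.  A protein missing its probability
    attribute is kept with probability 0 and a warning.  Raises
    :class:`lxml.etree.XMLSyntaxError` (which names the offending line)
    for malformed XML and :class:`ValueError` for documents without any
    protein group.
    """
    if isinstance(source, (str, Path)):
        name = str(source)
        handle: Union[str, IO[bytes]] = str(source)
    else:
        name = getattr(source, "name", "<stream>")
        handle = source

    records: list[ProteinRecord] = []
    n_groups = 0
    with _protxml.read(handle) as reader:
        for group in reader:
            n_groups += 1
            group_number = int(group.get("group_number", n_groups))
            for prot in group.get("protein", []):
                protein_name = prot.get("protein_name", "")
                accession, namespace = extract_accession(protein_name)
                prob = prot.get("probability")
                if prob is None:
                    logger.warning(
                        "protein %s has no probability attribute; treating as 0",
                        protein_name,
                    )
                    prob = 0.0
                asap, xpress = _extract_quant(prot.get("analysis_result"))
                peptides = [
                    rec
                    for rec in (_build_peptide(p) for p in prot.get("peptide", []))
                    if rec is not None
                ]
                cov = _as_float(prot.get("percent_coverage"))
                total = prot.get("total_number_peptides")
                records.append(
                    ProteinRecord(
                        group_index=group_number,
                        protein_name=protein_name,
                        accession=accession,
                        namespace=namespace,
                        probability=float(prob),
                        percent_coverage=cov,
                        total_peptides=int(total) if total is not None else len(peptides),
                        protein_asap=asap,
                        protein_xpress=xpress,
                        peptides=peptides,
                    )
                )
    if n_groups == 0:
        raise ValueError(f"no protein_group elements found in {name}")
    meta = RunMetadata(
        source_name=name,
        n_groups=n_groups,
        n_proteins=len(records),
        n_peptides=sum(len(r.peptides) for r in records),
    )
    return records, meta


#: fixed column order of the flat per-peptide export
TABLE_COLUMNS = (
    "accession",
    "protein_name",
    "protein_probability",
    "peptide_sequence",
    "peptide_probability",
    "charge",
    "start",
    "end",
    "region_class",
    "raw_ratio",
    "log2_ratio",
    "change_class",
)


def write_table(results, path: Union[str, Path]) -> None:
    """Write mapped peptide results as a TSV (one row per peptide).

    ``results`` is an iterable of pipeline ProteinResult objects.  Missing
    values serialize as ``NA``; the header and column order are fixed.
    """
    import pandas as pd

    rows = []
    for res in results:
        rec = res.record
        for m in res.mapped_peptides:
            start, end = (m.positions[0] if m.positions else (None, None))
            rows.append(
                {
                    "accession": rec.accession,
                    "protein_name": rec.protein_name,
                    "protein_probability": rec.probability,
                    "peptide_sequence": m.peptide.sequence,
                    "peptide_probability": m.peptide.probability,
                    "charge": m.peptide.charge,
                    "start": start,
                    "end": end,
                    "region_class": m.region_class,
                    "raw_ratio": m.raw_ratio,
                    "log2_ratio": m.log2_ratio,
                    "change_class": m.change_class,
                }
            )
    if not rows:
        raise ValueError("no mapped peptides to write")
    frame = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
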