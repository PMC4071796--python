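"""Synthetic protXML + annotation fixtures with known ground truth.

Every stage of the pipeline is testable offline against data this module
generates: membrane proteins with prescribed topology (soluble, type 1,
type 2 with adjustable tail length, multi-pass), in-silico tryptic
peptides carrying region-specific true log2 L:H effects plus Gaussian
noise, PeptideProphet-style probabilities, and a protXML document plus a
matching tabular annotation file that the package's own readers accept.

Sequences are random but trypsin-aware: lysine/arginine are placed every
7–12 residues so that each topological region of realistic size yields
several peptides in the retained 6–30 length window.  All randomness
flows from a single seed; identical seeds give identical fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import numpy as np
from lxml import etree

from .annotation import ProteinAnnotation, TopoFeature, classify_feature, save_annotations

PROTXML_NS = "http://regis-web.systemsbiology.net/protXML"

_NON_KR = "ACDEFGHILMNQSTVWY"  # canonical residues minus K, R (and P kept out
# of the post-cleavage position by construction, see _random_sequence)

TEMPLATES = ("soluble", "type1", "type2", "multi")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the study conditions.

    ``sigma`` is the peptide-level log2 noise, ``absent_ratio_fraction``
    the share of peptides written with the protXML "not computed"
    sentinel, ``subthreshold_fraction`` the share of proteins generated
    below the 0.90 probability cutoff.  Peptide probabilities are drawn
    from Beta(20, 1) (median ~0.966).
    """

    missed_cleavages: int = 0
    min_length: int = 6
    max_length: int = 30
    sigma: float = 0.2
    absent_ratio_fraction: float = 0.05
    subthreshold_fraction: float = 0.10
    prob_alpha: float = 20.0
    prob_beta: float = 1.0
    with_xpress: bool = True
    xpress_sigma: float = 0.1
    xpress_discordant_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.missed_cleavages <= 2):
            raise ValueError("missed_cleavages must be 0, 1 or 2")
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("invalid retained peptide length window")


@dataclass
class ProteinSpec:
    """Ground-truth description of one synthetic protein."""

    accession: str
    entry_name: str
    recommended_name: str
    template: str
    sequence: str
    features: list[TopoFeature]
    effects: Dict[str, float]
    sigma: float
    probability: float
    is_subthreshold: bool

    @property
    def protein_name(self) -> str:
        return f"sp|{self.accession}|{self.entry_name}"

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def molecular_weight(self) -> float:
        # average residue masses, Da (sufficient for report statistics)
        masses = {
            "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
            "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
            "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
            "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
        }
        return sum(masses[a] for a in self.sequence) + 18.02


@dataclass
class PeptideObservation:
    """One simulated quantified peptide with its ground truth."""

    sequence: str
    start: int
    end: int
    region: str
    true_log2: float
    linear_ratio: Optional[float]  # None = absent-ratio sentinel in the file
    probability: float
    charge: int
    xpress_ratio: Optional[float] = None


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    """Random sequence with K/R every 7–12 residues, never followed by P."""
    residues: list[str] = []
    next_kr = int(rng.integers(7, 13))
    while len(residues) < length:
        if len(residues) + 1 == next_kr and len(residues) + 1 < length:
            residues.append("K" if rng.random() < 0.5 else "R")
            next_kr += int(rng.integers(7, 13))
        else:
            residues.append(_NON_KR[int(rng.integers(len(_NON_KR)))])
    return "".join(residues[:length])


def _template_features(
    template: str,
    length: int,
    tail_length: int,
    tm_length: int,
    signal_length: int,
    n_tm: int,
) -> list[TopoFeature]:
    if template == "soluble":
        return []
    if template == "type2":
        if tail_length + tm_length >= length:
            raise ValueError("type2 template: tail + TM exceed protein length")
        return [
            TopoFeature("TOPO_DOM", 1, tail_length, "Cytoplasmic"),
            TopoFeature("TRANSMEM", tail_length + 1, tail_length + tm_length),
            TopoFeature("TOPO_DOM", tail_length + tm_length + 1, length, "Extracellular"),
        ]
    if template == "type1":
        if signal_length + tm_length + tail_length >= length:
            raise ValueError("type1 template: features exceed protein length")
        tm_start = length - tail_length - tm_length + 1
        return [
            TopoFeature("SIGNAL", 1, signal_length),
            TopoFeature("TOPO_DOM", signal_length + 1, tm_start - 1, "Extracellular"),
            TopoFeature("TRANSMEM", tm_start, tm_start + tm_length - 1),
            TopoFeature("TOPO_DOM", tm_start + tm_length, length, "Cytoplasmic"),
        ]
    if template == "multi":
        needed = n_tm * tm_length + (n_tm + 1) * 20
        if needed > length:
            raise ValueError("multi template: features exceed protein length")
        loop = (length - n_tm * tm_length) // (n_tm + 1)
        features: list[TopoFeature] = []
        pos = 1
        side = "Cytoplasmic"
        for i in range(n_tm):
            features.append(TopoFeature("TOPO_DOM", pos, pos + loop - 1, side))
            pos += loop
            features.append(TopoFeature("TRANSMEM", pos, pos + tm_length - 1))
            pos += tm_length
            side = "Extracellular" if side == "Cytoplasmic" else "Cytoplasmic"
        features.append(TopoFeature("TOPO_DOM", pos, length, side))
        return features
    raise ValueError(f"unknown template {template!r}; expected one of {TEMPLATES}")


def make_protein_spec(
    template: str,
    *,
    length: int = 296,
    tail_length: int = 29,
    tm_length: int = 23,
    signal_length: int = 22,
    n_tm: int = 4,
    effects: Optional[Dict[str, float]] = None,
    sigma: float = 0.2,
    probability: Optional[float] = None,
    is_subthreshold: bool = False,
    accession: str = "P00001",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ProteinSpec:
    """Build one ground-truth protein from a topology template.

    ``effects`` maps region categories (``cytoplasmic``,
    ``extra_cytoplasmic``, ``transmembrane``, ``signal``, ``default``) to
    true mean log2 L:H values; unlisted regions fall back to ``default``
    (0).  Deterministic for a given seed or generator state.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    features = _template_features(
        template, length, tail_length, tm_length, signal_length, n_tm
    )
    if probability is None:
        if is_subthreshold:
            probability = float(rng.uniform(0.30, 0.89))
        else:
            probability = float(1.0 - 0.10 * rng.beta(1.0, 3.0))
    idx = accession[1:] if accession[1:].isdigit() else accession
    return ProteinSpec(
        accession=accession,
        entry_name=f"SYN{idx}_MOUSE"[:16],
        recommended_name=f"Synthetic {template} protein {accession}",
        template=template,
        sequence=_random_sequence(length, rng),
        features=features,
        effects=dict(effects or {}),
        sigma=sigma,
        probability=float(probability),
        is_subthreshold=is_subthreshold,
    )


def tryptic_fragments(
    sequence: str, missed_cleavages: int = 0
) -> list[tuple[int, int]]:
    """1-based inclusive spans of tryptic fragments (cleave after K/R,
    except before P), with up to ``missed_cleavages`` internal sites."""
    cuts = [0]
    for i, residue in enumerate(sequence[:-1]):
        if residue in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    spans: list[tuple[int, int]] = []
    for mc in range(missed_cleavages + 1):
        for j in range(len(cuts) - 1 - mc):
            spans.append((cuts[j] + 1, cuts[j + 1 + mc]))
    return sorted(set(spans))


def _true_region(span: tuple[int, int], features: Sequence[TopoFeature]) -> str:
    """Ground-truth region: containment in one classified feature,
    ``spanning`` on partial overlap, ``unannotated`` otherwise.  Synthetic
    features never overlap, so plain containment is exact."""
    start, end = span
    overlap = False
    for feat in features:
        if feat.start <= start and end <= feat.end:
            cat = classify_feature(feat)
            return cat if cat != "unclassified" else "unannotated"
        if start <= feat.end and feat.start <= end:
            overlap = True
    return "spanning" if overlap else "unannotated"


def digest_and_quantify(
    spec: ProteinSpec,
    config: Optional[SyntheticConfig] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[PeptideObservation]:
    """In-silico digest one protein and simulate its quantified peptides.

    Each retained peptide (length window per config) gets a true log2
    ratio equal to its region's effect plus N(0, sigma) noise; the linear
    L:H written to the file is 2**log2.  A configurable fraction carries
    the absent-ratio sentinel instead, and XPRESS companion ratios are
    concordant within ``xpress_sigma`` except for an optional discordant
    fraction (offset by 3 log2 units, for validation tests).
    """
    config = config or SyntheticConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    observations: list[PeptideObservation] = []
    for start, end in tryptic_fragments(spec.sequence, config.missed_cleavages):
        length = end - start + 1
        if not (config.min_length <= length <= config.max_length):
            continue
        region = _true_region((start, end), spec.features)
        effect = spec.effects.get(region, spec.effects.get("default", 0.0))
        noise = float(rng.normal(0.0, config.sigma)) if config.sigma > 0 else 0.0
        true_log2 = effect + noise
        absent = bool(rng.random() < config.absent_ratio_fraction)
        linear = None if absent else float(2.0 ** true_log2)
        xpress = None
        if config.with_xpress and linear is not None:
            offset = float(rng.normal(0.0, config.xpress_sigma))
            if rng.random() < config.xpress_discordant_fraction:
                offset += 3.0
            xpress = float(linear * 2.0 ** offset)
        observations.append(
            PeptideObservation(
                sequence=spec.sequence[start - 1 : end],
                start=start,
                end=end,
                region=region,
                true_log2=true_log2,
                linear_ratio=linear,
                probability=float(rng.beta(config.prob_alpha, config.prob_beta)),
                charge=int(rng.integers(2, 4)),
                xpress_ratio=xpress,
            )
        )
    return observations


# ---------------------------------------------------------------------------
# protXML serialization

def _quant_element(
    parent, analysis: str, tag: str, ratio: Optional[float], stdev: float, n: int
) -> None:
    res = etree.SubElement(parent, "analysis_result", analysis=analysis)
    mean = -1.0 if ratio is None else ratio
    etree.SubElement(
        res,
        tag,
        ratio_mean=f"{mean:.12g}",
        ratio_standard_dev=f"{stdev:.4g}",
        ratio_number_peptides=str(n),
    )


def write_protxml(
    specs: Sequence[ProteinSpec],
    observations: Dict[str, list[PeptideObservation]],
    path: Union[str, Path],
) -> None:
    """Serialize specs + observations as a protXML document."""
    root = etree.Element("protein_summary", nsmap={None: PROTXML_NS})
    etree.SubElement(
        root, "protein_summary_header", reference_database="synthetic.fasta"
    )
    for i, spec in enumerate(specs, start=1):
        obs = observations.get(spec.accession, [])
        group = etree.SubElement(
            root,
            "protein_group",
            group_number=str(i),
            probability=f"{spec.probability:.4f}",
        )
        prot = etree.SubElement(
            group,
            "protein",
            protein_name=spec.protein_name,
            probability=f"{spec.probability:.4f}",
            n_indistinguishable_proteins="1",
            group_sibling_id="a",
            total_number_peptides=str(len(obs)),
        )
        covered = set()
        for o in obs:
            covered.update(range(o.start, o.end + 1))
        prot.set("percent_coverage", f"{100.0 * len(covered) / spec.length:.1f}")
        quantified = [o.linear_ratio for o in obs if o.linear_ratio is not None]
        if quantified:
            mean = sum(quantified) / len(quantified)
            stdev = (
                math.sqrt(sum((q - mean) ** 2 for q in quantified) / len(quantified))
                if len(quantified) > 1
                else 0.0
            )
            _quant_element(prot, "asapratio", "ASAPRatio", mean, stdev, len(quantified))
        for o in obs:
            pep = etree.SubElement(
                prot,
                "peptide",
                peptide_sequence=o.sequence,
                charge=str(o.charge),
                nsp_adjusted_probability=f"{o.probability:.4f}",
                is_nondegenerate_evidence="Y",
            )
            _quant_element(
                pep, "asapratio", "ASAPRatio", o.linear_ratio, 0.05, 1
            )
            if o.xpress_ratio is not None:
                _quant_element(pep, "xpress", "XPressRatio", o.xpress_ratio, 0.05, 1)
    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def annotation_from_spec(spec: ProteinSpec) -> ProteinAnnotation:
    return ProteinAnnotation(
        accession=spec.accession,
        recommended_name=spec.recommended_name,
        sequence=spec.sequence,
        molecular_weight=spec.molecular_weight,
        features=list(spec.features),
    )


@dataclass
class FixturePaths:
    protxml: Path
    annotations: Path
    protein_truth: Path
    peptide_truth: Path


def write_fixture(
    specs: Sequence[ProteinSpec],
    observations: Dict[str, list[PeptideObservation]],
    out_dir: Union[str, Path],
) -> FixturePaths:
    """Write protXML, annotation table and ground-truth tables to a directory.

    The protXML is parseable by :func:`ripmap.protxml_io.parse_protxml`
    and the annotation file loadable by
    :func:`ripmap.annotation.load_annotations`.  Annotation entries are
    written only for above-threshold proteins' accessions and all others
    alike — every spec gets one.
    """
    if not specs:
        raise ValueError("write_fixture needs at least one protein spec")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = FixturePaths(
        protxml=out / "synthetic.prot.xml",
        annotations=out / "annotations.tsv",
        protein_truth=out / "truth_proteins.tsv",
        peptide_truth=out / "truth_peptides.tsv",
    )
    write_protxml(specs, observations, paths.protxml)
    save_annotations(
        {spec.accession: annotation_from_spec(spec) for spec in specs},
        paths.annotations,
    )
    with open(paths.protein_truth, "w", encoding="utf-8") as handle:
        handle.write(
            "accession\ttemplate\tprobability\tis_subthreshold\tsigma"
            "\teffect_cytoplasmic\teffect_extra_cytoplasmic\teffect_default\n"
        )
        for spec in specs:
            handle.write(
                f"{spec.accession}\t{spec.template}\t{spec.probability:.4f}"
                f"\t{int(spec.is_subthreshold)}\t{spec.sigma:g}"
                f"\t{spec.effects.get('cytoplasmic', spec.effects.get('default', 0.0)):g}"
                f"\t{spec.effects.get('extra_cytoplasmic', spec.effects.get('default', 0.0)):g}"
                f"\t{spec.effects.get('default', 0.0):g}\n"
            )
    with open(paths.peptide_truth, "w", encoding="utf-8") as handle:
        handle.write(
            "accession\tsequence\tstart\tend\tregion\ttrue_log2\tlinear_ratio\n"
        )
        for spec in specs:
            for o in observations.get(spec.accession, []):
                linear = "NA" if o.linear_ratio is None else f"{o.linear_ratio:.6g}"
                handle.write(
                    f"{spec.accession}\t{o.sequence}\t{o.start}\t{o.end}"
                    f"\t{o.region}\t{o.true_log2:.6g}\t{linear}\n"
                )
    return paths


# ---------------------------------------------------------------------------
# cohort builders (the study conditions)

def make_recovery_cohort(
    n_proteins: int = 40,
    *,
    cytoplasmic_effect: float = 1.5,
    extra_cytoplasmic_effect: float = -0.5,
    sigma: float = 0.2,
    tail_length: int = 120,
    length: int = 600,
    seed: int = 0,
    config: Optional[SyntheticConfig] = None,
) -> tuple[list[ProteinSpec], Dict[str, list[PeptideObservation]]]:
    """Type-2 proteins with fixed opposing region effects, for parameter
    recovery: true cytoplasmic +1.5 and extra-cytoplasmic -0.5 log2 by
    default, peptide noise sigma 0.2.  The 120-residue cytoplasmic domain
    and 600-residue length give at least five retained tryptic peptides
    per region under the 7–12 K/R spacing."""
    rng = np.random.default_rng(seed)
    cfg = config or SyntheticConfig(sigma=sigma, absent_ratio_fraction=0.0)
    cfg = replace(cfg, sigma=sigma)
    effects = {
        "cytoplasmic": cytoplasmic_effect,
        "extra_cytoplasmic": extra_cytoplasmic_effect,
    }
    specs: list[ProteinSpec] = []
    observations: Dict[str, list[PeptideObservation]] = {}
    for i in range(n_proteins):
        spec = make_protein_spec(
            "type2",
            length=length,
            tail_length=tail_length,
            effects=effects,
            sigma=sigma,
            accession=f"P{10000 + i:05d}",
            probability=float(1.0 - 0.05 * rng.beta(1.0, 3.0)),
            rng=rng,
        )
        specs.append(spec)
        observations[spec.accession] = digest_and_quantify(spec, cfg, rng=rng)
    return specs, observations


def make_cohort(
    n_proteins: int = 625,
    *,
    tm_fraction: float = 0.51,
    signal_fraction_given_tm: float = 0.27,
    subthreshold_fraction: float = 0.10,
    protein_effect_sd: float = 0.5,
    sigma: float = 0.2,
    seed: int = 0,
    config: Optional[SyntheticConfig] = None,
) -> tuple[list[ProteinSpec], Dict[str, list[PeptideObservation]]]:
    """A mixed membrane-enrichment-style cohort.

    Defaults emulate the published exemplar run: 625 proteins (the size
    of the tool's demonstration dataset), about half membrane-spanning,
    roughly a quarter of those with a signal peptide, and one protein in
    ten below the 0.90 probability cutoff.  Each protein draws a single
    true effect from N(0, ``protein_effect_sd``) applied to all its
    regions, so protein-level fold changes follow that null-centred
    distribution.
    """
    rng = np.random.default_rng(seed)
    cfg = config or SyntheticConfig(sigma=sigma)
    specs: list[ProteinSpec] = []
    observations: Dict[str, list[PeptideObservation]] = {}
    for i in range(n_proteins):
        is_tm = rng.random() < tm_fraction
        if is_tm:
            if rng.random() < signal_fraction_given_tm:
                template = "type1"
            else:
                template = "type2" if rng.random() < 0.6 else "multi"
        else:
            template = "soluble"
        effect = float(rng.normal(0.0, protein_effect_sd))
        lengths = {"soluble": 320, "type1": 420, "type2": 360, "multi": 520}
        spec = make_protein_spec(
            template,
            length=lengths[template],
            tail_length=60,
            effects={"default": effect},
            sigma=sigma,
            is_subthreshold=bool(rng.random() < subthreshold_fraction),
            accession=f"P{20000 + i:05d}",
            rng=rng,
        )
        specs.append(spec)
        observations[spec.accession] = digest_and_quantify(spec, cfg, rng=rng)
    return specs, observations
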