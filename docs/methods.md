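# Methods

## Problem and model

`ripmap` quantifies differential abundance of membrane-protein *regions*
rather than whole proteins.  The measurement model is the standard
stable-isotope one: each identified peptide carries a linear
light:heavy (L:H) abundance ratio from ASAPRatio (XPRESS optionally as a
cross-check), and the log2 of that ratio estimates the fold change of the
protein segment the peptide came from.  For a membrane protein whose
topology is known, peptides therefore partition into topological
compartments, and the arithmetic mean of their clamped log2 ratios is the
compartment's fold change:

    Fc(region) = (1/n) * sum_i clamp(log2(r_i), rmin, rmax)

over the n deduplicated, quantified, validation-passing peptides whose
occurrences lie entirely inside that region.  Averaging in log space is
deliberate: it is symmetric for up- and down-regulation, whereas a mean
of linear ratios is biased upward.

The screen built on top encodes the biology of SPPL2a/b-type regulated
intramembrane proteolysis.  In protease-deficient cells, the
membrane-bound N-terminal fragment of a substrate is no longer cleared,
so its cytoplasmic tail accumulates relative to wild type, while the
previously shed ectodomain does not.  A candidate must therefore have
(a) exactly one transmembrane segment, (b) type-2 orientation — an
annotated cytoplasmic domain starting before the TM segment and an
extra-cytoplasmic domain after it — and (c) cytoplasmic Fc strictly
above the cutoff (default 1.0 log2 units, i.e. >2-fold).  Tail brevity
is a *description* of known substrates, not part of the selection rule;
an optional `max_tail_length` exists but is off by default.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.90 | ProteinProphet posterior below which a protein is discarded (strictly `<`; a protein exactly at the cutoff is kept) |
| `rmin`, `rmax` | −3.0, 3.0 | log2 saturation window; also the endpoints of the red–green color scale |
| `zn`, `zp` | −0.25, 0.25 | inclusive no-change zone on the log2 scale |
| `invert` | off | report heavy:light instead of light:heavy |
| `validate` | off | require \|log2(ASAP) − log2(XPRESS)\| ≤ `validation_tolerance` |
| `validation_tolerance` | 1.0 | log2 discrepancy allowed between the two quantitation tools |
| `elaborate` | off | display all occurrences of a repeated peptide instead of the best one |
| `fc_cutoff` | 1.0 | cytoplasmic Fc bound of the substrate screen |

Constraint enforced at construction: `rmin < zn ≤ 0 ≤ zp < rmax`.

## Numerical and procedural choices

* **Boundary conventions.** The protein filter keeps probability ==
  threshold (the rejection rule is strictly-below); the no-change zone is
  inclusive at both ends.  A linear ratio of 0 maps to −∞ and the XPRESS
  all-light convention (≥ 9999) to +∞; both saturate at the clamp bounds.
* **Negative ratio means** in protXML are the format's "not computed"
  sentinel and are treated as absent quantitation, never as values.
* **Adjusted ASAPRatio.** When a protein carries both the plain ASAPRatio
  and the recomputed (`adj_ratio_*`) result, the adjusted one is used.
* **Deduplication** keys on the modification-stripped peptide sequence,
  charge-agnostic; the highest PeptideProphet probability wins, ties go
  to more quantified spectra, then first occurrence.  In `elaborate`
  mode all occurrences are displayed, but region averages still use the
  best-per-sequence subset so that a repeated peptide cannot dominate a
  domain mean.
* **Region assignment** resolves residues covered by overlapping
  features with priority signal > transmembrane > cytoplasmic >
  extra-cytoplasmic, then classifies a peptide span by the set of
  distinct categories it touches: one category → that class; several →
  `spanning`; none → `unannotated`.  Uncovered residues count as their
  own category, so a peptide half inside an annotated domain is
  `spanning`.  Spanning, ambiguous (multi-locus with disagreeing
  regions), signal and transmembrane peptides never enter the
  cytoplasmic/extra-cytoplasmic averages — signal peptides are cleaved
  from the mature protein, and a boundary-crossing peptide's abundance
  is not attributable to a single compartment.
* **Mapping frame.** The precursor sequence including the signal peptide
  is used, 1-based inclusive, with no mature-chain renumbering;
  isoleucine and leucine are *not* treated as interchangeable, since the
  upstream database search already committed to a sequence.
* **Unannotated vs unmapped.** A protein without annotation yields
  peptides classed `unannotated` (no positions available); `unmapped` is
  reserved for peptides absent from an annotated sequence.
* **Color scale.** Values in [zn, zp] are gray `#808080`; above zp the
  green channel rises linearly from 64 at the zone edge to 255 at rmax,
  below zn the red channel mirrors this toward rmin.  The floor of 64
  keeps barely-significant changes visible; direction (down = red) is a
  documented default, and the negated scale is the exact channel-swapped
  mirror.
* **Determinism.** Zip members are written in sorted order with fixed
  timestamps, so identical inputs give byte-identical archives.  The
  report bundle keeps the original published report's member inventory,
  including the browser-note file under its historical (misspelled)
  name `suppoted_browsers_and_os.txt`; a switch emits the corrected
  spelling.

## Synthetic data: what it emulates and what it does not

The generator produces matched protXML + annotation fixtures with known
ground truth.  Topology templates: soluble, type 1 (signal peptide,
ectodomain, TM, cytoplasmic C-terminus), type 2 (cytoplasmic tail of
configurable length, single TM, large ectodomain — the invariant-chain
layout with a 29-residue tail is the template's namesake case), and
multi-pass with alternating loops.  Sequences are uniform-random over
the canonical residues except that K/R are placed every 7–12 residues
(never before P), so realistic region sizes yield several tryptic
peptides in the retained 6–30 length window.  Digestion cleaves after
K/R except before proline, 0 missed cleavages by default (configurable
to 2).

Each peptide's true log2 ratio is its region's effect plus N(0, σ)
noise (σ = 0.2 by default); PeptideProphet probabilities come from
Beta(20, 1); 5% of peptides carry the absent-ratio sentinel; 10% of
proteins are generated below the probability cutoff.  The standard
cohorts are: a *recovery cohort* of type-2 proteins with true
cytoplasmic +1.5 and extra-cytoplasmic −0.5 log2 effects (120-residue
tail so both domains hold ≥ 5 peptides), and a *mixed cohort* sized to
the 625-protein demonstration dataset, roughly half membrane-spanning
with about a quarter of those carrying a signal peptide, each protein
drawing one overall effect from N(0, 0.5).

What passing on these fixtures does **not** show: real spectra have
correlated, heteroscedastic ratio errors (chromatographic interference,
isotope-envelope overlap), shared peptides between homologous proteins,
missed and semi-tryptic cleavages, modified residues, and topology
annotations that are themselves wrong or incomplete.  The synthetic runs
validate the bookkeeping and the estimator, not the upstream
quantitation.

## Problem sizes

The test suite runs cohorts of 25–625 proteins; the acceptance script
uses 1,000 proteins for the filter check, 10,000 random pairs for the
peptide-location oracle, 30 proteins for effect recovery, 625 for the
bundle inventory and 100 for the determinism check — sizes chosen so the
whole script completes in seconds while keeping every per-protein count
at the scale the method is used at.

## Known limitations

* IPI identifiers load from a local annotation table only; there is no
  live IPI service, and no IPI→UniProt mapping is bundled.
* The online UniProt fetcher is a convenience outside the hermetic test
  suite; pipelines intended to be reproducible should cache annotations
  to the tabular format first.
* Proteins quantified only by XPRESS (no ASAPRatio anywhere) contribute
  no region averages, since ASAPRatio is the reported quantitation.
* Indistinguishable peptides listed under several proteins of a group
  are attached to each listing; no arbitration is attempted.
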