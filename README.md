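# ripmap

**Peptide-level isotope ratios mapped onto membrane-protein topology, with a
screen for intramembrane-protease substrate candidates.**

Quantitative membrane proteomics usually reports one fold change per
protein.  That average hides exactly the signal that matters for regulated
intramembrane proteolysis (RIP): when an intramembrane protease such as
SPPL2a/b is missing, the *cytoplasmic tail* of its substrates accumulates
while the shed ectodomain may simultaneously decrease.  A protein-level
ratio averages the two effects away.

`ripmap` works at the peptide level instead.  It reads ProteinProphet
protXML from the Trans Proteomic Pipeline (TPP) — protein groups with
posterior probabilities, peptides with PeptideProphet probabilities, and
ASAPRatio/XPRESS stable-isotope light:heavy (L:H) quantitation — places
each peptide on its protein's annotated topology (signal peptide,
transmembrane segments, cytoplasmic and extra-cytoplasmic domains, UniProt
convention, 1-based inclusive coordinates), and computes a **per-domain
average fold change**

> Fc(region) = mean over region peptides of clamp(log2(L:H), rmin, rmax)

from deduplicated, quantified peptides lying entirely inside one region.
It then screens for RIP substrate candidates: proteins with a single
transmembrane segment, type-2 orientation (cytoplasmic N-terminus,
extra-cytoplasmic C-terminal ectodomain) and a cytoplasmic domain mean
log2 above a cutoff (default 1.0, i.e. more than 2-fold tail
accumulation).  The result is a shareable static HTML bundle plus flat
TSV tables.

Defaults follow the published option set of this analysis style:
ProteinProphet cutoff 0.90 (strictly-below rejected), log2 window
[−3, 3], no-change zone [−0.25, 0.25], highest-probability occurrence
kept for repeatedly identified peptides.

## Worked example

```python
from ripmap import synthetic
from ripmap.pipeline import run_pipeline

specs, obs = synthetic.make_cohort(n_proteins=50, seed=42)
paths = synthetic.write_fixture(specs, obs, "scratch/demo")
run = run_pipeline(paths.protxml, paths.annotations)
print(len(run.results), len(run.discarded), run.summary.pct_tm)
```

Running `python examples/01_parse_and_filter.py` prints:

```
parsed 50 proteins (2008 peptides) from 50 groups
45 proteins at probability >= 0.90, 5 discarded
  discarded: P20002 - ProteinProphet probability 0.3813 < threshold 0.9000
```

i.e. 45 of 50 synthetic proteins pass the 0.90 posterior cutoff, and each
discarded entry carries the reason later written to `run_stats.out`.
`examples/02_topology_mapping.py` maps a type-2 protein with a 29-residue
cytoplasmic tail and ends with

```
cytoplasmic mean: RegionQuant(region='cytoplasmic', n_peptides=3, mean_log2=1.1999999999999997)
extra-cytoplasmic mean: RegionQuant(region='extra_cytoplasmic', n_peptides=25, mean_log2=-0.5999999999999998)
```

— opposing domain fold changes (tail up 2.3-fold, ectodomain down
1.5-fold) of the kind the substrate screen looks for; with the tail mean
above 1.0 the protein is flagged as a candidate
(`examples/03_domain_averages_and_screen.py`).

The other examples cover the full cohort screen and the HTML bundle
(`examples/04_report_bundle.py`), whose zip holds `index.html` (sortable,
filterable protein table), per-protein peptide maps under `index_files/`,
SVG graphics under `images/` and `small_images/`, `run_stats.out`,
`average_molecular_weight.txt` and a browser-support note.

A command-line wrapper exposes the same pipeline:

```
ripmap input.prot.xml --annotations annotations.tsv --out results/
```

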