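"""Per-domain fold changes and the intramembrane-protease substrate screen.

Runs the whole pipeline on a mixed synthetic cohort and lists the
proteins whose cytoplasmic tail accumulates more than 2-fold (log2 > 1)
on a type-2 single-TM backbone — the signature expected of SPPL2a/b
substrates when the protease is absent.
"""

import tempfile
from pathlib import Path

from ripmap import synthetic
from ripmap.pipeline import run_pipeline
from ripmap.screen import fc_distribution

# a cohort in which three proteins carry a strong cytoplasmic-tail effect
specs, observations = synthetic.make_cohort(n_proteins=80, seed=5)
cfg = synthetic.SyntheticConfig(sigma=0.1, absent_ratio_fraction=0.0)
for i in range(3):
    spec = synthetic.make_protein_spec(
        "type2", length=360, tail_length=40,
        effects={"cytoplasmic": 1.8, "extra_cytoplasmic": -0.4},
        sigma=0.1, probability=0.99, accession=f"P9000{i}", seed=100 + i,
    )
    specs.append(spec)
    observations[spec.accession] = synthetic.digest_and_quantify(spec, cfg, seed=100 + i)

paths = synthetic.write_fixture(specs, observations, Path(tempfile.mkdtemp()))
run = run_pipeline(paths.protxml, paths.annotations, fc_cutoff=1.0)

s = run.summary
print(f"{s.n_total} quantified proteins; {s.n_tm} with TM domain ({s.pct_tm}%)")
values, counts, edges = fc_distribution(run.results, "all")
print(f"protein-level log2 values: n={len(values)}, "
      f"mean={sum(values) / len(values):+.3f} (null-centred cohort)")

print(f"{len(run.candidates)} substrate candidate(s) at cytoplasmic log2 > 1:")
for c in run.candidates:
    extra = f"{c.extra_cytoplasmic_mean:+.2f}" if c.extra_cytoplasmic_mean is not None else "NA"
    print(f"  {c.accession}: tail {c.tail_length} aa, "
          f"cytoplasmic {c.cytoplasmic_mean:+.2f}, ectodomain {extra}")
    for reason in c.reasons:
        print("    -", reason)

# The three planted tail-accumulating proteins are recovered.  A background
# type-2 protein can also pass when its overall fold change (drawn from the
# null N(0, 0.5)) happens to push its cytoplasmic mean above 1 — the screen
# keys on topology and the tail's fold change, not on provenance.
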