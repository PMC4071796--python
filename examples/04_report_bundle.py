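"""Render the shareable HTML report bundle.

Produces the static index, per-protein peptide maps and the zip archive
with the documented member inventory.
"""

import tempfile
import zipfile
from pathlib import Path

from ripmap import synthetic
from ripmap.pipeline import run_pipeline, write_outputs

specs, observations = synthetic.make_cohort(n_proteins=40, seed=9)
workdir = Path(tempfile.mkdtemp())
paths = synthetic.write_fixture(specs, observations, workdir)
run = run_pipeline(paths.protxml, paths.annotations)

zip_path = write_outputs(run, workdir / "out")
print("bundle:", zip_path)
with zipfile.ZipFile(zip_path) as zf:
    top = sorted({n.split("/")[0] + ("/" if "/" in n else "") for n in zf.namelist()})
    for name in top:
        print("  ", name)
print((workdir / "out" / "report" / "average_molecular_weight.txt").read_text().strip())

# index.html is a sortable, filterable protein table; each protein page
# draws the sequence bar with feature tracks and peptide boxes colored
# red (down) to green (up) around a gray no-change zone.
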