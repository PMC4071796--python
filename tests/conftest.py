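"""Shared fixtures: all test data is generated, nothing is downloaded."""

from __future__ import annotations

import io

import pytest

from ripmap import synthetic
from ripmap.pipeline import run_pipeline


MINIMAL_PROTXML = """<?xml version="1.0" encoding="UTF-8"?>
<protein_summary xmlns="http://regis-web.systemsbiology.net/protXML">
<protein_summary_header reference_database="test.fasta"/>
<protein_group group_number="1" probability="0.99">
<protein protein_name="sp|P12345|TEST_MOUSE" probability="0.95"
         percent_coverage="30.1" total_number_peptides="2"
         n_indistinguishable_proteins="1" group_sibling_id="a">
<analysis_result analysis="asapratio">
  <ASAPRatio ratio_mean="1.5" ratio_standard_dev="0.1" ratio_number_peptides="2"/>
</analysis_result>
<analysis_result analysis="asapratio_pvalue">
  <ASAPRatio_pvalue adj_ratio_mean="1.4" adj_ratio_standard_dev="0.12"/>
</analysis_result>
<peptide peptide_sequence="MKTAYR" charge="2" nsp_adjusted_probability="0.95"
         is_nondegenerate_evidence="Y">
<analysis_result analysis="asapratio">
  <ASAPRatio ratio_mean="2.0" ratio_standard_dev="0.05" ratio_number_peptides="1"/>
</analysis_result>
<analysis_result analysis="xpress">
  <XPressRatio ratio_mean="2.2" ratio_standard_dev="0.05" ratio_number_peptides="1"/>
</analysis_result>
</peptide>
<peptide peptide_sequence="LLGNDAEK" charge="2" nsp_adjusted_probability="0.80"
         is_nondegenerate_evidence="Y">
<analysis_result analysis="asapratio">
  <ASAPRatio ratio_mean="-1" ratio_standard_dev="0" ratio_number_peptides="0"/>
</analysis_result>
</peptide>
</protein>
</protein_group>
</protein_summary>
"""


@pytest.fixture
def minimal_protxml():
    """One group, one protein (p=0.95), two peptides; second peptide carries
    the negative 'not computed' ASAPRatio sentinel."""
    return io.BytesIO(MINIMAL_PROTXML.encode())


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 60-protein mixed cohort written to disk: (specs, observations, paths)."""
    specs, obs = synthetic.make_cohort(n_proteins=60, seed=11)
    paths = synthetic.write_fixture(specs, obs, tmp_path_factory.mktemp("cohort"))
    return specs, obs, paths


@pytest.fixture(scope="session")
def small_run(small_cohort):
    """Pipeline output on the 60-protein cohort with default settings."""
    _, _, paths = small_cohort
    return run_pipeline(paths.protxml, paths.annotations)


def make_cd74_like(cyto_effect=1.2, extra_effect=-0.6, seed=7):
    """A type-2 protein shaped like the invariant chain: 29-residue
    cytoplasmic tail, single TM, large ectodomain; noise-free effects."""
    spec = synthetic.make_protein_spec(
        "type2",
        length=296,
        tail_length=29,
        tm_length=23,
        effects={"cytoplasmic": cyto_effect, "extra_cytoplasmic": extra_effect},
        sigma=0.0,
        probability=0.99,
        accession="P04441",
        seed=seed,
    )
    cfg = synthetic.SyntheticConfig(sigma=0.0, absent_ratio_fraction=0.0)
    obs = synthetic.digest_and_quantify(spec, cfg, seed=seed)
    return spec, obs
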