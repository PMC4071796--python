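"""Map peptides onto a membrane protein's annotated topology.

Builds one type-2 single-pass protein (29-residue cytoplasmic tail,
23-residue transmembrane helix, large ectodomain), digests it in silico
and shows where each quantified peptide lands.
"""

from ripmap import synthetic
from ripmap.mapping import map_protein
from ripmap.protxml_io import PeptideRecord, ProteinRecord, QuantResult
from ripmap.quantify import RunConfig

spec = synthetic.make_protein_spec(
    "type2", length=296, tail_length=29, tm_length=23,
    effects={"cytoplasmic": 1.2, "extra_cytoplasmic": -0.6},
    sigma=0.0, probability=0.99, accession="P04441", seed=7,
)
print("features:", [(f.category, f.start, f.end, f.subtype) for f in spec.features])

cfg = synthetic.SyntheticConfig(sigma=0.0, absent_ratio_fraction=0.0)
observations = synthetic.digest_and_quantify(spec, cfg, seed=7)

record = ProteinRecord(
    group_index=1, protein_name=spec.protein_name, accession=spec.accession,
    namespace="uniprot", probability=spec.probability,
    peptides=[
        PeptideRecord(sequence=o.sequence, charge=o.charge, probability=o.probability,
                      asap=QuantResult(o.linear_ratio))
        for o in observations if o.linear_ratio is not None
    ],
)
result = map_protein(record, synthetic.annotation_from_spec(spec), RunConfig())

for m in result.mapped_peptides:
    pos = f"{m.positions[0][0]:>3}..{m.positions[0][1]:<3}" if m.positions else "  unplaced"
    log2 = f"{m.log2_ratio:+.2f}" if m.log2_ratio is not None else "  NA"
    print(f"  {m.peptide.sequence:<30} {pos}  {m.region_class:<18} log2={log2} {m.color}")

# Peptides inside the tail report the +1.2 log2 effect (green), ectodomain
# peptides the -0.6 effect (red); any peptide straddling the TM boundary
# would be classed 'spanning' and kept out of the domain averages.
print("cytoplasmic mean:", result.cytoplasmic)
print("extra-cytoplasmic mean:", result.extra_cytoplasmic)
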