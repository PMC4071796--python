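"""Run summaries, fold-change distributions and the substrate screen."""

import math

import numpy as np
import pytest

from ripmap.annotation import ProteinAnnotation, TopoFeature
from ripmap.mapping import ProteinResult, map_protein
from ripmap.protxml_io import PeptideRecord, ProteinRecord, QuantResult
from ripmap.quantify import RegionQuant, RunConfig
from ripmap.screen import (
    RunSummary,
    fc_distribution,
    screen_sppl_candidates,
    summarize_run,
)
from tests.conftest import make_cd74_like
from ripmap import synthetic


class TestRunSummary:
    def test_published_count_table_gives_published_percentages(self):
        """The printed headline counts of the exemplar membrane-fraction
        analysis: 1231 quantified proteins, 629 with a TM domain, 458 of
        those without a signal peptide."""
        summary = RunSummary(
            n_total=1231, n_tm=629, n_signal=171, n_tm_no_signal=458,
            n_tm_cyto_quant=385, n_tm_extra_quant=362,
        )
        assert summary.pct_tm == 51
        assert summary.pct_tm_no_signal == 73

    def test_percentages_self_consistent(self):
        summary = RunSummary(n_total=10, n_tm=4, n_signal=2, n_tm_no_signal=3,
                             n_tm_cyto_quant=2, n_tm_extra_quant=1)
        assert summary.pct_tm == round(100 * summary.n_tm / summary.n_total)
        assert summary.pct_tm_no_signal == round(
            100 * summary.n_tm_no_signal / summary.n_tm
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            RunSummary(n_total=5, n_tm=6)
        with pytest.raises(ValueError):
            RunSummary(n_total=5, n_tm=2, n_tm_no_signal=3)

    def test_empty_run_is_all_zero(self):
        summary = summarize_run([])
        assert summary == RunSummary()
        assert summary.pct_tm == 0


def _result(record, ann, peptides=()):
    rec = ProteinRecord(
        group_index=1, protein_name=record, accession=record.split("|")[1]
        if "|" in record else record,
        namespace="uniprot", probability=0.99,
        protein_asap=QuantResult(1.0),
        peptides=list(peptides),
    )
    return map_protein(rec, ann, RunConfig())


def _annotation(accession, features, length=100):
    seq = ("ACDEFGHIKL" * ((length // 10) + 1))[:length]
    return ProteinAnnotation(
        accession=accession, recommended_name=accession, sequence=seq,
        molecular_weight=length * 110.0, features=features,
    )


class TestSummarizeRun:
    def test_counts_tm_and_soluble(self):
        tm_features = [
            TopoFeature("TOPO_DOM", 1, 10, "Cytoplasmic"),
            TopoFeature("TRANSMEM", 11, 31),
            TopoFeature("TOPO_DOM", 32, 100, "Extracellular"),
        ]
        sig_features = [TopoFeature("SIGNAL", 1, 20), TopoFeature("TRANSMEM", 40, 60)]
        results = [
            _result("sp|P00001|A", _annotation("P00001", tm_features)),
            _result("sp|P00002|B", _annotation("P00002", sig_features)),
            _result("sp|P00003|C", _annotation("P00003", [])),
        ]
        summary = summarize_run(results)
        assert summary.n_total == 3
        assert summary.n_tm == 2
        assert summary.n_signal == 1
        assert summary.n_tm_no_signal == 1

    def test_summary_matches_ground_truth_topology(self, small_cohort, small_run):
        specs, _, _ = small_cohort
        valid = {r.record.accession for r in small_run.results}
        truth_tm = sum(
            1 for s in specs
            if s.accession in valid
            and any(f.category == "TRANSMEM" for f in s.features)
        )
        assert small_run.summary.n_tm == truth_tm
        assert small_run.summary.n_total == len(small_run.results)


class TestFcDistribution:
    def test_histogram_counts_sum_to_values(self, small_run):
        for category in ("all", "tm", "cytoplasmic_domains", "extra_cytoplasmic_domains"):
            values, counts, edges = fc_distribution(small_run.results, category)
            assert counts.sum() == len(values)
            assert len(edges) == len(counts) + 1
            assert edges[0] == -3.0 and edges[-1] == 3.0

    def test_null_centred_cohort_mean_near_zero(self, small_run):
        values, _, _ = fc_distribution(small_run.results, "all")
        se = np.std(values) / math.sqrt(len(values))
        assert abs(np.mean(values)) <= 3 * se + 1e-9

    def test_empty_category(self):
        values, counts, _ = fc_distribution([], "all")
        assert values == [] and counts.sum() == 0

    def test_unknown_category_is_usage_error(self, small_run):
        with pytest.raises(ValueError, match="category"):
            fc_distribution(small_run.results, "mitochondrial")


def _run_cd74(cyto_effect, extra_effect=-0.6):
    spec, obs = make_cd74_like(cyto_effect, extra_effect)
    ann = synthetic.annotation_from_spec(spec)
    rec = ProteinRecord(
        group_index=1, protein_name=spec.protein_name, accession=spec.accession,
        namespace="uniprot", probability=spec.probability,
        peptides=[
            PeptideRecord(
                sequence=o.sequence, charge=o.charge, probability=o.probability,
                asap=QuantResult(o.linear_ratio),
            )
            for o in obs
            if o.linear_ratio is not None
        ],
    )
    return map_protein(rec, ann, RunConfig())


class TestSubstrateScreen:
    def test_cd74_like_protein_flagged_with_opposing_domain_means(self):
        result = _run_cd74(cyto_effect=1.2)
        candidates = screen_sppl_candidates([result], fc_cutoff=1.0)
        assert len(candidates) == 1
        cand = candidates[0]
        assert cand.cytoplasmic_mean == pytest.approx(1.2)
        assert cand.extra_cytoplasmic_mean == pytest.approx(-0.6)
        assert cand.cytoplasmic_mean > 0 > cand.extra_cytoplasmic_mean
        assert cand.tail_length == 29

    def test_tail_below_cutoff_not_flagged(self):
        result = _run_cd74(cyto_effect=0.8)
        assert screen_sppl_candidates([result], fc_cutoff=1.0) == []

    def test_multi_tm_protein_never_flagged(self):
        spec = synthetic.make_protein_spec(
            "multi", length=520, effects={"default": 2.0}, sigma=0.0,
            probability=0.99, accession="P11111", seed=3,
        )
        obs = synthetic.digest_and_quantify(
            spec, synthetic.SyntheticConfig(sigma=0.0, absent_ratio_fraction=0.0), seed=3
        )
        ann = synthetic.annotation_from_spec(spec)
        rec = ProteinRecord(
            group_index=1, protein_name=spec.protein_name, accession=spec.accession,
            namespace="uniprot", probability=0.99,
            peptides=[
                PeptideRecord(sequence=o.sequence, charge=2, probability=0.95,
                              asap=QuantResult(o.linear_ratio))
                for o in obs if o.linear_ratio is not None
            ],
        )
        result = map_protein(rec, ann, RunConfig())
        assert result.cytoplasmic is not None  # strongly up, but wrong topology
        assert screen_sppl_candidates([result]) == []

    def test_candidates_subset_of_tm_proteins_and_monotone_in_cutoff(self, small_run):
        results = small_run.results
        tm_accessions = {
            r.record.accession
            for r in results
            if r.annotation is not None and r.annotation.has_transmembrane()
        }
        assert screen_sppl_candidates(results, fc_cutoff=math.inf) == []
        previous: set = set()
        for cutoff in (2.0, 1.0, 0.5, 0.0, -1.0, -math.inf):
            current = {c.accession for c in screen_sppl_candidates(results, cutoff)}
            assert previous <= current
            assert current <= tm_accessions
            previous = current

    def test_optional_tail_length_limit(self):
        result = _run_cd74(cyto_effect=1.5)
        assert screen_sppl_candidates([result], max_tail_length=40)
        assert screen_sppl_candidates([result], max_tail_length=20) == []
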