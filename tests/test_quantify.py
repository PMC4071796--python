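"""Filtering, ratio transforms, deduplication and region averaging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ripmap.mapping import MappedPeptide
from ripmap.protxml_io import PeptideRecord, ProteinRecord, QuantResult
from ripmap.quantify import (
    RegionQuant,
    RunConfig,
    clamp,
    classify_change,
    dedupe_peptides,
    filter_proteins,
    region_average,
    select_ratio,
    to_log2,
)


def _record(prob, name="sp|P00001|X_MOUSE"):
    return ProteinRecord(
        group_index=1, protein_name=name, accession="P00001",
        namespace="uniprot", probability=prob,
    )


def _pep(seq="MKTAYK", prob=0.9, asap=None, xpress=None, n_spectra=None):
    return PeptideRecord(
        sequence=seq, charge=2, probability=prob,
        asap=QuantResult(asap, n_spectra=n_spectra) if asap is not None else None,
        xpress=QuantResult(xpress) if xpress is not None else None,
    )


class TestFilterProteins:
    def test_boundary_below_kept_and_discarded(self):
        valid, discarded = filter_proteins([_record(0.89), _record(0.90)], 0.90)
        assert [r.probability for r in valid] == [0.90]
        assert [d.record.probability for d in discarded] == [0.89]
        assert "0.8900" in discarded[0].reason

    def test_zero_threshold_keeps_everything(self):
        records = [_record(p) for p in (0.0, 0.3, 1.0)]
        valid, discarded = filter_proteins(records, 0.0)
        assert valid == records and discarded == []

    @settings(max_examples=100, deadline=None)
    @given(
        probs=st.lists(st.floats(0, 1), max_size=50),
        t1=st.floats(0, 1),
        t2=st.floats(0, 1),
    )
    def test_conservation_and_monotonicity(self, probs, t1, t2):
        records = [_record(p) for p in probs]
        lo, hi = sorted((t1, t2))
        v_lo, d_lo = filter_proteins(records, lo)
        v_hi, d_hi = filter_proteins(records, hi)
        assert len(v_lo) + len(d_lo) == len(probs)
        assert len(v_hi) + len(d_hi) == len(probs)
        assert len(v_hi) <= len(v_lo)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_proteins([], 1.5)


class TestSelectRatio:
    def test_concordant_xpress_passes(self):
        cfg = RunConfig(validate=True)
        assert select_ratio(_pep(asap=2.0, xpress=2.2), cfg) == (2.0, "pass")

    def test_discordant_xpress_fails(self):
        cfg = RunConfig(validate=True)
        assert select_ratio(_pep(asap=2.0, xpress=0.4), cfg) == (2.0, "fail")

    def test_absent_asap_is_untestable(self):
        assert select_ratio(_pep(), RunConfig(validate=True)) == (None, "untestable")

    def test_missing_xpress_is_untestable_but_quantified(self):
        assert select_ratio(_pep(asap=2.0), RunConfig(validate=True)) == (2.0, "untestable")

    def test_validation_off_always_passes(self):
        assert select_ratio(_pep(asap=2.0, xpress=0.4), RunConfig()) == (2.0, "pass")


class TestTransforms:
    @pytest.mark.parametrize(
        ("ratio", "invert", "expected"),
        [(1.0, False, 0.0), (2.0, True, -1.0), (0.25, False, -2.0)],
    )
    def test_log2_examples(self, ratio, invert, expected):
        assert to_log2(ratio, invert) == pytest.approx(expected)

    def test_degenerate_ratios_map_to_infinity_markers(self):
        assert to_log2(0.0) == -math.inf
        assert to_log2(9999.0) == math.inf
        assert clamp(to_log2(0.0)) == -3.0
        assert clamp(to_log2(9999.0)) == 3.0

    def test_negative_ratio_is_contract_violation(self):
        with pytest.raises(ValueError):
            to_log2(-1.0)

    @settings(max_examples=200, deadline=None)
    @given(ratio=st.floats(1e-6, 9e3))
    def test_double_inversion_is_identity(self, ratio):
        once = to_log2(ratio, invert=True)
        assert to_log2(ratio) == pytest.approx(-once)
        assert -(-to_log2(ratio)) == to_log2(ratio)

    @pytest.mark.parametrize(
        ("value", "expected"), [(5.2, 3.0), (-7.0, -3.0), (1.4, 1.4)]
    )
    def test_clamp_examples(self, value, expected):
        assert clamp(value) == expected

    @settings(max_examples=200, deadline=None)
    @given(value=st.floats(allow_nan=False), rmin=st.floats(-10, -0.5), rmax=st.floats(0.5, 10))
    def test_clamp_bounded_and_idempotent(self, value, rmin, rmax):
        out = clamp(value, rmin, rmax)
        assert rmin <= out <= rmax
        assert clamp(out, rmin, rmax) == out

    @pytest.mark.parametrize(
        ("value", "expected"),
        [
            (0.1, "no_change"),
            (0.30, "up"),
            (-0.25, "no_change"),  # inclusive boundary
            (0.25, "no_change"),
            (-0.26, "down"),
        ],
    )
    def test_change_classes_with_inclusive_zone(self, value, expected):
        assert classify_change(value) == expected


class TestDedupe:
    def test_keeps_highest_probability_occurrence(self):
        low, high = _pep(prob=0.80), _pep(prob=0.95)
        assert dedupe_peptides([low, high]) == [high]

    def test_elaborate_keeps_all_occurrences(self):
        low, high = _pep(prob=0.80), _pep(prob=0.95)
        assert dedupe_peptides([low, high], elaborate=True) == [low, high]

    def test_probability_tie_breaks_on_spectra_then_order(self):
        few = _pep(prob=0.9, asap=2.0, n_spectra=1)
        many = _pep(prob=0.9, asap=2.1, n_spectra=5)
        assert dedupe_peptides([few, many]) == [many]
        first = _pep(prob=0.9, asap=2.0)
        second = _pep(prob=0.9, asap=2.1)
        assert dedupe_peptides([first, second]) == [first]

    def test_distinct_sequences_unchanged(self):
        peps = [_pep("MKTAYK"), _pep("LLGNDAEK"), _pep("TTTTTK")]
        assert dedupe_peptides(peps) == peps


def _mapped(region, log2, flag="pass"):
    return MappedPeptide(
        peptide=_pep(asap=2.0), region_class=region, log2_ratio=log2,
        validation_flag=flag,
    )


class TestRegionAverage:
    def test_arithmetic_mean(self):
        mapped = [_mapped("cytoplasmic", 1.0), _mapped("cytoplasmic", 2.0)]
        quant = region_average(mapped, "cytoplasmic")
        assert quant == RegionQuant("cytoplasmic", 2, 1.5)

    def test_singleton(self):
        quant = region_average([_mapped("extra_cytoplasmic", 0.7)], "extra_cytoplasmic")
        assert quant.n_peptides == 1 and quant.mean_log2 == pytest.approx(0.7)

    def test_absent_when_no_contributor(self):
        assert region_average([_mapped("transmembrane", 1.0)], "cytoplasmic") is None
        assert region_average([], "cytoplasmic") is None

    def test_failed_validation_and_unquantified_excluded(self):
        mapped = [
            _mapped("cytoplasmic", 1.0),
            _mapped("cytoplasmic", 3.0, flag="fail"),
            MappedPeptide(peptide=_pep(), region_class="cytoplasmic"),
        ]
        quant = region_average(mapped, "cytoplasmic")
        assert quant.n_peptides == 1 and quant.mean_log2 == pytest.approx(1.0)

    def test_spanning_and_ambiguous_never_contribute(self):
        mapped = [_mapped("spanning", 2.0), _mapped("ambiguous", 2.0)]
        assert region_average(mapped, "cytoplasmic") is None
        assert region_average(mapped, "extra_cytoplasmic") is None

    @settings(max_examples=100, deadline=None)
    @given(values=st.lists(st.floats(-3, 3), min_size=1, max_size=20))
    def test_mean_within_contributor_range(self, values):
        mapped = [_mapped("cytoplasmic", v) for v in values]
        quant = region_average(mapped, "cytoplasmic")
        assert min(values) <= quant.mean_log2 <= max(values) + 1e-12

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            region_average([], "transmembrane")


class TestRunConfig:
    def test_defaults_match_published_options(self):
        cfg = RunConfig()
        assert (cfg.threshold, cfg.rmin, cfg.rmax, cfg.zn, cfg.zp) == (
            0.90, -3.0, 3.0, -0.25, 0.25,
        )
        assert not cfg.invert and not cfg.validate and not cfg.elaborate

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"threshold": 1.01},
            {"rmin": 0.0},
            {"zn": 0.1},
            {"zp": -0.1},
            {"zn": -4.0},
            {"zp": 3.5},
            {"validation_tolerance": 0.0},
        ],
    )
    def test_inconsistent_bounds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RunConfig(**kwargs)
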