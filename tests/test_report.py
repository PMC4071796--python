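"""Color scale, HTML rendering and the output bundle."""

import zipfile

import pytest
from hypothesis import given, settings, strategies as st
from lxml import html as lxml_html

from ripmap.annotation import ProteinAnnotation, TopoFeature
from ripmap.mapping import ProteinResult, map_protein
from ripmap.protxml_io import ProteinRecord, QuantResult
from ripmap.quantify import DiscardedProtein, RunConfig
from ripmap.report import (
    BROWSER_NOTE_CORRECTED,
    BROWSER_NOTE_MISSPELLED,
    color_for_ratio,
    render_html,
    write_bundle,
)
from ripmap.screen import summarize_run


class TestColorScale:
    @pytest.mark.parametrize(
        ("value", "expected"),
        [
            (0.0, "#808080"),
            (0.25, "#808080"),
            (-0.25, "#808080"),
            (3.0, "#00FF00"),
            (-3.0, "#FF0000"),
        ],
    )
    def test_zone_and_saturating_endpoints(self, value, expected):
        assert color_for_ratio(value) == expected

    def test_channel_floor_just_outside_zone(self):
        green = int(color_for_ratio(0.2500001)[3:5], 16)
        red = int(color_for_ratio(-0.2500001)[1:3], 16)
        assert green == 64 and red == 64

    def test_monotone_intensity_in_each_half_range(self):
        ups = [color_for_ratio(v) for v in (0.3, 0.8, 1.5, 2.2, 3.0)]
        greens = [int(c[3:5], 16) for c in ups]
        assert greens == sorted(greens) and len(set(greens)) == len(greens)
        downs = [color_for_ratio(v) for v in (-0.3, -0.8, -1.5, -2.2, -3.0)]
        reds = [int(c[1:3], 16) for c in downs]
        assert reds == sorted(reds) and len(set(reds)) == len(reds)

    @settings(max_examples=200, deadline=None)
    @given(value=st.floats(-3, 3))
    def test_negation_swaps_red_and_green_channels(self, value):
        cfg = RunConfig()  # symmetric bounds, so negation mirrors the scale
        color = color_for_ratio(value, cfg)
        mirror = color_for_ratio(-value, cfg)
        assert mirror[1:3] == color[3:5] and mirror[3:5] == color[1:3]

    def test_out_of_range_is_contract_violation(self):
        with pytest.raises(ValueError):
            color_for_ratio(3.5)


@pytest.fixture(scope="module")
def rendered(small_run_module):
    run = small_run_module
    docs = render_html(run.results, run.summary, run.config)
    return run, docs


@pytest.fixture(scope="module")
def small_run_module(tmp_path_factory):
    from ripmap import synthetic
    from ripmap.pipeline import run_pipeline

    specs, obs = synthetic.make_cohort(n_proteins=40, seed=23)
    paths = synthetic.write_fixture(specs, obs, tmp_path_factory.mktemp("report"))
    return run_pipeline(paths.protxml, paths.annotations)


class TestRenderHtml:
    def test_index_has_one_row_per_valid_protein(self, rendered):
        run, docs = rendered
        tree = lxml_html.fromstring(docs["index.html"])
        rows = tree.xpath("//table[@id='proteins']/tbody/tr")
        assert len(rows) == len(run.results)

    def test_every_protein_page_reachable_from_index(self, rendered):
        run, docs = rendered
        tree = lxml_html.fromstring(docs["index.html"])
        hrefs = set(tree.xpath("//a/@href"))
        for res in run.results:
            page = f"index_files/{res.record.accession}.html"
            assert page in docs and page in hrefs

    def test_pages_are_parseable_html(self, rendered):
        _, docs = rendered
        for path, text in docs.items():
            if path.endswith(".html"):
                assert lxml_html.fromstring(text) is not None

    def test_tm_filter_attributes_match_topology(self, rendered):
        run, docs = rendered
        tree = lxml_html.fromstring(docs["index.html"])
        flagged = tree.xpath("//tr[@data-tm='1']")
        n_tm = sum(
            1 for r in run.results
            if r.annotation is not None and r.annotation.has_transmembrane()
        )
        assert len(flagged) == n_tm

    def test_unannotated_protein_gets_badge(self):
        rec = ProteinRecord(
            group_index=1, protein_name="decoy_1", accession="decoy_1",
            namespace="unknown", probability=0.95,
            protein_asap=QuantResult(1.2),
        )
        result = map_protein(rec, None, RunConfig())
        docs = render_html([result], summarize_run([result]), RunConfig())
        assert "unannotated" in docs["index_files/decoy_1.html"]


class TestBundle:
    def test_inventory_exactly_the_published_members(self, small_run_module, tmp_path):
        run = small_run_module
        zip_path = write_bundle(
            run.results, run.summary, run.discarded, tmp_path / "report", run.config
        )
        names = zipfile.ZipFile(zip_path).namelist()
        top = {n.split("/")[0] + ("/" if "/" in n else "") for n in names}
        assert top == {
            "index.html",
            "run_stats.out",
            "average_molecular_weight.txt",
            BROWSER_NOTE_MISSPELLED,
            "images/",
            "small_images/",
            "index_files/",
        }

    def test_corrected_browser_note_name_switch(self, small_run_module, tmp_path):
        run = small_run_module
        zip_path = write_bundle(
            run.results, run.summary, run.discarded, tmp_path / "r2", run.config,
            corrected_browser_note_name=True,
        )
        names = zipfile.ZipFile(zip_path).namelist()
        assert BROWSER_NOTE_CORRECTED in names
        assert BROWSER_NOTE_MISSPELLED not in names

    def test_run_stats_line_count_equals_discarded(self, small_run_module, tmp_path):
        run = small_run_module
        write_bundle(run.results, run.summary, run.discarded, tmp_path / "r3", run.config)
        lines = (tmp_path / "r3" / "run_stats.out").read_text().splitlines()
        assert len(lines) == len(run.discarded)

    def test_average_molecular_weight(self, tmp_path):
        def result_with_mw(acc, mw):
            ann = ProteinAnnotation(
                accession=acc, recommended_name=acc, sequence="ACDEFGHIKL" * 10,
                molecular_weight=mw, features=[],
            )
            rec = ProteinRecord(
                group_index=1, protein_name=acc, accession=acc,
                namespace="uniprot", probability=0.99,
                protein_asap=QuantResult(1.0),
            )
            return map_protein(rec, ann, RunConfig())

        results = [result_with_mw("P00001", 10000.0), result_with_mw("P00002", 30000.0)]
        write_bundle(results, summarize_run(results), [], tmp_path / "mw", RunConfig())
        text = (tmp_path / "mw" / "average_molecular_weight.txt").read_text()
        assert "20000.0" in text
        assert "n_proteins\t2" in text

    def test_zip_is_byte_stable(self, small_run_module, tmp_path):
        run = small_run_module
        z1 = write_bundle(run.results, run.summary, run.discarded, tmp_path / "a", run.config)
        z2 = write_bundle(run.results, run.summary, run.discarded, tmp_path / "b", run.config)
        assert z1.read_bytes() == z2.read_bytes()
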