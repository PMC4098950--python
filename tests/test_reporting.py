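"""HTML/TSV report generation, engine statistics, warning log, summary totals."""

import random

import pytest
from lxml import html as lxml_html

from phoscompare.comparison import UniquenessStatus, classify_events
from phoscompare.io_formats import read_fasta, load_known_sites, parse_engine_table
from phoscompare.model import Engine, ModType, Sample
from phoscompare.pipeline import run
from phoscompare.reporting import (
    build_rows,
    render_html,
    summarize,
    write_engine_stats,
    write_log,
    write_summary_tsv,
    write_tsv,
)
from phoscompare.runlog import MULTI_MATCH, RunLog
from phoscompare.site_mapping import map_hit
from phoscompare.comparison import build_events

from conftest import config_for


@pytest.fixture(scope="module")
def run_result(bundle):
    return run(config_for(bundle))


def test_html_round_trip_recovers_every_row_field(bundle, run_result):
    """Data attributes in the HTML carry the full machine-readable row."""
    rows = run_result.rows
    summary = run_result.summary
    doc = lxml_html.fromstring(render_html(rows, summary=summary))
    trs = doc.cssselect if False else doc.xpath('//table[@id="events"]/tbody/tr')
    assert len(trs) == len(rows)
    for row, tr in zip(rows, trs):
        assert tr.get("data-accession") == row.accession
        assert tr.get("data-status") == row.status.value
        assert tr.get("data-sequence") == row.shared_sequence
        assert int(tr.get("data-start")) == row.shared_start
        assert int(tr.get("data-end")) == row.shared_end
        assert int(tr.get("data-n-peptides")) == row.n_peptides
        # sites with novelty flags
        site_text = tr.get("data-sites")
        expected_sites = ";".join(
            f"{res}{pos}:{mt.value}:{nov.value}" + (f"({','.join(src)})" if src else "")
            for pos, res, mt, nov, src in row.sites
        )
        assert site_text == expected_sites
        # detection marks per engine x sample
        detections = dict(
            part.split("=") for part in tr.get("data-detections").split(",") if part
        )
        for (eng, smp), n in row.detections.items():
            assert int(detections[f"{eng.value}:{smp.value}"]) == n
        counts = dict(p.split("=") for p in tr.get("data-residue-counts").split(","))
        for r, n in row.residue_counts.items():
            assert int(counts[r]) == n
        # presentation encodes the same status as the machine field
        assert tr.get("class") == row.status.value


def test_html_summary_counts_match_attributes(run_result):
    doc = lxml_html.fromstring(render_html(run_result.rows, summary=run_result.summary))
    (section,) = doc.xpath('//section[@id="summary"]')
    for key, value in run_result.summary.items():
        assert section.get("data-" + key.replace("_", "-")) == str(value)


def test_zero_rows_render_valid_empty_report():
    doc = lxml_html.fromstring(render_html([], summary={"total_peptides": 0}))
    assert doc.xpath('//table[@id="events"]')
    assert not doc.xpath('//table[@id="events"]/tbody/tr')


def test_novel_sites_bold_and_modified_residues_underlined(run_result):
    text = render_html(run_result.rows)
    any_novel = any(nov.value == "novel" for row in run_result.rows for *_x, nov, _s in
                    [(s[0], s[1], s[2], s[3], s[4]) for s in row.sites])
    assert "<u>" in text
    if any_novel:
        assert "<b><u>" in text or "<b>" in text


def test_tsv_is_deterministic_and_counts_match_html(tmp_path, run_result):
    p1 = write_tsv(run_result.rows, tmp_path / "a.tsv")
    p2 = write_tsv(run_result.rows, tmp_path / "b.tsv")
    assert p1.read_bytes() == p2.read_bytes()
    lines = p1.read_text().splitlines()
    assert len(lines) - 1 == len(run_result.rows)
    # statuses recomputed from the TSV equal the summary printed in the HTML
    status_idx = lines[0].split("\t").index("status")
    from collections import Counter

    tally = Counter(line.split("\t")[status_idx] for line in lines[1:])
    assert tally.get("unique_case", 0) == run_result.summary["unique_case_peptides"]
    assert tally.get("unique_control", 0) == run_result.summary["unique_control_peptides"]
    assert tally.get("common", 0) == run_result.summary["common_peptides"]


def test_engine_stats_row_counts_match_presence(tmp_path, run_result):
    paths = write_engine_stats(run_result.classified, tmp_path)
    for engine, path in paths.items():
        lines = path.read_text().splitlines()[1:]
        pep_lines = [l for l in lines if l.startswith("peptide\t")]
        expected = sum(
            1
            for ev, _st in run_result.classified
            if engine in {m.hit.engine for m in ev.members}
        )
        assert len(pep_lines) == expected


def test_engine_stats_disjoint_engines_give_disjoint_peptide_lists(tmp_path, tiny_db):
    from conftest import make_hit

    m = map_hit(make_hit(engine=Engine.MASCOT), tiny_db)
    p = map_hit(
        make_hit(peptide="MAAAASTK", mods=((6, "S", ModType.PHOSPHO),), engine=Engine.PARAGON,
                 accessions=("P23456",), scores={"confidence": 99.5}),
        tiny_db,
    )
    classified = classify_events(build_events([m, p], tiny_db))
    paths = write_engine_stats(classified, tmp_path)
    mascot_peps = {l.split("\t")[3] for l in paths[Engine.MASCOT].read_text().splitlines()[1:] if l.startswith("peptide")}
    paragon_peps = {l.split("\t")[3] for l in paths[Engine.PARAGON].read_text().splitlines()[1:] if l.startswith("peptide")}
    assert mascot_peps and paragon_peps and not (mascot_peps & paragon_peps)


def test_log_lines_and_counter_oracle(tmp_path, tiny_db):
    from conftest import make_hit

    log = RunLog()
    map_hit(make_hit(accessions=("P12345", "P34567")), tiny_db, log=log)  # multi-match
    map_hit(make_hit(peptide="WWWW", mods=()), tiny_db, log=log)  # unmapped
    path = write_log(log, tmp_path / "warnings.log")
    lines = path.read_text().splitlines()
    assert len(lines) == log.count() == sum(log.counters().values())
    assert lines[0].startswith(MULTI_MATCH + "\t")
    assert "P12345" in lines[0] and "P34567" in lines[0]


def test_clean_run_writes_empty_log(tmp_path):
    path = write_log(RunLog(), tmp_path / "warnings.log")
    assert path.exists() and path.read_text() == ""


def test_summary_partition_identity(run_result):
    s = run_result.summary
    assert (
        s["unique_case_peptides"] + s["unique_control_peptides"] + s["common_peptides"]
        == s["total_peptides"]
        == len(run_result.classified)
    )


def test_single_common_event_gives_zero_unique_totals(tiny_db):
    from conftest import make_hit

    members = [
        map_hit(make_hit(sample=Sample.CASE), tiny_db),
        map_hit(make_hit(sample=Sample.CONTROL), tiny_db),
    ]
    classified = classify_events(build_events(members, tiny_db))
    s = summarize(classified)
    assert s["unique_case_peptides"] == s["unique_control_peptides"] == 0
    assert s["common_peptides"] == 1
    assert s["unique_case_proteins"] == s["unique_control_proteins"] == 0


def test_summary_tsv_round_trip(tmp_path, run_result):
    path = write_summary_tsv(run_result.summary, tmp_path / "summary.tsv")
    back = dict(
        line.split("\t") for line in path.read_text().splitlines()[1:]
    )
    assert {k: int(v) for k, v in back.items()} == run_result.summary
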