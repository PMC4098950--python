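"""Event building, consensus classification, quantitative relabeling."""

import itertools
import random

import pytest

from phoscompare.comparison import (
    PhosphoEvent,
    PresenceMatrix,
    QuantConfig,
    QuantLabel,
    UniquenessStatus,
    apply_quant_labels,
    build_events,
    classify_events,
    classify_uniqueness,
    engine_partition,
    quantify_presence,
    unique_phosphoproteins,
)
from phoscompare.io_formats import ProteinDB
from phoscompare.model import Engine, ModType, Sample
from phoscompare.runlog import MISSING_RATIO, RunLog
from phoscompare.site_mapping import MappedPeptide, SiteAssignment

from conftest import make_hit


def mapped(
    db,
    peptide,
    start,
    accession="P12345",
    site_positions=(3,),
    engine=Engine.MASCOT,
    sample=Sample.CASE,
    mod_type=ModType.PHOSPHO,
    multi_match=False,
):
    """Construct a MappedPeptide directly (bypassing parsing) for unit tests."""
    seq = db.sequence(accession)
    sites = tuple(
        SiteAssignment(accession, pos, seq[pos - 1], mod_type) for pos in sorted(site_positions)
    )
    hit = make_hit(
        peptide=peptide,
        mods=tuple((pos - start + 1, seq[pos - 1], mod_type) for pos in sorted(site_positions)),
        engine=engine,
        sample=sample,
        accessions=(accession,),
    )
    return MappedPeptide(
        hit=hit,
        accession=accession,
        start=start,
        end=start + len(peptide) - 1,
        sites=sites,
        multi_match=multi_match,
    )


@pytest.fixture
def long_db():
    return ProteinDB(
        records={
            "P12345": ("MKSAPSTRAAGGLLK", "sp|P12345|A_X a"),
            "P77777": ("MMMSTYKRSAPQRST", "sp|P77777|B_X b"),
        },
        dialect="uniprot",
    )


# ---------------------------------------------------------------------------
# event building


def test_peptides_of_different_length_with_same_site_form_one_event(long_db):
    short = mapped(long_db, "SAPSTR", 3, sample=Sample.CASE)
    longer = mapped(long_db, "SAPSTRAAGGL", 3, sample=Sample.CASE)
    events = build_events([short, longer], long_db)
    (event,) = events
    assert len(event.members) == 2  # same peptide in the report, counted as two
    assert event.shared_sequence == "SAPSTR"  # interval intersection
    assert (event.shared_start, event.shared_end) == (3, 8)


def test_single_peptide_event_shares_itself(long_db):
    (event,) = build_events([mapped(long_db, "SAPSTR", 3)], long_db)
    assert event.shared_sequence == "SAPSTR"


def test_distinct_site_sets_split_events(long_db):
    a = mapped(long_db, "SAPSTR", 3, site_positions=(3,))
    b = mapped(long_db, "SAPSTR", 3, site_positions=(7,))
    c = mapped(long_db, "SAPSTR", 3, site_positions=(3, 7))
    events = build_events([a, b, c], long_db)
    assert len(events) == 3
    assert {e.site_set for e in events} == {a_site_set for a_site_set in (
        frozenset({(3, "S", ModType.PHOSPHO)}),
        frozenset({(7, "T", ModType.PHOSPHO)}),
        frozenset({(3, "S", ModType.PHOSPHO), (7, "T", ModType.PHOSPHO)}),
    )}


def test_phospho_and_acetyl_at_same_position_are_distinct_events(long_db):
    # modification type is part of site identity
    p = mapped(long_db, "MMMSTYKR", 1, accession="P77777", site_positions=(7,), mod_type=ModType.PHOSPHO)
    a = mapped(long_db, "MMMSTYKR", 1, accession="P77777", site_positions=(7,), mod_type=ModType.ACETYL)
    assert len(build_events([p, a], long_db)) == 2


def brute_force_partition(mapped_peptides):
    """Pairwise grouping oracle: same protein and identical site sets."""
    groups = []
    for mp in mapped_peptides:
        key_sites = frozenset((s.protein_position, s.residue, s.mod_type) for s in mp.sites)
        for group in groups:
            other = group[0]
            other_sites = frozenset((s.protein_position, s.residue, s.mod_type) for s in other.sites)
            if other.accession == mp.accession and other_sites == key_sites:
                group.append(mp)
                break
        else:
            groups.append([mp])
    return groups


def test_grouping_equals_brute_force_partition(long_db):
    rng = random.Random(2024)
    pool = []
    for _ in range(200):
        acc = rng.choice(["P12345", "P77777"])
        if acc == "P12345":
            start, pep_opts, site_opts = 3, ["SAPSTR", "SAPSTRAAGGL"], [(3,), (7,), (3, 7)]
        else:
            start, pep_opts, site_opts = 4, ["STYKRSAP", "STYKRSAPQ"], [(4,), (5,), (4, 6)]
        pool.append(
            mapped(
                long_db,
                rng.choice(pep_opts),
                start,
                accession=acc,
                site_positions=rng.choice(site_opts),
                sample=rng.choice([Sample.CASE, Sample.CONTROL]),
            )
        )
    events = build_events(pool, long_db)
    oracle = brute_force_partition(pool)
    got = sorted((ev.accession, tuple(sorted(ev.site_set)), len(ev.members)) for ev in events)
    want = sorted(
        (
            g[0].accession,
            tuple(sorted((s.protein_position, s.residue, s.mod_type) for s in g[0].sites)),
            len(g),
        )
        for g in oracle
    )
    assert got == want
    assert sum(len(ev.members) for ev in events) == len(pool)


# ---------------------------------------------------------------------------
# consensus classification


def consensus_sentence_oracle(matrix):
    """Literal translation of the consensus rule: unique to case only if detected
    in case by at least one engine and not detected in control by any engine."""
    detected_case = any(n > 0 for (eng, smp), n in matrix.items() if smp == Sample.CASE)
    detected_control = any(n > 0 for (eng, smp), n in matrix.items() if smp == Sample.CONTROL)
    if detected_case and not detected_control:
        return UniquenessStatus.UNIQUE_CASE
    if detected_control and not detected_case:
        return UniquenessStatus.UNIQUE_CONTROL
    return UniquenessStatus.COMMON


def all_matrices():
    engines = [Engine.MASCOT, Engine.PARAGON]
    cells = [(e, s) for e in engines for s in (Sample.CASE, Sample.CONTROL)]
    for counts in itertools.product([0, 1, 2], repeat=4):
        yield dict(zip(cells, counts))


def test_consensus_rule_on_all_81_presence_matrices():
    n = 0
    for matrix in all_matrices():
        if sum(matrix.values()) == 0:
            with pytest.raises(ValueError):
                classify_uniqueness(PresenceMatrix(detected=dict(matrix)))
            continue
        got = classify_uniqueness(PresenceMatrix(detected=dict(matrix)))
        assert got == consensus_sentence_oracle(matrix), matrix
        n += 1
    assert n == 80  # 81 matrices, one all-zero


def test_case_only_detection_is_unique_case():
    pm = PresenceMatrix(detected={(Engine.MASCOT, Sample.CASE): 1})
    assert classify_uniqueness(pm) == UniquenessStatus.UNIQUE_CASE


def test_once_in_each_sample_is_common():
    pm = PresenceMatrix(detected={(Engine.MASCOT, Sample.CASE): 1, (Engine.PARAGON, Sample.CONTROL): 1})
    assert classify_uniqueness(pm) == UniquenessStatus.COMMON


def test_consensus_dominance(long_db):
    """Adding a control detection to a case-unique event makes it common, never control-unique."""
    case_member = mapped(long_db, "SAPSTR", 3, sample=Sample.CASE)
    (event,) = build_events([case_member], long_db)
    assert classify_uniqueness(PresenceMatrix.from_event(event)) == UniquenessStatus.UNIQUE_CASE
    control_member = mapped(long_db, "SAPSTR", 3, sample=Sample.CONTROL, engine=Engine.PARAGON)
    (event2,) = build_events([case_member, control_member], long_db)
    assert classify_uniqueness(PresenceMatrix.from_event(event2)) == UniquenessStatus.COMMON


def test_partition_identity(long_db):
    rng = random.Random(7)
    pool = [
        mapped(
            long_db,
            "SAPSTR",
            3,
            site_positions=rng.choice([(3,), (7,), (3, 7)]),
            sample=rng.choice([Sample.CASE, Sample.CONTROL]),
            engine=rng.choice([Engine.MASCOT, Engine.PARAGON]),
        )
        for _ in range(80)
    ]
    classified = classify_events(build_events(pool, long_db))
    counts = {st: 0 for st in UniquenessStatus}
    for _ev, st in classified:
        counts[st] += 1
    assert sum(counts.values()) == len(classified)


# ---------------------------------------------------------------------------
# quantitative mode


def test_quant_thresholds():
    qc2 = QuantConfig(case_ratio_min=2.0, control_ratio_max=0.5)
    assert quantify_presence(make_hit(ratio=2.5), qc2) == QuantLabel.AS_CASE
    qc = QuantConfig(case_ratio_min=1.414, control_ratio_max=0.707)
    assert quantify_presence(make_hit(ratio=1.5), qc) == QuantLabel.AS_CASE
    assert quantify_presence(make_hit(ratio=0.5), qc) == QuantLabel.AS_CONTROL
    assert quantify_presence(make_hit(ratio=1.0), qc) == QuantLabel.NEITHER


def test_missing_ratio_is_neither_with_warning():
    log = RunLog()
    assert quantify_presence(make_hit(ratio=None), QuantConfig(), log=log) == QuantLabel.NEITHER
    assert quantify_presence(make_hit(ratio=-1.0), QuantConfig(), log=log) == QuantLabel.NEITHER
    assert log.count(MISSING_RATIO) == 2


def test_neutral_band_duplicates_into_both_samples():
    relabeled = apply_quant_labels([make_hit(ratio=1.0)], QuantConfig())
    assert {h.sample_label for h in relabeled} == {Sample.CASE, Sample.CONTROL}
    assert len(relabeled) == 2


def test_raising_case_cutoff_never_gains_case_calls():
    rng = random.Random(13)
    hits = [make_hit(ratio=round(rng.uniform(0.1, 4.0), 3)) for _ in range(300)]

    def n_case(cutoff):
        qc = QuantConfig(case_ratio_min=cutoff, control_ratio_max=0.5)
        return sum(1 for h in hits if quantify_presence(h, qc) == QuantLabel.AS_CASE)

    counts = [n_case(c) for c in (1.1, 1.414, 2.0, 3.0)]
    assert counts == sorted(counts, reverse=True)


def test_quant_config_rejects_inverted_band():
    with pytest.raises(ValueError):
        QuantConfig(case_ratio_min=0.9, control_ratio_max=0.7)
    with pytest.raises(ValueError):
        QuantConfig(case_ratio_min=2.0, control_ratio_max=1.5)


# ---------------------------------------------------------------------------
# protein attribution and engine partition


def test_unique_protein_sets_follow_definitions(long_db):
    unique_ev = build_events([mapped(long_db, "SAPSTR", 3, sample=Sample.CASE)], long_db)[0]
    multi_ev = build_events(
        [mapped(long_db, "STYKRSAP", 4, accession="P77777", site_positions=(5,), sample=Sample.CASE, multi_match=True)],
        long_db,
    )[0]
    common_ev = build_events(
        [
            mapped(long_db, "SAPSTR", 3, site_positions=(7,), sample=Sample.CASE),
            mapped(long_db, "SAPSTR", 3, site_positions=(7,), sample=Sample.CONTROL),
        ],
        long_db,
    )[0]
    classified = [
        (unique_ev, UniquenessStatus.UNIQUE_CASE),
        (multi_ev, UniquenessStatus.UNIQUE_CASE),
        (common_ev, UniquenessStatus.COMMON),
    ]
    proteins = unique_phosphoproteins(classified)
    assert proteins[Sample.CASE] == {"P12345"}  # multi-match event excluded
    assert proteins[Sample.CONTROL] == set()


def test_unique_proteins_equal_brute_force(long_db):
    rng = random.Random(31)
    classified = []
    for _ in range(120):
        acc = rng.choice(["P12345", "P77777"])
        start = 3 if acc == "P12345" else 4
        pep = "SAPSTR" if acc == "P12345" else "STYKRSAP"
        sites = rng.choice([(start,), (start + 1,)])
        mp = mapped(long_db, pep, start, accession=acc, site_positions=sites,
                    multi_match=rng.random() < 0.3)
        (ev,) = build_events([mp], long_db)
        classified.append((ev, rng.choice(list(UniquenessStatus))))
    got = unique_phosphoproteins(classified)
    want = {Sample.CASE: set(), Sample.CONTROL: set()}
    for ev, st in classified:
        if any(m.multi_match for m in ev.members):
            continue
        if st == UniquenessStatus.UNIQUE_CASE:
            want[Sample.CASE].add(ev.accession)
        if st == UniquenessStatus.UNIQUE_CONTROL:
            want[Sample.CONTROL].add(ev.accession)
    assert got == want


def test_engine_partition_detected_and_only_sets(long_db):
    both = build_events(
        [
            mapped(long_db, "SAPSTR", 3, engine=Engine.MASCOT),
            mapped(long_db, "SAPSTR", 3, engine=Engine.PARAGON),
        ],
        long_db,
    )[0]
    mascot_only = build_events(
        [mapped(long_db, "SAPSTR", 3, site_positions=(7,), engine=Engine.MASCOT)], long_db
    )[0]
    classified = classify_events([both, mascot_only])
    partition = engine_partition(classified)
    detected_m, only_m = partition[Engine.MASCOT]
    detected_p, only_p = partition[Engine.PARAGON]
    assert both in detected_m and both in detected_p
    assert both not in only_m and both not in only_p
    assert mascot_only in only_m and mascot_only not in detected_p
    # "only" sets are pairwise disjoint
    assert not ({id(e) for e in only_m} & {id(e) for e in only_p})


def test_engine_partition_matches_direct_set_computation(long_db):
    rng = random.Random(99)
    pool = []
    for _ in range(60):
        pool.append(
            mapped(
                long_db,
                "SAPSTR",
                3,
                site_positions=rng.choice([(3,), (7,), (3, 7)]),
                engine=rng.choice([Engine.MASCOT, Engine.PARAGON]),
                sample=rng.choice([Sample.CASE, Sample.CONTROL]),
            )
        )
    classified = classify_events(build_events(pool, long_db))
    partition = engine_partition(classified)
    for engine, (detected, only) in partition.items():
        for ev, _st in classified:
            engines = {m.hit.engine for m in ev.members}
            assert (ev in detected) == (engine in engines)
            assert (ev in only) == (engines == {engine})
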