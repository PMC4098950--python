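"""Synthetic fixture bundles with full ground truth.

The generator emulates a case/control phosphoproteomics experiment end to
end: a tryptic-like proteome (random segments cut after K/R), planted
modification sites, overlapping peptide variants of different lengths that
share identical site sets (missed-cleavage style), engine export tables in
the canonical dialects, a known-site database covering a chosen fraction of
planted sites, and — in quantitative mode — abundance ratios drawn strictly
inside the band that realizes each event's planned class.

Every random draw flows from the plan's seed, so a plan generates
byte-identical bundles on repeated runs.  The ground-truth table records
each event's expected classification, site set, shared sequence and novelty
so the whole pipeline can be checked against it exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from phoscompare.comparison import SiteKey, UniquenessStatus
from phoscompare.io_formats import (
    Modification,
    ProteinDB,
    SearchHit,
    write_engine_table,
    write_fasta,
)
from phoscompare.model import Engine, ModType, Sample

BODY_ALPHABET = "ACDEFGHILMNPQSTVWY"  # no K/R (segment-internal), no ambiguity codes
PHOSPHO_RESIDUES = "STYK"
PHOSPHO_WEIGHTS = (0.85, 0.13, 0.01, 0.01)
KNOWN_SOURCES = ("uniprot_sites", "phosida", "phosphositeplus")


class FixtureError(ValueError):
    """Infeasible fixture plan."""


@dataclass
class FixturePlan:
    """Declarative description of a synthetic experiment.

    ``n_unique_case``/``n_unique_control``/``n_common`` are the planned
    event counts per class.  ``peptides_per_event_range`` controls how many
    overlapping peptide variants (identical site sets, different lengths)
    realize each event.  ``multi_match_fraction`` of events get their base
    peptide planted a second time in a decoy protein, exercising the
    ambiguous-mapping path.  In ``quant_mode`` each event receives an
    abundance ratio drawn strictly above ``case_ratio_min``, strictly below
    ``control_ratio_max``, or strictly inside the neutral band according to
    its planned class.
    """

    n_unique_case: int = 10
    n_unique_control: int = 10
    n_common: int = 20
    n_proteins: int | None = None
    protein_length_range: tuple[int, int] = (150, 360)
    engines: tuple[Engine, ...] = (Engine.MASCOT, Engine.PARAGON)
    peptides_per_event_range: tuple[int, int] = (1, 2)
    multi_match_fraction: float = 0.0
    acetyl_fraction: float = 0.1
    known_site_fraction: float = 0.5
    n_unmodified: int = 8
    n_low_score: int = 8
    quant_mode: bool = False
    case_ratio_min: float = 1.414
    control_ratio_max: float = 0.707
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_unique_case", "n_unique_control", "n_common", "n_unmodified", "n_low_score"):
            if getattr(self, name) < 0:
                raise FixtureError(f"{name} must be >= 0")
        for name in ("multi_match_fraction", "acetyl_fraction", "known_site_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise FixtureError(f"{name} must be in [0, 1]")
        lo, hi = self.peptides_per_event_range
        if not 1 <= lo <= hi <= 3:
            raise FixtureError("peptides_per_event_range must satisfy 1 <= lo <= hi <= 3")
        if not self.engines:
            raise FixtureError("at least one engine required")
        self.engines = tuple(Engine(e) for e in self.engines)
        if self.protein_length_range[0] < 70:
            raise FixtureError(
                "protein_length_range lower bound must be >= 70 so every protein "
                "holds at least four tryptic-like segments"
            )

    @property
    def n_events(self) -> int:
        return self.n_unique_case + self.n_unique_control + self.n_common


@dataclass
class GroundTruthEvent:
    """The planned truth for one phosphosite equivalence class."""

    event_id: int
    accession: str
    status: UniquenessStatus
    site_set: frozenset[SiteKey]
    shared_start: int
    shared_end: int
    shared_sequence: str
    peptides: tuple[str, ...]
    multi_match: bool
    novel_sites: frozenset[SiteKey]
    ratio: float | None = None


@dataclass
class FixtureBundle:
    """Paths of everything the generator wrote, plus in-memory ground truth."""

    directory: Path
    fasta_path: Path
    tables: list[tuple[Path, Engine, Sample]]
    known_sites_path: Path
    ground_truth_path: Path
    ground_truth: list[GroundTruthEvent]
    plan: FixturePlan


def _make_segment(rng: random.Random, seen: set[str]) -> str:
    """A unique tryptic-like segment: 7-15 body residues plus a terminal K/R."""
    while True:
        body_len = rng.randint(7, 15)
        seg = "".join(rng.choice(BODY_ALPHABET) for _ in range(body_len)) + rng.choice("KR")
        if seg not in seen:
            seen.add(seg)
            return seg


def _expected_status(plan_class: str) -> UniquenessStatus:
    return {
        "unique_case": UniquenessStatus.UNIQUE_CASE,
        "unique_control": UniquenessStatus.UNIQUE_CONTROL,
        "common": UniquenessStatus.COMMON,
    }[plan_class]


def generate(plan: FixturePlan, out_dir: str | Path) -> FixtureBundle:
    """Realize a plan on disk; see the module docstring for what is emitted."""
    rng = random.Random(plan.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- proteome scaffold: proteins as lists of unique segments -----------
    seen_segments: set[str] = set()
    proteins: list[list[str]] = []

    def add_protein() -> None:
        target = rng.randint(*plan.protein_length_range)
        segs: list[str] = []
        length = 0
        while length + 16 <= target or len(segs) < 4:
            seg = _make_segment(rng, seen_segments)
            segs.append(seg)
            length += len(seg)
        proteins.append(segs)

    slots_needed = plan.n_events + plan.n_unmodified + plan.n_low_score
    if plan.n_proteins is not None:
        for _ in range(plan.n_proteins):
            add_protein()
        available = sum(max(0, len(p) - 2) for p in proteins)
        if available < slots_needed:
            raise FixtureError(
                f"plan infeasible: {plan.n_proteins} proteins provide {available} "
                f"interior peptide slots but {slots_needed} are needed"
            )
    else:
        while sum(max(0, len(p) - 2) for p in proteins) < slots_needed:
            add_protein()

    # interior slots (prev and next segment both exist) in shuffled order
    slots = [(pi, si) for pi, segs in enumerate(proteins) for si in range(1, len(segs) - 1)]
    rng.shuffle(slots)

    # --- plant events -------------------------------------------------------
    accession_of = [f"P{90000 + i:05d}" for i in range(len(proteins) + 1)]  # +1 decoy

    plan_classes = (
        ["unique_case"] * plan.n_unique_case
        + ["unique_control"] * plan.n_unique_control
        + ["common"] * plan.n_common
    )
    rng.shuffle(plan_classes)

    @dataclass
    class _Planted:
        event_id: int
        plan_class: str
        protein_idx: int
        seg_idx: int
        seg_positions: list[tuple[int, str, ModType]]  # (1-based pos in segment, residue, mod)
        n_members: int
        multi: bool
        ratio: float | None = None

    planted: list[_Planted] = []
    for event_id, plan_class in enumerate(plan_classes):
        pi, si = slots[event_id]
        seg = proteins[pi][si]
        is_acetyl = rng.random() < plan.acetyl_fraction
        if is_acetyl:
            n_sites = 1
        else:
            n_sites = rng.randint(1, 2)
        positions = rng.sample(range(1, len(seg)), k=n_sites)  # exclude terminal K/R
        positions.sort()
        seg_positions = []
        for pos in positions:
            if is_acetyl:
                residue, mod = "K", ModType.ACETYL
            else:
                residue = rng.choices(PHOSPHO_RESIDUES, weights=PHOSPHO_WEIGHTS)[0]
                mod = ModType.PHOSPHO
            seg = seg[: pos - 1] + residue + seg[pos:]
            seg_positions.append((pos, residue, mod))
        proteins[pi][si] = seg
        multi = rng.random() < plan.multi_match_fraction
        n_members = 1 if multi else rng.randint(*plan.peptides_per_event_range)
        planted.append(
            _Planted(event_id, plan_class, pi, si, seg_positions, n_members, multi)
        )

    # extra slots for hits that must disappear during filtering
    extra_slots = slots[plan.n_events : plan.n_events + plan.n_unmodified + plan.n_low_score]
    unmodified_slots = extra_slots[: plan.n_unmodified]
    low_score_slots = extra_slots[plan.n_unmodified :]

    # give one in three low-score/unmodified peptides a planted phospho-site
    # so score filtering, not just the unmodified-discard, is exercised
    for pi, si in low_score_slots:
        seg = proteins[pi][si]
        pos = rng.randint(1, len(seg) - 1)
        residue = rng.choices(PHOSPHO_RESIDUES, weights=PHOSPHO_WEIGHTS)[0]
        proteins[pi][si] = seg[: pos - 1] + residue + seg[pos:]

    # --- decoy protein holding second copies of multi-match peptides --------
    decoy_segments = [proteins[p.protein_idx][p.seg_idx] for p in planted if p.multi]
    decoy_idx: int | None = None
    if decoy_segments:
        proteins.append(list(decoy_segments))
        decoy_idx = len(proteins) - 1

    # --- assemble sequences and coordinate lookups --------------------------
    sequences = ["".join(segs) for segs in proteins]
    seg_offset: list[list[int]] = []  # 1-based protein offset of each segment
    for segs in proteins:
        offsets, pos = [], 1
        for seg in segs:
            offsets.append(pos)
            pos += len(seg)
        seg_offset.append(offsets)

    records: dict[str, tuple[str, str]] = {}
    for i, seq in enumerate(sequences):
        acc = accession_of[i]
        tag = "DECOY_SYN" if i == decoy_idx else f"SYN{i}_TEST"
        records[acc] = (seq, f"sp|{acc}|{tag} synthetic protein {i}")
    db = ProteinDB(records=records, dialect="uniprot")

    # --- realize events: peptides, sites, hits ------------------------------
    def variants(p: _Planted) -> list[tuple[str, int]]:
        """(peptide, protein start) per member; base first, then missed cleavages."""
        segs = proteins[p.protein_idx]
        offs = seg_offset[p.protein_idx]
        si = p.seg_idx
        out = [(segs[si], offs[si])]
        if p.n_members >= 2:
            out.append((segs[si] + segs[si + 1], offs[si]))
        if p.n_members >= 3:
            out.append((segs[si - 1] + segs[si], offs[si - 1]))
        return out

    def draw_scores(engine: Engine, good: bool) -> dict[str, float]:
        if engine == Engine.MASCOT:
            expect = (
                round(10 ** rng.uniform(-5, -2.1), 8)
                if good
                else round(rng.uniform(0.02, 0.5), 6)
            )
            return {
                "expect": expect,
                "ion_score": round(rng.uniform(35.0, 95.0), 2),
                "localization": round(rng.uniform(80.0, 100.0), 2),
            }
        if engine == Engine.PARAGON:
            conf = round(rng.uniform(99.0, 99.95), 3) if good else round(rng.uniform(50.0, 98.0), 3)
            return {"confidence": conf, "localization": round(rng.uniform(80.0, 100.0), 2)}
        return {"xcorr": round(rng.uniform(2.0, 5.0), 3), "localization": round(rng.uniform(80.0, 100.0), 2)}

    def draw_ratio(plan_class: str) -> float:
        lo_c, hi_c = plan.case_ratio_min, plan.control_ratio_max
        if plan_class == "unique_case":
            return round(rng.uniform(lo_c * 1.05, lo_c * 2.5), 4)
        if plan_class == "unique_control":
            return round(rng.uniform(hi_c * 0.3, hi_c * 0.95), 4)
        return round(rng.uniform(hi_c * 1.08, lo_c * 0.92), 4)

    hits: list[SearchHit] = []
    ground_truth: list[GroundTruthEvent] = []
    known_rows: list[tuple[str, int, str, ModType, str]] = []  # + source

    for p in planted:
        acc = accession_of[p.protein_idx]
        var = variants(p)
        base_start = seg_offset[p.protein_idx][p.seg_idx]
        site_set = frozenset(
            (base_start + pos - 1, residue, mod) for pos, residue, mod in p.seg_positions
        )
        # shared interval: intersection of member intervals == base segment
        shared_start = max(start for _pep, start in var)
        shared_end = min(start + len(pep) - 1 for pep, start in var)
        shared_sequence = sequences[p.protein_idx][shared_start - 1 : shared_end]

        novel: set[SiteKey] = set()
        for pos, residue, mod in p.seg_positions:
            key = (base_start + pos - 1, residue, mod)
            if rng.random() < plan.known_site_fraction:
                known_rows.append((acc, key[0], residue, mod, rng.choice(KNOWN_SOURCES)))
            else:
                novel.add(key)

        accessions: tuple[str, ...] = (acc,)
        if p.multi and decoy_idx is not None:
            accessions = (acc, accession_of[decoy_idx])

        ratio = draw_ratio(p.plan_class) if plan.quant_mode else None

        # sample assignment realizing the planned class under the consensus rule
        member_samples: list[tuple[int, Sample]] = []  # (variant index, sample)
        if plan.quant_mode:
            member_samples = [(i, Sample.CASE) for i in range(len(var))]
        elif p.plan_class == "unique_case":
            member_samples = [(i, Sample.CASE) for i in range(len(var))]
        elif p.plan_class == "unique_control":
            member_samples = [(i, Sample.CONTROL) for i in range(len(var))]
        else:  # common: at least one detection in each sample
            member_samples = [(0, Sample.CASE), (len(var) - 1, Sample.CONTROL)]
            for i in range(1, len(var) - 1):
                member_samples.append((i, rng.choice((Sample.CASE, Sample.CONTROL))))

        event_peptides: list[str] = []
        for vi, sample in member_samples:
            pep, start = var[vi]
            if pep not in event_peptides:
                event_peptides.append(pep)
            engine = rng.choice(plan.engines)
            mods = tuple(
                Modification(position=(base_start - start) + pos, residue=residue, mod_type=mod)
                for pos, residue, mod in p.seg_positions
            )
            hits.append(
                SearchHit(
                    engine=engine,
                    sample_label=sample,
                    file_id="",  # assigned by table writer naming
                    peptide_sequence=pep,
                    protein_accessions=accessions,
                    modifications=mods,
                    scores=draw_scores(engine, good=True),
                    ratio=ratio,
                )
            )
            # occasional corroborating detection by a second engine
            if len(plan.engines) > 1 and rng.random() < 0.25:
                other = rng.choice([e for e in plan.engines if e != engine])
                hits.append(
                    SearchHit(
                        engine=other,
                        sample_label=sample,
                        file_id="",
                        peptide_sequence=pep,
                        protein_accessions=accessions,
                        modifications=mods,
                        scores=draw_scores(other, good=True),
                        ratio=ratio,
                    )
                )

        ground_truth.append(
            GroundTruthEvent(
                event_id=p.event_id,
                accession=acc,
                status=_expected_status(p.plan_class),
                site_set=site_set,
                shared_start=shared_start,
                shared_end=shared_end,
                shared_sequence=shared_sequence,
                peptides=tuple(event_peptides),
                multi_match=p.multi,
                novel_sites=frozenset(novel),
                ratio=ratio,
            )
        )

    # --- chaff: unmodified peptides and sub-threshold identifications -------
    for pi, si in unmodified_slots:
        engine = rng.choice(plan.engines)
        hits.append(
            SearchHit(
                engine=engine,
                sample_label=rng.choice((Sample.CASE, Sample.CONTROL)),
                file_id="",
                peptide_sequence=proteins[pi][si],
                protein_accessions=(accession_of[pi],),
                scores=draw_scores(engine, good=True),
                ratio=1.0 if plan.quant_mode else None,
            )
        )
    filterable = [e for e in plan.engines if e in (Engine.MASCOT, Engine.PARAGON)]
    for pi, si in low_score_slots:
        if not filterable:
            break
        seg = proteins[pi][si]
        mod_positions = [
            i + 1 for i, ch in enumerate(seg[:-1]) if ch in PHOSPHO_RESIDUES
        ]
        if not mod_positions:
            continue
        pos = rng.choice(mod_positions)
        engine = rng.choice(filterable)
        hits.append(
            SearchHit(
                engine=engine,
                sample_label=rng.choice((Sample.CASE, Sample.CONTROL)),
                file_id="",
                peptide_sequence=seg,
                protein_accessions=(accession_of[pi],),
                modifications=(Modification(pos, seg[pos - 1], ModType.PHOSPHO),),
                scores=draw_scores(engine, good=False),
                ratio=1.0 if plan.quant_mode else None,
            )
        )

    # decoy known-site entries at unplanted positions (never match observed sites)
    planted_keys = {
        (gt.accession, pos) for gt in ground_truth for pos, _res, _mod in gt.site_set
    }
    n_decoy_sites = max(2, plan.n_events // 5)
    for _ in range(n_decoy_sites):
        pi = rng.randrange(len(proteins))
        acc = accession_of[pi]
        pos = rng.randint(1, len(sequences[pi]))
        if (acc, pos) in planted_keys:
            continue
        known_rows.append((acc, pos, sequences[pi][pos - 1], ModType.PHOSPHO, rng.choice(KNOWN_SOURCES)))

    # --- validation: planted peptides occur exactly where promised ----------
    for gt in ground_truth:
        target_seq = sequences[accession_of.index(gt.accession)]
        for pep in gt.peptides:
            if target_seq.find(pep) == -1:
                raise FixtureError(f"internal error: peptide {pep} missing from {gt.accession}")
            in_proteome = sum(1 for seq in sequences if pep in seq)
            expected = 2 if gt.multi_match else 1
            if in_proteome != expected:
                raise FixtureError(
                    f"internal error: peptide {pep} occurs in {in_proteome} proteins, "
                    f"expected {expected}"
                )

    # --- write everything ----------------------------------------------------
    fasta_path = write_fasta(db, out_dir / "proteome.fasta")

    tables: list[tuple[Path, Engine, Sample]] = []
    ext = {Engine.MASCOT: "csv", Engine.PARAGON: "tsv", Engine.SEQUEST_PD: "tsv"}
    if plan.quant_mode:
        for engine in plan.engines:
            sel = [h for h in hits if h.engine == engine]
            path = out_dir / f"{engine.value}_pooled.{ext[engine]}"
            write_engine_table(sel, path, engine)
            tables.append((path, engine, Sample.CASE))
    else:
        for engine in plan.engines:
            for sample in (Sample.CASE, Sample.CONTROL):
                sel = [h for h in hits if h.engine == engine and h.sample_label == sample]
                path = out_dir / f"{engine.value}_{sample.value}.{ext[engine]}"
                write_engine_table(sel, path, engine)
                tables.append((path, engine, sample))

    known_sites_path = out_dir / "known_sites.tsv"
    with open(known_sites_path, "w", encoding="utf-8", newline="\n") as fh:
        for acc, pos, residue, mod, _source in sorted(set(known_rows)):
            fh.write(f"{acc}\t{pos}\t{residue}\t{mod.value}\n")

    ground_truth_path = out_dir / "ground_truth.tsv"
    with open(ground_truth_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "event_id\taccession\tstatus\tsites\tshared_start\tshared_end\t"
            "shared_sequence\tpeptides\tmulti_match\tnovel_sites\tratio\n"
        )
        for gt in ground_truth:
            sites = ";".join(f"{res}{pos}:{mod.value}" for pos, res, mod in sorted(gt.site_set))
            novel = ";".join(f"{res}{pos}:{mod.value}" for pos, res, mod in sorted(gt.novel_sites))
            fh.write(
                "\t".join(
                    [
                        str(gt.event_id),
                        gt.accession,
                        gt.status.value,
                        sites,
                        str(gt.shared_start),
                        str(gt.shared_end),
                        gt.shared_sequence,
                        ";".join(gt.peptides),
                        "yes" if gt.multi_match else "no",
                        novel,
                        "" if gt.ratio is None else f"{gt.ratio}",
                    ]
                )
                + "\n"
            )

    return FixtureBundle(
        directory=out_dir,
        fasta_path=fasta_path,
        tables=tables,
        known_sites_path=known_sites_path,
        ground_truth_path=ground_truth_path,
        ground_truth=ground_truth,
        plan=plan,
    )


def expected_summary(ground_truth: list[GroundTruthEvent]) -> dict[str, int]:
    """The summary the pipeline should report for a bundle, from ground truth alone."""
    case_prot: set[str] = set()
    control_prot: set[str] = set()
    counts = {status: 0 for status in UniquenessStatus}
    for gt in ground_truth:
        counts[gt.status] += 1
        if gt.multi_match:
            continue
        if gt.status is UniquenessStatus.UNIQUE_CASE:
            case_prot.add(gt.accession)
        elif gt.status is UniquenessStatus.UNIQUE_CONTROL:
            control_prot.add(gt.accession)
    return {
        "unique_case_peptides": counts[UniquenessStatus.UNIQUE_CASE],
        "unique_control_peptides": counts[UniquenessStatus.UNIQUE_CONTROL],
        "common_peptides": counts[UniquenessStatus.COMMON],
        "total_peptides": len(ground_truth),
        "unique_case_proteins": len(case_prot),
        "unique_control_proteins": len(control_prot),
        "overlap_proteins": len(case_prot & control_prot),
    }
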