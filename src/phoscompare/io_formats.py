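"""Readers and writers for search-engine exports, FASTA proteomes and known-site tables.

Three peptide-spectrum-match (PSM) table dialects are supported, one per
search engine.  Vendor exports vary between software versions, so the
package defines one canonical column layout and modification-string grammar
per engine (documented in ``docs/methods.md``) and accepts a column-mapping
override for real-world exports whose headers differ.

Canonical layouts
-----------------
mascot       CSV;  columns ``prot_acc, pep_seq, pep_score, pep_expect,
             pep_var_mod, pep_loc_score, pep_ratio``; modification grammar
             ``Phospho@3; Acetyl@7`` (1-based peptide positions).
paragon      TSV;  columns ``Accessions, Sequence, Conf, Modifications,
             LocScore, Ratio``; grammar ``Phospho(S)@3; Acetyl(K)@7``.
sequest_pd   TSV;  columns ``Protein Group Accessions, Sequence,
             Modifications, XCorr, Localization Score, Abundance Ratio``;
             grammar ``S3(Phospho); K7(Acetyl)``.

Accession lists are semicolon-separated in all dialects.  Score and ratio
columns may be empty on a per-row basis; an empty cell means "not reported".
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from phoscompare.model import Engine, ModType, Sample
from phoscompare.runlog import REJECTED_ROW, RunLog


class FormatError(ValueError):
    """Fatal input-format problem: unreadable table, unknown column layout."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Modification:
    """One residue-level modification assignment on a peptide (1-based position)."""

    position: int
    residue: str
    mod_type: ModType


@dataclass(frozen=True)
class SearchHit:
    """One engine-reported peptide with residue-level modification assignments.

    ``scores`` maps score names (``expect``, ``ion_score``, ``confidence``,
    ``xcorr``, ``localization``) to numbers; only the scores the engine
    reports are present.  ``ratio`` is the case/control abundance ratio in
    quantitative experiments, ``None`` otherwise.
    """

    engine: Engine
    sample_label: Sample
    file_id: str
    peptide_sequence: str
    protein_accessions: tuple[str, ...]
    modifications: tuple[Modification, ...] = ()
    scores: Mapping[str, float] = field(default_factory=dict)
    ratio: float | None = None

    def __post_init__(self) -> None:
        if not self.protein_accessions:
            raise ValueError("SearchHit requires at least one protein accession")
        n = len(self.peptide_sequence)
        for mod in self.modifications:
            if not 1 <= mod.position <= n:
                raise ValueError(
                    f"modification position {mod.position} outside peptide of length {n}"
                )
            if self.peptide_sequence[mod.position - 1] != mod.residue:
                raise ValueError(
                    f"residue mismatch at peptide position {mod.position}: "
                    f"sequence has {self.peptide_sequence[mod.position - 1]}, "
                    f"modification says {mod.residue}"
                )


@dataclass
class ProteinDB:
    """In-memory FASTA proteome: accession -> (sequence, description)."""

    records: dict[str, tuple[str, str]]
    dialect: str = "uniprot"

    def __contains__(self, accession: str) -> bool:
        return accession in self.records

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, accession: str) -> str:
        return self.records[accession][0]

    def description(self, accession: str) -> str:
        return self.records[accession][1]


SiteEntry = tuple[str, int, str, ModType]


@dataclass
class KnownSiteDB:
    """Set of literature-described modification sites with per-site provenance.

    ``entries`` holds (accession, 1-based position, residue, mod_type)
    tuples; ``provenance`` maps each entry to the names of the source
    databases that reported it.
    """

    entries: set[SiteEntry] = field(default_factory=set)
    provenance: dict[SiteEntry, set[str]] = field(default_factory=dict)

    def add(self, entry: SiteEntry, source: str) -> None:
        self.entries.add(entry)
        self.provenance.setdefault(entry, set()).add(source)

    def union(self, other: "KnownSiteDB") -> "KnownSiteDB":
        merged = KnownSiteDB(entries=set(self.entries), provenance={k: set(v) for k, v in self.provenance.items()})
        for entry in other.entries:
            for source in other.provenance.get(entry, {"?"}):
                merged.add(entry, source)
        return merged

    def sources_for(self, entry: SiteEntry) -> set[str]:
        return self.provenance.get(entry, set())


@dataclass
class FilterConfig:
    """Score thresholds and modification targets.

    A threshold left as ``None`` is not applied.  ``target_residues`` are the
    residue letters whose modifications count (serine, threonine, tyrosine
    for phosphorylation plus lysine for acetylation by default);
    ``mod_types`` restricts which modification classes are processed.
    """

    mascot_expect_max: float | None = None
    mascot_ion_score_min: float | None = None
    paragon_confidence_min: float | None = None
    localization_score_min: float | None = None
    target_residues: frozenset[str] = frozenset("STYK")
    mod_types: frozenset[ModType] = frozenset({ModType.PHOSPHO, ModType.ACETYL})

    def __post_init__(self) -> None:
        for name in ("mascot_expect_max", "mascot_ion_score_min", "paragon_confidence_min", "localization_score_min"):
            value = getattr(self, name)
            if value is not None and not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value}")
        if not self.target_residues:
            raise ValueError("target_residues must be non-empty")
        object.__setattr__(self, "target_residues", frozenset(self.target_residues))
        object.__setattr__(self, "mod_types", frozenset(self.mod_types))


@dataclass(frozen=True)
class RejectedRow:
    """A table row that could not be decoded into a SearchHit."""

    file_id: str
    row_index: int
    reason: str


@dataclass
class ParseResult:
    """Hits plus row-level rejects; ``|hits| + |rejects|`` equals the data-row count."""

    hits: list[SearchHit]
    rejects: list[RejectedRow]


# ---------------------------------------------------------------------------
# dialect definitions

MOD_NAMES = {"phospho": ModType.PHOSPHO, "acetyl": ModType.ACETYL}

_MASCOT_TOKEN = re.compile(r"^(?P<name>[A-Za-z]+)@(?P<pos>\d+)$")
_PARAGON_TOKEN = re.compile(r"^(?P<name>[A-Za-z]+)\((?P<res>[A-Z])\)@(?P<pos>\d+)$")
_SEQUEST_TOKEN = re.compile(r"^(?P<res>[A-Z])(?P<pos>\d+)\((?P<name>[A-Za-z]+)\)$")


def _decode_mascot_mods(text: str, peptide: str) -> list[Modification]:
    mods = []
    for token in (t.strip() for t in text.split(";") if t.strip()):
        m = _MASCOT_TOKEN.match(token)
        if m is None:
            raise ValueError(f"undecodable modification token {token!r}")
        name = m.group("name").lower()
        if name not in MOD_NAMES:
            raise ValueError(f"unknown modification type {m.group('name')!r}")
        pos = int(m.group("pos"))
        if not 1 <= pos <= len(peptide):
            raise ValueError(f"modification position {pos} outside peptide")
        mods.append(Modification(pos, peptide[pos - 1], MOD_NAMES[name]))
    return mods


def _decode_paragon_mods(text: str, peptide: str) -> list[Modification]:
    mods = []
    for token in (t.strip() for t in text.split(";") if t.strip()):
        m = _PARAGON_TOKEN.match(token)
        if m is None:
            raise ValueError(f"undecodable modification token {token!r}")
        name = m.group("name").lower()
        if name not in MOD_NAMES:
            raise ValueError(f"unknown modification type {m.group('name')!r}")
        pos = int(m.group("pos"))
        if not 1 <= pos <= len(peptide):
            raise ValueError(f"modification position {pos} outside peptide")
        if peptide[pos - 1] != m.group("res"):
            raise ValueError(
                f"residue mismatch for token {token!r}: peptide has {peptide[pos - 1]} at {pos}"
            )
        mods.append(Modification(pos, m.group("res"), MOD_NAMES[name]))
    return mods


def _decode_sequest_mods(text: str, peptide: str) -> list[Modification]:
    mods = []
    for token in (t.strip() for t in text.split(";") if t.strip()):
        m = _SEQUEST_TOKEN.match(token)
        if m is None:
            raise ValueError(f"undecodable modification token {token!r}")
        name = m.group("name").lower()
        if name not in MOD_NAMES:
            raise ValueError(f"unknown modification type {m.group('name')!r}")
        pos = int(m.group("pos"))
        if not 1 <= pos <= len(peptide):
            raise ValueError(f"modification position {pos} outside peptide")
        if peptide[pos - 1] != m.group("res"):
            raise ValueError(
                f"residue mismatch for token {token!r}: peptide has {peptide[pos - 1]} at {pos}"
            )
        mods.append(Modification(pos, m.group("res"), MOD_NAMES[name]))
    return mods


def _encode_mascot_mods(mods: Sequence[Modification]) -> str:
    return "; ".join(f"{m.mod_type.value.capitalize()}@{m.position}" for m in mods)


def _encode_paragon_mods(mods: Sequence[Modification]) -> str:
    return "; ".join(f"{m.mod_type.value.capitalize()}({m.residue})@{m.position}" for m in mods)


def _encode_sequest_mods(mods: Sequence[Modification]) -> str:
    return "; ".join(f"{m.residue}{m.position}({m.mod_type.value.capitalize()})" for m in mods)


@dataclass(frozen=True)
class Dialect:
    separator: str
    accessions: str
    sequence: str
    modifications: str
    score_columns: Mapping[str, str]  # score name -> column
    ratio: str
    decode_mods: callable
    encode_mods: callable


DIALECTS: dict[Engine, Dialect] = {
    Engine.MASCOT: Dialect(
        separator=",",
        accessions="prot_acc",
        sequence="pep_seq",
        modifications="pep_var_mod",
        score_columns={"ion_score": "pep_score", "expect": "pep_expect", "localization": "pep_loc_score"},
        ratio="pep_ratio",
        decode_mods=_decode_mascot_mods,
        encode_mods=_encode_mascot_mods,
    ),
    Engine.PARAGON: Dialect(
        separator="\t",
        accessions="Accessions",
        sequence="Sequence",
        modifications="Modifications",
        score_columns={"confidence": "Conf", "localization": "LocScore"},
        ratio="Ratio",
        decode_mods=_decode_paragon_mods,
        encode_mods=_encode_paragon_mods,
    ),
    Engine.SEQUEST_PD: Dialect(
        separator="\t",
        accessions="Protein Group Accessions",
        sequence="Sequence",
        modifications="Modifications",
        score_columns={"xcorr": "XCorr", "localization": "Localization Score"},
        ratio="Abundance Ratio",
        decode_mods=_decode_sequest_mods,
        encode_mods=_encode_sequest_mods,
    ),
}


def _cell(row: pd.Series, column: str) -> str | None:
    if column not in row.index:
        return None
    value = row[column]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    return text or None


# ---------------------------------------------------------------------------
# operations


def parse_engine_table(
    path: str | Path,
    engine: Engine,
    sample_label: Sample,
    column_map: Mapping[str, str] | None = None,
    log: RunLog | None = None,
) -> ParseResult:
    """Parse one search-engine export table into SearchHits.

    ``column_map`` renames canonical columns for exports whose headers
    differ (keys: ``accessions``, ``sequence``, ``modifications``, ``ratio``
    and score names).  Rows whose modification string cannot be decoded are
    returned in the rejects list (and logged) rather than aborting the run;
    a missing required column is fatal.
    """
    path = Path(path)
    engine = Engine(engine)
    sample_label = Sample(sample_label)
    dialect = DIALECTS[engine]

    def col(canonical: str, default: str) -> str:
        return (column_map or {}).get(canonical, default)

    try:
        table = pd.read_csv(path, sep=dialect.separator, dtype=str, keep_default_na=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV/TSV structure
        raise FormatError(f"cannot read {path}: {exc}") from exc

    required = {
        "accessions": col("accessions", dialect.accessions),
        "sequence": col("sequence", dialect.sequence),
        "modifications": col("modifications", dialect.modifications),
    }
    missing = [name for name in required.values() if name not in table.columns]
    if missing:
        raise FormatError(
            f"{path}: unknown column layout for {engine.value} — missing columns {missing}"
        )

    file_id = path.name
    hits: list[SearchHit] = []
    rejects: list[RejectedRow] = []
    for idx, row in table.iterrows():
        peptide = _cell(row, required["sequence"])
        if peptide is None:
            continue  # blank filler row, not a data row
        peptide = peptide.upper()
        try:
            if not peptide.isalpha():
                raise ValueError(f"invalid peptide sequence {peptide!r}")
            acc_text = _cell(row, required["accessions"])
            if acc_text is None:
                raise ValueError("missing protein accession")
            accessions = tuple(a.strip() for a in acc_text.split(";") if a.strip())
            mod_text = _cell(row, required["modifications"])
            mods = tuple(dialect.decode_mods(mod_text, peptide)) if mod_text else ()
            scores: dict[str, float] = {}
            for score_name, column in dialect.score_columns.items():
                cell = _cell(row, col(score_name, column))
                if cell is not None:
                    scores[score_name] = float(cell)
            ratio_cell = _cell(row, col("ratio", dialect.ratio))
            ratio = float(ratio_cell) if ratio_cell is not None else None
            hits.append(
                SearchHit(
                    engine=engine,
                    sample_label=sample_label,
                    file_id=file_id,
                    peptide_sequence=peptide,
                    protein_accessions=accessions,
                    modifications=mods,
                    scores=scores,
                    ratio=ratio,
                )
            )
        except (ValueError, TypeError) as exc:
            reject = RejectedRow(file_id=file_id, row_index=int(idx), reason=str(exc))
            rejects.append(reject)
            if log is not None:
                log.warn(REJECTED_ROW, f"{file_id} row {idx}: {exc}")
    return ParseResult(hits=hits, rejects=rejects)


def write_engine_table(hits: Iterable[SearchHit], path: str | Path, engine: Engine) -> Path:
    """Write SearchHits in the canonical dialect of ``engine`` (inverse of the parser)."""
    path = Path(path)
    engine = Engine(engine)
    dialect = DIALECTS[engine]
    rows = []
    for hit in hits:
        if hit.engine != engine:
            raise ValueError(f"hit from {hit.engine.value} cannot be written as {engine.value}")
        row = {
            dialect.accessions: ";".join(hit.protein_accessions),
            dialect.sequence: hit.peptide_sequence,
            dialect.modifications: dialect.encode_mods(hit.modifications),
        }
        for score_name, column in dialect.score_columns.items():
            row[column] = hit.scores.get(score_name, "")
        row[dialect.ratio] = "" if hit.ratio is None else hit.ratio
        rows.append(row)
    columns = [dialect.accessions, dialect.sequence, dialect.modifications]
    columns += list(dialect.score_columns.values()) + [dialect.ratio]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep=dialect.separator, index=False)
    return path


def apply_filters(
    hits: Sequence[SearchHit],
    cfg: FilterConfig,
    log: RunLog | None = None,
) -> list[SearchHit]:
    """Keep only hits meeting every configured threshold for their engine.

    Order is preserved and the operation is idempotent.  A hit lacking a
    score that a configured threshold references is rejected with a warning
    rather than passed through unchecked.
    """
    kept: list[SearchHit] = []
    for hit in hits:
        checks: list[tuple[str, float, bool]] = []  # (score name, threshold, keep-if-greater)
        if hit.engine == Engine.MASCOT:
            if cfg.mascot_expect_max is not None:
                checks.append(("expect", cfg.mascot_expect_max, False))
            if cfg.mascot_ion_score_min is not None:
                checks.append(("ion_score", cfg.mascot_ion_score_min, True))
        elif hit.engine == Engine.PARAGON:
            if cfg.paragon_confidence_min is not None:
                checks.append(("confidence", cfg.paragon_confidence_min, True))
        if cfg.localization_score_min is not None:
            checks.append(("localization", cfg.localization_score_min, True))

        ok = True
        for score_name, threshold, keep_if_ge in checks:
            if score_name not in hit.scores:
                ok = False
                if log is not None:
                    log.warn(
                        REJECTED_ROW,
                        f"{hit.file_id}: peptide {hit.peptide_sequence} lacks score "
                        f"{score_name!r} referenced by a configured threshold",
                    )
                break
            value = hit.scores[score_name]
            if keep_if_ge:
                ok = value >= threshold
            else:
                ok = value <= threshold
            if not ok:
                break
        if ok:
            kept.append(hit)
    return kept


def discard_unmodified(hits: Sequence[SearchHit], cfg: FilterConfig) -> list[SearchHit]:
    """Drop peptides carrying no modification of a configured type on a target residue."""
    return [
        hit
        for hit in hits
        if any(
            mod.mod_type in cfg.mod_types and mod.residue in cfg.target_residues
            for mod in hit.modifications
        )
    ]


def restrict_modifications(hits: Sequence[SearchHit], cfg: FilterConfig) -> list[SearchHit]:
    """Strip modifications outside the configured types/residues from each hit.

    Applied after :func:`discard_unmodified` so that site sets — the unit of
    comparison — only contain the modification classes under study.
    """
    out = []
    for hit in hits:
        mods = tuple(
            m
            for m in hit.modifications
            if m.mod_type in cfg.mod_types and m.residue in cfg.target_residues
        )
        out.append(hit if mods == hit.modifications else replace(hit, modifications=mods))
    return out


# ---------------------------------------------------------------------------
# FASTA and known-site databases

_UNIPROT_ID = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|]+)\|")
_REFSEQ_GI = re.compile(r"ref\|(?P<acc>[^|]+)\|")


def _detect_dialect(header_id: str) -> str:
    return "uniprot" if _UNIPROT_ID.match(header_id) else "refseq"


def _accession_from_header(header_id: str, dialect: str) -> str:
    if dialect == "uniprot":
        m = _UNIPROT_ID.match(header_id)
        if m:
            return m.group("acc")
    else:
        m = _REFSEQ_GI.search(header_id)
        if m:
            return m.group("acc")
    # bare accession (RefSeq "NP_000001.1 desc" style, or unprefixed headers)
    return header_id.split()[0] if " " in header_id else header_id


def read_fasta(path: str | Path, dialect: str | None = None) -> ProteinDB:
    """Load a protein FASTA into a ProteinDB.

    The header dialect (UniProt ``sp|ACC|NAME`` vs RefSeq ``ref|ACC|`` or
    bare accession) is auto-detected from the first record and can be forced
    with ``dialect``.  Duplicate accessions and empty files are fatal.
    """
    path = Path(path)
    records: dict[str, tuple[str, str]] = {}
    detected: str | None = dialect
    for record in SeqIO.parse(str(path), "fasta"):
        if detected is None:
            detected = _detect_dialect(record.id)
        accession = _accession_from_header(record.id, detected)
        if accession in records:
            raise FormatError(f"{path}: duplicate accession {accession!r}")
        sequence = str(record.seq).upper()
        if not sequence:
            raise FormatError(f"{path}: empty sequence for {accession!r}")
        records[accession] = (sequence, record.description)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return ProteinDB(records=records, dialect=detected or "uniprot")


def write_fasta(db: ProteinDB, path: str | Path) -> Path:
    """Write a ProteinDB as FASTA using its stored header descriptions."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for accession, (sequence, description) in db.records.items():
            fh.write(f">{description}\n")
            for i in range(0, len(sequence), 60):
                fh.write(sequence[i : i + 60] + "\n")
    return path


def read_known_sites(
    path: str | Path,
    source: str | None = None,
    log: RunLog | None = None,
) -> KnownSiteDB:
    """Load a 4-column TSV (accession, position, residue, mod_type) of known sites.

    Duplicate rows collapse to a single entry; malformed rows are rejected
    with a warning.  An empty file yields an empty database, in which case
    every observed site is reported as novel.
    """
    path = Path(path)
    source = source or path.stem
    db = KnownSiteDB()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) != 4:
                    raise ValueError(f"expected 4 columns, got {len(fields)}")
                accession, pos_text, residue, mod_name = (f.strip() for f in fields)
                position = int(pos_text)
                if position < 1:
                    raise ValueError(f"position must be >= 1, got {position}")
                if len(residue) != 1 or not residue.isalpha():
                    raise ValueError(f"invalid residue {residue!r}")
                mod_type = ModType(mod_name.lower())
                db.add((accession, position, residue.upper(), mod_type), source)
            except ValueError as exc:
                if log is not None:
                    log.warn(REJECTED_ROW, f"{path.name} line {lineno}: {exc}")
    return db


def load_known_sites(
    paths: Sequence[str | Path],
    log: RunLog | None = None,
) -> KnownSiteDB:
    """Union several known-site files, retaining which source knew each site."""
    merged = KnownSiteDB()
    for path in paths:
        merged = merged.union(read_known_sites(path, log=log))
    return merged
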