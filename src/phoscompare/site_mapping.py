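"""Mapping modified peptides onto protein sequence coordinates.

Peptide-relative modification positions are translated to absolute,
1-based protein coordinates ("Ser-3" convention).  Peptides whose sequence
occurs in more than one database protein, or more than once within one
protein, are flagged ``multi_match`` and logged; they still appear in the
report but are excluded from unique-phosphoprotein attribution downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

from phoscompare.io_formats import ProteinDB, SearchHit
from phoscompare.model import ModType
from phoscompare.runlog import MULTI_MATCH, UNMAPPED_PEPTIDE, RunLog


@dataclass(frozen=True, order=True)
class SiteAssignment:
    """A modification anchored to an absolute protein coordinate (1-based)."""

    accession: str
    protein_position: int
    residue: str
    mod_type: ModType


@dataclass(frozen=True)
class MappedPeptide:
    """A SearchHit located in a protein, with sites in protein coordinates.

    ``start``/``end`` are 1-based inclusive; ``multi_match`` is set when the
    peptide sequence occurs at more than one place in the proteome.
    ``matched_accessions`` lists every database protein containing the
    sequence; the first resolvable reported accession is the primary one.
    """

    hit: SearchHit
    accession: str
    start: int
    end: int
    sites: tuple[SiteAssignment, ...]
    multi_match: bool
    matched_accessions: tuple[str, ...] = ()


def locate_peptide(peptide: str, protein: str) -> list[int]:
    """All 1-based start positions of ``peptide`` in ``protein``, ascending.

    Overlapping occurrences are enumerated.
    """
    positions: list[int] = []
    i = protein.find(peptide)
    while i != -1:
        positions.append(i + 1)
        i = protein.find(peptide, i + 1)
    return positions


def map_hit(hit: SearchHit, db: ProteinDB, log: RunLog | None = None) -> MappedPeptide | None:
    """Locate a hit's peptide in the proteome and translate its sites.

    The peptide is anchored in the first engine-reported accession present
    in the database that actually contains the sequence.  If no reported
    accession resolves, a whole-database scan is attempted: a single
    matching protein rescues the hit (with a warning), anything else leaves
    it unmapped (warning, not fatal).  Within the primary protein the first
    (lowest) occurrence is used for site coordinates.
    """
    peptide = hit.peptide_sequence
    occurrences: list[tuple[str, int]] = []  # (accession, 1-based start), db order
    for accession, (sequence, _desc) in db.records.items():
        for start in locate_peptide(peptide, sequence):
            occurrences.append((accession, start))

    if not occurrences:
        if log is not None:
            log.warn(
                UNMAPPED_PEPTIDE,
                f"{hit.file_id}: peptide {peptide} not found in any database protein "
                f"(reported accessions: {', '.join(hit.protein_accessions)})",
            )
        return None

    matched_accessions = tuple(dict.fromkeys(acc for acc, _ in occurrences))
    primary: str | None = None
    for accession in hit.protein_accessions:
        if accession in matched_accessions:
            primary = accession
            break
    if primary is None:
        # reported accessions absent from (or not containing the peptide in)
        # the FASTA: rescue only when the scan is unambiguous
        if len(matched_accessions) == 1:
            primary = matched_accessions[0]
            if log is not None:
                log.warn(
                    UNMAPPED_PEPTIDE,
                    f"{hit.file_id}: reported accession(s) "
                    f"{', '.join(hit.protein_accessions)} did not resolve for peptide "
                    f"{peptide}; rescued to {primary}",
                )
        else:
            if log is not None:
                log.warn(
                    UNMAPPED_PEPTIDE,
                    f"{hit.file_id}: peptide {peptide} matches multiple proteins "
                    f"({', '.join(matched_accessions)}) and none of its reported "
                    f"accession(s) resolve; left unmapped",
                )
            return None

    start = min(pos for acc, pos in occurrences if acc == primary)
    multi_match = len(occurrences) > 1
    if multi_match and log is not None:
        places = ", ".join(f"{acc}:{pos}" for acc, pos in occurrences)
        log.warn(MULTI_MATCH, f"{hit.file_id}: peptide {peptide} matches {places}")

    sites = tuple(
        sorted(
            SiteAssignment(
                accession=primary,
                protein_position=start + mod.position - 1,
                residue=mod.residue,
                mod_type=mod.mod_type,
            )
            for mod in hit.modifications
        )
    )
    return MappedPeptide(
        hit=hit,
        accession=primary,
        start=start,
        end=start + len(peptide) - 1,
        sites=sites,
        multi_match=multi_match,
        matched_accessions=matched_accessions,
    )
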