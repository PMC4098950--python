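"""Site novelty annotation and modified-residue bookkeeping.

A site is *novel* when no loaded known-site database lists the exact
(accession, position, residue, modification type) tuple.  Matching requires
residue agreement, not just position, which guards against coordinate drift
between sequence-database versions.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping, Sequence

from phoscompare.comparison import PhosphoEvent
from phoscompare.io_formats import KnownSiteDB
from phoscompare.site_mapping import SiteAssignment

DEFAULT_RESIDUES = "STYK"


class Novelty(str, Enum):
    KNOWN = "known"
    NOVEL = "novel"


def annotate_novelty(site: SiteAssignment, db: KnownSiteDB) -> Novelty:
    """KNOWN iff the exact site tuple appears in the union of loaded databases."""
    entry = (site.accession, site.protein_position, site.residue, site.mod_type)
    return Novelty.KNOWN if entry in db.entries else Novelty.NOVEL


def site_sources(site: SiteAssignment, db: KnownSiteDB) -> set[str]:
    """Names of the source databases that list this site (empty if novel)."""
    return db.sources_for((site.accession, site.protein_position, site.residue, site.mod_type))


def count_modified_residues(
    event: PhosphoEvent,
    residues: str = DEFAULT_RESIDUES,
) -> dict[str, int]:
    """Counts of modified residues in the event's site set, by residue letter.

    Residues listed in ``residues`` always appear (possibly 0); residues in
    the site set but outside that list are reported too.
    """
    counts = {r: 0 for r in residues}
    for _pos, residue, _mt in event.site_set:
        counts[residue] = counts.get(residue, 0) + 1
    return counts


def residue_fraction_percents(
    counts: Mapping[str, int],
) -> dict[str, tuple[int, float]]:
    """Per-residue (count, percent of all modified residues) at one decimal.

    Percentages are presented sum-preservingly: every category is rounded to
    one decimal except the smallest nonzero one, which absorbs the rounding
    residual so the column totals exactly 100.0 (the usual convention for
    published composition tables).  A zero total yields 0.0% everywhere
    rather than a division error.
    """
    total = sum(counts.values())
    if total == 0:
        return {residue: (count, 0.0) for residue, count in counts.items()}
    percents = {
        residue: round(100.0 * count / total, 1) for residue, count in counts.items()
    }
    nonzero = [r for r, c in counts.items() if c > 0]
    smallest = min(nonzero, key=lambda r: (counts[r], r))
    others = sum(p for r, p in percents.items() if r != smallest)
    adjusted = round(100.0 - others, 1)
    if adjusted >= 0:
        percents[smallest] = adjusted
    return {residue: (counts[residue], percents[residue]) for residue in counts}


def summarize_residue_fractions(
    events: Sequence[PhosphoEvent],
    residues: str = DEFAULT_RESIDUES,
) -> dict[str, tuple[int, float]]:
    """Dataset-wide modified-residue counts and percents over non-redundant events."""
    totals = {r: 0 for r in residues}
    for event in events:
        for residue, count in count_modified_residues(event, residues).items():
            totals[residue] = totals.get(residue, 0) + count
    return residue_fraction_percents(totals)
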