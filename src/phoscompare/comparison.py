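"""Phosphosite equivalence classes and case/control uniqueness classification.

The unit of comparison is the *event*: all mapped peptides on one protein
whose modified-site sets are identical, regardless of peptide length.  Two
overlapping tryptic peptides carrying the same phosphoserine are therefore
one event with two members, and the report shows their shared sequence.

Classification follows a multi-engine consensus rule: an event is unique to
the case sample only if at least one search engine detected it in the case
sample and *no* engine detected it in the control sample (and symmetrically
for control); everything else is common.

Quantitative experiments (iTRAQ/SILAC-style pooled samples) carry a
case/control abundance ratio per peptide instead of separate sample runs.
Ratios above/below user cutoffs re-label the peptide as if it had been
identified qualitatively in only the case/only the control sample; ratios
inside the neutral band count as present in both, so the event is common.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from phoscompare.io_formats import ProteinDB, SearchHit
from phoscompare.model import Engine, ModType, Sample
from phoscompare.runlog import EMPTY_SHARED_INTERVAL, MISSING_RATIO, RunLog
from phoscompare.site_mapping import MappedPeptide

SiteKey = tuple[int, str, ModType]  # (protein_position, residue, mod_type)


class UniquenessStatus(str, Enum):
    """Exactly one status per event: unique to a sample, or common to both."""

    UNIQUE_CASE = "unique_case"
    UNIQUE_CONTROL = "unique_control"
    COMMON = "common"


class QuantLabel(str, Enum):
    """Presence call derived from an abundance ratio in quantitative mode."""

    AS_CASE = "as_case"
    AS_CONTROL = "as_control"
    NEITHER = "neither"


@dataclass(frozen=True)
class QuantConfig:
    """Fold-change cutoffs for quantitative mode.

    Ratios strictly above ``case_ratio_min`` count as case-enriched, ratios
    strictly below ``control_ratio_max`` as control-enriched.  The defaults
    are sqrt(2) and 1/sqrt(2): a half-log2-fold band around parity.
    """

    case_ratio_min: float = 1.414
    control_ratio_max: float = 0.707

    def __post_init__(self) -> None:
        if not (0 < self.control_ratio_max < 1 < self.case_ratio_min):
            raise ValueError(
                "require 0 < control_ratio_max < 1 < case_ratio_min, got "
                f"({self.case_ratio_min}, {self.control_ratio_max})"
            )


@dataclass
class PhosphoEvent:
    """Equivalence class of mapped peptides sharing a protein and exact site set."""

    accession: str
    site_set: frozenset[SiteKey]
    members: list[MappedPeptide]
    shared_start: int
    shared_end: int
    shared_sequence: str

    @property
    def mod_types(self) -> frozenset[ModType]:
        return frozenset(mt for _, _, mt in self.site_set)

    @property
    def multi_match(self) -> bool:
        """True if any member peptide matched more than one place in the proteome."""
        return any(m.multi_match for m in self.members)


@dataclass
class PresenceMatrix:
    """Engine x sample detection counts for one event."""

    detected: dict[tuple[Engine, Sample], int] = field(default_factory=dict)

    @classmethod
    def from_event(cls, event: PhosphoEvent) -> "PresenceMatrix":
        pm = cls()
        for member in event.members:
            key = (member.hit.engine, member.hit.sample_label)
            pm.detected[key] = pm.detected.get(key, 0) + 1
        return pm

    def total(self, sample: Sample) -> int:
        return sum(n for (eng, smp), n in self.detected.items() if smp == sample)

    def engines_detecting(self) -> set[Engine]:
        return {eng for (eng, _smp), n in self.detected.items() if n > 0}

    def grand_total(self) -> int:
        return sum(self.detected.values())


def site_key(assignment) -> SiteKey:
    return (assignment.protein_position, assignment.residue, assignment.mod_type)


def build_events(
    mapped: Sequence[MappedPeptide],
    db: ProteinDB,
    log: RunLog | None = None,
) -> list[PhosphoEvent]:
    """Group mapped peptides into events by (protein, exact modified-site set).

    The shared interval is the intersection of the member peptides' protein
    intervals; because every member contains every site, the intersection
    always covers the site set when it is non-empty.  Should members ever
    fail to overlap, the minimal interval covering all sites is used and a
    warning emitted.
    """
    groups: dict[tuple[str, frozenset[SiteKey]], list[MappedPeptide]] = {}
    for mp in mapped:
        key = (mp.accession, frozenset(site_key(s) for s in mp.sites))
        groups.setdefault(key, []).append(mp)

    events: list[PhosphoEvent] = []
    for (accession, sites), members in groups.items():
        shared_start = max(m.start for m in members)
        shared_end = min(m.end for m in members)
        positions = [pos for pos, _res, _mt in sites]
        if shared_start > shared_end or (
            positions and not all(shared_start <= p <= shared_end for p in positions)
        ):
            shared_start, shared_end = min(positions), max(positions)
            if log is not None:
                log.warn(
                    EMPTY_SHARED_INTERVAL,
                    f"{accession}: member intervals do not overlap; falling back to "
                    f"minimal site-covering interval [{shared_start}, {shared_end}]",
                )
        sequence = db.sequence(accession)[shared_start - 1 : shared_end]
        events.append(
            PhosphoEvent(
                accession=accession,
                site_set=sites,
                members=members,
                shared_start=shared_start,
                shared_end=shared_end,
                shared_sequence=sequence,
            )
        )
    return events


def classify_uniqueness(pm: PresenceMatrix) -> UniquenessStatus:
    """Apply the multi-engine consensus rule to one event's presence matrix."""
    case_n = pm.total(Sample.CASE)
    control_n = pm.total(Sample.CONTROL)
    if case_n + control_n == 0:
        raise ValueError("event with an all-zero presence matrix is ill-formed")
    if case_n >= 1 and control_n == 0:
        return UniquenessStatus.UNIQUE_CASE
    if control_n >= 1 and case_n == 0:
        return UniquenessStatus.UNIQUE_CONTROL
    return UniquenessStatus.COMMON


def classify_events(
    events: Sequence[PhosphoEvent],
) -> list[tuple[PhosphoEvent, UniquenessStatus]]:
    """Classify every event; the statuses partition the event list."""
    return [(ev, classify_uniqueness(PresenceMatrix.from_event(ev))) for ev in events]


def quantify_presence(
    hit: SearchHit,
    qc: QuantConfig,
    log: RunLog | None = None,
) -> QuantLabel:
    """Turn a hit's abundance ratio into a presence call.

    Missing or non-positive ratios yield NEITHER with a warning, which in
    re-labeling places the peptide in both samples (the conservative call).
    """
    if hit.ratio is None or hit.ratio <= 0:
        if log is not None:
            log.warn(
                MISSING_RATIO,
                f"{hit.file_id}: peptide {hit.peptide_sequence} has "
                f"{'no' if hit.ratio is None else 'non-positive'} abundance ratio",
            )
        return QuantLabel.NEITHER
    if hit.ratio > qc.case_ratio_min:
        return QuantLabel.AS_CASE
    if hit.ratio < qc.control_ratio_max:
        return QuantLabel.AS_CONTROL
    return QuantLabel.NEITHER


def apply_quant_labels(
    hits: Sequence[SearchHit],
    qc: QuantConfig,
    log: RunLog | None = None,
) -> list[SearchHit]:
    """Re-label hits by their ratio call before event building.

    Case-enriched peptides become case detections, control-enriched become
    control detections; peptides in the neutral band are duplicated into
    both samples so their events classify as common.
    """
    out: list[SearchHit] = []
    for hit in hits:
        label = quantify_presence(hit, qc, log=log)
        if label is QuantLabel.AS_CASE:
            out.append(replace(hit, sample_label=Sample.CASE))
        elif label is QuantLabel.AS_CONTROL:
            out.append(replace(hit, sample_label=Sample.CONTROL))
        else:
            out.append(replace(hit, sample_label=Sample.CASE))
            out.append(replace(hit, sample_label=Sample.CONTROL))
    return out


def unique_phosphoproteins(
    classified: Sequence[tuple[PhosphoEvent, UniquenessStatus]],
) -> dict[Sample, set[str]]:
    """Proteins owning at least one sample-unique event that maps unambiguously.

    An event contributes only if every member peptide matched a single
    place in the proteome (``multi_match`` false throughout); a protein may
    appear in both samples' sets when it has distinct unique events in each
    — those are the proteins with between-sample differences in
    phosphorylation sites.
    """
    result: dict[Sample, set[str]] = {Sample.CASE: set(), Sample.CONTROL: set()}
    for event, status in classified:
        if event.multi_match:
            continue
        if status is UniquenessStatus.UNIQUE_CASE:
            result[Sample.CASE].add(event.accession)
        elif status is UniquenessStatus.UNIQUE_CONTROL:
            result[Sample.CONTROL].add(event.accession)
    return result


def engine_partition(
    classified: Sequence[tuple[PhosphoEvent, UniquenessStatus]],
) -> dict[Engine, tuple[list[PhosphoEvent], list[PhosphoEvent]]]:
    """Per-engine (detected, detected-only-by-this-engine) event lists.

    The "only" lists are pairwise disjoint; together they expose which
    identifications are supported by multiple engines and which are
    engine-specific.
    """
    engines: list[Engine] = []
    for event, _status in classified:
        for eng in PresenceMatrix.from_event(event).engines_detecting():
            if eng not in engines:
                engines.append(eng)
    partition: dict[Engine, tuple[list[PhosphoEvent], list[PhosphoEvent]]] = {
        eng: ([], []) for eng in sorted(engines, key=lambda e: e.value)
    }
    for event, _status in classified:
        detecting = PresenceMatrix.from_event(event).engines_detecting()
        for eng in detecting:
            partition[eng][0].append(event)
            if len(detecting) == 1:
                partition[eng][1].append(event)
    return partition
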