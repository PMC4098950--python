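"""Report generation: HTML comparison report, TSVs, engine statistics, warning log.

The tab-separated report is the primary machine-readable surface; the HTML
document renders the same rows with the conventional colour coding (case-
unique red, control-unique blue, common black; novel sites bold; modified
residues underlined) while carrying every field redundantly in ``data-``
attributes so downstream consumers never have to interpret styling.
"""

from __future__ import annotations

import html as html_mod
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from phoscompare.annotation import (
    DEFAULT_RESIDUES,
    Novelty,
    annotate_novelty,
    count_modified_residues,
)
from phoscompare.comparison import (
    PhosphoEvent,
    PresenceMatrix,
    UniquenessStatus,
    unique_phosphoproteins,
)
from phoscompare.io_formats import KnownSiteDB, ProteinDB
from phoscompare.model import Engine, ModType, Sample
from phoscompare.runlog import RunLog
from phoscompare.site_mapping import SiteAssignment


@dataclass
class ComparisonRow:
    """One report line per phosphosite equivalence class."""

    accession: str
    description: str
    shared_sequence: str
    shared_start: int
    shared_end: int
    # (position, residue, mod_type, novelty, sources) per site, ascending
    sites: tuple[tuple[int, str, ModType, Novelty, tuple[str, ...]], ...]
    detections: dict[tuple[Engine, Sample], int]
    status: UniquenessStatus
    residue_counts: dict[str, int]
    n_peptides: int
    multi_match: bool


def build_rows(
    classified: Sequence[tuple[PhosphoEvent, UniquenessStatus]],
    db: ProteinDB,
    known: KnownSiteDB | None = None,
    residues: str = DEFAULT_RESIDUES,
) -> list[ComparisonRow]:
    """Assemble annotated report rows, sorted by protein and position."""
    known = known or KnownSiteDB()
    rows: list[ComparisonRow] = []
    for event, status in classified:
        site_fields = []
        for pos, residue, mod_type in sorted(event.site_set):
            sa = SiteAssignment(event.accession, pos, residue, mod_type)
            novelty = annotate_novelty(sa, known)
            sources = tuple(sorted(known.sources_for((event.accession, pos, residue, mod_type))))
            site_fields.append((pos, residue, mod_type, novelty, sources))
        rows.append(
            ComparisonRow(
                accession=event.accession,
                description=db.description(event.accession),
                shared_sequence=event.shared_sequence,
                shared_start=event.shared_start,
                shared_end=event.shared_end,
                sites=tuple(site_fields),
                detections=dict(PresenceMatrix.from_event(event).detected),
                status=status,
                residue_counts=count_modified_residues(event, residues),
                n_peptides=len(event.members),
                multi_match=event.multi_match,
            )
        )
    rows.sort(key=lambda r: (r.accession, r.shared_start, tuple(s[0] for s in r.sites)))
    return rows


def summarize(
    classified: Sequence[tuple[PhosphoEvent, UniquenessStatus]],
) -> dict[str, int]:
    """Headline totals: peptide-class counts per status and unique-protein counts.

    ``overlap_proteins`` counts proteins present in both samples' unique
    sets — proteins identified in both samples but with differences in
    their phosphorylation sites.
    """
    counts = {status: 0 for status in UniquenessStatus}
    for _event, status in classified:
        counts[status] += 1
    proteins = unique_phosphoproteins(classified)
    return {
        "unique_case_peptides": counts[UniquenessStatus.UNIQUE_CASE],
        "unique_control_peptides": counts[UniquenessStatus.UNIQUE_CONTROL],
        "common_peptides": counts[UniquenessStatus.COMMON],
        "total_peptides": len(classified),
        "unique_case_proteins": len(proteins[Sample.CASE]),
        "unique_control_proteins": len(proteins[Sample.CONTROL]),
        "overlap_proteins": len(proteins[Sample.CASE] & proteins[Sample.CONTROL]),
    }


# ---------------------------------------------------------------------------
# serialization helpers

def _format_sites(row: ComparisonRow) -> str:
    parts = []
    for pos, residue, mod_type, novelty, sources in row.sites:
        text = f"{residue}{pos}:{mod_type.value}:{novelty.value}"
        if sources:
            text += f"({','.join(sources)})"
        parts.append(text)
    return ";".join(parts)


def _engines_in(rows: Sequence[ComparisonRow]) -> list[Engine]:
    seen = {eng for row in rows for (eng, _smp) in row.detections}
    return sorted(seen, key=lambda e: e.value)


def _detection_columns(engines: Sequence[Engine]) -> list[tuple[Engine, Sample]]:
    return [(eng, smp) for eng in engines for smp in (Sample.CASE, Sample.CONTROL)]


def write_tsv(
    rows: Sequence[ComparisonRow],
    path: str | Path,
    engines: Sequence[Engine] | None = None,
    residues: str = DEFAULT_RESIDUES,
) -> Path:
    """Write the machine-readable report: UTF-8, header row, one event per row.

    Output is byte-identical for identical inputs.
    """
    path = Path(path)
    engines = list(engines) if engines is not None else _engines_in(rows)
    det_cols = _detection_columns(engines)
    header = (
        ["accession", "description", "status", "shared_sequence", "shared_start", "shared_end", "sites", "n_peptides"]
        + [f"n_{eng.value}_{smp.value}" for eng, smp in det_cols]
        + [f"n_{r}" for r in residues]
        + ["multi_match"]
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fields = [
                row.accession,
                row.description,
                row.status.value,
                row.shared_sequence,
                str(row.shared_start),
                str(row.shared_end),
                _format_sites(row),
                str(row.n_peptides),
            ]
            fields += [str(row.detections.get(col, 0)) for col in det_cols]
            fields += [str(row.residue_counts.get(r, 0)) for r in residues]
            fields.append("yes" if row.multi_match else "no")
            fh.write("\t".join(fields) + "\n")
    return path


_CSS = """
body { font-family: sans-serif; margin: 1.5em; }
table { border-collapse: collapse; }
th, td { border: 1px solid #999; padding: 2px 8px; font-size: 90%; }
tr.unique_case td { color: #c00000; }
tr.unique_control td { color: #0000c0; }
tr.common td { color: #000000; }
td.seq { font-family: monospace; }
"""


def _marked_sequence(row: ComparisonRow) -> str:
    """Shared sequence with modified residues underlined (novel ones also bold)."""
    marks: dict[int, Novelty] = {}
    for pos, _residue, _mt, novelty, _sources in row.sites:
        idx = pos - row.shared_start
        if 0 <= idx < len(row.shared_sequence):
            marks[idx] = novelty
    out = []
    for i, letter in enumerate(row.shared_sequence):
        letter = html_mod.escape(letter)
        if i in marks:
            inner = f"<u>{letter}</u>"
            if marks[i] is Novelty.NOVEL:
                inner = f"<b>{inner}</b>"
            out.append(inner)
        else:
            out.append(letter)
    return "".join(out)


def render_html(
    rows: Sequence[ComparisonRow],
    summary: Mapping[str, int] | None = None,
    title: str = "Phosphopeptide case/control comparison",
    engines: Sequence[Engine] | None = None,
    residues: str = DEFAULT_RESIDUES,
) -> str:
    """Render the comparison report as a single self-contained HTML document."""
    engines = list(engines) if engines is not None else _engines_in(rows)
    det_cols = _detection_columns(engines)
    esc = html_mod.escape
    parts = [
        "<!DOCTYPE html>",
        '<html lang="en"><head><meta charset="utf-8">',
        f"<title>{esc(title)}</title>",
        f"<style>{_CSS}</style>",
        "</head><body>",
        f"<h1>{esc(title)}</h1>",
    ]
    if summary is not None:
        attrs = " ".join(f'data-{k.replace("_", "-")}="{v}"' for k, v in summary.items())
        parts.append(f'<section id="summary" {attrs}><h2>Summary</h2><ul>')
        for key, value in summary.items():
            parts.append(f"<li>{esc(key.replace('_', ' '))}: {value}</li>")
        parts.append("</ul></section>")
    header_cells = (
        ["Accession", "Protein", "Shared sequence", "Sites", "Peptides"]
        + [f"{eng.value} / {smp.value}" for eng, smp in det_cols]
        + list(residues)
        + ["Status"]
    )
    parts.append('<table id="events"><thead><tr>')
    parts.extend(f"<th>{esc(c)}</th>" for c in header_cells)
    parts.append("</tr></thead><tbody>")
    for row in rows:
        detections = ",".join(
            f"{eng.value}:{smp.value}={row.detections.get((eng, smp), 0)}" for eng, smp in det_cols
        )
        residue_counts = ",".join(f"{r}={row.residue_counts.get(r, 0)}" for r in residues)
        attrs = {
            "data-accession": row.accession,
            "data-description": row.description,
            "data-status": row.status.value,
            "data-sequence": row.shared_sequence,
            "data-start": str(row.shared_start),
            "data-end": str(row.shared_end),
            "data-sites": _format_sites(row),
            "data-detections": detections,
            "data-n-peptides": str(row.n_peptides),
            "data-residue-counts": residue_counts,
            "data-multi-match": "yes" if row.multi_match else "no",
        }
        attr_text = " ".join(f'{k}="{esc(v)}"' for k, v in attrs.items())
        parts.append(f'<tr class="{row.status.value}" {attr_text}>')
        site_text = "; ".join(
            (f"<b>{residue}{pos}</b>" if novelty is Novelty.NOVEL else f"{residue}{pos}")
            + f" ({mt.value})"
            for pos, residue, mt, novelty, _src in row.sites
        )
        cells = [
            esc(row.accession),
            esc(row.description),
            f'<span class="seq">{_marked_sequence(row)}</span>',
            site_text,
            str(row.n_peptides),
        ]
        cells += [str(row.detections.get(col, 0)) for col in det_cols]
        cells += [str(row.residue_counts.get(r, 0)) for r in residues]
        cells.append(row.status.value)
        parts.extend(f"<td>{c}</td>" for c in cells)
        parts.append("</tr>")
    parts.append("</tbody></table></body></html>")
    return "\n".join(parts)


def write_engine_stats(
    classified: Sequence[tuple[PhosphoEvent, UniquenessStatus]],
    out_dir: str | Path,
) -> dict[Engine, Path]:
    """One TSV per engine: all modified peptide classes that engine identified,
    plus the uniquely modified proteins attributable under its detections.

    Rows are tagged ``peptide`` or ``unique_protein`` in the first column;
    the ``only_this_engine`` flag marks engine-specific identifications.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from phoscompare.comparison import engine_partition

    partition = engine_partition(classified)
    status_of = {id(ev): status for ev, status in classified}
    paths: dict[Engine, Path] = {}
    for engine, (detected, only) in partition.items():
        only_ids = {id(ev) for ev in only}
        path = out_dir / f"engine_stats_{engine.value}.tsv"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("record\taccession\tsites\tshared_sequence\tstatus\tonly_this_engine\tsample\n")
            pep_rows = []
            for ev in detected:
                sites = ";".join(f"{res}{pos}:{mt.value}" for pos, res, mt in sorted(ev.site_set))
                pep_rows.append(
                    (
                        "peptide",
                        ev.accession,
                        sites,
                        ev.shared_sequence,
                        status_of[id(ev)].value,
                        "yes" if id(ev) in only_ids else "no",
                        "",
                    )
                )
            prot_rows = set()
            for ev in detected:
                status = status_of[id(ev)]
                if ev.multi_match or status is UniquenessStatus.COMMON:
                    continue
                sample = (
                    Sample.CASE if status is UniquenessStatus.UNIQUE_CASE else Sample.CONTROL
                )
                prot_rows.add(("unique_protein", ev.accession, "", "", "", "", sample.value))
            for row in sorted(pep_rows) + sorted(prot_rows):
                fh.write("\t".join(row) + "\n")
        paths[engine] = path
    return paths


def write_log(log: RunLog, path: str | Path) -> Path:
    """Write the plain-text warning log (one tagged line per warning, input order)."""
    return log.write(path)


def write_summary_tsv(summary: Mapping[str, int], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("quantity\tcount\n")
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")
    return path
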