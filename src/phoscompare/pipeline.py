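"""Run orchestration: parse -> filter -> discard unmodified -> (quant relabel)
-> map -> build events -> classify -> annotate -> report.

The :class:`RunConfig` is the single declarative surface for a comparison
run; the command-line interface builds one from flags or a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from phoscompare import io_formats, reporting
from phoscompare.comparison import (
    PhosphoEvent,
    QuantConfig,
    UniquenessStatus,
    apply_quant_labels,
    build_events,
    classify_events,
)
from phoscompare.io_formats import FilterConfig, KnownSiteDB, ProteinDB
from phoscompare.model import Engine, ModType, Sample
from phoscompare.runlog import UNPARSED_FILE, RunLog
from phoscompare.site_mapping import map_hit


class ConfigError(ValueError):
    """Missing or inconsistent run configuration."""


@dataclass(frozen=True)
class InputFile:
    """One engine export table with its engine attribution and group label."""

    path: Path
    engine: Engine
    sample_label: Sample
    replicate: str | None = None


@dataclass
class RunConfig:
    """Everything a comparison run needs.

    A qualitative run requires at least one case and one control file; a
    quantitative run (pooled/labeled samples carrying abundance ratios)
    requires at least one file of any label, since presence is derived from
    the ratios.  Default score thresholds are Mascot expect <= 0.01 and
    Paragon confidence >= 99; quantitative cutoffs default to >1.414 /
    <0.707 (half a log2 fold change around parity).
    """

    inputs: list[InputFile]
    fasta_path: Path
    known_site_paths: list[Path] = field(default_factory=list)
    filters: FilterConfig = field(
        default_factory=lambda: FilterConfig(mascot_expect_max=0.01, paragon_confidence_min=99.0)
    )
    quant: bool = False
    quant_config: QuantConfig = field(default_factory=QuantConfig)
    out_dir: Path | None = None
    write_html: bool = True
    write_log: bool = True
    title: str = "Phosphopeptide case/control comparison"

    def validate(self) -> None:
        if not self.inputs:
            raise ConfigError("at least one input file is required")
        if not self.quant:
            labels = {inp.sample_label for inp in self.inputs}
            if Sample.CASE not in labels or Sample.CONTROL not in labels:
                raise ConfigError(
                    "a qualitative run requires a minimum of one case file and one control file"
                )
        if self.fasta_path is None:
            raise ConfigError("a protein FASTA file is required for site mapping")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a declarative run description.

        Layout::

            fasta: proteome.fasta
            inputs:
              - {path: mascot_case.csv, engine: mascot, sample: case}
            known_sites: [known_sites.tsv]
            filters: {mascot_expect_max: 0.01, paragon_confidence_min: 99,
                      localization_score_min: null, residues: STYK,
                      mods: [phospho, acetyl]}
            quant: {enabled: false, case_ratio_min: 1.414, control_ratio_max: 0.707}
            output: {dir: out, html: true, log: true}

        Relative paths resolve against the YAML file's directory.
        """
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        inputs = [
            InputFile(
                path=resolve(item["path"]),
                engine=Engine(item["engine"]),
                sample_label=Sample(item.get("sample", "case")),
                replicate=item.get("replicate"),
            )
            for item in raw.get("inputs", [])
        ]
        fraw = raw.get("filters", {}) or {}
        filters = FilterConfig(
            mascot_expect_max=fraw.get("mascot_expect_max", 0.01),
            mascot_ion_score_min=fraw.get("mascot_ion_score_min"),
            paragon_confidence_min=fraw.get("paragon_confidence_min", 99.0),
            localization_score_min=fraw.get("localization_score_min"),
            target_residues=frozenset(fraw.get("residues", "STYK")),
            mod_types=frozenset(ModType(m) for m in fraw.get("mods", ["phospho", "acetyl"])),
        )
        qraw = raw.get("quant", {}) or {}
        oraw = raw.get("output", {}) or {}
        return cls(
            inputs=inputs,
            fasta_path=resolve(raw["fasta"]) if "fasta" in raw else None,
            known_site_paths=[resolve(p) for p in raw.get("known_sites", [])],
            filters=filters,
            quant=bool(qraw.get("enabled", False)),
            quant_config=QuantConfig(
                case_ratio_min=qraw.get("case_ratio_min", 1.414),
                control_ratio_max=qraw.get("control_ratio_max", 0.707),
            ),
            out_dir=resolve(oraw["dir"]) if "dir" in oraw else None,
            write_html=bool(oraw.get("html", True)),
            write_log=bool(oraw.get("log", True)),
        )


@dataclass
class RunResult:
    """Everything a run computed, plus the paths of files it wrote."""

    classified: list[tuple[PhosphoEvent, UniquenessStatus]]
    rows: list[reporting.ComparisonRow]
    summary: dict[str, int]
    db: ProteinDB
    known: KnownSiteDB
    log: RunLog
    outputs: dict[str, Path] = field(default_factory=dict)

    @property
    def events(self) -> list[PhosphoEvent]:
        return [ev for ev, _st in self.classified]


def run(config: RunConfig) -> RunResult:
    """Execute a full comparison run.

    Fatal conditions (missing inputs, unreadable tables, unknown column
    layouts) raise; row-level problems accumulate in the warning log.
    """
    config.validate()
    log = RunLog()

    db = io_formats.read_fasta(config.fasta_path)
    known = io_formats.load_known_sites(config.known_site_paths, log=log)

    hits = []
    for inp in config.inputs:
        try:
            result = io_formats.parse_engine_table(
                inp.path, inp.engine, inp.sample_label, log=log
            )
        except (OSError, io_formats.FormatError) as exc:
            log.warn(UNPARSED_FILE, f"{inp.path}: {exc}")
            raise
        hits.extend(result.hits)

    hits = io_formats.apply_filters(hits, config.filters, log=log)
    hits = io_formats.discard_unmodified(hits, config.filters)
    hits = io_formats.restrict_modifications(hits, config.filters)
    if config.quant:
        hits = apply_quant_labels(hits, config.quant_config, log=log)

    mapped = [mp for hit in hits if (mp := map_hit(hit, db, log=log)) is not None]
    events = build_events(mapped, db, log=log)
    classified = classify_events(events)

    residues = "".join(sorted(config.filters.target_residues, key="STYK".index))
    rows = reporting.build_rows(classified, db, known, residues=residues)
    summary = reporting.summarize(classified)

    outputs: dict[str, Path] = {}
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        engines = sorted({inp.engine for inp in config.inputs}, key=lambda e: e.value)
        outputs["report_tsv"] = reporting.write_tsv(rows, out_dir / "comparison.tsv", engines=engines, residues=residues)
        outputs["summary_tsv"] = reporting.write_summary_tsv(summary, out_dir / "summary.tsv")
        for engine, p in reporting.write_engine_stats(classified, out_dir).items():
            outputs[f"engine_stats_{engine.value}"] = p
        if config.write_html:
            html = reporting.render_html(rows, summary=summary, title=config.title, engines=engines, residues=residues)
            html_path = out_dir / "comparison.html"
            html_path.write_text(html, encoding="utf-8")
            outputs["report_html"] = html_path
        if config.write_log:
            outputs["log"] = reporting.write_log(log, out_dir / "warnings.log")

    return RunResult(
        classified=classified,
        rows=rows,
        summary=summary,
        db=db,
        known=known,
        log=log,
        outputs=outputs,
    )
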