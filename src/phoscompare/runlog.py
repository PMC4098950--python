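"""Run-time warning collection for the plain-text log output.

Non-fatal anomalies (rejected rows, ambiguous peptide mappings, missing
abundance ratios) are recorded here in input order and written out as one
tagged line per warning.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

UNPARSED_FILE = "UNPARSED_FILE"
REJECTED_ROW = "REJECTED_ROW"
MULTI_MATCH = "MULTI_MATCH"
UNMAPPED_PEPTIDE = "UNMAPPED_PEPTIDE"
MISSING_RATIO = "MISSING_RATIO"
EMPTY_SHARED_INTERVAL = "EMPTY_SHARED_INTERVAL"

CATEGORIES = (
    UNPARSED_FILE,
    REJECTED_ROW,
    MULTI_MATCH,
    UNMAPPED_PEPTIDE,
    MISSING_RATIO,
    EMPTY_SHARED_INTERVAL,
)


@dataclass
class RunLog:
    """Ordered collection of categorised warnings emitted during a run."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def warn(self, category: str, message: str) -> None:
        if category not in CATEGORIES:
            raise ValueError(f"unknown warning category: {category}")
        self.entries.append((category, message))

    def count(self, category: str | None = None) -> int:
        if category is None:
            return len(self.entries)
        return sum(1 for cat, _ in self.entries if cat == category)

    def counters(self) -> Counter:
        return Counter(cat for cat, _ in self.entries)

    def write(self, path: str | Path) -> Path:
        """Write one ``CATEGORY<TAB>message`` line per warning, in input order."""
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            for category, message in self.entries:
                fh.write(f"{category}\t{message}\n")
        return path
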