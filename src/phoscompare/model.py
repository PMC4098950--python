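"""Shared enumerations for engines, sample groups and modification types."""

from enum import Enum


class Engine(str, Enum):
    """Database search engine that produced a peptide-spectrum match table."""

    MASCOT = "mascot"
    PARAGON = "paragon"
    SEQUEST_PD = "sequest_pd"


class Sample(str, Enum):
    """Group label attached to every input file: case (treated/stimulated) or control."""

    CASE = "case"
    CONTROL = "control"


class ModType(str, Enum):
    """Post-translational modification classes the comparison tracks."""

    PHOSPHO = "phospho"
    ACETYL = "acetyl"


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
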