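"""Cell population data (CPD) parameter identities.

Modern haematology analysers with a VCS-type cell-analysis module report,
for each leukocyte population, the mean (MN) and standard deviation (SD) of
each measurement channel: impedance volume (V), radio-frequency
conductivity (C), and five light-scatter/absorbance channels (MALS, UMALS,
LMALS, LALS and axial light loss, AL2).  A CPD parameter name therefore has
the canonical form ``{MN|SD}-{channel}-{cell type}``, e.g. ``SD-V-NE`` is
the standard deviation of neutrophil volume.

The core grammar admits 2 statistics x 7 channels x 4 cell types = 56
canonical names.  Cell types are extensible (e.g. basophils on instruments
that report them) via the ``extra_cell_types`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

STATISTICS = ("MN", "SD")
CHANNELS = ("V", "C", "MALS", "UMALS", "LMALS", "LALS", "AL2")
CELL_TYPES = ("NE", "LY", "MO", "EO")

#: Aliases used in the prior CPD literature (Coulter-style shorthand),
#: normalised to the canonical hyphenated form.
PARAMETER_ALIASES: dict[str, str] = {
    "MNV": "MN-V-NE",        # mean neutrophil volume
    "MNV-SD": "SD-V-NE",     # SD of neutrophil volume
    "MNC": "MN-C-NE",
    "MNC-SD": "SD-C-NE",
}


class ParameterParseError(ValueError):
    """Raised when a string cannot be parsed as a CPD parameter name."""


@dataclass(frozen=True, order=True)
class CPDParameter:
    """Parsed identity of one CPD parameter.

    Attributes
    ----------
    statistic : str
        ``"MN"`` (population mean) or ``"SD"`` (population standard
        deviation).
    channel : str
        Measurement channel: ``V``, ``C``, ``MALS``, ``UMALS``, ``LMALS``,
        ``LALS`` or ``AL2``.
    cell_type : str
        Leukocyte population: ``NE``, ``LY``, ``MO``, ``EO`` or a
        registered extra cell type.
    """

    statistic: str
    channel: str
    cell_type: str

    def __str__(self) -> str:
        return f"{self.statistic}-{self.channel}-{self.cell_type}"

    @property
    def name(self) -> str:
        """Canonical hyphenated name, e.g. ``"SD-V-NE"``."""
        return str(self)


def parse_parameter(
    name: str, extra_cell_types: Iterable[str] = ()
) -> CPDParameter:
    """Parse a CPD parameter name into its (statistic, channel, cell type).

    Accepts hyphen or underscore separators and any letter case; known
    literature aliases (``MNV``, ``MNV-SD``, ...) are normalised.  Unknown
    tokens are rejected with an error naming the offending token.

    Parameters
    ----------
    name : str
        Parameter name such as ``"SD-V-NE"`` or ``"sd_v_ne"``.
    extra_cell_types : iterable of str
        Additional cell-type tokens to accept beyond NE/LY/MO/EO.

    Returns
    -------
    CPDParameter
    """
    if not isinstance(name, str):
        raise ParameterParseError(f"parameter name must be a string, got {name!r}")
    cleaned = name.strip().upper().replace("_", "-")
    cleaned = PARAMETER_ALIASES.get(cleaned, cleaned)
    tokens = cleaned.split("-")
    if len(tokens) != 3:
        raise ParameterParseError(
            f"{name!r}: expected 3 tokens (statistic-channel-celltype), got {len(tokens)}"
        )
    statistic, channel, cell_type = tokens
    if statistic not in STATISTICS:
        raise ParameterParseError(f"{name!r}: unknown statistic {statistic!r}")
    if channel not in CHANNELS:
        raise ParameterParseError(f"{name!r}: unknown channel {channel!r}")
    allowed_cells = set(CELL_TYPES) | {c.upper() for c in extra_cell_types}
    if cell_type not in allowed_cells:
        raise ParameterParseError(f"{name!r}: unknown cell type {cell_type!r}")
    return CPDParameter(statistic, channel, cell_type)


def is_parameter_name(name: str, extra_cell_types: Iterable[str] = ()) -> bool:
    """True if ``name`` parses as a CPD parameter."""
    try:
        parse_parameter(name, extra_cell_types)
        return True
    except ParameterParseError:
        return False


def canonical_parameters(
    extra_cell_types: Iterable[str] = (),
) -> list[CPDParameter]:
    """All canonical parameters of the grammar, in a fixed order.

    With no extra cell types this is the 56-name core roster.
    """
    cells = list(CELL_TYPES) + [c.upper() for c in extra_cell_types]
    return [
        CPDParameter(s, ch, ct)
        for s in STATISTICS
        for ch in CHANNELS
        for ct in cells
    ]
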