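"""Exception hierarchy for hybridiag.

Data-quality problems found while *validating* objects are returned as
violation values (see :func:`hybridiag.panel_model.validate_panel`); exceptions
are reserved for inputs that cannot be represented at all (bad files, codes
outside the panel, impossible band patterns).
"""


class HybridiagError(Exception):
    """Base class for all package errors."""


class PanelError(HybridiagError):
    """A marker panel is malformed beyond what a validation report can express."""


class GenotypeTableError(HybridiagError):
    """A genotype CSV could not be parsed or validated.

    Carries ``line`` (1-based file line number) when the problem is tied to a
    specific row.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class BandDecodeError(HybridiagError):
    """An observed gel band pattern cannot be decoded into a genotype."""


class SimulationError(HybridiagError):
    """A cross specification or simulation configuration is invalid."""
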