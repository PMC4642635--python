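"""Exception hierarchy.

All data-level failures raise :class:`HapshareError` subclasses so the CLI
can map them to a single exit code; programming errors propagate as usual.
"""


class HapshareError(Exception):
    """Base class for all data and model errors raised by hapshare."""


class ParseError(HapshareError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{message}" + (f" ({loc})" if loc else ""))
        self.path = path
        self.line = line


class ModelError(HapshareError):
    """Structurally invalid APFA or an operation on an incompatible model."""


class InvalidPathError(ModelError):
    """A haplotype path is disconnected or does not exist in the model."""


class UntraceableHaplotypeError(HapshareError):
    """A phased haplotype cannot be traced through the APFA."""

    def __init__(self, individual: str, haplotype: int, level: int, allele: str):
        super().__init__(
            f"haplotype {haplotype} of individual {individual!r} carries allele "
            f"{allele!r} at interval {level}, which no outgoing edge emits"
        )
        self.individual = individual
        self.haplotype = haplotype
        self.level = level
        self.allele = allele


class PedigreeError(HapshareError):
    """Cyclic pedigree, unknown individual id, or inconsistent records."""


class DimensionError(HapshareError):
    """Mismatched shapes, ragged input, or incompatible id sets."""


class NumericalError(HapshareError):
    """Singular or non-positive-definite matrix where SPD is required."""
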