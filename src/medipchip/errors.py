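"""Exception hierarchy shared across the pipeline.

``ConfigError`` maps to CLI exit code 2 and ``FormatError`` to exit code 3;
everything else is an ordinary failure (exit 1).
"""


class MedipChipError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MedipChipError):
    """Invalid run configuration or simulation parameters."""


class SizingError(ConfigError):
    """A synthetic genome too small to place the requested promoters."""


class FormatError(MedipChipError):
    """Malformed input file (FASTA / BED / TSV / GMT)."""


class CoordinateError(MedipChipError):
    """A genomic coordinate outside its contig."""


class AlignmentError(MedipChipError):
    """Probe sets differ across arrays that must share a design."""


class IntegrityError(MedipChipError):
    """Duplicate keys where a table requires unique gene identifiers."""
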