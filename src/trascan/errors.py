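"""Exception hierarchy.

``TrascanError`` is the base for everything the pipeline raises on
purpose; the CLI maps it to exit code 2 (data error) while genuine usage
mistakes exit with 1.
"""


class TrascanError(Exception):
    """Base class for all deliberate pipeline errors."""


class FormatError(TrascanError):
    """A file does not conform to the expected dialect (fatal)."""


class RecordError(TrascanError):
    """A single record is malformed; the message names the line/locus."""


class ReferenceMismatchError(TrascanError):
    """A variant's reference allele disagrees with the genome sequence."""
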