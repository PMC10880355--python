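"""Exception hierarchy.

``DataError`` covers malformed or inconsistent *input data* (bad FASTA,
duplicate chromosome names, infeasible fixture specs); plain ``ValueError``
is reserved for caller contract violations (unsorted input, negative k).
The CLI maps usage errors to exit code 1 and ``DataError`` to exit code 2.
"""


class DataError(Exception):
    """Malformed or inconsistent input data."""


class FastaParseError(DataError):
    """Input is not FASTA-formatted; carries the offending byte offset."""

    def __init__(self, message: str, byte_offset: int):
        super().__init__(f"{message} (byte offset {byte_offset})")
        self.byte_offset = byte_offset
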