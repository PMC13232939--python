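"""Exception hierarchy for the binseq package."""


class BinseqError(Exception):
    """Base class for all binseq errors."""


class EncodingError(BinseqError):
    """A byte in a sequence cannot be encoded under the active scheme."""


class CorruptionError(BinseqError):
    """Decoded data contains a code absent from the decode table."""


class FormatError(BinseqError):
    """A file does not conform to the BQ/VBQ layout (bad magic, size, version...)."""


class CorruptIndexError(FormatError):
    """The trailing VBQ block index fails its magic/integrity checks."""


class IndexPairError(FormatError):
    """The block index does not belong to this file (byte-count mismatch)."""


class BlockCorruptionError(FormatError):
    """A VBQ block payload does not parse into the advertised record count."""


class BlockSizeError(BinseqError):
    """A single record exceeds the virtual block size; a larger block is needed."""


class PairedEndError(BinseqError):
    """Paired-end inputs disagree (unequal record counts or missing mate)."""


class ParallelError(BinseqError):
    """A worker failed; carries the partition that was being processed."""

    def __init__(self, message: str, partition=None):
        super().__init__(message)
        self.partition = partition
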