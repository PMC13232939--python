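"""The in-memory record container shared by the BQ and VBQ readers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass
class SeqRecord:
    """One decoded record.

    ``seq`` holds the primary (first-mate or single-end) sequence as ASCII
    bytes; ``ext`` the extended (second-mate) sequence when the source is
    paired.  Quality strings are raw Phred+33 bytes; ``name``/``ext_name``
    are sequence headers without the leading '@'.  Fields absent from the
    source format are None.
    """

    seq: bytes
    ext: Optional[bytes] = None
    flag: Optional[int] = None
    qual: Optional[bytes] = None
    ext_qual: Optional[bytes] = None
    name: Optional[bytes] = None
    ext_name: Optional[bytes] = None

    @property
    def is_paired(self) -> bool:
        return self.ext is not None

    def total_bases(self) -> int:
        return len(self.seq) + (len(self.ext) if self.ext is not None else 0)
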