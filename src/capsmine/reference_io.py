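"""FASTA indexing and random-access subsequence extraction.

The index is a plain-text file whose first line is ``#`` followed by the
32-hex-digit MD5 of the raw FASTA bytes, and then one tab-delimited line per
sequence with five columns: name, byte offset of the first base, bases per
full line, bases in the last line, total length.  The digest header makes
derived files self-validating caches: a derived file is reused only while its
recorded digest still matches the source file on disk.

Coordinates are 1-based and inclusive throughout, following VCF convention.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "FastaIndexEntry",
    "FastaIndex",
    "build_fasta_index",
    "fetch_subsequence",
    "file_md5",
    "cache_is_valid",
    "read_cache_md5",
]

_MD5_LINE = re.compile(r"^#([0-9a-f]{32})\s*$")


def file_md5(path: str | Path) -> str:
    """MD5 digest (hex) of a file's raw bytes."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass(frozen=True)
class FastaIndexEntry:
    """Index record for one FASTA sequence.

    Attributes
    ----------
    name : str
        Sequence identifier, the header text up to the first whitespace.
    offset : int
        Byte position of the sequence's first base within the FASTA file.
    line_bases : int
        Bases per full sequence line.
    last_line_bases : int
        Bases in the final (possibly short) line.
    length : int
        Total bases.
    """

    name: str
    offset: int
    line_bases: int
    last_line_bases: int
    length: int


class FastaIndex:
    """Random-access view of a FASTA file via its five-column index."""

    def __init__(
        self,
        fasta_path: str | Path,
        entries: list[FastaIndexEntry],
        source_md5: str,
        eol_bytes: int,
    ) -> None:
        self.fasta_path = Path(fasta_path)
        self.entries = list(entries)
        self.by_name = {e.name: e for e in entries}
        self.source_md5 = source_md5
        self._eol = eol_bytes

    def __contains__(self, name: str) -> bool:
        return name in self.by_name

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def length(self, name: str) -> int:
        return self.by_name[name].length

    def save(self, path: str | Path) -> None:
        """Write the index file: '#<md5>' then one tab line per sequence."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"#{self.source_md5}\n")
            for e in self.entries:
                fh.write(
                    f"{e.name}\t{e.offset}\t{e.line_bases}\t"
                    f"{e.last_line_bases}\t{e.length}\n"
                )

    @classmethod
    def load(cls, index_path: str | Path, fasta_path: str | Path) -> "FastaIndex":
        entries: list[FastaIndexEntry] = []
        with open(index_path, encoding="utf-8") as fh:
            first = fh.readline()
            m = _MD5_LINE.match(first)
            if not m:
                raise ValueError(f"{index_path}: missing '#<md5>' header line")
            md5 = m.group(1)
            for line in fh:
                if not line.strip():
                    continue
                name, offset, lb, llb, length = line.rstrip("\n").split("\t")
                entries.append(
                    FastaIndexEntry(name, int(offset), int(lb), int(llb), int(length))
                )
        return cls(fasta_path, entries, md5, _detect_eol(fasta_path))


def _detect_eol(path: str | Path) -> int:
    """Number of bytes in this file's line terminator (1 for LF, 2 for CRLF)."""
    with open(path, "rb") as fh:
        chunk = fh.read(1 << 16)
    i = chunk.find(b"\n")
    if i > 0 and chunk[i - 1 : i] == b"\r":
        return 2
    return 1


def build_fasta_index(fasta_path: str | Path) -> FastaIndex:
    """Scan a FASTA file and build its five-column byte-offset index.

    Every sequence must use one uniform line width, except possibly its last
    line.  An empty file, an empty sequence, or ragged line widths are
    rejected.
    """
    fasta_path = Path(fasta_path)
    entries: list[FastaIndexEntry] = []
    name = None
    offset = line_bases = last_line_bases = length = 0
    # track bytes so offsets count the file's literal line terminators
    pos = 0

    def flush() -> None:
        if name is None:
            return
        if length == 0:
            raise ValueError(f"{fasta_path}: sequence '{name}' is empty")
        entries.append(
            FastaIndexEntry(name, offset, line_bases, last_line_bases, length)
        )

    with open(fasta_path, "rb") as fh:
        for raw in fh:
            nbytes = len(raw)
            line = raw.rstrip(b"\r\n")
            if line.startswith(b">"):
                flush()
                name = line[1:].split()[0].decode() if line[1:].split() else ""
                if not name:
                    raise ValueError(f"{fasta_path}: header with no name at byte {pos}")
                offset = pos + nbytes
                line_bases = last_line_bases = length = 0
            elif line:
                if name is None:
                    raise ValueError(f"{fasta_path}: sequence data before any header")
                n = len(line)
                if line_bases == 0:
                    line_bases = n
                elif last_line_bases != line_bases or n > line_bases:
                    # a full-width line may only follow full-width lines
                    raise ValueError(
                        f"{fasta_path}: non-uniform line widths in sequence '{name}'"
                    )
                last_line_bases = n
                length += n
            pos += nbytes
    flush()
    if not entries:
        raise ValueError(f"{fasta_path}: no sequences found (empty or not FASTA)")
    return FastaIndex(fasta_path, entries, file_md5(fasta_path), _detect_eol(fasta_path))


def fetch_subsequence(
    index: FastaIndex, name: str, start_1based: int, end_1based: int
) -> str:
    """Bases ``start..end`` (1-based, inclusive) of a sequence, uppercased.

    Out-of-range ends are clipped to the sequence, so the returned string may
    be shorter than requested; callers learn actual flank lengths from its
    length.  Softmasked bases are uppercased; non-ACGT letters pass through.
    """
    try:
        entry = index.by_name[name]
    except KeyError:
        raise KeyError(f"sequence '{name}' not present in index") from None
    start = max(1, start_1based)
    end = min(entry.length, end_1based)
    if start > end:
        return ""
    lb = entry.line_bases
    stride = lb + index._eol

    def byte_pos(i: int) -> int:  # i is 1-based base number
        return entry.offset + (i - 1) // lb * stride + (i - 1) % lb

    first, last = byte_pos(start), byte_pos(end)
    with open(index.fasta_path, "rb") as fh:
        fh.seek(first)
        raw = fh.read(last - first + 1)
    return raw.replace(b"\r", b"").replace(b"\n", b"").decode().upper()


def read_cache_md5(derived_path: str | Path) -> str | None:
    """Digest recorded in a derived file's first line, or None."""
    try:
        with open(derived_path, encoding="utf-8") as fh:
            m = _MD5_LINE.match(fh.readline())
    except (OSError, UnicodeDecodeError):
        return None
    return m.group(1) if m else None


def cache_is_valid(derived_path: str | Path, source_path: str | Path) -> bool:
    """True iff the derived file exists and its recorded MD5 matches source."""
    recorded = read_cache_md5(derived_path)
    if recorded is None:
        return False
    try:
        return recorded == file_md5(source_path)
    except OSError:
        return False
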