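"""REBASE (GCG flavor) enzyme parsing and degenerate-site scanning.

A restriction enzyme is represented by its recognition pattern over the 15
IUPAC nucleotide codes plus the annotated cut offsets: an apostrophe marks the
top-strand cut point, an underscore the bottom-strand one (e.g. TaqI is
``T'CGA``).  Enzymes sharing an identical (pattern, cuts) triple — true
isoschizomers — are merged into one :class:`EnzymeGroup` so that one marker
line can list all member names.

Scanning is IUPAC-aware and, by default, runs on both strands: the pattern is
matched against the sequence and against its reverse complement (positions
mapped back).  Palindromic patterns report each physical site once, on the
plus strand.  Any non-ACGT base in the scanned window (e.g. N) fails the
match — an ambiguous reference base is never assumed to be cut.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

__all__ = [
    "EnzymeSpec",
    "EnzymeGroup",
    "SiteHit",
    "IUPAC_CODES",
    "expand_iupac",
    "parse_rebase_gcg",
    "parse_annotated_site",
    "group_enzymes",
    "matches_at",
    "find_sites",
]

#: the 15 standard IUPAC nucleotide codes (Biopython's table minus 'X')
IUPAC_CODES: dict[str, frozenset[str]] = {
    c: frozenset(v) for c, v in ambiguous_dna_values.items() if c != "X"
}


def expand_iupac(code: str) -> set[str]:
    """Concrete bases covered by one IUPAC letter (W -> {A,T}, N -> all four)."""
    try:
        return set(IUPAC_CODES[code.upper()])
    except KeyError:
        raise ValueError(f"unknown IUPAC nucleotide code: {code!r}") from None


def annotate_site(pattern: str, top_cut: int | None, bottom_cut: int | None) -> str:
    """Re-insert cut marks into a pattern: apostrophe = top, underscore = bottom."""
    marks = []
    if top_cut is not None:
        marks.append((top_cut, "'"))
    if bottom_cut is not None:
        marks.append((bottom_cut, "_"))
    out = pattern
    for off, ch in sorted(marks, reverse=True):
        out = out[:off] + ch + out[off:]
    return out


def parse_annotated_site(site: str) -> tuple[str, int | None, int | None]:
    """Split an annotated site like ``T'CGA`` into (pattern, top_cut, bottom_cut)."""
    pattern, top, bottom = [], None, None
    for ch in site:
        if ch == "'":
            top = len(pattern)
        elif ch == "_":
            bottom = len(pattern)
        else:
            pattern.append(ch.upper())
    pat = "".join(pattern)
    if not pat or any(c not in IUPAC_CODES for c in pat):
        raise ValueError(f"not a recognition site: {site!r}")
    return pat, top, bottom


@dataclass(frozen=True)
class EnzymeSpec:
    """One restriction enzyme: name, IUPAC pattern, annotated cut offsets."""

    name: str
    pattern: str
    top_cut: int | None = None
    bottom_cut: int | None = None

    @property
    def annotated_site(self) -> str:
        return annotate_site(self.pattern, self.top_cut, self.bottom_cut)


@dataclass(frozen=True)
class EnzymeGroup:
    """Enzymes sharing an identical (pattern, top_cut, bottom_cut) triple."""

    members: tuple[str, ...]
    pattern: str
    top_cut: int | None = None
    bottom_cut: int | None = None

    @property
    def name(self) -> str:
        return ",".join(self.members)

    @property
    def annotated_site(self) -> str:
        return annotate_site(self.pattern, self.top_cut, self.bottom_cut)

    @property
    def is_palindromic(self) -> bool:
        return self.pattern == reverse_complement(self.pattern)


@dataclass(frozen=True, order=True)
class SiteHit:
    """One recognition-site occurrence: leftmost 0-based offset and strand."""

    start: int
    strand: str = "+"  # "+" or "-"


# candidate site token: IUPAC letters with optional cut marks, no digits
_SITE_TOKEN = re.compile(r"^[ACGTRYSWKMBDHVNacgtryswkmbdhvn'_]+$")


def parse_rebase_gcg(path: str | Path) -> list[EnzymeSpec]:
    """Parse a REBASE enzyme file in the GCG flavor.

    The layout of these files drifts between releases, so the parser is
    anchored on the two fields the algorithm needs: a line is a data record
    when its first token is an enzyme name and some later token is a
    recognition site made of IUPAC letters with optional ' and _ cut marks.
    Comment lines (``;``, ``#``) and records without a parsable site are
    skipped, the latter with a warning.
    """
    path = Path(path)
    enzymes: list[EnzymeSpec] = []
    n_skipped = 0
    with open(path, encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith((";", "#", "!")):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                continue
            name = tokens[0]
            site = next(
                (t for t in tokens[1:] if _SITE_TOKEN.match(t) and any(c.isalpha() for c in t)),
                None,
            )
            if site is None:
                n_skipped += 1
                log.warning("%s:%d: no recognition site for %r, skipped", path, lineno, name)
                continue
            try:
                pattern, top, bottom = parse_annotated_site(site)
            except ValueError:
                n_skipped += 1
                log.warning("%s:%d: unparsable site %r for %r, skipped", path, lineno, site, name)
                continue
            enzymes.append(EnzymeSpec(name, pattern, top, bottom))
    if not enzymes:
        raise ValueError(f"{path}: no enzymes parsed — is this a GCG-flavor REBASE file?")
    log.info("parsed %d enzymes from %s (%d records skipped)", len(enzymes), path, n_skipped)
    return enzymes


def group_enzymes(enzymes: list[EnzymeSpec]) -> list[EnzymeGroup]:
    """Merge isoschizomers: one group per distinct (pattern, cuts) triple."""
    by_key: dict[tuple, list[str]] = {}
    for e in enzymes:
        by_key.setdefault((e.pattern, e.top_cut, e.bottom_cut), []).append(e.name)
    groups = [
        EnzymeGroup(tuple(sorted(set(names))), pattern, top, bottom)
        for (pattern, top, bottom), names in by_key.items()
    ]
    groups.sort(key=lambda g: g.members[0])
    return groups


def matches_at(pattern: str, sequence: str, offset_0based: int) -> bool:
    """True iff ``sequence[offset:offset+len(pattern)]`` fits the IUPAC pattern.

    A non-ACGT base in the window (including N) never matches.
    """
    window = sequence[offset_0based : offset_0based + len(pattern)]
    if len(window) < len(pattern):
        return False
    for p, s in zip(pattern, window.upper()):
        if s not in "ACGT" or s not in IUPAC_CODES[p]:
            return False
    return True


def _pattern_regex(pattern: str) -> re.Pattern[str]:
    # lookahead so overlapping occurrences are all reported; N is [ACGT],
    # never a wildcard, so ambiguous sequence bases cannot match
    body = "".join("[%s]" % "".join(sorted(IUPAC_CODES[c])) for c in pattern)
    return re.compile(f"(?=({body}))")


def find_sites(
    enzyme: EnzymeGroup | EnzymeSpec | str,
    sequence: str,
    scan_minus_strand: bool = True,
) -> list[SiteHit]:
    """All recognition-site occurrences of an enzyme in a sequence.

    Plus-strand hits are direct pattern matches; minus-strand hits are matches
    of the pattern in the reverse complement, mapped back to the leftmost
    coordinate on the input.  Palindromic patterns are scanned on the plus
    strand only, so each physical site is reported once.  The result is sorted
    by start position.
    """
    pattern = enzyme if isinstance(enzyme, str) else enzyme.pattern
    seq = sequence.upper()
    rx = _pattern_regex(pattern)
    hits = [SiteHit(m.start(), "+") for m in rx.finditer(seq)]
    palindromic = pattern == reverse_complement(pattern)
    if scan_minus_strand and not palindromic:
        rc = reverse_complement(seq)
        L, k = len(seq), len(pattern)
        hits += [SiteHit(L - k - m.start(), "-") for m in rx.finditer(rc)]
    return sorted(hits)
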