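"""VCF to V2C conversion: loci, genotype codes, and flank-embedded alleles.

The V2C intermediate format stores, per variant locus, three lines:

1. ``>`` + locus ID (``contig:pos``, 1-based);
2. tab-separated genotypes as allele-code pairs (``0`` = reference allele,
   ``1..k`` = alternatives, ``./.`` = missing);
3. one tab-separated field per allele, each holding comma-separated
   ``allele_seq, allele_len, embedded_seq`` where the embedded sequence is
   the allele flanked by two reference fragments (40 bp by default for the
   mining stage, so a SNP's embedded sequence is 40+1+40 = 81 bp and a 10 bp
   insertion allele's is 40+10+40 = 90 bp).

The file opens with ``#<md5>`` of the source VCF so it can serve as a cache,
plus an optional ``#SAMPLES`` line preserving sample order for downstream
genotype reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from cyvcf2 import VCF

from .reference_io import FastaIndex, fetch_subsequence, file_md5

log = logging.getLogger(__name__)

__all__ = [
    "Locus",
    "AlleleContext",
    "V2CRecord",
    "parse_vcf",
    "build_allele_context",
    "to_v2c_record",
    "write_v2c",
    "read_v2c",
    "MISSING",
]

#: sentinel for a missing allele call
MISSING: None = None


@dataclass
class Locus:
    """One variant record: position, alleles, per-sample genotype code pairs.

    Genotype pairs are unphased and stored sorted (``(0, 1)``, never
    ``(1, 0)``); a missing call is ``(None, None)``.  Half-missing calls are
    treated as fully missing.
    """

    contig: str
    pos: int  # 1-based position of the variant's first base
    ref_allele: str
    alt_alleles: list[str]
    genotypes: list[tuple[int | None, int | None]]
    sample_names: list[str] = field(default_factory=list)

    @property
    def locus_id(self) -> str:
        return f"{self.contig}:{self.pos}"

    @property
    def alleles(self) -> list[str]:
        return [self.ref_allele, *self.alt_alleles]

    @property
    def n_alt(self) -> int:
        return len(self.alt_alleles)

    def observed_alleles(self) -> set[int]:
        """Allele codes appearing in at least one non-missing genotype."""
        out: set[int] = set()
        for a, b in self.genotypes:
            if a is not None:
                out.add(a)
                out.add(b)  # type: ignore[arg-type]
        return out


@dataclass(frozen=True)
class AlleleContext:
    """An allele embedded between two reference flanks."""

    allele_code: int
    allele_seq: str
    embedded_seq: str
    flank_up_len: int
    flank_down_len: int

    @property
    def allele_len(self) -> int:
        return len(self.allele_seq)


def _normalize_gt(raw: list) -> tuple[int | None, int | None]:
    alleles = [a for a in raw[:-1] if isinstance(a, int)]  # last element = phased flag
    if len(alleles) != 2 or any(a < 0 for a in alleles):
        return (MISSING, MISSING)
    a, b = sorted(alleles)
    return (a, b)


def parse_vcf(vcf_path: str | Path, biallelic_only: bool = False) -> Iterator[Locus]:
    """Stream loci from a VCF 4.x file.

    Accepts ``/`` and ``|`` genotype separators (phase is dropped), any
    caller's records, and multi-allelic sites (codes 1..k).  Records with
    symbolic alleles (``<...>``), breakends or ``*`` alleles are skipped with
    a warning; INFO content is ignored entirely.  A VCF whose FORMAT lacks GT
    is rejected.
    """
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    n_skipped = 0
    for v in vcf:
        if v.FORMAT and "GT" not in v.FORMAT:
            raise ValueError(f"{vcf_path}: record {v.CHROM}:{v.POS} has no GT in FORMAT")
        alts = list(v.ALT)
        if not alts or any(
            a.startswith("<") or a == "*" or "[" in a or "]" in a or "." in a
            for a in alts
        ):
            n_skipped += 1
            log.warning("skipping %s:%d: symbolic/breakend/star allele", v.CHROM, v.POS)
            continue
        if biallelic_only and len(alts) != 1:
            n_skipped += 1
            continue
        genotypes = [_normalize_gt(g) for g in v.genotypes]
        yield Locus(v.CHROM, v.POS, v.REF.upper(), [a.upper() for a in alts],
                    genotypes, samples)
    if n_skipped:
        log.info("%s: skipped %d records", vcf_path, n_skipped)


def build_allele_context(
    locus: Locus, reference: FastaIndex, flank_len: int = 40
) -> list[AlleleContext]:
    """Embed every allele of a locus between two reference flanks.

    The upstream flank is ``reference[pos-flank_len .. pos-1]`` and the
    downstream flank ``reference[pos+len(ref) .. pos+len(ref)+flank_len-1]``,
    both clipped at contig boundaries; all alleles share the same flanks.
    The reference allele is checked against the reference bases at the locus
    to guard against a mismatched genome build.
    """
    ref_end = locus.pos + len(locus.ref_allele) - 1
    on_ref = fetch_subsequence(reference, locus.contig, locus.pos, ref_end)
    if on_ref != locus.ref_allele.upper():
        raise ValueError(
            f"{locus.locus_id}: REF allele {locus.ref_allele!r} does not match "
            f"reference bases {on_ref!r} — wrong reference build?"
        )
    up = fetch_subsequence(reference, locus.contig, locus.pos - flank_len, locus.pos - 1)
    down = fetch_subsequence(reference, locus.contig, ref_end + 1, ref_end + flank_len)
    return [
        AlleleContext(code, allele.upper(), up + allele.upper() + down, len(up), len(down))
        for code, allele in enumerate(locus.alleles)
    ]


@dataclass
class V2CRecord:
    """One V2C record: locus ID, genotype pairs, per-allele sequence triples."""

    locus_id: str
    genotypes: list[tuple[int | None, int | None]]
    alleles: list[tuple[str, int, str]]  # (allele_seq, allele_len, embedded_seq)

    @property
    def contig(self) -> str:
        return self.locus_id.rsplit(":", 1)[0]

    @property
    def pos(self) -> int:
        return int(self.locus_id.rsplit(":", 1)[1])

    @property
    def ref_allele(self) -> str:
        return self.alleles[0][0]

    @property
    def alt_alleles(self) -> list[str]:
        return [a[0] for a in self.alleles[1:]]

    def observed_alleles(self) -> set[int]:
        out: set[int] = set()
        for a, b in self.genotypes:
            if a is not None:
                out.add(a)
                out.add(b)  # type: ignore[arg-type]
        return out


def to_v2c_record(locus: Locus, contexts: list[AlleleContext]) -> V2CRecord:
    return V2CRecord(
        locus.locus_id,
        list(locus.genotypes),
        [(c.allele_seq, c.allele_len, c.embedded_seq) for c in contexts],
    )


def _gt_str(gt: tuple[int | None, int | None]) -> str:
    a, b = gt
    return "./." if a is None else f"{a}/{b}"


def _parse_gt(s: str) -> tuple[int | None, int | None]:
    a, b = s.replace("|", "/").split("/")
    if a == "." or b == ".":
        return (MISSING, MISSING)
    x, y = sorted((int(a), int(b)))
    return (x, y)


def write_v2c(
    records: Iterable[V2CRecord],
    path: str | Path,
    vcf_md5: str,
    sample_names: list[str] | None = None,
) -> int:
    """Write V2C records; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#{vcf_md5}\n")
        if sample_names:
            fh.write("#SAMPLES\t" + "\t".join(sample_names) + "\n")
        for rec in records:
            fh.write(f">{rec.locus_id}\n")
            fh.write("\t".join(_gt_str(g) for g in rec.genotypes) + "\n")
            fh.write(
                "\t".join(f"{seq},{length},{embedded}" for seq, length, embedded in rec.alleles)
                + "\n"
            )
            n += 1
    return n


def read_v2c(path: str | Path) -> tuple[str, list[str] | None, list[V2CRecord]]:
    """Read a V2C file back: (source md5, sample names or None, records)."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing '#<md5>' header")
    md5 = lines[0][1:]
    samples: list[str] | None = None
    i = 1
    if i < len(lines) and lines[i].startswith("#SAMPLES\t"):
        samples = lines[i].split("\t")[1:]
        i += 1
    records: list[V2CRecord] = []
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' at line {i + 1}")
        locus_id = lines[i][1:]
        gts = [_parse_gt(s) for s in lines[i + 1].split("\t")] if lines[i + 1] else []
        alleles = []
        for fld in lines[i + 2].split("\t"):
            seq, length, embedded = fld.split(",")
            alleles.append((seq, int(length), embedded))
        records.append(V2CRecord(locus_id, gts, alleles))
        i += 3
    return md5, samples, records


def convert_vcf(
    vcf_path: str | Path,
    reference: FastaIndex,
    out_path: str | Path | None = None,
    flank_len: int = 40,
    biallelic_only: bool = False,
) -> tuple[list[V2CRecord], list[str]]:
    """Full VCF -> V2C conversion; optionally writes the V2C file.

    Returns the records and the VCF sample names.
    """
    records: list[V2CRecord] = []
    samples: list[str] = []
    for locus in parse_vcf(vcf_path, biallelic_only=biallelic_only):
        samples = locus.sample_names
        contexts = build_allele_context(locus, reference, flank_len)
        records.append(to_v2c_record(locus, contexts))
    if out_path is not None:
        write_v2c(records, out_path, file_md5(vcf_path), samples)
    log.info("%s: converted %d loci", vcf_path, len(records))
    return records, samples
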