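"""CAPS marker mining: differential digestion of alleles at a variant locus.

For every locus x enzyme group, each allele's 40 bp-flanked embedded sequence
is scanned for the enzyme's recognition site.  A CAPS marker is emitted when
the alleles actually observed in the population split into at least one
digested and at least one undigested allele — i.e. the variant creates or
destroys a cut site, so a PCR product spanning it can be genotyped on a gel.
Each sample's genotype is then re-expressed as a digestion genotype over
``+`` (cut) and ``-`` (uncut) alleles: ``-/-`` homozygotes run as one band,
``+/+`` as two, ``-/+`` heterozygotes as three (for single-cut markers).

Markers are written in a 4-segment text format: locus ID line, enzyme line
(names plus the annotated recognition site, apostrophe = top-strand cut,
underscore = bottom-strand cut), one tab-separated field per allele
(``ref|alt, [code], allele_seq, [+|-], display context``), and one
tab-separated field per genotype class listing the samples that carry it.
Display contexts are the allele (uppercase) between two reference flanks
(lowercase, 500 bp by default), sized for primer design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .rebase_enzymes import EnzymeGroup, find_sites, parse_annotated_site
from .reference_io import FastaIndex, fetch_subsequence
from .v2c import V2CRecord

log = logging.getLogger(__name__)

__all__ = [
    "MarkerAllele",
    "CapsMarker",
    "allele_is_digested",
    "digestion_genotype",
    "build_output_context",
    "mine_locus",
    "mine",
    "write_caps_output",
    "read_caps_output",
    "markers_to_table",
]

MISSING_GT = "./."
MISSING_DG = "?/?"


@dataclass(frozen=True)
class MarkerAllele:
    """Per-allele record of a marker: tag, code, sequence, cut flag, context."""

    tag: str  # "ref" or "alt"
    code: int
    seq: str
    digested: bool
    context: str = ""  # lowercase flanks + uppercase allele (display/primer window)

    @property
    def flag(self) -> str:
        return "+" if self.digested else "-"


@dataclass
class CapsMarker:
    """A (locus x enzyme-group) pair with per-allele cut flags and genotypes."""

    locus_id: str
    enzyme_names: tuple[str, ...]
    annotated_site: str
    alleles: list[MarkerAllele]
    sample_names: list[str]
    genotypes: list[tuple[int | None, int | None]]

    @property
    def pattern(self) -> str:
        return parse_annotated_site(self.annotated_site)[0]

    @property
    def cut_flags(self) -> dict[int, str]:
        return {a.code: a.flag for a in self.alleles}

    def digestion_genotypes(self) -> list[str]:
        flags = self.cut_flags
        return [digestion_genotype(gt, flags) for gt in self.genotypes]

    def sample_digestion(self) -> dict[str, tuple[str, str]]:
        """sample name -> (numeric genotype string, digestion genotype)."""
        flags = self.cut_flags
        return {
            s: (_gt_str(gt), digestion_genotype(gt, flags))
            for s, gt in zip(self.sample_names, self.genotypes)
        }


def allele_is_digested(
    embedded_seq: str, enzyme: EnzymeGroup, scan_minus_strand: bool = True
) -> bool:
    """True iff the enzyme's recognition site occurs anywhere in the
    flank-embedded allele sequence."""
    return bool(find_sites(enzyme, embedded_seq, scan_minus_strand))


def digestion_genotype(
    gt: tuple[int | None, int | None], cut_flags: dict[int, str]
) -> str:
    """Re-express a numeric genotype in cut/uncut alleles.

    Missing -> ``?/?``; like flags -> ``+/+`` or ``-/-``; mixed -> ``-/+``
    (minus first, the display convention for heterozygotes).
    """
    a, b = gt
    if a is None:
        return MISSING_DG
    try:
        fa, fb = cut_flags[a], cut_flags[b]  # type: ignore[index]
    except KeyError as e:
        raise KeyError(f"allele code {e.args[0]} has no cut flag") from None
    if fa == fb:
        return f"{fa}/{fb}"
    return "-/+"


def build_output_context(
    record: V2CRecord, reference: FastaIndex, out_flank: int = 500
) -> list[str]:
    """Per-allele display sequence: lowercase reference flanks, uppercase allele.

    With unclipped flanks a SNP's context is 500+1+500 = 1001 bp and a 10 bp
    insertion allele's is 500+10+500 = 1010 bp; flanks are clipped at contig
    ends.
    """
    pos, contig = record.pos, record.contig
    ref_end = pos + len(record.ref_allele) - 1
    up = fetch_subsequence(reference, contig, pos - out_flank, pos - 1).lower()
    down = fetch_subsequence(reference, contig, ref_end + 1, ref_end + out_flank).lower()
    return [up + seq.upper() + down for seq, _, _ in record.alleles]


def mine_locus(
    record: V2CRecord,
    enzyme_groups: Sequence[EnzymeGroup],
    sample_names: list[str],
    output_contexts: list[str] | None = None,
    scan_minus_strand: bool = True,
) -> list[CapsMarker]:
    """All CAPS markers at one locus: one per enzyme group whose site is
    present on some observed allele and absent on another.

    Alleles never observed in a non-missing genotype cannot support a marker,
    so they are excluded from the digested/undigested split (but still listed
    in the emitted marker with their cut flags).
    """
    observed = record.observed_alleles()
    if len(observed) < 2:
        return []
    markers: list[CapsMarker] = []
    contexts = output_contexts or [""] * len(record.alleles)
    for group in enzyme_groups:
        digested = [
            allele_is_digested(embedded, group, scan_minus_strand)
            for _, _, embedded in record.alleles
        ]
        if not any(digested[c] for c in observed) or all(digested[c] for c in observed):
            continue
        alleles = [
            MarkerAllele("ref" if code == 0 else "alt", code, seq, digested[code], ctx)
            for code, ((seq, _, _), ctx) in enumerate(zip(record.alleles, contexts))
        ]
        markers.append(
            CapsMarker(
                record.locus_id,
                group.members,
                group.annotated_site,
                alleles,
                sample_names,
                list(record.genotypes),
            )
        )
    return markers


def mine(
    records: Iterable[V2CRecord],
    enzyme_groups: Sequence[EnzymeGroup],
    sample_names: list[str],
    reference: FastaIndex | None = None,
    out_flank: int = 500,
    scan_minus_strand: bool = True,
) -> list[CapsMarker]:
    """Mine all loci; attaches display contexts when a reference is given.

    Output order is deterministic: locus file order, then enzyme group name.
    """
    markers: list[CapsMarker] = []
    n_loci = 0
    for rec in records:
        n_loci += 1
        ctx = build_output_context(rec, reference, out_flank) if reference else None
        markers.extend(
            mine_locus(rec, enzyme_groups, sample_names, ctx, scan_minus_strand)
        )
    log.info("mined %d loci -> %d CAPS markers", n_loci, len(markers))
    return markers


# ---------------------------------------------------------------------------
# 4-segment output format


def _gt_str(gt: tuple[int | None, int | None]) -> str:
    a, b = gt
    return MISSING_GT if a is None else f"{a}/{b}"


def _genotype_fields(marker: CapsMarker) -> list[str]:
    """Group samples by (numeric genotype, digestion genotype), missing last."""
    groups: dict[tuple[int, int] | None, list[str]] = {}
    for s, gt in zip(marker.sample_names, marker.genotypes):
        key = None if gt[0] is None else (gt[0], gt[1])  # type: ignore[arg-type]
        groups.setdefault(key, []).append(s)
    flags = marker.cut_flags
    fields = []
    for key in sorted((k for k in groups if k is not None)) + (
        [None] if None in groups else []
    ):
        gt = (None, None) if key is None else key
        fields.append(
            f"{_gt_str(gt)} [{digestion_genotype(gt, flags)}] " + " ".join(groups[key])
        )
    return fields


def write_caps_output(markers: Iterable[CapsMarker], path: str | Path) -> int:
    """Write markers in the 4-segment format; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in markers:
            fh.write(f">{m.locus_id}\n")
            fh.write(",".join(m.enzyme_names) + "\t" + m.annotated_site + "\n")
            fh.write(
                "\t".join(
                    f"{a.tag}, [{a.code}], {a.seq}, [{a.flag}], {a.context}"
                    for a in m.alleles
                )
                + "\n"
            )
            fh.write("\t".join(_genotype_fields(m)) + "\n")
            n += 1
    return n


def read_caps_output(path: str | Path) -> list[CapsMarker]:
    """Read a 4-segment marker file back into :class:`CapsMarker` objects.

    Sample order follows the grouped genotype fields, so writing the result
    again reproduces the file byte for byte.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    markers: list[CapsMarker] = []
    for i in range(0, len(lines), 4):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' at line {i + 1}")
        locus_id = lines[i][1:]
        names, annotated = lines[i + 1].split("\t")
        alleles = []
        for fld in lines[i + 2].split("\t"):
            tag, code, seq, flag, ctx = fld.split(", ", 4)
            alleles.append(
                MarkerAllele(tag, int(code.strip("[]")), seq, flag.strip("[]") == "+", ctx)
            )
        sample_names: list[str] = []
        genotypes: list[tuple[int | None, int | None]] = []
        for fld in lines[i + 3].split("\t"):
            gt_s, _dg, samples_s = fld.split(" ", 2)
            a, b = gt_s.split("/")
            gt = (None, None) if a == "." else (int(a), int(b))
            for s in samples_s.split(" "):
                if s:
                    sample_names.append(s)
                    genotypes.append(gt)
        markers.append(
            CapsMarker(
                locus_id, tuple(names.split(",")), annotated, alleles,
                sample_names, genotypes,
            )
        )
    return markers


def markers_to_table(markers: Sequence[CapsMarker]) -> pd.DataFrame:
    """One-row-per-marker summary for downstream scripting."""
    rows = []
    for m in markers:
        dgs = m.digestion_genotypes()
        rows.append(
            {
                "locus": m.locus_id,
                "enzymes": ",".join(m.enzyme_names),
                "site": m.annotated_site,
                "allele_flags": ";".join(f"{a.code}:{a.flag}" for a in m.alleles),
                "n_cut_hom": dgs.count("+/+"),
                "n_het": dgs.count("-/+"),
                "n_uncut_hom": dgs.count("-/-"),
                "n_missing": dgs.count(MISSING_DG),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus", "enzymes", "site", "allele_flags",
            "n_cut_hom", "n_het", "n_uncut_hom", "n_missing",
        ],
    )
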