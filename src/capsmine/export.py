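"""FASTA export of marker regions for batch primer design.

For each marker locus, one FASTA record is written: the reference-allele
display context (variant centered between the two reference flanks, flank
length as configured at mining time).  Only the reference allele is exported
— primers are designed on the assembly the user actually has — and loci
carrying several markers (several enzymes) are exported once.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .mining import CapsMarker, build_output_context
from .reference_io import FastaIndex
from .v2c import V2CRecord

log = logging.getLogger(__name__)

__all__ = ["export_fasta", "export_loci_fasta"]


def export_fasta(markers: Iterable[CapsMarker], path: str | Path) -> int:
    """Write one record per marker locus using the attached display contexts.

    Returns the number of records written.  Duplicate loci (one per enzyme)
    are collapsed to the first occurrence.
    """
    seen: set[str] = set()
    records = []
    for m in markers:
        if m.locus_id in seen:
            continue
        seen.add(m.locus_id)
        ref = next(a for a in m.alleles if a.code == 0)
        records.append(SeqRecord(Seq(ref.context), id=m.locus_id, description=""))
    n = SeqIO.write(records, str(path), "fasta")
    log.info("exported %d sequences to %s", n, path)
    return n


def export_loci_fasta(
    records: Iterable[V2CRecord],
    reference: FastaIndex,
    path: str | Path,
    out_flank: int = 500,
) -> int:
    """Export reference-allele contexts straight from V2C records."""
    out = []
    seen: set[str] = set()
    for rec in records:
        if rec.locus_id in seen:
            continue
        seen.add(rec.locus_id)
        ctx = build_output_context(rec, reference, out_flank)[0]
        out.append(SeqRecord(Seq(ctx), id=rec.locus_id, description=""))
    n = SeqIO.write(out, str(path), "fasta")
    log.info("exported %d sequences to %s", n, path)
    return n
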