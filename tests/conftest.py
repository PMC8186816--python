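"""Shared fixtures: small synthetic datasets and an independent site oracle."""

from __future__ import annotations

import itertools
from pathlib import Path

import pytest

from capsmine import default_enzyme_groups, generate_fixture
from capsmine.rebase_enzymes import IUPAC_CODES

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Independent reverse complement (string translation, not the package's)."""
    return seq.translate(_COMPLEMENT)[::-1]


def oracle_find_sites(pattern: str, seq: str) -> list[tuple[int, str]]:
    """Brute-force scanner: expand the pattern to concrete words, substring-
    search both strands.  Palindromic patterns report plus-strand hits only."""
    words = {
        "".join(w)
        for w in itertools.product(*[sorted(IUPAC_CODES[c]) for c in pattern])
    }
    k, L = len(pattern), len(seq)
    hits = [(i, "+") for i in range(L - k + 1) if seq[i : i + k] in words]
    if pattern != revcomp(pattern):
        hits += [(i, "-") for i in range(L - k + 1) if revcomp(seq[i : i + k]) in words]
    return sorted(hits)


def write_fasta(path: Path, seqs: dict[str, str], width: int = 60) -> Path:
    with open(path, "w", newline="\n") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def write_vcf(
    path: Path,
    records: list[tuple[str, int, str, str, list[str]]],
    samples: list[str],
    contigs: dict[str, int] | None = None,
) -> Path:
    """Write a minimal VCF; records are (chrom, pos, ref, alt_csv, gts)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for chrom, pos, ref, alt, gts in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
    return path


@pytest.fixture(scope="session")
def enzyme_groups():
    return default_enzyme_groups()


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A compact planted-truth dataset shared across tests (seed 11)."""
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture(11, out, n_samples=60, n_planted_per_enzyme=5,
                            n_decoys=40, n_multiallelic=3)
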