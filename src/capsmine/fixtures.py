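"""Synthetic reference/VCF fixtures with planted, verifiable ground truth.

The generator emulates the input side of a genotyping-by-sequencing style
experiment at desk scale: one contig per variant locus, an F2 population
whose genotypes segregate 1:2:1, and a catalogue of restriction enzymes.
Per enzyme it plants variants that demonstrably create or destroy exactly
one recognition site — site-loss and site-gain SNPs, site-spanning MNPs,
deletions and insertions — plus "trap" loci carrying a second, constitutive
site in the flank (differential at the mining flank, multi-cut at the
display flank), decoy SNPs verified to leave every enzyme's digestion
status unchanged, and a few multi-allelic decoys.  One planted locus is the
trait locus: its alternative allele acts as a dominant restorer, the
population splits into carrier and non-carrier groups, and a configurable
number of loci are linked to it through a shared gamete-level model with a
given recombination fraction.

Every constructed locus is verified against the site scanner before being
accepted (and re-drawn otherwise), so the recorded truth table is exact by
construction, not merely probable.  All randomness flows from one seed;
identical seeds give byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .rebase_enzymes import (
    EnzymeGroup,
    expand_iupac,
    find_sites,
    group_enzymes,
    parse_rebase_gcg,
)

log = logging.getLogger(__name__)

__all__ = [
    "PlantedVariant",
    "FixtureTruth",
    "generate_fixture",
    "packaged_enzyme_file",
    "default_enzyme_groups",
]

BASES = "ACGT"
PLANT_KINDS = ("site_loss_snp", "site_gain_snp", "mnp", "deletion", "insertion")


def packaged_enzyme_file() -> Path:
    """Path of the miniature REBASE-style enzyme file shipped with the package."""
    return Path(str(resources.files("capsmine").joinpath("data/enzymes_six.gcg")))


def default_enzyme_groups() -> list[EnzymeGroup]:
    return group_enzymes(parse_rebase_gcg(packaged_enzyme_file()))


@dataclass(frozen=True)
class PlantedVariant:
    """Truth record for one generated locus."""

    locus_id: str
    contig: str
    pos: int
    kind: str  # one of PLANT_KINDS, or "trap", "decoy", "multiallelic_decoy"
    enzyme: str | None  # enzyme group name, None for decoys
    digested_allele: int | None
    trap: bool = False
    trait: bool = False
    trait_linked: bool = False


@dataclass
class FixtureTruth:
    """Everything the tests need to score a run against the generator."""

    seed: int
    sample_names: list[str]
    variants: list[PlantedVariant]
    groups: dict[str, list[str]]  # phenotype groups (carrier / non-carrier)
    trait_locus_id: str

    def marker_pairs(self) -> set[tuple[str, str]]:
        """The exact (locus_id, enzyme group) pairs mining must recover."""
        return {
            (v.locus_id, v.enzyme)
            for v in self.variants
            if v.enzyme is not None
        }

    def trap_pairs(self) -> set[tuple[str, str]]:
        return {(v.locus_id, v.enzyme) for v in self.variants if v.trap}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "sample_names": self.sample_names,
            "groups": self.groups,
            "trait_locus_id": self.trait_locus_id,
            "variants": [asdict(v) for v in self.variants],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            d["seed"],
            d["sample_names"],
            [PlantedVariant(**v) for v in d["variants"]],
            {k: list(v) for k, v in d["groups"].items()},
            d["trait_locus_id"],
        )


# ---------------------------------------------------------------------------
# sequence construction helpers


def _rand_bases(rng: np.random.Generator, n: int) -> list[str]:
    return [BASES[i] for i in rng.integers(0, 4, size=n)]


def _concrete_word(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        sorted(expand_iupac(c))[rng.integers(0, len(expand_iupac(c)))] for c in pattern
    )


def _breaking_base(rng: np.random.Generator, pattern_char: str) -> str:
    choices = sorted(set(BASES) - expand_iupac(pattern_char))
    if not choices:
        raise ValueError(f"cannot break an N position")
    return choices[rng.integers(0, len(choices))]


def _nondegenerate_positions(pattern: str) -> list[int]:
    return [j for j, c in enumerate(pattern) if len(expand_iupac(c)) < 4]


def _overlaps(start: int, length: int, lo: int, hi: int) -> bool:
    return start < hi and start + length > lo


def _scrub(
    contig: list[str],
    group: EnzymeGroup,
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    max_iter: int = 400,
) -> bool:
    """Mutate flank bases until the enzyme hits only protected intervals.

    Never touches a base inside a protected interval.  Returns False if it
    fails to converge (caller re-draws the whole locus).
    """
    k = len(group.pattern)
    for _ in range(max_iter):
        seq = "".join(contig)
        unwanted = [
            h
            for h in find_sites(group, seq)
            if not any(_overlaps(h.start, k, lo, hi) for lo, hi in protected)
        ]
        if not unwanted:
            return True
        h = unwanted[0]
        free = [
            i
            for i in range(h.start, h.start + k)
            if not any(lo <= i < hi for lo, hi in protected)
        ]
        if not free:
            return False
        i = free[rng.integers(0, len(free))]
        contig[i] = sorted(set(BASES) - {contig[i]})[rng.integers(0, 3)]
    return False


# ---------------------------------------------------------------------------
# per-locus planting

_MINING_FLANK = 40
_OUT_FLANK = 500


def _context(contig_seq: str, pos0: int, ref_len: int, allele: str, flank: int) -> str:
    up = contig_seq[max(0, pos0 - flank) : pos0]
    down = contig_seq[pos0 + ref_len : pos0 + ref_len + flank]
    return up + allele + down


def _digested(group: EnzymeGroup, ctx: str) -> bool:
    return bool(find_sites(group, ctx))


def _verify_locus(
    contig_seq: str,
    pos0: int,
    ref: str,
    alts: list[str],
    target: EnzymeGroup | None,
    all_groups: list[EnzymeGroup],
    expect_digested: dict[int, bool] | None,
    expect_out_hits: dict[int, int] | None,
) -> bool:
    alleles = [ref, *alts]
    # mining-flank differential exactly as mining will see it
    for g in all_groups:
        flags = [
            _digested(g, _context(contig_seq, pos0, len(ref), a, _MINING_FLANK))
            for a in alleles
        ]
        if target is not None and g.name == target.name:
            if expect_digested is not None and any(
                flags[c] != expect_digested[c] for c in expect_digested
            ):
                return False
        elif len(set(flags)) != 1:  # other enzymes must not be differential
            return False
    if target is not None and expect_out_hits is not None:
        for code, want in expect_out_hits.items():
            ctx = _context(contig_seq, pos0, len(ref), alleles[code], _OUT_FLANK)
            if len(find_sites(target, ctx)) != want:
                return False
    return True


def _plant_one(
    rng: np.random.Generator,
    kind: str,
    target: EnzymeGroup,
    all_groups: list[EnzymeGroup],
    contig_len: int,
    with_trap: bool = False,
) -> tuple[str, int, str, list[str], int]:
    """Build one locus; returns (contig_seq, pos0, ref, alts, digested_code).

    Re-draws until the locus verifies exactly: the target enzyme is
    differential at the mining flank with the intended cut/uncut assignment,
    the display window carries exactly the intended hit counts, and no other
    enzyme in the catalogue is differential.
    """
    pat = target.pattern
    k = len(pat)
    pos0 = contig_len // 2
    nd = _nondegenerate_positions(pat)
    for _attempt in range(300):
        contig = _rand_bases(rng, contig_len)
        word = _concrete_word(rng, pat)
        if kind in ("site_loss_snp", "site_gain_snp"):
            j = nd[rng.integers(0, len(nd))]
            s0 = pos0 - j
            contig[s0 : s0 + k] = list(word)
            broken = _breaking_base(rng, pat[j])
            if kind == "site_loss_snp":
                ref, alts, dig = word[j], [broken], 0
            else:
                contig[pos0] = broken
                ref, alts, dig = broken, [word[j]], 1
            protected = [(s0, s0 + k)]
        elif kind == "mnp":
            starts = [
                j
                for j in range(k - 2)
                if sum(1 for x in (j, j + 1, j + 2) if x in nd) >= 2
            ]
            j = starts[rng.integers(0, len(starts))]
            s0 = pos0 - j
            contig[s0 : s0 + k] = list(word)
            ref = word[j : j + 3]
            alt = "".join(
                _breaking_base(rng, pat[j + t])
                if (j + t) in nd
                else BASES[rng.integers(0, 4)]
                for t in range(3)
            )
            alts, dig = [alt], 0
            protected = [(s0, s0 + k)]
        elif kind == "deletion":
            # ref = anchor + 4 deleted bases; the site starts in the deleted span
            s0 = pos0 + 1
            contig[s0 : s0 + k] = list(word)
            contig_seq0 = "".join(contig)
            ref = contig_seq0[pos0 : pos0 + 5]
            alts, dig = [ref[0]], 0
            protected = [(pos0, s0 + k)]
        elif kind == "insertion":
            # site spans the anchor; 9 inserted bases split it
            j = 1 + rng.integers(0, k - 2)  # anchor strictly inside the site
            s0 = pos0 - j
            contig[s0 : s0 + k] = list(word)
            insert = "".join(_rand_bases(rng, 9))
            ref = contig[pos0]
            alts, dig = [ref + insert], 0
            protected = [(s0, s0 + k)]
        else:
            raise ValueError(f"unknown planted kind: {kind}")

        trap_hits = 0
        if with_trap:
            # constitutive second site: outside the mining flank, inside the
            # display window of both alleles
            side = 1 if rng.integers(0, 2) else -1
            d = int(rng.integers(70, 350))
            t0 = pos0 + side * d - (k if side < 0 else 0)
            trap_word = _concrete_word(rng, pat)
            if any(_overlaps(t0, k, lo, hi) for lo, hi in protected):
                continue
            contig[t0 : t0 + k] = list(trap_word)
            protected = protected + [(t0, t0 + k)]
            trap_hits = 1

        if not _scrub(contig, target, protected, rng):
            continue
        contig_seq = "".join(contig)
        expect_out = {0: (1 if dig == 0 else 0) + trap_hits,
                      1: (1 if dig == 1 else 0) + trap_hits}
        if _verify_locus(
            contig_seq, pos0, ref, alts, target, all_groups,
            expect_digested={0: dig == 0, 1: dig == 1},
            expect_out_hits=expect_out,
        ):
            return contig_seq, pos0, ref, alts, dig
    raise RuntimeError(f"could not plant a verified {kind} locus for {target.name}")


def _plant_decoy(
    rng: np.random.Generator,
    all_groups: list[EnzymeGroup],
    contig_len: int,
    n_alts: int = 1,
) -> tuple[str, int, str, list[str]]:
    """A variant verified to leave every enzyme's digestion status unchanged."""
    pos0 = contig_len // 2
    for _ in range(300):
        contig = _rand_bases(rng, contig_len)
        contig_seq = "".join(contig)
        ref = contig_seq[pos0]
        others = sorted(set(BASES) - {ref})
        idx = rng.permutation(3)[:n_alts]
        alts = [others[i] for i in sorted(idx)]
        if _verify_locus(contig_seq, pos0, ref, alts, None, all_groups, None, None):
            return contig_seq, pos0, ref, alts
    raise RuntimeError("could not build a neutral decoy locus")


# ---------------------------------------------------------------------------
# population simulation


def _f2_genotype(rng: np.random.Generator) -> tuple[int, int]:
    c = rng.choice(3, p=[0.25, 0.5, 0.25])
    return [(0, 0), (0, 1), (1, 1)][int(c)]


def _simulate_population(
    rng: np.random.Generator,
    n_samples: int,
    loci_kinds: list[str],  # "biallelic" | "multiallelic" | "trait" | "linked"
    recomb_fraction: float,
) -> tuple[list[list[tuple[int | None, int | None]]], list[tuple[int, int]]]:
    """Per-locus genotype lists plus the trait locus's true genotypes.

    The trait locus and the loci flagged "linked" share gametes: each sample
    draws two trait-locus gametes, and a linked locus's gamete allele equals
    the trait allele flipped with probability ``recomb_fraction``.
    """
    trait_g1 = rng.integers(0, 2, size=n_samples)
    trait_g2 = rng.integers(0, 2, size=n_samples)
    trait_true = [tuple(sorted((int(a), int(b)))) for a, b in zip(trait_g1, trait_g2)]
    genotypes: list[list[tuple[int | None, int | None]]] = []
    for kind in loci_kinds:
        if kind == "trait":
            genotypes.append(list(trait_true))
        elif kind == "linked":
            flip1 = rng.random(n_samples) < recomb_fraction
            flip2 = rng.random(n_samples) < recomb_fraction
            g1 = np.where(flip1, 1 - trait_g1, trait_g1)
            g2 = np.where(flip2, 1 - trait_g2, trait_g2)
            genotypes.append(
                [tuple(sorted((int(a), int(b)))) for a, b in zip(g1, g2)]
            )
        elif kind == "multiallelic":
            draws = rng.choice(3, p=[0.5, 0.25, 0.25], size=(n_samples, 2))
            genotypes.append([tuple(sorted((int(a), int(b)))) for a, b in draws])
        else:
            genotypes.append([_f2_genotype(rng) for _ in range(n_samples)])
    return genotypes, trait_true


# ---------------------------------------------------------------------------
# top-level generator


@dataclass
class Fixture:
    reference_path: Path
    vcf_path: Path
    truth_path: Path
    groups_path: Path
    truth: FixtureTruth


def generate_fixture(
    seed: int,
    out_dir: str | Path,
    n_samples: int = 96,
    n_planted_per_enzyme: int = 10,
    n_decoys: int = 200,
    enzymes: list[EnzymeGroup] | None = None,
    contig_len: int = 1100,
    n_traps_per_enzyme: int = 2,
    n_multiallelic: int = 5,
    missing_rate: float = 0.02,
    n_linked: int = 2,
    recomb_fraction: float = 0.05,
) -> Fixture:
    """Generate a reference FASTA, a VCF and a truth table, all from one seed.

    Defaults model a small F2 mapping population: 96 individuals, 1:2:1
    segregation with 2% missing calls, ten planted site-altering variants
    per enzyme (two of each of the five kinds), two two-site trap loci per
    enzyme, 200 neutral decoy SNPs, a handful of multi-allelic decoys, and a
    dominant trait locus with two linked loci at a 5% recombination
    fraction.  Contigs are 1,100 bp with the variant centered, long enough
    for unclipped display flanks.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = enzymes if enzymes is not None else default_enzyme_groups()
    if any(len(g.pattern) >= contig_len // 2 for g in groups):
        raise ValueError("enzyme pattern too long for the requested contig length")
    rng = np.random.default_rng(seed)
    sample_names = [f"s{i + 1:03d}" for i in range(n_samples)]

    # ---- build loci --------------------------------------------------------
    loci: list[dict] = []  # contig_seq, pos0, ref, alts, kind, enzyme, digested
    for g in groups:
        for i in range(n_planted_per_enzyme):
            kind = PLANT_KINDS[i % len(PLANT_KINDS)]
            seq, pos0, ref, alts, dig = _plant_one(rng, kind, g, groups, contig_len)
            loci.append(dict(seq=seq, pos0=pos0, ref=ref, alts=alts, kind=kind,
                             enzyme=g.name, digested=dig, trap=False))
        for _ in range(n_traps_per_enzyme):
            seq, pos0, ref, alts, dig = _plant_one(
                rng, "site_loss_snp", g, groups, contig_len, with_trap=True
            )
            loci.append(dict(seq=seq, pos0=pos0, ref=ref, alts=alts, kind="trap",
                             enzyme=g.name, digested=dig, trap=True))
    for _ in range(n_decoys):
        seq, pos0, ref, alts = _plant_decoy(rng, groups, contig_len)
        loci.append(dict(seq=seq, pos0=pos0, ref=ref, alts=alts, kind="decoy",
                         enzyme=None, digested=None, trap=False))
    for _ in range(n_multiallelic):
        seq, pos0, ref, alts = _plant_decoy(rng, groups, contig_len, n_alts=2)
        loci.append(dict(seq=seq, pos0=pos0, ref=ref, alts=alts,
                         kind="multiallelic_decoy", enzyme=None, digested=None,
                         trap=False))

    # trait locus = first planted site-loss SNP; next n_linked planted loci
    # of the same enzyme share its gametes
    planted_idx = [i for i, d in enumerate(loci) if d["kind"] in PLANT_KINDS]
    trait_idx = next(i for i in planted_idx if loci[i]["kind"] == "site_loss_snp")
    linked_idx = [i for i in planted_idx if i != trait_idx][:n_linked]

    kinds_for_sim = []
    for i, d in enumerate(loci):
        if i == trait_idx:
            kinds_for_sim.append("trait")
        elif i in linked_idx:
            kinds_for_sim.append("linked")
        elif d["kind"] == "multiallelic_decoy":
            kinds_for_sim.append("multiallelic")
        else:
            kinds_for_sim.append("biallelic")
    genotypes, trait_true = _simulate_population(
        rng, n_samples, kinds_for_sim, recomb_fraction
    )

    # phenotype groups from TRUE trait genotypes (before missing-data masking):
    # the alternative allele is the dominant restorer
    carriers = [s for s, (a, b) in zip(sample_names, trait_true) if a + b >= 1]
    noncarriers = [s for s in sample_names if s not in set(carriers)]
    phen_groups = {"restored": carriers, "sterile": noncarriers}

    if missing_rate > 0:
        for gts in genotypes:
            mask = rng.random(n_samples) < missing_rate
            for j in np.flatnonzero(mask):
                gts[j] = (None, None)

    # ---- write files -------------------------------------------------------
    contig_names = [f"c{i + 1:04d}" for i in range(len(loci))]
    ref_path = out_dir / "reference.fa"
    with open(ref_path, "w", encoding="utf-8", newline="\n") as fh:
        for name, d in zip(contig_names, loci):
            fh.write(f">{name}\n")
            seq = d["seq"]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    vcf_path = out_dir / "variants.vcf"
    with open(vcf_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=capsmine-fixture\n")
        for name, d in zip(contig_names, loci):
            fh.write(f"##contig=<ID={name},length={len(d['seq'])}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for name, d, gts in zip(contig_names, loci, genotypes):
            pos = d["pos0"] + 1
            alt = ",".join(d["alts"])
            gt_s = "\t".join(
                "./." if a is None else f"{a}/{b}" for a, b in gts
            )
            fh.write(f"{name}\t{pos}\t.\t{d['ref']}\t{alt}\t.\tPASS\t.\tGT\t{gt_s}\n")

    variants = [
        PlantedVariant(
            locus_id=f"{name}:{d['pos0'] + 1}",
            contig=name,
            pos=d["pos0"] + 1,
            kind=d["kind"],
            enzyme=d["enzyme"],
            digested_allele=d["digested"],
            trap=d["trap"],
            trait=(i == trait_idx),
            trait_linked=(i in linked_idx),
        )
        for i, (name, d) in enumerate(zip(contig_names, loci))
    ]
    truth = FixtureTruth(
        seed=seed,
        sample_names=sample_names,
        variants=variants,
        groups=phen_groups,
        trait_locus_id=variants[trait_idx].locus_id,
    )
    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)

    groups_path = out_dir / "groups.json"
    with open(groups_path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "mode": "B",
                "groups": phen_groups,
                "thresholds": {k: 0.10 for k in phen_groups},
            },
            fh,
            indent=1,
        )
    log.info(
        "fixture: %d loci (%d planted, %d traps, %d decoys), %d samples",
        len(loci),
        len(planted_idx),
        n_traps_per_enzyme * len(groups),
        n_decoys + n_multiallelic,
        n_samples,
    )
    return Fixture(ref_path, vcf_path, truth_path, groups_path, truth)
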