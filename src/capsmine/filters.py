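"""Marker filtration: segregation prefilter, single-cut filter, group filter.

Three independent filters narrow a marker set down to assays worth running:

* the **segregation prefilter** drops bi-allelic loci whose hom-ref / het /
  hom-alt counts deviate from the expected F2 ratio (1:2:1 by default,
  Pearson goodness-of-fit, df = 2) at a chosen significance level, or that
  have too many missing genotypes;
* the **single-cut filter** keeps only markers whose enzyme cuts each
  digested allele's display window exactly once — at the polymorphic site —
  and each undigested allele's window not at all, so gels show clean 1-3
  band profiles;
* the **group filter** keeps markers whose digestion genotypes co-segregate
  with user-defined sample groups, either one genotype per group (mode A,
  for co-dominant scoring) or one homozygote class against everything else
  (mode B, for a dominant trait in an F2), with a per-group tolerance for
  inconsistent individuals.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import chi2 as chi2_dist

from .mining import CapsMarker
from .rebase_enzymes import find_sites, parse_annotated_site
from .v2c import Locus, V2CRecord

log = logging.getLogger(__name__)

__all__ = [
    "SegregationParams",
    "GroupSpec",
    "segregation_test",
    "segregation_filter",
    "single_cut_filter",
    "group_filter",
]


@dataclass(frozen=True)
class SegregationParams:
    """Expected (a:h:b) class ratio, significance level, missing-data cap."""

    expected_ratio: tuple[float, float, float] = (1.0, 2.0, 1.0)
    alpha: float = 0.05
    max_missing: int = 5

    def __post_init__(self) -> None:
        if not all(r > 0 for r in self.expected_ratio):
            raise ValueError("ratio components must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def segregation_test(
    counts: Sequence[int], expected_ratio: Sequence[float] = (1.0, 2.0, 1.0)
) -> tuple[float, float]:
    """Pearson goodness-of-fit of observed class counts to a ratio.

    Returns (chi-square statistic, p-value) with df = len(counts) - 1 and no
    continuity correction.  For the three F2 classes and df = 2 the p-value
    equals ``exp(-chi2 / 2)``.
    """
    n = sum(counts)
    if n == 0:
        return float("nan"), 0.0
    total = sum(expected_ratio)
    stat = sum(
        (o - n * r / total) ** 2 / (n * r / total)
        for o, r in zip(counts, expected_ratio)
    )
    return stat, float(chi2_dist.sf(stat, df=len(counts) - 1))


def segregation_filter(
    loci: Iterable[Locus | V2CRecord], params: SegregationParams = SegregationParams()
) -> list[Locus | V2CRecord]:
    """Retain bi-allelic loci that segregate as expected.

    A locus is dropped when its missing-genotype count exceeds
    ``params.max_missing`` or the hom-ref/het/hom-alt counts deviate from the
    expected ratio at ``params.alpha``.  Multi-allelic loci are retained with
    a warning: the three-class test is undefined for them.
    """
    kept: list[Locus | V2CRecord] = []
    n_missing_drop = n_ratio_drop = 0
    for locus in loci:
        n_alt = len(locus.alt_alleles)
        if n_alt != 1:
            log.warning(
                "%s: multi-allelic (%d ALTs), segregation test skipped",
                locus.locus_id, n_alt,
            )
            kept.append(locus)
            continue
        missing = sum(1 for a, _ in locus.genotypes if a is None)
        if missing > params.max_missing:
            n_missing_drop += 1
            continue
        counts = [0, 0, 0]  # hom-ref, het, hom-alt
        for a, b in locus.genotypes:
            if a is not None:
                counts[a + b] += 1  # type: ignore[operator]
        _, p = segregation_test(counts, params.expected_ratio)
        if p < params.alpha:
            n_ratio_drop += 1
            continue
        kept.append(locus)
    log.info(
        "segregation filter: kept %d loci (dropped %d for missing data, %d for ratio)",
        len(kept), n_missing_drop, n_ratio_drop,
    )
    return kept


def single_cut_filter(
    markers: Iterable[CapsMarker], scan_minus_strand: bool = True
) -> list[CapsMarker]:
    """Retain markers whose display window carries only the polymorphic site.

    Over each allele's full display context (flank + allele + flank, both
    strands), the enzyme group's hit count must be exactly 1 on every
    digested allele and exactly 0 on every undigested allele; additional
    constitutive sites in the flanks would clutter the gel profile.
    """
    kept: list[CapsMarker] = []
    n_in = 0
    for m in markers:
        n_in += 1
        pattern = m.pattern
        ok = True
        for a in m.alleles:
            hits = len(find_sites(pattern, a.context, scan_minus_strand))
            if hits != (1 if a.digested else 0):
                ok = False
                break
        if ok:
            kept.append(m)
    log.info("single-cut filter: kept %d of %d markers", len(kept), n_in)
    return kept


_GENOTYPE_CLASSES = ("+/+", "-/+", "-/-")


@dataclass
class GroupSpec:
    """Named sample groups with per-group mismatch tolerances.

    ``groups`` maps a group name to its sample list; ``thresholds`` gives the
    maximum tolerated fraction of inconsistent individuals per group (the
    same default applies to unlisted groups); ``mode`` is ``"A"`` (one
    genotype per group) or ``"B"`` (one homozygote class vs the rest).
    """

    groups: dict[str, list[str]]
    thresholds: dict[str, float] = field(default_factory=dict)
    mode: str = "B"
    default_threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.mode not in ("A", "B"):
            raise ValueError(f"mode must be 'A' or 'B', not {self.mode!r}")
        if not 2 <= len(self.groups) <= 3:
            raise ValueError("need 2 or 3 groups")
        seen: set[str] = set()
        for name, members in self.groups.items():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"groups overlap on samples: {sorted(overlap)}")
            seen |= set(members)
        for t in self.thresholds.values():
            if not 0 <= t <= 1:
                raise ValueError("thresholds must lie in [0, 1]")

    def threshold(self, group: str) -> float:
        return self.thresholds.get(group, self.default_threshold)

    @classmethod
    def from_file(cls, path: str | Path) -> "GroupSpec":
        """Load from JSON: {"mode": .., "groups": {..}, "thresholds": {..}}."""
        with open(path, encoding="utf-8") as fh:
            cfg = json.load(fh)
        return cls(
            groups={k: list(v) for k, v in cfg["groups"].items()},
            thresholds=dict(cfg.get("thresholds", {})),
            mode=cfg.get("mode", "B"),
            default_threshold=float(cfg.get("default_threshold", 0.10)),
        )


def _mismatch_fraction(members: list[str], dg: dict[str, str], target: str) -> float:
    """Fraction of a group whose digestion genotype differs from target
    (missing ``?/?`` counts as inconsistent)."""
    bad = sum(1 for s in members if dg[s] != target)
    return bad / len(members)


def _match_fraction(members: list[str], dg: dict[str, str], target: str) -> float:
    return sum(1 for s in members if dg[s] == target) / len(members)


def _passes_mode_a(marker: CapsMarker, spec: GroupSpec) -> bool:
    dg = {s: d for s, (_, d) in marker.sample_digestion().items()}
    names = list(spec.groups)
    for assignment in itertools.permutations(_GENOTYPE_CLASSES, len(names)):
        if all(
            _mismatch_fraction(spec.groups[g], dg, cls) <= spec.threshold(g)
            for g, cls in zip(names, assignment)
        ):
            return True
    return False


def _passes_mode_b(
    marker: CapsMarker, spec: GroupSpec, fixed: tuple[str, str] | None = None
) -> bool:
    if len(spec.groups) != 2:
        raise ValueError("mode B requires exactly 2 groups")
    dg = {s: d for s, (_, d) in marker.sample_digestion().items()}
    g1, g2 = spec.groups
    candidates = (
        [fixed]
        if fixed is not None
        else [(h, gh) for h in ("+/+", "-/-") for gh in (g1, g2)]
    )
    for hom, g_hom in candidates:
        g_rest = g2 if g_hom == g1 else g1
        if (
            _mismatch_fraction(spec.groups[g_hom], dg, hom) <= spec.threshold(g_hom)
            and _match_fraction(spec.groups[g_rest], dg, hom) <= spec.threshold(g_rest)
        ):
            return True
    return False


def group_filter(
    markers: Iterable[CapsMarker],
    spec: GroupSpec,
    fixed_assignment: tuple[str, str] | None = None,
) -> list[CapsMarker]:
    """Retain markers whose digestion genotypes match the group structure.

    Mode A searches injective assignments of the groups onto distinct
    digestion genotype classes; mode B searches both homozygote classes and
    both group labelings (pass ``fixed_assignment=(hom_class, group_name)``
    to pin mode B to one assignment).  Threshold comparison is inclusive: a
    10% mismatch passes a 0.10 threshold.
    """
    kept: list[CapsMarker] = []
    n_in = 0
    for m in markers:
        n_in += 1
        known = set(m.sample_names)
        unknown = {s for g in spec.groups.values() for s in g} - known
        if unknown:
            raise ValueError(f"group samples not in marker {m.locus_id}: {sorted(unknown)}")
        if spec.mode == "A":
            ok = _passes_mode_a(m, spec)
        else:
            ok = _passes_mode_b(m, spec, fixed_assignment)
        if ok:
            kept.append(m)
    log.info("group filter (mode %s): kept %d of %d markers", spec.mode, len(kept), n_in)
    return kept
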