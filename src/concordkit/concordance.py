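"""k-of-N concordance summaries over variant equivalence classes.

Concordance is the fraction of the union of equivalence classes supported by
every one of the N compared call sets (intersection over union).  Classes are
also stratified into tiers by exact support k, into known vs novel against a
catalogue of previously observed sites, and summarized by the Ti/Tv ratio per
tier — the standard purity heuristic, since true coding variation is
transition-rich (Ti/Tv ~ 3) while random artifacts are transversion-rich
(Ti/Tv ~ 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .normalize import (
    EquivalenceClass,
    IntervalizedIndel,
    MatchConfig,
    cluster_variants,
    indel_match,
    intervalize,
    left_normalize,
)
from .variants import CallSet, Reference, VariantCall, VariantClass, filter_calls

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class ConcordanceReport:
    """Tiered summary of one clustering of N call sets."""

    n_sets: int
    tier_counts: dict[int, int]
    titv_by_tier: dict[int, float | None] = field(default_factory=dict)
    strata: dict[str, "ConcordanceReport"] | None = None

    @property
    def union_size(self) -> int:
        return sum(self.tier_counts.values())

    @property
    def intersection_size(self) -> int:
        return self.tier_counts.get(self.n_sets, 0)

    @property
    def concordance(self) -> float:
        """Intersection over union; NaN for an empty union."""
        if self.union_size == 0:
            return math.nan
        return self.intersection_size / self.union_size

    def to_dict(self) -> dict:
        d = {
            "n_sets": self.n_sets,
            "tier_counts": {str(k): v for k, v in sorted(self.tier_counts.items())},
            "union_size": self.union_size,
            "intersection_size": self.intersection_size,
            "concordance": None if math.isnan(self.concordance) else self.concordance,
            "titv_by_tier": {str(k): v for k, v in sorted(self.titv_by_tier.items())},
        }
        if self.strata is not None:
            d["strata"] = {k: v.to_dict() for k, v in self.strata.items()}
        return d


def titv_ratio(snv_classes: Iterable[EquivalenceClass]) -> float | None:
    """Transition/transversion ratio over class representatives.

    One vote per class.  Returns None (NA) when there are no transversions.
    """
    ti = tv = 0
    for ec in snv_classes:
        rep = ec.representative
        if rep.vclass is not VariantClass.SNV:
            raise ValueError(f"non-SNV class at {rep.chrom}:{rep.pos} ({rep.ref}->{rep.alt})")
        if (rep.ref, rep.alt) in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ti / tv


def concordance_report(
    classes: Sequence[EquivalenceClass], n_sets: int, with_titv: bool = False
) -> ConcordanceReport:
    """Tier counts, union/intersection and concordance for one clustering."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    tier_counts: dict[int, int] = {k: 0 for k in range(1, n_sets + 1)}
    by_tier: dict[int, list[EquivalenceClass]] = {k: [] for k in range(1, n_sets + 1)}
    for ec in classes:
        k = ec.support
        if not 1 <= k <= n_sets:
            raise ValueError(f"class support {k} outside 1..{n_sets}")
        tier_counts[k] += 1
        by_tier[k].append(ec)
    titv: dict[int, float | None] = {}
    if with_titv:
        for k, tier in by_tier.items():
            snvs = [ec for ec in tier if ec.representative.vclass is VariantClass.SNV]
            titv[k] = titv_ratio(snvs) if snvs else None
    return ConcordanceReport(n_sets=n_sets, tier_counts=tier_counts, titv_by_tier=titv)


def stratify_known_novel(
    classes: Sequence[EquivalenceClass],
    known_sites: Iterable[tuple[str, int, str, str]] | CallSet,
    cfg: MatchConfig,
    ref: Reference,
) -> tuple[list[EquivalenceClass], list[EquivalenceClass]]:
    """Partition classes into (known, novel) against a known-sites catalogue.

    A class is known iff its representative matches a catalogue entry: SNVs
    by exact (chrom, pos, ref, alt) key, indels under the windowed
    ``indel_match``.  The partition is exhaustive and exclusive.
    """
    if isinstance(known_sites, CallSet):
        entries = [v.key for v in known_sites]
    else:
        entries = list(known_sites)

    exact_keys = set()
    known_indels: list[IntervalizedIndel] = []
    for chrom, pos, kref, kalt in entries:
        try:
            v = VariantCall(chrom=chrom, pos=pos, ref=kref, alt=kalt)
        except ValueError:
            continue
        if v.is_indel:
            known_indels.append(intervalize(v, cfg, ref))
        else:
            # catalogue entries may carry untrimmed flanks; index both forms
            exact_keys.add((chrom, pos, kref, kalt))
            try:
                n = left_normalize(v, ref)
            except (KeyError, ValueError):
                continue
            if n.is_indel:
                known_indels.append(intervalize(n, cfg, ref))
            else:
                exact_keys.add(n.key)

    known, novel = [], []
    for ec in classes:
        rep = ec.representative
        if rep.is_indel:
            rep_ii = intervalize(rep, cfg, ref)
            is_known = any(indel_match(rep_ii, ki, cfg) for ki in known_indels)
        else:
            is_known = rep.key in exact_keys
        (known if is_known else novel).append(ec)
    return known, novel


@dataclass
class ConcordanceSummary:
    mean: float
    sd: float
    per_sample: list[float]
    mean_tier_fractions: dict[int, float]


def mean_concordance(reports: Sequence[ConcordanceReport]) -> ConcordanceSummary:
    """Arithmetic mean (and SD) of per-sample concordance and tier fractions."""
    if not reports:
        raise ValueError("at least one report required")
    n_sets = {r.n_sets for r in reports}
    if len(n_sets) != 1:
        raise ValueError(f"mixed n_sets: {sorted(n_sets)}")
    import numpy as np

    vals = np.array([r.concordance for r in reports], dtype=float)
    fracs: dict[int, list[float]] = {k: [] for k in range(1, reports[0].n_sets + 1)}
    for r in reports:
        u = r.union_size
        for k in fracs:
            fracs[k].append(r.tier_counts.get(k, 0) / u if u else math.nan)
    return ConcordanceSummary(
        mean=float(np.nanmean(vals)),
        sd=float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0,
        per_sample=[float(v) for v in vals],
        mean_tier_fractions={k: float(np.nanmean(v)) for k, v in fracs.items()},
    )


def depth_sweep(
    callsets: Sequence[CallSet],
    thresholds: Sequence[int],
    cfg: MatchConfig,
    ref: Reference,
    with_titv: bool = False,
) -> list[tuple[int, ConcordanceReport]]:
    """Recluster after per-pipeline depth filtering at each threshold.

    Each call set is filtered to calls with depth > t in its own set before
    clustering (threshold 0 keeps everything carrying any depth and so
    reproduces the unfiltered report when all calls have depth recorded).
    Rows are ordered by threshold.
    """
    out = []
    for t in sorted(thresholds):
        filtered = [filter_calls(cs, min_depth=t + 1) if t > 0 else cs for cs in callsets]
        classes = cluster_variants(filtered, cfg, ref)
        out.append((t, concordance_report(classes, len(callsets), with_titv=with_titv)))
    return out
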