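"""Truth-set evaluation and cross-platform comparison.

Sensitivity/specificity are computed against genotyping-array-style truth
genotypes, which — unlike a VCF — record homozygous-reference sites, so both
halves of the confusion matrix are defined: a non-reference truth genotype
missed by the call set is a false negative, and any call at an array
homozygous-reference site is a false positive.  Specificity's denominator is
the array's hom-ref sites, not every genomic position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

from .normalize import EquivalenceClass, MatchConfig, cluster_variants
from .variants import CallSet, Reference, RegionSet, VariantCall, Zygosity, restrict_to_regions


@dataclass(frozen=True)
class TruthEntry:
    ref: str
    alt: str
    genotype: str  # HOM_REF | HET | HOM_ALT


class GenotypeTruthSet:
    """Array-style site genotypes, one entry per (chrom, pos), SNP sites only."""

    def __init__(self, entries: dict[tuple[str, int], TruthEntry] | None = None):
        self.entries: dict[tuple[str, int], TruthEntry] = dict(entries or {})
        for (chrom, pos), e in self.entries.items():
            if len(e.ref) != 1 or len(e.alt) != 1:
                raise ValueError(f"array truth sites must be SNPs ({chrom}:{pos})")
            if e.genotype not in ("HOM_REF", "HET", "HOM_ALT"):
                raise ValueError(f"bad genotype {e.genotype!r} at {chrom}:{pos}")

    def add(self, chrom: str, pos: int, ref: str, alt: str, genotype: str) -> None:
        if (chrom, pos) in self.entries:
            raise ValueError(f"duplicate truth site {chrom}:{pos}")
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError(f"array truth sites must be SNPs ({chrom}:{pos})")
        if genotype not in ("HOM_REF", "HET", "HOM_ALT"):
            raise ValueError(f"bad genotype {genotype!r} at {chrom}:{pos}")
        self.entries[(chrom, pos)] = TruthEntry(ref, alt, genotype)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTruthSet":
        """Read truth TSV with columns chrom, pos, ref, alt, genotype."""
        entries: dict[tuple[str, int], TruthEntry] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.lower().startswith("chrom\t"):
                    continue
                chrom, pos, ref, alt, gt = line.split("\t")[:5]
                entries[(chrom, int(pos))] = TruthEntry(ref.upper(), alt.upper(), gt)
        return cls(entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SensSpec:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else math.nan

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


def evaluate_against_truth(
    cs: CallSet,
    truth: GenotypeTruthSet,
    cfg: MatchConfig | None = None,
    discordant_counts_both: bool = True,
) -> SensSpec:
    """Confusion matrix of a call set against array truth genotypes.

    A non-ref truth site is TP iff the call set has a call with the same
    position, alt allele and genotype; otherwise FN.  A hom-ref truth site is
    FP iff the call set has any call anchored there, else TN.  A call at a
    non-ref truth site with a discordant allele counts FN + FP when
    ``discordant_counts_both`` (a missed truth genotype and a spurious call).
    """
    by_site: dict[tuple[str, int], list[VariantCall]] = {}
    for v in cs:
        by_site.setdefault((v.chrom, v.pos), []).append(v)

    res = SensSpec()
    for site, e in truth.entries.items():
        calls = by_site.get(site, [])
        if e.genotype == "HOM_REF":
            if calls:
                res.fp += 1
            else:
                res.tn += 1
            continue
        want_zyg = Zygosity.HET if e.genotype == "HET" else Zygosity.HOM_ALT
        hit = any(c.ref == e.ref and c.alt == e.alt and c.zygosity is want_zyg for c in calls)
        if hit:
            res.tp += 1
        else:
            res.fn += 1
            if calls and discordant_counts_both:
                res.fp += 1
    return res


def intersect_k(
    callsets: Sequence[CallSet], k: int, cfg: MatchConfig, ref: Reference,
    classes: Sequence[EquivalenceClass] | None = None,
) -> CallSet:
    """Representatives of classes supported by >= k of the call sets."""
    if not 1 <= k <= len(callsets):
        raise ValueError(f"k must be in 1..{len(callsets)}")
    if classes is None:
        classes = cluster_variants(callsets, cfg, ref)
    label = f">= {k} of {len(callsets)}"
    reps = [ec.representative for ec in classes if ec.support >= k]
    return CallSet(label, callsets[0].sample, reps)


def unique_to(
    callsets: Sequence[CallSet], label: str, cfg: MatchConfig, ref: Reference,
    classes: Sequence[EquivalenceClass] | None = None,
) -> CallSet:
    """Representatives of classes whose only supporting source is ``label``."""
    if label not in {cs.label for cs in callsets}:
        raise ValueError(f"unknown call-set label {label!r}")
    if classes is None:
        classes = cluster_variants(callsets, cfg, ref)
    reps = [ec.representative for ec in classes if ec.labels == {label}]
    return CallSet(f"unique-to-{label}", "", reps)


def rate_percent(numerator: int, denominator: int, decimals: int = 1) -> float | None:
    """numerator/denominator as a percentage, rounded half-away-from-zero.

    Returns None (NA) for a zero denominator.
    """
    if denominator == 0:
        return None
    if not 0 <= numerator <= denominator:
        raise ValueError("require 0 <= numerator <= denominator")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RateResult:
    n_query: int
    n_confirmed: int
    decimals: int = 1

    @property
    def percent(self) -> float | None:
        return rate_percent(self.n_confirmed, self.n_query, self.decimals)

    def to_dict(self) -> dict:
        return {"n_query": self.n_query, "n_confirmed": self.n_confirmed, "percent": self.percent}


def validation_rate(
    query: CallSet, reference: CallSet, cfg: MatchConfig, ref: Reference, decimals: int = 1
) -> RateResult:
    """Fraction of query calls confirmed by the reference (validation) set.

    A query call is confirmed when its equivalence class, under the usual
    SNV/indel match semantics, also contains a reference-set call.
    """
    if reference.label == query.label:
        reference = CallSet("__validation_reference__", reference.sample, reference.calls)
    classes = cluster_variants([query, reference], cfg, ref)
    ref_cs = reference
    confirmed = 0
    for ec in classes:
        q = ec.members.get(query.label, [])
        if q and ec.members.get(ref_cs.label):
            confirmed += len(q)
    return RateResult(n_query=len(query), n_confirmed=confirmed, decimals=decimals)


@dataclass
class CrossPlatformReport:
    mode: str
    n_other: int
    n_other_contained: int
    n_pipeline: int
    n_pipeline_contained: int
    unique_to_other: CallSet

    @property
    def other_containment_percent(self) -> float | None:
        return rate_percent(self.n_other_contained, self.n_other, 1)

    @property
    def pipeline_containment_percent(self) -> float | None:
        return rate_percent(self.n_pipeline_contained, self.n_pipeline, 1)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_other": self.n_other,
            "n_other_contained": self.n_other_contained,
            "other_containment_percent": self.other_containment_percent,
            "n_pipeline": self.n_pipeline,
            "n_pipeline_contained": self.n_pipeline_contained,
            "pipeline_containment_percent": self.pipeline_containment_percent,
            "n_unique_to_other": len(self.unique_to_other),
        }


def cross_platform_report(
    pipeline_sets: Sequence[CallSet],
    other: CallSet,
    regions: RegionSet | None,
    cfg: MatchConfig,
    ref: Reference,
    mode: str = "union",
) -> CrossPlatformReport:
    """Two-directional containment between N pipeline sets and another platform.

    The other-platform set is restricted to the capture regions first.  In
    ``union`` mode the pipeline side is any class supported by >= 1 pipeline;
    in ``intersection`` mode, by all pipelines.  Containment is class
    co-membership under the match config, not raw key equality.
    """
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    if regions is not None:
        other = restrict_to_regions(other, regions)
    if other.label in {cs.label for cs in pipeline_sets}:
        other_cs = CallSet("__other_platform__", other.sample, other.calls)
    else:
        other_cs = other
    n_pipelines = len(pipeline_sets)
    classes = cluster_variants(list(pipeline_sets) + [other_cs], cfg, ref)

    need = 1 if mode == "union" else n_pipelines
    n_other = n_other_contained = 0
    n_pipeline = n_pipeline_contained = 0
    unique_other = []
    for ec in classes:
        other_calls = ec.members.get(other_cs.label, [])
        pipeline_support = sum(1 for lab, v in ec.members.items() if v and lab != other_cs.label)
        if other_calls:
            n_other += 1
            if pipeline_support >= need:
                n_other_contained += 1
            if pipeline_support == 0:
                unique_other.append(ec.representative)
        if pipeline_support >= need:
            n_pipeline += 1
            if other_calls:
                n_pipeline_contained += 1
    return CrossPlatformReport(
        mode=mode,
        n_other=n_other,
        n_other_contained=n_other_contained,
        n_pipeline=n_pipeline,
        n_pipeline_contained=n_pipeline_contained,
        unique_to_other=CallSet(f"unique-to-{other.label}", other.sample, unique_other),
    )
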