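"""Indel left-normalization, intervalized matching, and variant clustering.

Two call sets rarely disagree about a SNV's representation, but the same
indel in a homopolymer or short tandem repeat can be reported at any of the
equivalent positions within the run.  Left-normalization rewrites every indel
to the unique leftmost minimal anchored representation; intervalization then
widens the normalized coordinate by a +/- window so that residual coordinate
disagreement (default 10 each side, a total range of 20) still matches.
Matching on normalized+intervalized indels instead of raw VCF keys is what
turns near-zero apparent cross-pipeline indel agreement into the true
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from .variants import CallSet, Reference, VariantCall, VariantClass, Zygosity


class CompositionMode(str, Enum):
    """How strictly the edited sequence must agree for an indel match."""

    EXACT_ALLELE = "exact"
    LENGTH_ONLY = "length"


@dataclass(frozen=True)
class MatchConfig:
    """Parameters defining when two calls are "the same variant".

    window
        Coordinate slack on each side of the normalized indel position
        (inclusive); the default 10 gives a total matching range of 20.
    require_zygosity_snv / require_zygosity_indel
        Whether the genotype state is part of the SNV / indel match.
    composition_mode
        EXACT_ALLELE compares the inserted/deleted sequence itself;
        LENGTH_ONLY compares only the net length change.
    """

    window: int = 10
    require_zygosity_snv: bool = True
    require_zygosity_indel: bool = False
    composition_mode: CompositionMode = CompositionMode.EXACT_ALLELE

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")


def left_normalize(v: VariantCall, ref: Reference) -> VariantCall:
    """Return the leftmost minimal anchored representation of ``v``.

    Shared trailing bases are trimmed (extending left through the reference
    whenever an allele would become empty, which is what shifts the position
    left through repeats), then shared leading bases are trimmed down to a
    single anchor.  Applying the returned edit to the reference yields the
    same alternate sequence as applying ``v``; the operation is idempotent.
    SNVs/MNVs are returned with shared flanks trimmed only.
    """
    ref.check(v)
    seq = ref.sequences[v.chrom]
    pos, a, b = v.pos, v.ref, v.alt
    while True:
        if a[-1] == b[-1]:
            if len(a) > 1 and len(b) > 1:
                a, b = a[:-1], b[:-1]
                continue
            if pos > 1:
                ext = seq[pos - 2]
                a, b = ext + a[:-1], ext + b[:-1]
                pos -= 1
                continue
        break
    while len(a) > 1 and len(b) > 1 and a[0] == b[0]:
        a, b = a[1:], b[1:]
        pos += 1
    if (pos, a, b) == (v.pos, v.ref, v.alt):
        return v
    return replace(v, pos=pos, ref=a, alt=b)


@dataclass(frozen=True)
class IntervalizedIndel:
    """A left-normalized indel widened to its matching interval.

    ``net_len`` is len(alt) - len(ref) (positive for insertions);
    ``edited_seq`` is the inserted or deleted nucleotide string after
    removing the shared anchor base.  ``lo``/``hi`` are the normalized
    position +/- the window, clamped to the chromosome.
    """

    call: VariantCall
    lo: int
    hi: int
    net_len: int
    edited_seq: str

    @property
    def pos(self) -> int:
        return self.call.pos


def intervalize(v: VariantCall, cfg: MatchConfig, ref: Reference) -> IntervalizedIndel:
    """Left-normalize an indel and attach its +/- window interval."""
    n = left_normalize(v, ref)
    vc = n.vclass
    if vc is VariantClass.INS:
        edited = n.alt[len(n.ref):]
    elif vc is VariantClass.DEL:
        edited = n.ref[len(n.alt):]
    else:
        raise ValueError(f"intervalize requires an indel, got {vc.value} at {v.chrom}:{v.pos}")
    lo = max(1, n.pos - cfg.window)
    hi = min(ref.chrom_length(n.chrom), n.pos + cfg.window)
    return IntervalizedIndel(call=n, lo=lo, hi=hi, net_len=len(n.alt) - len(n.ref), edited_seq=edited)


def snv_match(a: VariantCall, b: VariantCall, cfg: MatchConfig) -> bool:
    """Exact-site SNV match: coordinate, base change, and (optionally) zygosity."""
    if a.vclass is not VariantClass.SNV or b.vclass is not VariantClass.SNV:
        raise ValueError("snv_match requires SNV inputs")
    if (a.chrom, a.pos, a.ref, a.alt) != (b.chrom, b.pos, b.ref, b.alt):
        return False
    return not cfg.require_zygosity_snv or a.zygosity == b.zygosity


def indel_match(a: IntervalizedIndel, b: IntervalizedIndel, cfg: MatchConfig) -> bool:
    """Windowed indel match on normalized position, net length and composition."""
    if a.call.chrom != b.call.chrom:
        return False
    if abs(a.pos - b.pos) > cfg.window:
        return False
    if a.net_len != b.net_len:
        return False
    if cfg.composition_mode is CompositionMode.EXACT_ALLELE and a.edited_seq != b.edited_seq:
        return False
    return not cfg.require_zygosity_indel or a.call.zygosity == b.call.zygosity


@dataclass
class EquivalenceClass:
    """A cluster of matched calls across call sets — the unit of concordance.

    ``members`` maps source label -> the (normalized) calls that landed in
    this class; ``support`` is the number of distinct labels present.
    """

    members: dict[str, list[VariantCall]] = field(default_factory=dict)

    @property
    def support(self) -> int:
        return sum(1 for v in self.members.values() if v)

    @property
    def representative(self) -> VariantCall:
        return min(
            (c for calls in self.members.values() for c in calls),
            key=lambda c: (c.chrom, c.pos, c.ref, c.alt),
        )

    @property
    def labels(self) -> set[str]:
        return {k for k, v in self.members.items() if v}

    def all_calls(self) -> list[VariantCall]:
        return [c for calls in self.members.values() for c in calls]


def _snv_key(v: VariantCall, cfg: MatchConfig):
    key = (v.chrom, v.pos, v.ref, v.alt)
    return key + (v.zygosity,) if cfg.require_zygosity_snv else key


def _indel_group_key(ii: IntervalizedIndel, cfg: MatchConfig):
    key: tuple = (ii.call.chrom, ii.net_len)
    if cfg.composition_mode is CompositionMode.EXACT_ALLELE:
        key += (ii.edited_seq,)
    if cfg.require_zygosity_indel:
        key += (ii.call.zygosity,)
    return key


def cluster_variants(
    sets: Sequence[CallSet], cfg: MatchConfig, ref: Reference, raw: bool = False
) -> list[EquivalenceClass]:
    """Cluster calls across call sets into match equivalence classes.

    SNVs (and MNVs and complex substitutions) cluster by exact normalized
    key; indels cluster by single-linkage connected components of the
    windowed ``indel_match`` graph.  On a line this reduces to chaining:
    within each (chrom, net length[, composition]) group, sorted positions
    belong to one component exactly while consecutive gaps stay <= window.
    The result is deterministic and invariant under permutation of the input
    sets and of calls within sets; classes are ordered by representative.

    With ``raw=True`` every call — indels included — clusters by its exact
    as-reported key with no normalization and no window; this is the naive
    comparison whose indel agreement collapses in repeat context.
    """
    if not sets:
        raise ValueError("at least one call set required")

    exact: dict[tuple, EquivalenceClass] = {}
    indel_groups: dict[tuple, list[tuple[IntervalizedIndel, str]]] = {}

    for cs in sets:
        for v in cs:
            if raw:
                key = v.key + ((v.zygosity,) if cfg.require_zygosity_snv else ())
                ec = exact.setdefault(key, EquivalenceClass())
                ec.members.setdefault(cs.label, []).append(v)
                continue
            n = left_normalize(v, ref)
            if n.vclass in (VariantClass.INS, VariantClass.DEL):
                ii = intervalize(n, cfg, ref)
                indel_groups.setdefault(_indel_group_key(ii, cfg), []).append((ii, cs.label))
            else:
                ec = exact.setdefault(_snv_key(n, cfg), EquivalenceClass())
                ec.members.setdefault(cs.label, []).append(n)

    classes = list(exact.values())
    for group in indel_groups.values():
        group.sort(key=lambda t: (t[0].pos, t[0].call.ref, t[0].call.alt, t[1]))
        current: EquivalenceClass | None = None
        prev_pos: int | None = None
        for ii, label in group:
            if current is None or ii.pos - prev_pos > cfg.window:
                current = EquivalenceClass()
                classes.append(current)
            current.members.setdefault(label, []).append(ii.call)
            prev_pos = ii.pos
    classes.sort(key=lambda ec: (lambda r: (r.chrom, r.pos, r.ref, r.alt))(ec.representative))
    return classes
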