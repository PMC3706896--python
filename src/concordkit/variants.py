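"""Core variant data model and file ingestion.

Coordinates are VCF-style throughout: positions are 1-based and alleles are
anchored (an indel shares its first base with the reference).  BED intervals
are 0-based half-open and are converted at the I/O boundary only.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


class Zygosity(str, Enum):
    HET = "HET"
    HOM_ALT = "HOM_ALT"


class VariantClass(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    MNV = "MNV"
    OTHER = "OTHER"


def classify(ref: str, alt: str) -> VariantClass:
    """Classify an anchored ref/alt allele pair.

    SNV: single-base substitution.  INS/DEL: length change where the shorter
    allele is a prefix of the longer (the usual anchored representation).
    MNV: equal-length multi-base substitution.  Anything else is OTHER.

    Raises ``ValueError`` on empty alleles, non-ACGT characters, or ref == alt.
    """
    if not ref or not alt:
        raise ValueError("alleles must be non-empty")
    if not (_ACGT.issuperset(ref) and _ACGT.issuperset(alt)):
        raise ValueError(f"non-ACGT character in alleles {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(ref) == len(alt):
        return VariantClass.MNV
    if len(alt) > len(ref) and alt.startswith(ref):
        return VariantClass.INS
    if len(ref) > len(alt) and ref.startswith(alt):
        return VariantClass.DEL
    return VariantClass.OTHER


@dataclass(frozen=True)
class VariantCall:
    """One variant observation from one source (pipeline or platform).

    ``pos`` is the 1-based position of the first base of ``ref``.  Optional
    attributes carry per-call annotations used by downstream filters:
    ``depth`` (supporting reads), ``quality_flag`` (e.g. VQHIGH/VQLOW),
    ``known`` (membership in a known-sites catalogue), ``consequence``
    (e.g. NONSYN/NONSENSE/SYN/NONE).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: Zygosity = Zygosity.HET
    depth: int | None = None
    quality_flag: str | None = None
    known: bool | None = None
    consequence: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be non-negative")
        classify(self.ref, self.alt)  # validates alleles

    @property
    def vclass(self) -> VariantClass:
        return classify(self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.vclass in (VariantClass.INS, VariantClass.DEL)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference-allele span."""
        return self.pos + len(self.ref) - 1

    def with_source(self, source: str) -> "VariantCall":
        return replace(self, source=source)


class CallSet:
    """A labeled collection of calls from one pipeline/platform/sample.

    Enforces uniqueness per (chrom, pos, ref, alt); multiallelic records must
    be split before construction (``read_callset`` does this).
    """

    def __init__(self, label: str, sample: str = "", calls: Iterable[VariantCall] = ()):
        self.label = label
        self.sample = sample
        self._calls: dict[tuple[str, int, str, str], VariantCall] = {}
        for c in calls:
            self.add(c)

    def add(self, call: VariantCall) -> None:
        if call.key in self._calls:
            raise ValueError(f"duplicate call {call.key} in call set {self.label!r}")
        if call.source != self.label:
            call = call.with_source(self.label)
        self._calls[call.key] = call

    @property
    def calls(self) -> list[VariantCall]:
        return list(self._calls.values())

    def __len__(self) -> int:
        return len(self._calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self._calls.values())

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self._calls

    def get(self, key: tuple[str, int, str, str]) -> VariantCall | None:
        return self._calls.get(key)

    def subset(self, calls: Iterable[VariantCall], label: str | None = None) -> "CallSet":
        return CallSet(label or self.label, self.sample, calls)

    def by_class(self, *classes: VariantClass) -> "CallSet":
        wanted = set(classes)
        return self.subset(c for c in self if c.vclass in wanted)


class RegionSet:
    """Merged, sorted genomic intervals (0-based half-open internally)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        raw: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty/negative interval {chrom}:{start}-{end}")
            raw.setdefault(chrom, []).append((start, end))
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, ivs in raw.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._by_chrom[chrom] = ([s for s, _ in merged], [e for _, e in merged])

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._by_chrom):
            starts, ends = self._by_chrom[chrom]
            out.extend((chrom, s, e) for s, e in zip(starts, ends))
        return out

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff the 0-based half-open query intersects any interval."""
        if chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[chrom]
        i = bisect.bisect_right(starts, start)
        if i > 0 and ends[i - 1] > start:
            return True
        return i < len(starts) and starts[i] < end

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self._by_chrom.values())


class Reference:
    """In-memory reference: chromosome name -> uppercase nucleotide string."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = {k: v.upper() for k, v in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Reference":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def fetch(self, chrom: str, pos: int, length: int) -> str:
        """Sequence of ``length`` bases starting at 1-based ``pos``."""
        seq = self.sequences[chrom]
        return seq[pos - 1 : pos - 1 + length]

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def check(self, v: VariantCall) -> None:
        got = self.fetch(v.chrom, v.pos, len(v.ref))
        if got != v.ref:
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.pos}: call ref {v.ref!r}, reference has {got!r}"
            )

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.sequences:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _zygosity_from_gt(alleles: Sequence[int | None], alt_index: int) -> Zygosity | None:
    """Zygosity of one split ALT from a genotype tuple; None means no call.

    Single-allele (hemizygous) genotypes are treated as HOM_ALT.
    """
    called = [a for a in alleles if a is not None]
    if not called or alt_index not in called:
        return None
    if len(called) == 1:
        return Zygosity.HOM_ALT
    return Zygosity.HOM_ALT if all(a == alt_index for a in called) else Zygosity.HET


def read_callset(
    vcf_path: str | Path,
    label: str,
    sample: str | None = None,
    keep_filtered: bool = False,
) -> CallSet:
    """Read a VCF into a CallSet, splitting multiallelic records.

    Zygosity is derived from GT (0/1 -> HET, 1/1 -> HOM_ALT); DP populates
    ``depth``.  Records with FILTER other than PASS/"." are excluded unless
    ``keep_filtered``.  0/0 and ./. genotypes are skipped.  INFO keys VQ,
    KNOWN and CSQ populate quality_flag, known and consequence when present.
    """
    import pysam

    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)
    if sample is None:
        if len(samples) > 1:
            raise ValueError(f"{vcf_path}: multi-sample VCF, sample name required")
        sample = samples[0] if samples else None
    elif sample not in samples:
        raise ValueError(f"{vcf_path}: sample {sample!r} not present (has {samples})")

    cs = CallSet(label, sample or "")
    for rec in vf:
        if not keep_filtered:
            flt = set(rec.filter.keys())
            if flt and flt != {"PASS"}:
                continue
        if rec.alts is None:
            continue
        if sample is not None:
            fmt = rec.samples[sample]
            gt = fmt.get("GT")
            depth = fmt.get("DP")
        else:
            gt, depth = None, None
        def _info(key):
            try:
                return rec.info.get(key)
            except (KeyError, ValueError):  # key absent from header
                return None

        quality_flag = _info("VQ")
        known_raw = _info("KNOWN")
        known = bool(known_raw) if known_raw is not None else None
        consequence = _info("CSQ")
        for alt_index, alt in enumerate(rec.alts, start=1):
            if alt is None or not _ACGT.issuperset(alt):
                logger.warning("%s: skipping symbolic/invalid ALT at %s:%d", vcf_path, rec.chrom, rec.pos)
                continue
            if gt is not None:
                zyg = _zygosity_from_gt(gt, alt_index)
                if zyg is None:
                    continue
            else:
                zyg = Zygosity.HET
            cs.add(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref.upper(),
                    alt=alt.upper(),
                    zygosity=zyg,
                    depth=int(depth) if depth is not None else None,
                    quality_flag=quality_flag,
                    known=known,
                    consequence=consequence,
                    source=label,
                )
            )
    return cs


_VCF_HEADER_LINES = [
    '##INFO=<ID=VQ,Number=1,Type=String,Description="Quality flag">',
    '##INFO=<ID=KNOWN,Number=1,Type=Integer,Description="1 if site is in the known-sites catalogue">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence tag">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]


def write_callset(cs: CallSet, path: str | Path, ref: Reference) -> None:
    """Write a CallSet as a sorted single-sample VCF 4.2 file."""
    import pysam

    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    for chrom in ref.sequences:
        header.contigs.add(chrom, length=ref.chrom_length(chrom))
    sample = cs.sample or "SAMPLE"
    header.add_sample(sample)

    order = {c: i for i, c in enumerate(ref.sequences)}
    calls = sorted(cs, key=lambda v: (order.get(v.chrom, len(order)), v.pos, v.ref, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in calls:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt), filter="PASS"
            )
            if v.quality_flag is not None:
                rec.info["VQ"] = v.quality_flag
            if v.known is not None:
                rec.info["KNOWN"] = int(v.known)
            if v.consequence is not None:
                rec.info["CSQ"] = v.consequence
            rec.samples[sample]["GT"] = (0, 1) if v.zygosity is Zygosity.HET else (1, 1)
            rec.samples[sample].phased = False
            if v.depth is not None:
                rec.samples[sample]["DP"] = v.depth
            out.write(rec)


def read_regions(bed_path: str | Path) -> RegionSet:
    """Read a BED3 file (0-based half-open) into a RegionSet."""
    intervals = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{bed_path}:{lineno}: expected >= 3 BED columns")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return RegionSet(intervals)


def read_known_sites(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Read a known-sites TSV (chrom, pos, ref, alt; 1-based)."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("chrom\t"):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            out.add((chrom, int(pos), ref.upper(), alt.upper()))
    return out


def restrict_to_regions(cs: CallSet, rs: RegionSet) -> CallSet:
    """Retain calls intersecting the region set.

    SNVs use their anchored position; indels/MNVs their full reference span
    (closed [pos, pos + len(ref) - 1] in 1-based terms).
    """
    kept = []
    for v in cs:
        start0 = v.pos - 1
        end0 = v.pos - 1 + (1 if v.vclass is VariantClass.SNV else len(v.ref))
        if rs.overlaps(v.chrom, start0, end0):
            kept.append(v)
    return cs.subset(kept)


def filter_calls(
    cs: CallSet,
    min_depth: int = 0,
    quality_flags: set[str] | None = None,
    consequence_tags: set[str] | None = None,
) -> CallSet:
    """Conjunctive attribute filtering.

    When a filter is active, calls lacking that attribute are dropped
    (conservative).  ``min_depth`` uses >= semantics; ``min_depth=0`` with no
    other filter is the identity.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be non-negative")
    kept = []
    for v in cs:
        if min_depth > 0 and (v.depth is None or v.depth < min_depth):
            continue
        if quality_flags is not None and v.quality_flag not in quality_flags:
            continue
        if consequence_tags is not None and v.consequence not in consequence_tags:
            continue
        kept.append(v)
    return cs.subset(kept)
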