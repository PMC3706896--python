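"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the normalization
oracle enumerates candidate edits by applying them to the sequence and
comparing results; the clustering oracle builds the exhaustive pairwise
match graph and takes networkx connected components.
"""

from __future__ import annotations

import itertools

import networkx as nx

from concordkit.normalize import (
    IntervalizedIndel,
    MatchConfig,
    indel_match,
    intervalize,
    snv_match,
)
from concordkit.variants import CallSet, Reference, VariantCall, VariantClass


_TI = {"A": "G", "G": "A", "C": "T", "T": "C"}


def make_snv(reference: Reference, chrom: str, pos: int, zyg=None, transversion=False):
    """Reference-consistent SNV at a position (transition unless asked otherwise)."""
    from concordkit.variants import Zygosity

    base = reference.sequences[chrom][pos - 1]
    alt = _TI[base] if not transversion else {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
    return VariantCall(chrom, pos, base, alt, zygosity=zyg or Zygosity.HET)


def apply_edit(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply a 1-based anchored edit to a sequence."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def oracle_leftmost(v: VariantCall, reference: Reference, margin: int = 80):
    """Leftmost minimal anchored representation by exhaustive enumeration.

    Applies the edit, then scans every candidate deletion/insertion position
    (within a window comfortably larger than any repeat run the generator
    produces) for the leftmost position whose edit reproduces the same
    alternate sequence.  Returns (pos, ref, alt).
    """
    chrom_seq = reference.sequences[v.chrom]
    lo = max(0, v.pos - 1 - margin)
    hi = min(len(chrom_seq), v.pos - 1 + len(v.ref) + margin)
    seq = chrom_seq[lo:hi]
    local = apply_edit(seq, v.pos - lo, v.ref, v.alt)
    k = len(seq) - len(local)
    if k > 0:  # net deletion
        for i in range(1, len(seq) - k + 1):
            if seq[:i] + seq[i + k :] == local:
                return (lo + i, seq[i - 1 : i + k], seq[i - 1])
        raise AssertionError("no equivalent deletion found")
    if k < 0:  # net insertion
        m = -k
        for j in range(1, len(seq) + 1):
            ins = local[j : j + m]
            if seq[:j] + ins + seq[j:] == local:
                return (lo + j, seq[j - 1], seq[j - 1] + ins)
        raise AssertionError("no equivalent insertion found")
    first = next(i for i in range(len(seq)) if seq[i] != local[i])
    last = next(i for i in range(len(seq) - 1, -1, -1) if seq[i] != local[i])
    return (lo + first + 1, seq[first : last + 1], local[first : last + 1])


def oracle_cluster(sets: list[CallSet], cfg: MatchConfig, reference: Reference):
    """Connected components of the exhaustive pairwise match graph.

    Returns a set of frozensets of (label, normalized call key) node ids —
    an order-free canonical form directly comparable with
    ``canonical_classes(cluster_variants(...))``.
    """
    from concordkit.normalize import left_normalize

    nodes = []
    seen = set()
    for cs in sets:
        for v in cs:
            n = left_normalize(v, reference)
            nid = (cs.label, n.key)
            if nid in seen:
                continue
            seen.add(nid)
            ii = intervalize(n, cfg, reference) if n.is_indel else None
            nodes.append((nid, n, ii))

    g = nx.Graph()
    g.add_nodes_from(nid for nid, _, _ in nodes)
    for (ida, a, iia), (idb, b, iib) in itertools.combinations(nodes, 2):
        if (iia is None) != (iib is None):
            continue
        if iia is not None:
            if indel_match(iia, iib, cfg):
                g.add_edge(ida, idb)
        else:
            if a.vclass is VariantClass.SNV and b.vclass is VariantClass.SNV:
                if snv_match(a, b, cfg):
                    g.add_edge(ida, idb)
            else:
                key_a = a.key + ((a.zygosity,) if cfg.require_zygosity_snv else ())
                key_b = b.key + ((b.zygosity,) if cfg.require_zygosity_snv else ())
                if key_a == key_b:
                    g.add_edge(ida, idb)
    return {frozenset(c) for c in nx.connected_components(g)}


def canonical_classes(classes):
    """Canonicalize cluster_variants output to match oracle_cluster's form."""
    return {
        frozenset((label, c.key) for label, calls in ec.members.items() for c in calls)
        for ec in classes
    }
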