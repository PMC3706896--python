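"""Putative de novo variant detection with multi-generational filtering.

A child's call absent from both parents is a de novo candidate — but with
per-individual false-negative (dropout) rates, most such candidates are
inherited variants the parents' call sets simply missed.  Filtering the
candidates against grandparental call sets removes candidates whose allele is
visible one generation further up, collapsing the candidate list toward the
handful of genuinely new mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .normalize import MatchConfig, cluster_variants
from .variants import CallSet, Reference, filter_calls

logger = logging.getLogger(__name__)


@dataclass
class Pedigree:
    """Individuals with parent links spanning 2-3 generations.

    ``generation`` assigns founders 0; every individual's parents must have a
    strictly smaller generation index (this also guarantees acyclicity).
    """

    individuals: set[str] = field(default_factory=set)
    father: dict[str, str] = field(default_factory=dict)
    mother: dict[str, str] = field(default_factory=dict)
    generation: dict[str, int] = field(default_factory=dict)
    family: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for child, parent_map in (("father", self.father), ("mother", self.mother)):
            for kid, par in parent_map.items():
                if kid not in self.individuals or par not in self.individuals:
                    raise ValueError(f"unknown individual in {child} link {kid}->{par}")
                if self.generation[par] >= self.generation[kid]:
                    raise ValueError(
                        f"parent {par} (gen {self.generation[par]}) not older than "
                        f"{kid} (gen {self.generation[kid]})"
                    )

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        return self.father.get(individual), self.mother.get(individual)

    def grandparents(self, individual: str) -> list[str]:
        gps = []
        for par in self.parents(individual):
            if par is not None:
                gps.extend(g for g in self.parents(par) if g is not None)
        return gps

    @classmethod
    def from_ped(cls, path: str | Path) -> "Pedigree":
        """Read a PED-like TSV: family, individual, father, mother, sex, generation.

        '0' or '.' in a parent column means unknown.
        """
        ped = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{lineno}: expected 6 columns")
                fam, ind, fa, mo, _sex, gen = parts[:6]
                ped.individuals.add(ind)
                ped.family[ind] = fam
                ped.generation[ind] = int(gen)
                if fa not in ("0", "."):
                    ped.father[ind] = fa
                if mo not in ("0", "."):
                    ped.mother[ind] = mo
        ped.validate()
        return ped


def _present_keys(
    child: CallSet, others: Sequence[CallSet], cfg: MatchConfig, ref: Reference
) -> set[tuple[str, int, str, str]]:
    """Normalized keys of child calls whose class contains a call from any other set.

    Matching ignores zygosity: a heterozygous parent call must suppress a
    homozygous child candidate, so allele presence alone decides.
    """
    presence_cfg = MatchConfig(
        window=cfg.window,
        require_zygosity_snv=False,
        require_zygosity_indel=False,
        composition_mode=cfg.composition_mode,
    )
    labels = [child.label] + [o.label for o in others]
    if len(set(labels)) == len(labels):
        sets, child_label = [child] + list(others), child.label
    else:  # relabel defensively when callers reuse a label
        sets = [CallSet("__child__", child.sample, child.calls)] + [
            CallSet(f"__other_{i}__", o.sample, o.calls) for i, o in enumerate(others)
        ]
        child_label = "__child__"
    classes = cluster_variants(sets, presence_cfg, ref)
    hit = set()
    for ec in classes:
        child_calls = ec.members.get(child_label, [])
        if child_calls and len(ec.labels) > 1:
            hit.update(c.key for c in child_calls)
    return hit


def _normalized_callset(cs: CallSet, ref: Reference) -> CallSet:
    from .normalize import left_normalize

    seen: dict[tuple, object] = {}
    for v in cs:
        n = left_normalize(v, ref)
        seen.setdefault(n.key, n)
    return CallSet(cs.label, cs.sample, seen.values())


def candidate_de_novo(
    child: CallSet,
    father: CallSet,
    mother: CallSet,
    cfg: MatchConfig,
    ref: Reference,
) -> CallSet:
    """Child calls with no matching call in either parent (normalized keys).

    Both parents are required; zygosity is never part of the parental match.
    Output calls are left-normalized representatives.
    """
    if father is None or mother is None:
        raise ValueError("both parent call sets are required")
    child_n = _normalized_callset(child, ref)
    inherited = _present_keys(child_n, [father, mother], cfg, ref)
    return CallSet(
        f"{child.label}-denovo-candidates",
        child.sample,
        (v for v in child_n if v.key not in inherited),
    )


def ancestor_filter(
    candidates: CallSet,
    ancestors: Sequence[CallSet],
    cfg: MatchConfig,
    ref: Reference,
) -> CallSet:
    """Remove candidates whose allele appears in any ancestor call set.

    A grandparental match implies the child inherited the allele through a
    parental false negative.  An empty ancestor list is the identity.
    """
    if not ancestors:
        logger.warning("ancestor_filter called with no ancestors; returning candidates unchanged")
        return candidates
    seen = _present_keys(candidates, list(ancestors), cfg, ref)
    return CallSet(
        candidates.label + "-ancestor-filtered",
        candidates.sample,
        (v for v in candidates if v.key not in seen),
    )


def consequence_filter(cs: CallSet, tags: set[str], strict: bool = False) -> CallSet:
    """Retain calls whose consequence tag is in ``tags``.

    In strict mode a call without a tag is an error; otherwise it is dropped.
    """
    if strict and any(v.consequence is None for v in cs):
        raise ValueError("calls without consequence tags present (strict mode)")
    return filter_calls(cs, consequence_tags=tags)
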