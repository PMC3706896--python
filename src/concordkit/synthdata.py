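"""Synthetic study generator: reference, truth variants, per-pipeline call
sets, an orthogonal-platform set, and multi-generational pedigrees.

The generator emulates the statistical structure of a multi-pipeline exome
comparison study, scaled down so everything runs at desk scale:

* a toy reference with homopolymer runs injected so indel representation
  ambiguity actually occurs;
* a truth set of SNVs (transition-rich, Ti/Tv ~ 3) and indels placed
  preferentially inside runs, with known-site labels and consequence tags;
* per-pipeline call sets with independent false-negative dropout,
  pipeline-private false positives (transversion-rich, Ti/Tv ~ 0.5),
  representation "jitter" that re-anchors an emitted indel at an equivalent
  non-leftmost coordinate in its run, per-call depths, and zygosity errors;
* an orthogonal platform set that additionally carries a private stratum of
  truth the pipelines never emit;
* a three-generation pedigree with Mendelian transmission, injected de novo
  events, and per-individual call dropout.

Every generator is deterministic under a fixed seed and returns in-memory
truth provenance sufficient to compute expected values for every downstream
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .evaluation import GenotypeTruthSet
from .pedigree import Pedigree
from .variants import CallSet, Reference, VariantCall, VariantClass, Zygosity

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_CONSEQUENCES = ("NONSYN", "NONSENSE", "SYN", "NONE")
_CONSEQUENCE_P = (0.10, 0.02, 0.25, 0.63)


@dataclass(frozen=True)
class PipelineSpec:
    """Error model of one simulated variant-calling pipeline."""

    label: str
    fn_rate: float = 0.05
    fp_rate: float = 0.04
    fp_titv: float = 0.5
    jitter_prob: float = 0.5
    depth_mean: float = 120.0
    depth_shape: float = 2.0
    zygosity_error_rate: float = 0.0
    calls_indels: bool = True

    def __post_init__(self) -> None:
        for r in (self.fn_rate, self.fp_rate, self.jitter_prob, self.zygosity_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")


@dataclass(frozen=True)
class PedigreeSpec:
    """Three- (or two-) generation family simulation parameters."""

    generations: int = 3
    n_children: int = 2
    n_sites: int = 8000
    n_de_novo: int = 2
    dropout: float = 0.05
    allele_freq_range: tuple[float, float] = (0.3, 0.9)

    def __post_init__(self) -> None:
        if self.generations not in (2, 3):
            raise ValueError("generations must be 2 or 3")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout outside [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level generator settings (defaults are the simulated study)."""

    seed: int = 0
    genome_length: int = 500_000
    n_chromosomes: int = 2
    homopolymer_per_kb: float = 2.0
    run_length_range: tuple[int, int] = (6, 14)
    n_snv: int = 2000
    n_indel: int = 200
    indel_geom_p: float = 0.55
    max_indel_len: int = 20
    known_fraction: float = 0.7
    titv_true: float = 3.0
    het_fraction: float = 2 / 3
    indel_in_run_prob: float = 0.9
    min_spacing: int = 25
    platform_private_rate: float = 0.11
    platform_fn_rate: float = 0.05
    pipelines: tuple[PipelineSpec, ...] = ()
    pedigree: PedigreeSpec = field(default_factory=PedigreeSpec)

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), salt])


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def expected_concordance(fn_rates: Sequence[float], fp_rates: Sequence[float]) -> float:
    """Analytic N-way concordance under the generator's error model.

    With independent per-pipeline false-negative events and pipeline-private
    false positives, the expected number of equivalence classes per truth
    variant detected by at least one pipeline is 1 - prod(fn_i), every class
    supported by all N pipelines has probability prod(1 - fn_i), and each
    pipeline contributes a disjoint stratum of fp_i * n_truth singleton
    classes.  Concordance = intersection / union is then independent of the
    truth-set size.
    """
    fn = np.asarray(fn_rates, dtype=float)
    fp = np.asarray(fp_rates, dtype=float)
    p_all = float(np.prod(1.0 - fn))
    p_any = 1.0 - float(np.prod(fn))
    return p_all / (p_any + float(fp.sum()))


def calibrate_fp_rates(fn_rates: Sequence[float], target: float) -> list[float]:
    """Per-pipeline FP rates (equal shares) giving the target concordance."""
    fn = np.asarray(fn_rates, dtype=float)
    p_all = float(np.prod(1.0 - fn))
    p_any = 1.0 - float(np.prod(fn))
    total = p_all / target - p_any
    if total < 0:
        raise ValueError(
            f"target concordance {target} unreachable with fn rates {list(fn_rates)}"
        )
    return [total / len(fn)] * len(fn)


def default_pipelines(target_concordance: float = 0.574) -> tuple[PipelineSpec, ...]:
    """Five pipelines with FN rates mirroring typical per-tool sensitivities
    (roughly 87-95%) and FP rates calibrated to the target N-way concordance.

    Two of the five call SNVs only, as in the emulated study design.
    """
    labels = ["gatk", "soapsnp", "snver", "gnumap", "samtools"]
    fns = [0.047, 0.053, 0.077, 0.134, 0.055]
    indels = [True, True, False, False, True]
    fps = calibrate_fp_rates(fns, target_concordance)
    return tuple(
        PipelineSpec(label=l, fn_rate=fn, fp_rate=fp, calls_indels=ci)
        for l, fn, fp, ci in zip(labels, fns, fps, indels)
    )


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def find_runs(seq: str, min_len: int = 4) -> list[tuple[int, int, str]]:
    """Maximal homopolymer runs as (start0, length, base)."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i, seq[i]))
        i = j
    return runs


def make_reference(cfg: SimulationConfig) -> Reference:
    """Random reference with homopolymer runs injected at the configured density.

    With ``homopolymer_per_kb == 0`` the background sequence is constrained so
    that no run of length > 3 occurs.
    """
    rng = cfg.rng(1)
    per_chrom = cfg.genome_length // cfg.n_chromosomes
    seqs = {}
    for c in range(cfg.n_chromosomes):
        arr = _BASES[rng.integers(0, 4, size=per_chrom)]
        if cfg.homopolymer_per_kb == 0:
            # break any background run at length 3
            seq = arr  # mutate in place below
            for i in range(3, per_chrom):
                if seq[i] == seq[i - 1] == seq[i - 2] == seq[i - 3]:
                    choices = [b for b in "ACGT" if b != seq[i - 1]]
                    seq[i] = choices[rng.integers(0, 3)]
        else:
            n_runs = int(round(cfg.homopolymer_per_kb * per_chrom / 1000))
            lo, hi = cfg.run_length_range
            starts = rng.integers(100, per_chrom - hi - 100, size=n_runs)
            for s in starts:
                length = int(rng.integers(lo, hi + 1))
                base = str(_BASES[rng.integers(0, 4)])
                arr[s : s + length] = base
                # delimit the run so it is maximal
                for edge in (s - 1, s + length):
                    if arr[edge] == base:
                        choices = [b for b in "ACGT" if b != base]
                        arr[edge] = choices[rng.integers(0, 3)]
        seqs[f"chr{c + 1}"] = "".join(arr)
    return Reference(seqs)


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    """Ground-truth variants plus provenance needed by downstream oracles."""

    variants: list[VariantCall]
    known_keys: set[tuple[str, int, str, str]]
    platform_private: set[tuple[str, int, str, str]] = field(default_factory=set)

    @property
    def snvs(self) -> list[VariantCall]:
        return [v for v in self.variants if v.vclass is VariantClass.SNV]

    @property
    def indels(self) -> list[VariantCall]:
        return [v for v in self.variants if v.is_indel]

    def pipeline_visible(self) -> list[VariantCall]:
        return [v for v in self.variants if v.key not in self.platform_private]


class _SitePool:
    """Draws genome positions keeping a global minimum spacing (shared across
    pipelines so false positives stay disjoint)."""

    def __init__(self, ref: Reference, spacing: int):
        self.ref = ref
        self.spacing = spacing
        self._used: dict[str, list[int]] = {c: [] for c in ref.sequences}
        self._chroms = list(ref.sequences)

    def reserve(self, chrom: str, pos: int) -> bool:
        import bisect

        used = self._used[chrom]
        i = bisect.bisect_left(used, pos)
        for j in (i - 1, i):
            if 0 <= j < len(used) and abs(used[j] - pos) < self.spacing:
                return False
        used.insert(i, pos)
        return True

    def draw(self, rng: np.random.Generator, margin: int = 100) -> tuple[str, int]:
        for _ in range(10_000):
            chrom = self._chroms[rng.integers(0, len(self._chroms))]
            n = self.ref.chrom_length(chrom)
            pos = int(rng.integers(margin, n - margin))
            if self.reserve(chrom, pos):
                return chrom, pos
        raise RuntimeError("site pool exhausted; lower variant counts or enlarge genome")


def _draw_snv_alleles(ref_base: str, titv: float, rng: np.random.Generator) -> str:
    p_ti = titv / (1.0 + titv)
    if rng.random() < p_ti:
        return _TRANSITION[ref_base]
    tv = [b for b in "ACGT" if b != ref_base and b != _TRANSITION[ref_base]]
    return tv[int(rng.integers(0, 2))]


def _draw_zygosity(cfg: SimulationConfig, rng: np.random.Generator) -> Zygosity:
    return Zygosity.HET if rng.random() < cfg.het_fraction else Zygosity.HOM_ALT


def _draw_consequence(rng: np.random.Generator) -> str:
    return _CONSEQUENCES[int(rng.choice(len(_CONSEQUENCES), p=_CONSEQUENCE_P))]


def simulate_truth(cfg: SimulationConfig, ref: Reference) -> tuple[TruthSet, _SitePool]:
    """Draw the ground-truth variant set.

    SNVs are transition-rich at ``titv_true``; indels (geometric sizes,
    capped) are placed inside homopolymer runs with probability
    ``indel_in_run_prob``, anchored at their leftmost representation.
    Known-site labels are drawn at ``known_fraction``; a
    ``platform_private_rate`` fraction is marked private to the orthogonal
    platform.  Positions keep a minimum spacing so distinct truth variants
    never share a matching window.
    """
    rng = cfg.rng(2)
    pool = _SitePool(ref, cfg.min_spacing)

    # use the engineered long runs (not length-4 background noise) so in-run
    # indels admit several equivalent representations
    min_run = min(6, cfg.run_length_range[0])
    run_slots: list[tuple[str, int, int, str]] = []
    for chrom, seq in ref.sequences.items():
        for start0, length, base in find_runs(seq, min_len=min_run):
            if start0 > 100 and start0 + length < len(seq) - 100:
                run_slots.append((chrom, start0, length, base))
    rng.shuffle(run_slots)

    variants: list[VariantCall] = []

    # --- indels ---
    sizes = np.minimum(rng.geometric(cfg.indel_geom_p, size=cfg.n_indel), cfg.max_indel_len)
    slot_i = 0
    for size in sizes:
        size = int(size)
        is_del = rng.random() < 0.5
        placed = False
        if rng.random() < cfg.indel_in_run_prob:
            while slot_i < len(run_slots):
                chrom, start0, length, base = run_slots[slot_i]
                slot_i += 1
                if is_del and length < size:
                    continue
                pos = start0  # 1-based anchor = base before the run
                if not pool.reserve(chrom, pos):
                    continue
                anchor = ref.sequences[chrom][start0 - 1]
                if is_del:
                    v_ref, v_alt = anchor + base * size, anchor
                else:
                    v_ref, v_alt = anchor, anchor + base * size
                variants.append(VariantCall(chrom, pos, v_ref, v_alt,
                                            zygosity=_draw_zygosity(cfg, rng)))
                placed = True
                break
        if not placed:
            chrom, pos = pool.draw(rng)
            seq = ref.sequences[chrom]
            anchor = seq[pos - 1]
            if is_del:
                v_ref, v_alt = seq[pos - 1 : pos + size], anchor
            else:
                ins = "".join(_BASES[rng.integers(0, 4, size=size)])
                v_ref, v_alt = anchor, anchor + ins
            if v_ref == v_alt:
                continue
            v = VariantCall(chrom, pos, v_ref, v_alt, zygosity=_draw_zygosity(cfg, rng))
            from .normalize import left_normalize

            variants.append(left_normalize(v, ref))

    # --- SNVs ---
    for _ in range(cfg.n_snv):
        chrom, pos = pool.draw(rng)
        ref_base = ref.sequences[chrom][pos - 1]
        alt = _draw_snv_alleles(ref_base, cfg.titv_true, rng)
        variants.append(
            VariantCall(chrom, pos, ref_base, alt, zygosity=_draw_zygosity(cfg, rng),
                        consequence=_draw_consequence(rng))
        )

    known = {v.key for v in variants if rng.random() < cfg.known_fraction}
    private = {v.key for v in variants if rng.random() < cfg.platform_private_rate}
    truth = TruthSet(
        variants=[replace(v, known=(v.key in known), source="truth") for v in variants],
        known_keys=known,
        platform_private=private,
    )
    return truth, pool


# ---------------------------------------------------------------------------
# Equivalent indel representations (jitter machinery)
# ---------------------------------------------------------------------------

def equivalent_representations(
    v: VariantCall, ref: Reference, max_steps: int = 50
) -> list[VariantCall]:
    """All right-shifted representations equivalent to a left-normalized indel.

    The first element is ``v`` itself (leftmost); subsequent elements shift
    the edit right one base at a time while the edit stays equivalent
    (rotating the edited string through the reference).  The last element is
    the rightmost-aligned representation.
    """
    seq = ref.sequences[v.chrom]
    vc = v.vclass
    reps = [v]
    if vc is VariantClass.DEL:
        k = len(v.ref) - 1
        i = v.pos  # 0-based start of the deleted segment
        for _ in range(max_steps):
            if i + k >= len(seq) or seq[i] != seq[i + k]:
                break
            i += 1
            reps.append(replace(v, pos=i, ref=seq[i - 1 : i + k], alt=seq[i - 1]))
    elif vc is VariantClass.INS:
        e = v.alt[1:]
        j = v.pos  # 0-based index the insertion precedes
        for _ in range(max_steps):
            if j >= len(seq) or e[0] != seq[j]:
                break
            e = e[1:] + seq[j]
            j += 1
            reps.append(replace(v, pos=j, ref=seq[j - 1], alt=seq[j - 1] + e))
    else:
        raise ValueError("equivalent_representations requires an indel")
    return reps


# ---------------------------------------------------------------------------
# Call sets
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCallSet:
    callset: CallSet
    recovered_truth: set[tuple[str, int, str, str]]  # truth keys emitted (pre-jitter)
    fp_keys: set[tuple[str, int, str, str]]


def _draw_depth(spec: PipelineSpec, rng: np.random.Generator) -> int:
    lam = rng.gamma(spec.depth_shape, spec.depth_mean / spec.depth_shape)
    return int(rng.poisson(lam))


def simulate_callset(
    truth: TruthSet,
    spec: PipelineSpec,
    ref: Reference,
    rng: np.random.Generator,
    pool: _SitePool | None = None,
    sample: str = "S1",
) -> SimulatedCallSet:
    """Emit one pipeline's call set from the truth under its error model.

    Truth variants are dropped independently at ``fn_rate``; emitted indels
    are re-anchored at a uniformly chosen non-leftmost equivalent coordinate
    with probability ``jitter_prob``; zygosity flips at
    ``zygosity_error_rate``; depths are gamma-Poisson and independent of
    truth status.  False positives (``fp_rate`` x the visible truth count)
    are placed at fresh positions drawn from the shared site pool, keeping
    them pipeline-private, with SNV alleles at ``fp_titv``.
    """
    if pool is None:
        pool = _SitePool(ref, 25)
        for v in truth.variants:
            pool.reserve(v.chrom, v.pos)

    calls: list[VariantCall] = []
    recovered: set = set()
    visible = [v for v in truth.pipeline_visible() if spec.calls_indels or not v.is_indel]
    for v in visible:
        if rng.random() < spec.fn_rate:
            continue
        recovered.add(v.key)
        out = v
        if v.is_indel and spec.jitter_prob > 0 and rng.random() < spec.jitter_prob:
            reps = equivalent_representations(v, ref)
            if len(reps) > 1:
                out = reps[int(rng.integers(1, len(reps)))]
        if spec.zygosity_error_rate > 0 and rng.random() < spec.zygosity_error_rate:
            flipped = Zygosity.HOM_ALT if out.zygosity is Zygosity.HET else Zygosity.HET
            out = replace(out, zygosity=flipped)
        calls.append(replace(out, depth=_draw_depth(spec, rng), source=spec.label))

    n_truth_visible = len(visible)
    n_fp = int(round(spec.fp_rate * n_truth_visible))
    n_indel_visible = sum(1 for v in visible if v.is_indel)
    p_indel_fp = n_indel_visible / n_truth_visible if n_truth_visible else 0.0
    fp_keys: set = set()
    for _ in range(n_fp):
        chrom, pos = pool.draw(rng)
        seq = ref.sequences[chrom]
        anchor = seq[pos - 1]
        if spec.calls_indels and rng.random() < p_indel_fp:
            size = int(min(rng.geometric(0.55), 20))
            if rng.random() < 0.5 and len(set(seq[pos : pos + size])) >= 1:
                v_ref, v_alt = seq[pos - 1 : pos + size], anchor
            else:
                ins = "".join(_BASES[rng.integers(0, 4, size=size)])
                v_ref, v_alt = anchor, anchor + ins
            if v_ref == v_alt:
                continue
            from .normalize import left_normalize

            fp = left_normalize(
                VariantCall(chrom, pos, v_ref, v_alt, zygosity=_draw_zygosity_default(rng)),
                ref,
            )
        else:
            alt = _draw_snv_alleles(anchor, spec.fp_titv, rng)
            fp = VariantCall(chrom, pos, anchor, alt, zygosity=_draw_zygosity_default(rng))
        fp = replace(fp, depth=_draw_depth(spec, rng), source=spec.label)
        fp_keys.add(fp.key)
        calls.append(fp)

    cs = CallSet(spec.label, sample)
    for c in calls:
        if c.key not in cs:
            cs.add(c)
    return SimulatedCallSet(callset=cs, recovered_truth=recovered, fp_keys=fp_keys)


def _draw_zygosity_default(rng: np.random.Generator) -> Zygosity:
    return Zygosity.HET if rng.random() < 2 / 3 else Zygosity.HOM_ALT


def simulate_platform(
    truth: TruthSet,
    ref: Reference,
    rng: np.random.Generator,
    fn_rate: float = 0.05,
    vqhigh_fraction: float = 0.9,
    label: str = "platform",
    sample: str = "S1",
) -> SimulatedCallSet:
    """Orthogonal-platform call set: all truth (including the private stratum
    the pipelines never emit) minus its own dropouts, with quality flags."""
    calls = []
    recovered = set()
    for v in truth.variants:
        if rng.random() < fn_rate:
            continue
        recovered.add(v.key)
        flag = "VQHIGH" if rng.random() < vqhigh_fraction else "VQLOW"
        calls.append(replace(v, quality_flag=flag, source=label))
    cs = CallSet(label, sample, calls)
    return SimulatedCallSet(callset=cs, recovered_truth=recovered, fp_keys=set())


def simulate_study(
    cfg: SimulationConfig, ref: Reference | None = None, sample: str = "S1", salt: int = 3
) -> tuple[Reference, TruthSet, list[SimulatedCallSet], SimulatedCallSet]:
    """End-to-end scenario: reference, truth, N pipeline sets, platform set."""
    if ref is None:
        ref = make_reference(cfg)
    truth, pool = simulate_truth(cfg, ref)
    pipelines = cfg.pipelines or default_pipelines()
    rng = cfg.rng(salt)
    sims = [simulate_callset(truth, spec, ref, rng, pool, sample) for spec in pipelines]
    platform = simulate_platform(truth, ref, rng, fn_rate=cfg.platform_fn_rate, sample=sample)
    return ref, truth, sims, platform


def simulate_array_truth(
    truth: TruthSet,
    ref: Reference,
    rng: np.random.Generator,
    n_homref: int = 1000,
    extra_homref_positions: Iterable[tuple[str, int]] = (),
) -> GenotypeTruthSet:
    """Array-style truth genotypes: truth SNVs plus hom-ref sites.

    Hom-ref sites are drawn uniformly away from truth variants; positions in
    ``extra_homref_positions`` (e.g. known pipeline FP sites) are added so the
    specificity denominator exercises false-positive counting.
    """
    ts = GenotypeTruthSet()
    occupied = {(v.chrom, v.pos) for v in truth.variants}
    for v in truth.snvs:
        gt = "HET" if v.zygosity is Zygosity.HET else "HOM_ALT"
        ts.add(v.chrom, v.pos, v.ref, v.alt, gt)
    chroms = list(ref.sequences)
    added = 0
    while added < n_homref:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(100, ref.chrom_length(chrom) - 100))
        if (chrom, pos) in occupied or (chrom, pos) in ts.entries:
            continue
        base = ref.sequences[chrom][pos - 1]
        ts.add(chrom, pos, base, _TRANSITION[base], "HOM_REF")
        added += 1
    for chrom, pos in extra_homref_positions:
        if (chrom, pos) not in ts.entries:
            base = ref.sequences[chrom][pos - 1]
            ts.add(chrom, pos, base, _TRANSITION[base], "HOM_REF")
    return ts


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class SimulatedFamily:
    pedigree: Pedigree
    callsets: dict[str, CallSet]
    genotypes: dict[str, dict[tuple[str, int, str, str], Zygosity]]
    de_novo_manifest: dict[str, list[VariantCall]]


def simulate_pedigree(
    cfg: SimulationConfig, ref: Reference, seed_salt: int = 7
) -> SimulatedFamily:
    """Simulate one family with Mendelian transmission and injected de novos.

    Founder genotypes are drawn per site from a population allele frequency
    ~ Uniform over ``allele_freq_range`` — size-biased toward common
    variation, as the variants an individual carries are.  Children receive
    one allele from each parent; each child gets ``n_de_novo`` injected
    heterozygous de novo SNVs (tagged NONSYN) at fresh sites.  Every
    individual's observed call set then applies ``dropout`` false negatives.
    """
    ped_cfg = cfg.pedigree
    rng = cfg.rng(seed_salt)
    pool = _SitePool(ref, cfg.min_spacing)

    sites: list[tuple[VariantCall, float]] = []
    flo, fhi = ped_cfg.allele_freq_range
    for _ in range(ped_cfg.n_sites):
        chrom, pos = pool.draw(rng)
        base = ref.sequences[chrom][pos - 1]
        alt = _draw_snv_alleles(base, cfg.titv_true, rng)
        v = VariantCall(chrom, pos, base, alt, consequence=_draw_consequence(rng))
        sites.append((v, float(rng.uniform(flo, fhi))))

    ped = Pedigree()

    def add_ind(name: str, gen: int, father: str | None = None, mother: str | None = None):
        ped.individuals.add(name)
        ped.generation[name] = gen
        ped.family[name] = "FAM1"
        if father:
            ped.father[name] = father
        if mother:
            ped.mother[name] = mother

    # alleles[name] = dict key -> (a1, a2) booleans (alt presence per haplotype)
    alleles: dict[str, dict[tuple, tuple[bool, bool]]] = {}

    def draw_founder(name: str, gen: int = 0):
        add_ind(name, gen)
        u = rng.random((len(sites), 2))
        alleles[name] = {
            v.key: (bool(u[i, 0] < f), bool(u[i, 1] < f)) for i, (v, f) in enumerate(sites)
        }

    def transmit(name: str, gen: int, father: str, mother: str):
        add_ind(name, gen, father, mother)
        hap = rng.integers(0, 2, size=(len(sites), 2))
        geno = {}
        for (v, _f), (hp, hm) in zip(sites, hap):
            geno[v.key] = (alleles[father][v.key][hp], alleles[mother][v.key][hm])
        alleles[name] = geno

    if ped_cfg.generations == 3:
        for gp in ("gpF1", "gpF2", "gpM1", "gpM2"):
            draw_founder(gp)
        transmit("father", 1, "gpF1", "gpF2")
        transmit("mother", 1, "gpM1", "gpM2")
    else:
        draw_founder("father", 0)
        draw_founder("mother", 0)
    children = [f"child{i + 1}" for i in range(ped_cfg.n_children)]
    for ch in children:
        transmit(ch, ped_cfg.generations - 1, "father", "mother")
    ped.validate()

    site_by_key = {v.key: v for v, _ in sites}
    manifest: dict[str, list[VariantCall]] = {}
    de_novo_by_child: dict[str, list[VariantCall]] = {}
    for ch in children:
        dn = []
        for _ in range(ped_cfg.n_de_novo):
            chrom, pos = pool.draw(rng)
            base = ref.sequences[chrom][pos - 1]
            alt = _draw_snv_alleles(base, cfg.titv_true, rng)
            dn.append(VariantCall(chrom, pos, base, alt, zygosity=Zygosity.HET,
                                  consequence="NONSYN"))
        manifest[ch] = dn
        de_novo_by_child[ch] = dn

    genotypes: dict[str, dict[tuple, Zygosity]] = {}
    callsets: dict[str, CallSet] = {}
    for name in ped.individuals:
        geno: dict[tuple, Zygosity] = {}
        for key, (a1, a2) in alleles[name].items():
            if a1 and a2:
                geno[key] = Zygosity.HOM_ALT
            elif a1 or a2:
                geno[key] = Zygosity.HET
        for dn in de_novo_by_child.get(name, []):
            geno[dn.key] = Zygosity.HET
        genotypes[name] = geno
        observed = []
        dropped = rng.random(len(geno)) < ped_cfg.dropout
        for (key, zyg), miss in zip(geno.items(), dropped):
            if miss:
                continue
            base = site_by_key.get(key)
            if base is None:
                base = next(d for d in de_novo_by_child[name] if d.key == key)
            observed.append(
                VariantCall(base.chrom, base.pos, base.ref, base.alt, zygosity=zyg,
                            consequence=base.consequence, source=name)
            )
        callsets[name] = CallSet(name, name, observed)
    return SimulatedFamily(
        pedigree=ped, callsets=callsets, genotypes=genotypes, de_novo_manifest=manifest
    )
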