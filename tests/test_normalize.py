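import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from concordkit.normalize import (
    CompositionMode,
    MatchConfig,
    cluster_variants,
    indel_match,
    intervalize,
    left_normalize,
    snv_match,
)
from concordkit.synthdata import equivalent_representations
from concordkit.variants import CallSet, Reference, VariantCall, Zygosity

from _oracles import apply_edit, canonical_classes, oracle_cluster, oracle_leftmost


class TestLeftNormalize:
    def test_homopolymer_deletion_shifts_left(self):
        ref = Reference({"chr1": "GCAAAAC"})
        v = VariantCall("chr1", 5, "AA", "A")
        n = left_normalize(v, ref)
        assert (n.pos, n.ref, n.alt) == (2, "CA", "C")

    def test_idempotent(self):
        ref = Reference({"chr1": "GCAAAAC"})
        n = left_normalize(VariantCall("chr1", 2, "CA", "C"), ref)
        assert (n.pos, n.ref, n.alt) == (2, "CA", "C")
        assert left_normalize(n, ref) == n

    def test_dinucleotide_insertion_representations_converge(self):
        # in-phase insertion of AG anywhere inside ...TAGAGAGC... is one variant
        ref = Reference({"chr1": "CCTAGAGAGCAA"})
        reps = [
            VariantCall("chr1", 3, "T", "TAG"),
            VariantCall("chr1", 5, "G", "GAG"),
            VariantCall("chr1", 7, "G", "GAG"),
            VariantCall("chr1", 9, "G", "GAG"),
        ]
        outs = {left_normalize(v, ref).key for v in reps}
        assert outs == {("chr1", 3, "T", "TAG")}
        # all inputs produce the same alternate sequence (edit-preserving)
        alts = {apply_edit(ref.sequences["chr1"], v.pos, v.ref, v.alt) for v in reps}
        assert len(alts) == 1

    def test_snv_with_padded_flanks_trimmed(self):
        ref = Reference({"chr1": "GCAAAAC"})
        v = VariantCall("chr1", 2, "CAA", "CGA")  # padded SNV A->G at pos 3
        n = left_normalize(v, ref)
        assert (n.pos, n.ref, n.alt) == (3, "A", "G")

    def test_reference_mismatch_raises(self):
        ref = Reference({"chr1": "GCAAAAC"})
        with pytest.raises(ValueError, match="reference mismatch"):
            left_normalize(VariantCall("chr1", 1, "T", "TA"), ref)

    def test_matches_bcftools_norm(self, tmp_path, small_sim):
        """Cross-check against an external normalizer on simulated indels."""
        import subprocess
        from concordkit.variants import write_callset, read_callset
        from concordkit.variants import VariantClass

        _, ref, truth, sims, _ = small_sim
        cs = sims[0].callset.by_class(VariantClass.INS, VariantClass.DEL)
        fasta = tmp_path / "ref.fa"
        ref.write_fasta(fasta)
        subprocess.run(["samtools", "faidx", str(fasta)], check=True)
        raw_vcf = tmp_path / "raw.vcf"
        write_callset(cs, raw_vcf, ref)
        out_vcf = tmp_path / "norm.vcf"
        subprocess.run(
            ["bcftools", "norm", "-f", str(fasta), "-o", str(out_vcf), str(raw_vcf)],
            check=True, capture_output=True,
        )
        theirs = {v.key for v in read_callset(out_vcf, label="bcftools")}
        ours = {left_normalize(v, ref).key for v in cs}
        assert ours == theirs

    def test_oracle_equivalence_on_jittered_indels(self, small_sim):
        _, ref, truth, _, _ = small_sim
        rng = np.random.default_rng(5)
        checked = 0
        for v in truth.indels:
            reps = equivalent_representations(v, ref)
            probe = reps[int(rng.integers(0, len(reps)))]
            n = left_normalize(probe, ref)
            assert (n.pos, n.ref, n.alt) == oracle_leftmost(probe, ref)
            # edit-preserving
            s = ref.sequences[v.chrom]
            assert apply_edit(s, probe.pos, probe.ref, probe.alt) == apply_edit(s, n.pos, n.ref, n.alt)
            checked += 1
        assert checked > 50


@given(
    run_len=st.integers(4, 12),
    del_len=st.integers(1, 3),
    offset=st.integers(0, 8),
    base=st.sampled_from("ACGT"),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_normalization_property_homopolymer(run_len, del_len, offset, base):
    """Any in-run deletion representation normalizes to the oracle leftmost."""
    if del_len > run_len:
        del_len = run_len
    flank = "GC" if base not in "GC" else "AT"
    seq = flank * 3 + base * run_len + flank * 3
    ref = Reference({"c": seq})
    start0 = 6 + min(offset, run_len - del_len)  # deletion start inside the run
    v = VariantCall("c", start0, seq[start0 - 1 : start0 + del_len], seq[start0 - 1])
    n = left_normalize(v, ref)
    assert (n.pos, n.ref, n.alt) == oracle_leftmost(v, ref)
    assert left_normalize(n, ref) == n


class TestIntervalize:
    def test_window_arithmetic_and_clamping(self, toy_ref):
        v = VariantCall("chr1", 3, "AA", "A")
        ii = intervalize(v, MatchConfig(window=10), toy_ref)
        assert ii.lo == max(1, ii.pos - 10) == 1
        assert ii.hi == ii.pos + 10
        assert ii.net_len == -1 and ii.edited_seq == "A"

    def test_window_zero(self, toy_ref):
        v = VariantCall("chr1", 3, "AA", "A")
        ii = intervalize(v, MatchConfig(window=0), toy_ref)
        assert ii.lo == ii.hi == ii.pos

    def test_snv_rejected(self, toy_ref):
        with pytest.raises(ValueError, match="indel"):
            intervalize(VariantCall("chr1", 2, "C", "T"), MatchConfig(), toy_ref)

    def test_wider_window_matches_superset(self, small_sim):
        _, ref, _, sims, _ = small_sim
        from concordkit.variants import VariantClass

        sets = [s.callset.by_class(VariantClass.INS, VariantClass.DEL) for s in sims[:3]]
        for w_small, w_big in [(0, 10), (10, 30)]:
            small = oracle_cluster(sets, MatchConfig(window=w_small), ref)
            big = oracle_cluster(sets, MatchConfig(window=w_big), ref)
            # every small-window class is contained in some big-window class
            for c in small:
                assert any(c <= d for d in big)


class TestMatchPredicates:
    def test_snv_match_reflexive_and_strict(self):
        cfg = MatchConfig()
        a = VariantCall("chr1", 100, "A", "G", zygosity=Zygosity.HET)
        assert snv_match(a, a, cfg)
        hom = VariantCall("chr1", 100, "A", "G", zygosity=Zygosity.HOM_ALT)
        assert not snv_match(a, hom, cfg)
        assert snv_match(a, hom, MatchConfig(require_zygosity_snv=False))
        assert not snv_match(a, VariantCall("chr1", 100, "A", "T"), cfg)

    def test_indel_match_window_boundary_inclusive(self):
        # two G-runs whose leftmost deletion anchors sit exactly 10 bp apart
        ref = Reference({"c": "TT" + "GGG" + "ACGTACT" + "GGG" + "TT"})
        cfg = MatchConfig(window=10)
        a = intervalize(VariantCall("c", 2, "TG", "T"), cfg, ref)
        b = intervalize(VariantCall("c", 12, "TG", "T"), cfg, ref)
        assert (a.pos, b.pos) == (2, 12)
        assert indel_match(a, b, cfg)  # distance 10 == window, inclusive
        assert not indel_match(a, b, MatchConfig(window=9))

    def test_indel_match_length_mismatch(self):
        ref = Reference({"c": "TT" + "GGG" + "ACGTACT" + "GGG" + "TT"})
        cfg = MatchConfig(window=10)
        one = intervalize(VariantCall("c", 2, "TG", "T"), cfg, ref)
        two = intervalize(VariantCall("c", 2, "TGG", "T"), cfg, ref)
        assert not indel_match(one, two, cfg)  # net_len -1 vs -2

    def test_composition_length_only_relaxation(self):
        ref = Reference({"c": "TTACGGGCAGTTT" + "ACGT" * 4})
        cfg_exact = MatchConfig(window=10)
        cfg_len = MatchConfig(window=10, composition_mode=CompositionMode.LENGTH_ONLY)
        a = intervalize(VariantCall("c", 3, "AC", "A"), cfg_exact, ref)   # del C
        b = intervalize(VariantCall("c", 8, "CA", "C"), cfg_exact, ref)   # del A
        assert not indel_match(a, b, cfg_exact)
        assert indel_match(a, b, cfg_len)

    def test_jittered_pair_matches_after_normalization(self):
        ref = Reference({"c": "TT" + "G" * 8 + "ACGTT"})
        cfg = MatchConfig(window=10)
        # same homopolymer deletion reported 3 bp apart pre-normalization
        ia = intervalize(VariantCall("c", 4, "GG", "G"), cfg, ref)
        ib = intervalize(VariantCall("c", 7, "GG", "G"), cfg, ref)
        assert ia.pos == ib.pos == 2
        assert indel_match(ia, ib, cfg)


class TestClusterVariants:
    def test_identical_sets_form_single_class(self, toy_ref):
        v = VariantCall("chr1", 2, "C", "T")
        sets = [CallSet(f"p{i}", calls=[v]) for i in range(5)]
        classes = cluster_variants(sets, MatchConfig(), toy_ref)
        assert len(classes) == 1 and classes[0].support == 5

    def test_single_linkage_chain(self):
        # normalized positions 100/105/112 with window 10: one chained class
        seq = "ACGT" * 60
        ref = Reference({"c": seq})
        def del_at(pos):  # unique-composition 1bp deletion at an exact position
            return VariantCall("c", pos, seq[pos - 1 : pos + 1], seq[pos - 1])
        cfg = MatchConfig(window=10, composition_mode=CompositionMode.LENGTH_ONLY)
        sets = [CallSet("A", calls=[del_at(100)]),
                CallSet("B", calls=[del_at(105)]),
                CallSet("C", calls=[del_at(112)])]
        classes = cluster_variants(sets, cfg, ref)
        assert len(classes) == 1
        assert classes[0].labels == {"A", "B", "C"}
        # yet A and C alone are too far apart to match directly
        assert len(cluster_variants([sets[0], sets[2]], cfg, ref)) == 2

    def test_matches_connected_components_oracle(self, small_sim):
        _, ref, _, sims, _ = small_sim
        cfg = MatchConfig()
        sets = [s.callset for s in sims[:3]]
        ours = canonical_classes(cluster_variants(sets, cfg, ref))
        assert ours == oracle_cluster(sets, cfg, ref)

    def test_permutation_invariance(self, small_sim):
        _, ref, _, sims, _ = small_sim
        cfg = MatchConfig()
        sets = [s.callset for s in sims[:4]]
        a = canonical_classes(cluster_variants(sets, cfg, ref))
        b = canonical_classes(cluster_variants(sets[::-1], cfg, ref))
        shuffled = [CallSet(cs.label, cs.sample, sorted(cs, key=lambda v: (v.alt, -v.pos)))
                    for cs in sets]
        c = canonical_classes(cluster_variants(shuffled, cfg, ref))
        assert a == b == c

    def test_empty_input_rejected(self, toy_ref):
        with pytest.raises(ValueError):
            cluster_variants([], MatchConfig(), toy_ref)
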