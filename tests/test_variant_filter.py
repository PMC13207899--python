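import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

import azcma
from azcma import variant_filter as vf
from azcma.genome import BASES, COMPLEMENT, Transcript, decode_seq, encode_seq


# ---------------------------------------------------------------------------
# six-class and trinucleotide labels
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ref, alt, expected",
    [
        ("C", "G", "C:G>G:C"),
        ("G", "C", "C:G>G:C"),
        ("T", "C", "T:A>C:G"),
        ("C", "T", "C:G>T:A"),
        ("A", "T", "T:A>A:T"),
        ("G", "T", "C:G>A:T"),
    ],
)
def test_classify_six(ref, alt, expected):
    assert vf.classify_six(ref, alt) == expected


def test_classify_six_complement_equivalence_exhaustive():
    for ref, alt in itertools.permutations(BASES, 2):
        assert vf.classify_six(ref, alt) == vf.classify_six(COMPLEMENT[ref], COMPLEMENT[alt])
    assert len({vf.classify_six(r, a) for r, a in itertools.permutations(BASES, 2)}) == 6


def test_classify_six_rejects_bad_input():
    with pytest.raises(ValueError):
        vf.classify_six("C", "C")
    with pytest.raises(ValueError):
        vf.classify_six("CA", "C")


def test_trinuc_context_examples():
    seqs = {"chr1": encode_seq("AACTG")}
    assert vf.trinuc_context(seqs, "chr1", 3, "C", "G") == "A[C>G]T"
    # purine centre: AGT with G>C collapses onto A[C>G]T
    seqs2 = {"chr1": encode_seq("AAGTG")}
    assert vf.trinuc_context(seqs2, "chr1", 3, "G", "C") == "A[C>G]T"


def test_trinuc_context_exhaustive_96():
    """All 4 x 6 x 4 SNV configurations map onto the 96 labels, each exactly
    twice (once from the pyrimidine strand, once from the purine strand)."""
    seen = {}
    for left, centre, right in itertools.product(BASES, repeat=3):
        seqs = {"c": encode_seq(left + centre + right)}
        for alt in BASES:
            if alt == centre:
                continue
            label = vf.trinuc_context(seqs, "c", 2, centre, alt)
            assert label in vf.CONTEXTS_96
            seen[label] = seen.get(label, 0) + 1
    assert len(seen) == 96
    assert set(seen.values()) == {2}


def test_trinuc_context_edge_raises():
    seqs = {"chr1": encode_seq("ACT")}
    with pytest.raises(ValueError, match="edge"):
        vf.trinuc_context(seqs, "chr1", 1, "A", "T")


# ---------------------------------------------------------------------------
# MA filters
# ---------------------------------------------------------------------------


def make_call(**kw):
    base = dict(chrom="chr1", pos=100, ref="C", alt="G", qual=45.0,
                depth=10, alt_reads=6, alt_plus=3, alt_minus=3, line_id="L1")
    base.update(kw)
    return vf.VariantCall(**base)


CLEAN_ANC = {("chr1", 100): vf.AncestorEvidence(depth=30, alt_reads=0)}


def test_filter_retains_good_call():
    retained, tally = vf.apply_ma_filters([make_call()], CLEAN_ANC)
    assert len(retained) == 1 and sum(tally.values()) == 0


@pytest.mark.parametrize(
    "call_kw, ancestor, reason",
    [
        (dict(depth=4, alt_reads=4, alt_plus=2, alt_minus=2), CLEAN_ANC, "line_depth"),
        (dict(), {("chr1", 100): vf.AncestorEvidence(3, 0)}, "ancestor_depth"),
        (dict(alt_reads=4, alt_plus=2, alt_minus=2), CLEAN_ANC, "alt_support"),
        (dict(), {("chr1", 100): vf.AncestorEvidence(30, 2)}, "ancestor_alt"),
        (dict(qual=30.0), CLEAN_ANC, "quality"),
        (dict(alt_plus=6, alt_minus=0), CLEAN_ANC, "strand"),
        (dict(pos=999), CLEAN_ANC, "no_ancestor_evidence"),
    ],
)
def test_filter_rejection_reasons(call_kw, ancestor, reason):
    retained, tally = vf.apply_ma_filters([make_call(**call_kw)], ancestor)
    assert not retained
    assert tally[reason] == 1 and sum(tally.values()) == 1


def test_filter_tally_conservation_and_monotonicity():
    rng = np.random.default_rng(7)
    calls, ancestor = [], {}
    for i in range(300):
        depth = int(rng.integers(1, 20))
        alt = int(rng.integers(0, depth + 1))
        plus = int(rng.integers(0, alt + 1))
        calls.append(vf.VariantCall("chr1", i + 1, "C", "T", float(rng.integers(0, 60)),
                                    depth, alt, plus, alt - plus, "L1"))
        if rng.random() < 0.9:
            ancestor[("chr1", i + 1)] = vf.AncestorEvidence(
                int(rng.integers(1, 20)), int(rng.integers(0, 3)))
    strict = vf.FilterConfig()
    loose = vf.FilterConfig(min_depth=3, min_alt_reads=2)
    r_strict, t_strict = vf.apply_ma_filters(calls, ancestor, strict)
    r_loose, _ = vf.apply_ma_filters(calls, ancestor, loose)
    assert len(r_strict) + sum(t_strict.values()) == len(calls)
    key = lambda v: (v.chrom, v.pos)
    assert {key(v) for v in r_strict} <= {key(v) for v in r_loose}


# ---------------------------------------------------------------------------
# CDS effects
# ---------------------------------------------------------------------------


def test_cds_effect_codon_examples():
    seqs = {"c": encode_seq("AAGCCTTT")}  # codon GCC at 0-based 2..5
    tr = Transcript(name="t", chrom="c", strand="+", parts=[(2, 5)])
    # third-position GCC->GCG stays alanine
    eff, _ = vf.annotate_cds_effect("c", 5, "C", "G", [tr], seqs)
    assert eff == "synonymous"
    # first-position GCC->CCC is Ala->Pro
    eff, _ = vf.annotate_cds_effect("c", 3, "G", "C", [tr], seqs)
    assert eff == "nonsynonymous"
    # outside any CDS
    eff, _ = vf.annotate_cds_effect("c", 1, "A", "T", [tr], seqs)
    assert eff == "noncoding"


def test_cds_effect_minus_strand():
    # minus-strand CDS whose sense codon is GCC: genome carries its revcomp GGC
    seqs = {"c": encode_seq("AAGGCTT")}
    tr = Transcript(name="t", chrom="c", strand="-", parts=[(2, 5)])
    assert decode_seq(tr.coding_codes(seqs)) == "GCC"
    # genome G at 0-based 2 is the codon's third base (C on sense): C->G syn
    eff, _ = vf.annotate_cds_effect("c", 3, "G", "C", [tr], seqs)
    assert eff == "synonymous"


def test_cds_effect_stop_gained():
    seqs = {"c": encode_seq("TACAAA")}  # codon TAC (Tyr); TAC->TAA is a stop
    tr = Transcript(name="t", chrom="c", strand="+", parts=[(0, 6)])
    eff, _ = vf.annotate_cds_effect("c", 3, "C", "A", [tr], seqs)
    assert eff == "stop-gained"


def test_cds_effect_agrees_with_whole_cds_translation(small_bundle):
    """Codon-level classification agrees with brute-force translation of the
    whole mutant CDS on 1000 random synthetic coding SNVs."""
    rng = np.random.default_rng(12)
    trs = small_bundle.transcripts
    seqs = small_bundle.sequences
    for _ in range(1000):
        tr = trs[rng.integers(0, len(trs))]
        s, e = tr.parts[0]
        pos0 = int(rng.integers(s, e))
        ref = BASES[int(seqs[tr.chrom][pos0])]
        alt = BASES[int((seqs[tr.chrom][pos0] + rng.integers(1, 4)) % 4)]
        eff, _ = vf.annotate_cds_effect(tr.chrom, pos0 + 1, ref, alt, trs, seqs)
        # independent oracle: translate reference and mutant CDS end to end
        mutated = seqs[tr.chrom].copy()
        mutated[pos0] = encode_seq(alt)[0]
        ref_prot = str(Seq(decode_seq(tr.coding_codes(seqs))).translate())
        alt_prot = str(Seq(decode_seq(tr.coding_codes({tr.chrom: mutated}))).translate())
        if ref_prot == alt_prot:
            expected = "synonymous"
        elif "*" in alt_prot and "*" not in ref_prot:
            expected = "stop-gained"
        else:
            expected = "nonsynonymous"
        assert eff == expected


# ---------------------------------------------------------------------------
# corruption-mode fixtures: perfect precision and recall
# ---------------------------------------------------------------------------


def test_corruptions_rejected_truth_recovered(small_bundle):
    model = azcma.MutagenesisModel(
        rates={"PR": 2e-5, "nonPR_H3K9me3": 1.5e-5, "non_H3K9me3": 8e-6}, seed=21)
    res = azcma.inject_mutations(
        small_bundle, model, corruptions={k: 3 for k in
                                          ("low_depth", "low_alt", "ancestral",
                                           "single_strand", "low_qual")})
    expected_reason = {
        "low_depth": "line_depth",
        "low_alt": "alt_support",
        "ancestral": "ancestor_alt",
        "single_strand": "strand",
        "low_qual": "quality",
    }
    truth_keys = set(map(tuple, res.truth[["line_id", "chrom", "pos"]].to_numpy()))
    for line_id, calls in res.variants.items():
        retained, tally = vf.apply_ma_filters(calls, res.ancestor)
        got = {(line_id, v.chrom, v.pos) for v in retained}
        want = {k for k in truth_keys if k[0] == line_id}
        assert got == want  # precision = recall = 1
        sub = res.corruptions[res.corruptions.line_id == line_id]
        for kind, n in sub["kind"].value_counts().items():
            assert tally[expected_reason[kind]] >= n


def test_maline_meta_validates_transfer_cycle():
    vf.MALineMeta("L1", "WT", "5AzC", days=18, transfers=6)
    with pytest.raises(ValueError):
        vf.MALineMeta("L1", "WT", "5AzC", days=20, transfers=6)
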