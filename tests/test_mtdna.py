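"""Control-region alignment, variant calling, motifs, classification and
haplotype sharing."""

import numpy as np
import pytest

from helpers import enumerate_optimal_alignments

from haplotrace.errors import InputError, QualityError
from haplotrace.mtdna import (
    ABSENT,
    PRESENT,
    UNDETERMINED,
    CODING,
    CONTROL,
    Hvs1Sequence,
    MotifDef,
    ReferenceWindow,
    VariantCall,
    align_to_rcrs,
    detect_motif,
    shared_haplotypes,
)
from haplotrace.simulate import MALAGASY_MOTIF, POLYNESIAN_MOTIF


def _seq(sequence, window, sample="s1", pop="A"):
    return Hvs1Sequence(sample, pop, sequence, window)


def _sub(pos, ref, alt):
    return VariantCall(pos, ref, alt, "substitution")


# ------------------------------------------------------------- alignment --

def test_identity_yields_no_variants(reference):
    window = (16051, 16365)
    s = _seq(reference.slice(window).sequence, window)
    assert align_to_rcrs(s, reference) == []


def test_single_substitution_called_in_rcrs_coordinates(reference):
    window = (16051, 16365)
    ref_seq = reference.slice(window).sequence
    pos = 16223
    offset = pos - window[0]
    old = ref_seq[offset]
    new = {"A": "G", "G": "A", "C": "T", "T": "C"}[old]
    mutated = ref_seq[:offset] + new + ref_seq[offset + 1:]
    calls = align_to_rcrs(_seq(mutated, window), reference)
    assert calls == [_sub(pos, old, new)]


def test_homopolymer_deletion_is_three_prime_normalised():
    """A base deleted in a homopolymer is reported at the 3'-most position
    among all optimal alignments (exhaustive NW oracle on a toy)."""
    ref = ReferenceWindow(start=101, sequence="ACGTAAAAGCTTGCA")
    qry = "ACGTAAAGCTTGCA"  # one A of the AAAA run removed
    window = (101, 101 + len(ref.sequence) - 1)
    calls = align_to_rcrs(_seq(qry, window), ref)

    optimal = enumerate_optimal_alignments(ref.sequence, qry)
    del_positions = []
    for rg, qg in optimal:
        ref_off = -1
        for rb, qb in zip(rg, qg):
            if rb != "-":
                ref_off += 1
            if qb == "-":
                del_positions.append(101 + ref_off)
    assert len(calls) == 1
    assert calls[0].kind == "deletion"
    assert calls[0].position == max(del_positions) == 108


def test_low_identity_raises_quality_error(reference):
    window = (16051, 16150)
    junk = "G" * 100
    with pytest.raises(QualityError):
        align_to_rcrs(_seq(junk, window), reference)


def test_reference_must_cover_declared_window(reference):
    s = _seq("ACGT", (1, 4))
    with pytest.raises(InputError):
        align_to_rcrs(s, reference)


# ----------------------------------------------------------------- motifs --

_CONTROL_TRIO = [_sub(16217, "T", "C"), _sub(16247, "A", "G"), _sub(16261, "C", "T")]


@pytest.mark.parametrize(
    "variants, motif, typed, expected",
    [
        (_CONTROL_TRIO + [_sub(14022, "A", "G")], POLYNESIAN_MOTIF,
         {CONTROL, CODING}, PRESENT),
        (_CONTROL_TRIO + [_sub(1473, "T", "C"), _sub(3423, "T", "C")],
         MALAGASY_MOTIF, {CONTROL, CODING}, PRESENT),
        ([], POLYNESIAN_MOTIF, {CONTROL, CODING}, ABSENT),
        ([], MALAGASY_MOTIF, {CONTROL, CODING}, ABSENT),
        # 14022 lies in the untyped coding region -> undetermined
        (_CONTROL_TRIO, POLYNESIAN_MOTIF, {CONTROL}, UNDETERMINED),
        # a typed required variant missing -> absent regardless of coding
        (_CONTROL_TRIO[:2], POLYNESIAN_MOTIF, {CONTROL}, ABSENT),
    ],
)
def test_motif_detection(variants, motif, typed, expected):
    assert detect_motif(variants, motif, typed) == expected


def test_motif_detection_is_monotone():
    """Adding variants never flips present -> absent (nor absent when all
    required typed variants were already matched)."""
    rng = np.random.default_rng(0)
    extras = [_sub(16300 + i, "A", "G") for i in range(1, 30)]
    base = _CONTROL_TRIO + [_sub(14022, "A", "G")]
    for _ in range(50):
        sub = [v for v in base if rng.random() < 0.7]
        before = detect_motif(sub, POLYNESIAN_MOTIF, {CONTROL, CODING})
        added = sub + list(rng.choice(extras, size=5, replace=False))
        after = detect_motif(added, POLYNESIAN_MOTIF, {CONTROL, CODING})
        if before == PRESENT:
            assert after == PRESENT


# --------------------------------------------------------- classification --

def test_classify_exact_b4a_set(mt_table):
    variants = [_sub(16189, "T", "C"), _sub(16299, "A", "G")]
    assert mt_table.classify(variants).haplogroup == "B4a"


def test_classify_b4a_plus_motif_is_b4a1a1(mt_table):
    variants = [
        _sub(16189, "T", "C"), _sub(16299, "A", "G"),
        _sub(16217, "T", "C"), _sub(16247, "A", "G"), _sub(16261, "C", "T"),
        _sub(14022, "A", "G"),
    ]
    assert mt_table.classify(variants).haplogroup == "B4a1a1"


def test_classify_empty_is_root(mt_table):
    assert mt_table.classify([]).haplogroup == "rCRS"


def test_classify_private_variants_do_not_change_call(mt_table):
    variants = [_sub(16189, "T", "C"), _sub(16299, "A", "G"), _sub(16355, "C", "T")]
    assert mt_table.classify(variants).haplogroup == "B4a"


# ---------------------------------------------------------------- sharing --

def _pop_from_haplotypes(reference, window, haplotypes, pop):
    """Build sequences carrying the given variant sets (pos -> alt)."""
    base = reference.slice(window).sequence
    out = []
    for i, hap in enumerate(haplotypes):
        seq = list(base)
        for pos, alt in hap:
            seq[pos - window[0]] = alt
        out.append(_seq("".join(seq), window, sample=f"{pop}{i}", pop=pop))
    return out


def test_sharing_counts_and_symmetry(reference):
    window = (16051, 16365)
    h1 = ((16111, "G"),)
    h2 = ((16150, "C"), (16153, "A"))
    h3 = ((16204, "T"),)
    pa = _pop_from_haplotypes(reference, window, [h1, h2, h2], "A")
    pb = _pop_from_haplotypes(reference, window, [h2, h3], "B")

    res = shared_haplotypes(pa, pb, reference, window)
    assert res.count == 1
    assert res.shared == {frozenset(h2)}
    rev = shared_haplotypes(pb, pa, reference, window)
    assert rev.count == res.count and rev.shared == res.shared

    # self-sharing returns all distinct haplotypes
    self_res = shared_haplotypes(pa, pa, reference, window)
    assert self_res.count == 2  # h1 and h2 are the distinct haplotypes of A

    # disjoint variant sets share nothing
    pc = _pop_from_haplotypes(reference, window, [h3], "C")
    assert shared_haplotypes(pa, pc, reference, window).count == 0


def test_sharing_excludes_short_sequences(reference):
    window = (16051, 16365)
    short_window = (16051, 16200)
    pa = _pop_from_haplotypes(reference, window, [((16111, "G"),)], "A")
    short = _pop_from_haplotypes(reference, short_window, [((16111, "G"),)], "B")
    res = shared_haplotypes(pa, pa + short, reference, window)
    assert res.excluded_b == 1
    with pytest.raises(InputError):
        shared_haplotypes(short, pa, reference, window)


def test_motifdef_validation():
    with pytest.raises(InputError):
        MotifDef("bad", ())
    with pytest.raises(InputError):
        MotifDef("dup", ((16189, "C"), (16189, "T")))
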