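"""mtDNA control-region analysis: reference alignment, variant calls,
Polynesian/Malagasy motif detection, motif-table haplogroup classification
and haplotype sharing.

Coordinates are 1-based positions on a circular mitochondrial reference of
length 16,569 (rCRS numbering).  Hypervariable segment I (HVS-I) lives near
the origin; the default comparison window is 16051-16365.  Variants are
expressed relative to the reference, with indels normalised to their
3'-most equivalent position, following mtDNA nomenclature convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from .errors import InputError, QualityError

logger = logging.getLogger(__name__)

MT_LENGTH = 16569
DEFAULT_HVS1_WINDOW = (16051, 16365)

CONTROL = "control"
CODING = "coding"

# boundaries of the mtDNA control region (D-loop): 16024..16569 + 1..576
_CONTROL_INTERVALS = ((16024, 16569), (1, 576))


def region_of(position: int) -> str:
    """Classify an rCRS position as control- or coding-region."""
    for lo, hi in _CONTROL_INTERVALS:
        if lo <= position <= hi:
            return CONTROL
    return CODING


def _window_positions(start, end):
    """Positions of a 1-based closed interval, wrapping the circular origin."""
    if start <= end:
        return list(range(start, end + 1))
    return list(range(start, MT_LENGTH + 1)) + list(range(1, end + 1))


@dataclass(frozen=True)
class VariantCall:
    """A substitution or single-base indel relative to the reference.

    ``position`` is the 1-based rCRS coordinate; for insertions it is the
    reference position *after which* the base is inserted.  Gaps are encoded
    as ``"-"``.
    """

    position: int
    ref: str
    alt: str
    kind: str  # substitution | insertion | deletion

    def __post_init__(self):
        if not 1 <= self.position <= MT_LENGTH:
            raise InputError(f"position {self.position} outside reference")
        if self.kind == "substitution" and (
            self.ref == self.alt or "-" in (self.ref, self.alt)
        ):
            raise InputError(f"invalid substitution {self.ref}>{self.alt}")

    def __str__(self):
        if self.kind == "substitution":
            return f"{self.ref}{self.position}{self.alt}"
        if self.kind == "deletion":
            return f"{self.position}del{self.ref}"
        return f"{self.position}.1{self.alt}"


@dataclass
class Hvs1Sequence:
    """An HVS-I sequence with its declared rCRS window (1-based, closed;
    may wrap the origin at 16,569)."""

    sample_id: str
    population: str
    sequence: str
    declared_window: tuple = DEFAULT_HVS1_WINDOW

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise InputError(f"{self.sample_id}: empty sequence")
        for p in self.declared_window:
            if not 1 <= p <= MT_LENGTH:
                raise InputError(f"{self.sample_id}: window endpoint {p} invalid")

    def covers(self, window) -> bool:
        own = set(_window_positions(*self.declared_window))
        return set(_window_positions(*window)) <= own


@dataclass
class ReferenceWindow:
    """A contiguous slice of the mitochondrial reference.

    ``start`` is the rCRS coordinate of the first base; coordinates advance
    circularly, so a window may span the origin.
    """

    start: int
    sequence: str

    def positions(self):
        return [((self.start - 1 + i) % MT_LENGTH) + 1 for i in range(len(self.sequence))]

    def coord(self, offset):
        return ((self.start - 1 + offset) % MT_LENGTH) + 1

    def base_at(self, position):
        offset = (position - self.start) % MT_LENGTH
        if offset >= len(self.sequence):
            raise InputError(f"position {position} outside reference window")
        return self.sequence[offset]

    def covers(self, window) -> bool:
        return set(_window_positions(*window)) <= set(self.positions())

    def slice(self, window):
        """Subsequence of the window as a new ReferenceWindow."""
        pos = _window_positions(*window)
        return ReferenceWindow(
            start=window[0], sequence="".join(self.base_at(p) for p in pos)
        )


def _make_aligner(match, mismatch, gap):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def align_to_rcrs(
    seq: Hvs1Sequence,
    reference_window: ReferenceWindow,
    *,
    match=1.0,
    mismatch=-1.0,
    gap=-2.0,
    min_identity=0.8,
):
    """Globally align an HVS-I sequence to the reference window and call
    variants in rCRS coordinates.

    Needleman-Wunsch with linear gap costs (defaults +1/-1/-2); indels are
    shifted to the 3'-most equivalent position.  An alignment whose identity
    (matches over aligned columns) falls below ``min_identity`` raises
    :class:`QualityError` (wrong-region safeguard).
    """
    if not reference_window.covers(seq.declared_window):
        raise InputError(
            f"{seq.sample_id}: reference window does not cover declared window"
        )
    ref = reference_window.slice(seq.declared_window)
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(ref.sequence, seq.sequence.upper())[0]
    ref_g, qry_g = str(aln[0]), str(aln[1])

    matches = sum(a == b and a != "-" for a, b in zip(ref_g, qry_g))
    if matches / len(ref_g) < min_identity:
        raise QualityError(
            f"{seq.sample_id}: alignment identity {matches / len(ref_g):.2f} "
            f"below floor {min_identity} (wrong region?)"
        )

    variants = []
    ref_off = -1  # offset of the last consumed reference base
    for rb, qb in zip(ref_g, qry_g):
        if rb != "-":
            ref_off += 1
        if rb == qb:
            continue
        if qb == "-":
            variants.append(("deletion", ref_off, rb))
        elif rb == "-":
            variants.append(("insertion", ref_off, qb))
        else:
            variants.append(("substitution", ref_off, qb))

    # 3'-normalise single-base indels through homopolymer runs
    n = len(ref.sequence)
    calls = []
    for kind, off, base in variants:
        if kind == "deletion":
            while off + 1 < n and ref.sequence[off + 1] == base:
                off += 1
            calls.append(VariantCall(ref.coord(off), base, "-", "deletion"))
        elif kind == "insertion":
            while off + 1 < n and ref.sequence[off + 1] == base:
                off += 1
            anchor = max(off, 0)
            calls.append(
                VariantCall(ref.coord(anchor), "-", base, "insertion")
            )
        else:
            calls.append(
                VariantCall(ref.coord(off), ref.sequence[off], base, "substitution")
            )
    calls.sort(key=lambda v: v.position)
    return calls


@dataclass(frozen=True)
class MotifDef:
    """A named set of diagnostic derived variants, each tagged with the
    region (control/coding) in which it must be assayed.

    ``required_variants`` is a tuple of ``(position, derived_allele)``.
    """

    name: str
    required_variants: tuple  # ((position, allele), ...)
    regions: dict = field(default_factory=dict, hash=False)  # position -> region

    def __post_init__(self):
        if not self.required_variants:
            raise InputError(f"motif {self.name}: empty variant set")
        positions = [p for p, _ in self.required_variants]
        if len(set(positions)) != len(positions):
            raise InputError(f"motif {self.name}: duplicate positions")

    def region(self, position):
        return self.regions.get(position, region_of(position))


PRESENT = "present"
ABSENT = "absent"
UNDETERMINED = "undetermined"


def detect_motif(variants, motif: MotifDef, typed_regions) -> str:
    """Decide whether a motif is present, absent or undetermined.

    ``present``: every required variant lying in a typed region is observed
    and no required variant falls in an untyped region.  ``undetermined``:
    all typed required variants match but at least one required variant lies
    in an untyped region.  Otherwise ``absent``.
    """
    observed = {(v.position, v.alt) for v in variants}
    untyped = False
    for pos, allele in motif.required_variants:
        if motif.region(pos) not in typed_regions:
            untyped = True
            continue
        if (pos, allele) not in observed:
            return ABSENT
    return UNDETERMINED if untyped else PRESENT


@dataclass
class MtAssignment:
    """Motif-table classification result."""

    haplogroup: str
    matched: int
    ambiguous: bool = False


class MtMotifTable:
    """Miniature motif-table classifier for mtDNA haplogroups.

    ``entries`` maps haplogroup label to a set of diagnostic
    ``(position, derived_allele)`` pairs; sets are cumulative along the tree
    (a child's set contains its parent's).  Classification returns the
    deepest fully-matched entry, falling back to the tree root when nothing
    matches.
    """

    def __init__(self, entries, tree):
        from .haplotree import HaploTree  # local to avoid import cycle in docs

        if not isinstance(tree, HaploTree):
            raise InputError("tree must be a HaploTree")
        self.entries = {hg: frozenset(vs) for hg, vs in entries.items()}
        if not self.entries:
            raise InputError("empty motif table")
        self.tree = tree
        for hg, vs in self.entries.items():
            if hg not in tree.parent:
                raise InputError(f"motif-table label {hg!r} not in tree")
            par = tree.parent[hg]
            while par is not None:
                if par in self.entries and not self.entries[par] <= vs:
                    raise InputError(
                        f"{hg}: diagnostic set does not contain parent {par}'s"
                    )
                par = tree.parent[par]

    def classify(self, variants) -> MtAssignment:
        observed = {(v.position, v.alt) for v in variants}
        matched = [
            hg for hg, vs in self.entries.items() if vs <= observed
        ]
        if not matched:
            return MtAssignment(self.tree.root, 0)
        best_depth = max(self.tree.depth(h) for h in matched)
        deepest = sorted(h for h in matched if self.tree.depth(h) == best_depth)
        return MtAssignment(
            haplogroup=deepest[0],
            matched=len(self.entries[deepest[0]]),
            ambiguous=len(deepest) > 1,
        )


def classify_mt_haplogroup(variants, table: MtMotifTable) -> MtAssignment:
    """Classify a variant list against a miniature motif table (deepest
    fully-matched entry; root label when nothing matches)."""
    return table.classify(variants)


@dataclass
class SharedHaplotypes:
    """Distinct haplotypes (variant sets within the window) found in both
    populations, with exclusion counts for short sequences."""

    shared: set
    count: int
    excluded_a: int
    excluded_b: int


def _haplotype_set(sequences, reference, window, **aln_kwargs):
    haps = set()
    excluded = 0
    usable = 0
    win_pos = set(_window_positions(*window))
    for s in sequences:
        if not s.covers(window):
            excluded += 1
            continue
        usable += 1
        calls = align_to_rcrs(s, reference, **aln_kwargs)
        haps.add(
            frozenset(
                (v.position, v.alt) for v in calls if v.position in win_pos
            )
        )
    return haps, excluded, usable


def shared_haplotypes(
    pop_a,
    pop_b,
    reference: ReferenceWindow,
    window=DEFAULT_HVS1_WINDOW,
    **aln_kwargs,
) -> SharedHaplotypes:
    """Count distinct HVS-I haplotypes shared between two populations.

    Haplotype identity is the identical variant set within the comparison
    window.  Sequences whose declared window does not cover the comparison
    window are excluded (with a logged count); if a population retains no
    usable sequence an :class:`InputError` is raised.
    """
    haps_a, excl_a, usable_a = _haplotype_set(pop_a, reference, window, **aln_kwargs)
    haps_b, excl_b, usable_b = _haplotype_set(pop_b, reference, window, **aln_kwargs)
    if usable_a == 0 or usable_b == 0:
        raise InputError("comparison window covered by no sequence of a population")
    if excl_a or excl_b:
        logger.info(
            "shared_haplotypes: excluded %d + %d sequences not covering %s",
            excl_a, excl_b, window,
        )
    shared = haps_a & haps_b
    return SharedHaplotypes(shared, len(shared), excl_a, excl_b)
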