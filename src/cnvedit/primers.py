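"""Allele-discriminating mismatch primer design at Cas9 cut sites.

Cas9 cleaves between the 17th and 18th protospacer bases (3 bp upstream
of the NGG PAM), and its small indels cluster around that point.  A
primer whose 3'-end sits on the cut site therefore anneals across the
mutation hotspot: on an edited allele the 3' terminus no longer matches
and extension fails, so only wild-type (unedited) alleles amplify.  A
single natural mismatch at the very 3' end is often not discriminating
enough on its own, so an additional *intentional* mismatch is placed at
the third base from the 3'-end, destabilising extension on any template
that deviates near the terminus while still permitting it on the exact
wild-type sequence.

Coordinates are 0-based with half-open intervals throughout; a cut site
is the inter-base index such that the cut falls between ``position - 1``
and ``position``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp

__all__ = [
    "Protospacer",
    "CutSite",
    "MismatchPrimer",
    "TargetNotFoundError",
    "DEFAULT_SUBSTITUTION",
    "find_cut_site",
    "design_mismatch_primer",
    "wildtype_specificity_check",
]

_PAM_RE = re.compile(r"^[ACGT]GG$")

# Transition swap on the primer-strand base (A<->G, C<->T): keeps the
# base chemically similar while breaking the Watson-Crick pair.
DEFAULT_SUBSTITUTION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class TargetNotFoundError(ValueError):
    """Protospacer + PAM absent at the stated reference location."""


class PrimerDesignError(ValueError):
    """Requested primer cannot be built from the reference window."""


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Protospacer:
    """A 20-nt Cas9 target with its NGG PAM.

    ``start`` is the 0-based offset of the protospacer's leftmost base on
    the reference plus strand, regardless of ``strand``; for a minus-
    strand target the stored ``sequence``/``pam`` read along the minus
    strand (i.e. the reverse complement of the reference slice).
    """

    sequence: str
    pam: str
    strand: Literal["+", "-"]
    start: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "pam", self.pam.upper())
        if len(seq) != 20 or set(seq) - set("ACGT"):
            raise ValueError("protospacer must be a 20-nt ACGT string")
        if not _PAM_RE.match(self.pam):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.start < 0:
            raise ValueError("start must be non-negative")


@dataclass(frozen=True)
class CutSite:
    """Blunt Cas9 cut as a 0-based inter-base index on the reference."""

    position: int

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("cut position must be non-negative")


@dataclass(frozen=True)
class MismatchPrimer:
    sequence: str
    anneal_start: int
    anneal_end: int
    strand: Literal["+", "-"]
    mismatch_offset_from_3prime: int
    template_base: str
    substituted_base: str
    tm: float

    @property
    def length(self) -> int:
        return self.anneal_end - self.anneal_start

    @property
    def three_prime_tetramer(self) -> str:
        return self.sequence[-4:]


def find_cut_site(reference: str, proto: Protospacer) -> CutSite:
    """Locate the blunt cut 3 bp from the PAM for a verified protospacer.

    Plus strand: protospacer at [start, start+20), PAM at
    [start+20, start+23), cut at ``start + 17``.  Minus strand: the
    protospacer's stated sequence is the reverse complement of
    reference[start:start+20], the PAM sits at [start-3, start) on the
    plus strand, and the cut maps to ``start + 3``.
    """
    reference = reference.upper()
    s = proto.start
    if proto.strand == "+":
        if reference[s : s + 20] != proto.sequence:
            raise TargetNotFoundError(
                f"protospacer not found on + strand at offset {s}"
            )
        pam = reference[s + 20 : s + 23]
        if pam != proto.pam or not _PAM_RE.match(pam):
            raise TargetNotFoundError(f"PAM mismatch at offset {s + 20}: {pam!r}")
        return CutSite(position=s + 17)
    if _revcomp(reference[s : s + 20]) != proto.sequence:
        raise TargetNotFoundError(f"protospacer not found on - strand at offset {s}")
    if s < 3:
        raise TargetNotFoundError("minus-strand PAM would run off the reference")
    pam = _revcomp(reference[s - 3 : s])
    if pam != proto.pam or not _PAM_RE.match(pam):
        raise TargetNotFoundError(f"PAM mismatch upstream of offset {s}: {pam!r}")
    return CutSite(position=s + 3)


def design_mismatch_primer(
    reference: str,
    cut: CutSite,
    length: int = 22,
    direction: Literal["forward", "reverse"] = "forward",
    three_prime_offset: int = 0,
    substitution: dict[str, str] | None = None,
) -> MismatchPrimer:
    """Build a wild-type-specific primer ending on the Cas9 cut site.

    The primer copies the template except for one intentional
    substitution at the third base from its 3'-end.  ``three_prime_offset``
    shifts the 3' terminus away from the cut (positive = downstream in
    the primer's extension direction, at most ±2).
    """
    reference = reference.upper()
    if not 18 <= length <= 30:
        raise PrimerDesignError("primer length must be within [18, 30]")
    if abs(three_prime_offset) > 2:
        raise PrimerDesignError("3' terminus must stay within ±2 of the cut site")
    subs = DEFAULT_SUBSTITUTION if substitution is None else substitution

    if direction == "forward":
        end = cut.position + three_prime_offset
        start = end - length
        if start < 0 or end > len(reference):
            raise PrimerDesignError("primer window outside the reference")
        template = reference[start:end]
        strand: Literal["+", "-"] = "+"
    elif direction == "reverse":
        start = cut.position - three_prime_offset
        end = start + length
        if start < 0 or end > len(reference):
            raise PrimerDesignError("primer window outside the reference")
        template = _revcomp(reference[start:end])
        strand = "-"
    else:
        raise ValueError("direction must be 'forward' or 'reverse'")

    idx = length - 3  # 0-based from the 5' end = third base from the 3' end
    base = template[idx]
    if base not in subs:
        raise PrimerDesignError(f"ambiguous template base {base!r} at mismatch site")
    new_base = subs[base]
    primer_seq = template[:idx] + new_base + template[idx + 1 :]
    return MismatchPrimer(
        sequence=primer_seq,
        anneal_start=start,
        anneal_end=end,
        strand=strand,
        mismatch_offset_from_3prime=3,
        template_base=base,
        substituted_base=new_base,
        tm=float(MeltingTemp.Tm_NN(Seq(primer_seq))),
    )


def wildtype_specificity_check(
    primer: MismatchPrimer,
    allele_sequences: Sequence[str],
    reference: str,
) -> list[bool]:
    """Predict which allele templates the primer can extend on.

    An allele is flagged amplifiable iff the primer's final four 3'
    bases pair perfectly with the allele, apart from the intentional
    mismatch position; an indel overlapping that 3' tetramer kills
    extension.  This is a terminal-stability heuristic: mutations outside
    the tetramer (or beyond the anneal window) do not affect the call, so
    a distant insertion still reads amplifiable and should be reviewed.
    """
    from Bio import Align

    reference = reference.upper()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5

    if primer.strand == "+":
        tet_lo, tet_hi = primer.anneal_end - 4, primer.anneal_end
        tet_primer = primer.three_prime_tetramer
    else:
        tet_lo, tet_hi = primer.anneal_start, primer.anneal_start + 4
        tet_primer = _revcomp(primer.three_prime_tetramer)
    # position of the intentional mismatch within the plus-strand tetramer
    mm_local = 1 if primer.strand == "+" else 2

    flags: list[bool] = []
    for allele in allele_sequences:
        allele = allele.upper()
        aln = aligner.align(reference, allele)[0]
        ref_blocks, qry_blocks = aln.aligned
        # map each tetramer reference base to an allele base; gaps break pairing
        mapped: dict[int, str] = {}
        ok = True
        for (rs, re_), (qs, qe) in zip(ref_blocks, qry_blocks):
            for i in range(re_ - rs):
                if tet_lo <= rs + i < tet_hi:
                    mapped[rs + i] = allele[qs + i]
        # insertions inside the tetramer shift the register: detect a query
        # gap whose reference anchor lies strictly inside the tetramer
        prev_q = None
        for (rs, re_), (qs, qe) in zip(ref_blocks, qry_blocks):
            if prev_q is not None and qs > prev_q and tet_lo < rs < tet_hi:
                ok = False
            prev_q = qe
        if len(mapped) < tet_hi - tet_lo:
            ok = False  # deletion removed a tetramer base
        if ok:
            for j, refpos in enumerate(range(tet_lo, tet_hi)):
                if j == mm_local:
                    continue  # intentional mismatch position
                if mapped[refpos] != tet_primer[j]:
                    ok = False
                    break
        flags.append(ok)
    return flags
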