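"""Reporter architecture: sequences, cut geometry, 3'-flap arithmetic, repair products.

The reporter carries two nearly identical 152-bp repeats (the "F segment", a
middle stretch of the GFP coding sequence) separated by a 42-nt spacer that
embeds the 18-nt I-SceI recognition site.  The repeats differ by a single
nucleotide at the centre of the segment, so that annealing one strand of each
repeat during single-strand annealing (SSA) produces a 152-bp heteroduplex
with a central mismatch.  All coordinates are 0-based, half-open and
top-strand oriented: the "left" repeat is proximal to the barcode/watermark
block and donates the top strand of the heteroduplex, the "right" repeat
donates the bottom strand.

Conventions
-----------
* A mismatch code ``X:Y`` means the heteroduplex presents ``X`` on the top
  strand and ``Y`` on the bottom strand.  Consequently the left repeat
  carries ``X`` on its top strand while the right repeat carries ``Y`` on its
  *bottom* strand (i.e. ``complement(Y)`` on its top strand).
* Flap lengths follow from the cut position within the spacer: after 5'
  resection and annealing of the repeats, the unannealed 3' tails are the
  spacer halves left on either side of the cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

NUCLEOTIDES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# -- fixture constants --------------------------------------------------------
#
# The repeat segment is a synthetic 152-mer derived from the central window of
# the eGFP coding sequence, edited at a handful of positions so that it
# carries exactly 19 CpG dinucleotides (the count the methylation assay keys
# on) and so that no CpG overlaps the central variant position.  All logic is
# sequence-agnostic; the constant only pins down a reproducible fixture.
F_SEGMENT = (
    "GGAGCGCGCGATCGTCGTCGAGGACGACGGCGACGACAAGACCCGCGCCGAGGTGAAGTTCGAGGGCGACACC"
    "CTGGTGAACCGCATCGAGCTGAAGGGCATCGACTTCAAGGAGGACGGCAACATCCTGGGGCACAAGCTGGAGT"
    "ACAACT"
)
F_LENGTH = 152
MISMATCH_OFFSET = 76  # centre of the even-length segment, fixed by convention

# Fixed 20-nt identification sequence adjacent to the barcode.
WATERMARK = "AGATCGGAAGAGCGTCGTGT"
BARCODE_LENGTH = 20

# 42-nt spacer: 24 nt of filler followed by the 18-nt I-SceI recognition site.
# With the site flush at the right end, the documented I-SceI cut offsets
# (top 33, bottom 29, 4-nt 3' overhang) fall inside the recognition sequence.
ISCEI_SITE = "TAGGGATAACAGGGTAAT"
SPACER = "ACTAGTCCAGTGTGGTGGAATTCT" + ISCEI_SITE
SPACER_LENGTH = 42

assert len(F_SEGMENT) == F_LENGTH
assert len(SPACER) == SPACER_LENGTH
assert sum(1 for i in range(F_LENGTH - 1) if F_SEGMENT[i : i + 2] == "CG") == 19

#: CpG positions (index of the C) within the F segment.
F_SEGMENT_CPGS = tuple(
    i for i in range(F_LENGTH - 1) if F_SEGMENT[i : i + 2] == "CG"
)

#: Mismatch codes used in the study: top-strand allele first.
CONSTRUCT_CODES = ("A:G", "T:G", "A:C", "T:C", "G:T")


@dataclass(frozen=True)
class MismatchSpec:
    """One of the five engineered mismatches, ``top:bottom``.

    ``left_allele`` pairs to the top strand of the heteroduplex (it is the
    base the left repeat donates) and ``right_allele`` to the bottom strand.
    """

    construct_code: str
    top_allele: str
    bottom_allele: str

    @property
    def left_allele(self) -> str:
        return self.top_allele

    @property
    def right_allele(self) -> str:
        return self.bottom_allele

    @classmethod
    def from_code(cls, code: str) -> "MismatchSpec":
        top, _, bottom = code.partition(":")
        if not top or not bottom or top not in NUCLEOTIDES or bottom not in NUCLEOTIDES:
            raise ValueError(f"malformed mismatch code {code!r}")
        if top == bottom:
            raise ValueError(f"identical alleles in {code!r}: no mismatch possible")
        if complement(top) == bottom:
            raise ValueError(f"{code!r} is a Watson-Crick pair, not a mismatch")
        return cls(construct_code=code, top_allele=top, bottom_allele=bottom)


@dataclass(frozen=True)
class CutSite:
    """A double-strand break within the spacer.

    ``top_cut`` and ``bottom_cut`` are 0-based offsets of the breaks on the
    top and bottom strands; their difference is the length of the 3'
    overhang (0 for a blunt cut).
    """

    name: str
    top_cut: int
    bottom_cut: int

    @property
    def overhang(self) -> int:
        return self.top_cut - self.bottom_cut

    def __post_init__(self) -> None:
        if not (0 <= self.bottom_cut <= self.top_cut <= SPACER_LENGTH + self.overhang):
            raise ValueError(
                f"cut {self.name!r} outside spacer: top={self.top_cut} "
                f"bottom={self.bottom_cut}"
            )
        if self.top_cut > SPACER_LENGTH:
            raise ValueError(f"cut {self.name!r} beyond spacer end")


#: I-SceI leaves a 4-nt 3' overhang; flaps on the reference construct are 33/13.
ISCEI = CutSite("I-SceI", top_cut=33, bottom_cut=29)
#: Control guide RNA, blunt cut near the I-SceI site; flaps 31/11.
GRNA1 = CutSite("gRNA1", top_cut=31, bottom_cut=31)
#: Guide RNA at the symmetrically opposite location; flaps 0/42.
GRNA2 = CutSite("gRNA2", top_cut=0, bottom_cut=0)

CUT_SITES = {"iscei": ISCEI, "grna1": GRNA1, "grna2": GRNA2}


@dataclass(frozen=True)
class ReporterConstruct:
    """A barcoded TRIP reporter with two mismatched repeats."""

    f_segment: str
    mismatch: MismatchSpec
    barcode: str
    watermark: str = WATERMARK
    spacer: str = SPACER
    mismatch_offset: int = MISMATCH_OFFSET

    @property
    def left_repeat(self) -> str:
        """Top-strand sequence of the barcode-proximal repeat."""
        o = self.mismatch_offset
        return self.f_segment[:o] + self.mismatch.top_allele + self.f_segment[o + 1 :]

    @property
    def right_repeat(self) -> str:
        """Top-strand sequence of the distal repeat.

        The right repeat donates its *bottom* strand to the heteroduplex, so
        its top strand carries the complement of the bottom-strand allele.
        """
        o = self.mismatch_offset
        return (
            self.f_segment[:o]
            + complement(self.mismatch.bottom_allele)
            + self.f_segment[o + 1 :]
        )

    def repeat_with_top_base(self, base: str) -> str:
        """F segment whose top strand carries ``base`` at the variant position."""
        o = self.mismatch_offset
        return self.f_segment[:o] + base + self.f_segment[o + 1 :]

    def sequence(self) -> str:
        """Top strand of the intact (uncut) reporter."""
        return (
            self.barcode
            + self.watermark
            + self.left_repeat
            + self.spacer
            + self.right_repeat
        )

    def to_dict(self) -> dict:
        return {
            "construct": self.mismatch.construct_code,
            "barcode": self.barcode,
            "watermark": self.watermark,
            "f_segment": self.f_segment,
            "spacer": self.spacer,
            "mismatch_offset": self.mismatch_offset,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


@dataclass(frozen=True)
class HeteroduplexState:
    """The annealed intermediate of SSA: a mismatched duplex with 3' flaps."""

    duplex_length: int
    mismatch_position: int
    top_flap: int
    bottom_flap: int


@dataclass(frozen=True)
class RepairProduct:
    pathway: str  # "SSA" or "NHEJ"
    sequence: str
    resolved_allele: str | None
    repaired: bool
    # Bottom-strand allele retained alongside the top strand when the
    # heteroduplex is left unresolved (needed to simulate amplification).
    top_strand_base: str | None = None
    bottom_strand_base: str | None = None


def build_reference_construct(
    spec: MismatchSpec, barcode: str, f_segment: str = F_SEGMENT
) -> ReporterConstruct:
    """Assemble a reporter for one mismatch spec, barcode and repeat segment."""
    if len(f_segment) != F_LENGTH:
        raise ValueError(f"F segment must be {F_LENGTH} nt, got {len(f_segment)}")
    if any(b not in NUCLEOTIDES for b in f_segment):
        raise ValueError("F segment contains ambiguous bases")
    if len(barcode) != BARCODE_LENGTH:
        raise ValueError(f"barcode must be {BARCODE_LENGTH} nt, got {len(barcode)}")
    if spec.top_allele == spec.bottom_allele:
        raise ValueError("identical alleles on both repeats: no mismatch")
    return ReporterConstruct(f_segment=f_segment, mismatch=spec, barcode=barcode)


def flap_lengths(construct: ReporterConstruct, cut: CutSite) -> tuple[int, int]:
    """3'-flap lengths (top, bottom) after resection and annealing.

    The top-strand flap is the spacer prefix left attached to the left
    repeat's top strand (``top_cut`` nucleotides); the bottom-strand flap is
    the spacer suffix on the right repeat's bottom strand.
    """
    spacer_length = len(construct.spacer)
    if cut.top_cut > spacer_length or cut.bottom_cut > spacer_length:
        raise ValueError(f"cut {cut.name!r} outside spacer")
    top_flap = cut.top_cut
    bottom_flap = spacer_length - cut.bottom_cut
    return top_flap, bottom_flap


def longer_flap_strand(cut: CutSite, construct: ReporterConstruct | None = None) -> str:
    """Which strand carries the longer 3' flap for this cut ("top"/"bottom")."""
    if construct is None:
        construct = build_reference_construct(
            MismatchSpec.from_code("G:T"), "A" * BARCODE_LENGTH
        )
    top, bottom = flap_lengths(construct, cut)
    return "top" if top >= bottom else "bottom"


def form_heteroduplex(construct: ReporterConstruct, cut: CutSite) -> HeteroduplexState:
    """Resect and anneal: the repeats define a full-length mismatched duplex."""
    top_flap, bottom_flap = flap_lengths(construct, cut)
    return HeteroduplexState(
        duplex_length=len(construct.f_segment),
        mismatch_position=construct.mismatch_offset,
        top_flap=top_flap,
        bottom_flap=bottom_flap,
    )


def repair_product(
    construct: ReporterConstruct,
    cut: CutSite,
    pathway: str,
    resolved_strand: str | None = None,
    repaired: bool = True,
) -> RepairProduct:
    """Sequence product of one repair event.

    SSA collapses the reporter to a single repeat: resolution toward the top
    strand keeps the top-strand allele, resolution toward the bottom strand
    keeps the bottom-strand allele (the product's top strand then carries its
    complement).  An unresolved SSA product retains both strand identities.
    NHEJ deletes the 3' overhang, destroying the I-SceI site but keeping both
    repeats.
    """
    if pathway == "NHEJ":
        if resolved_strand is not None:
            raise ValueError("NHEJ does not resolve a mismatch strand")
        # Scar: delete the 4-nt I-SceI overhang (site-destroying); blunt cuts
        # re-ligate with a minimal 1-nt deletion so the site never survives.
        lo, hi = cut.bottom_cut, max(cut.top_cut, cut.bottom_cut + 1)
        scarred = construct.spacer[: min(lo, SPACER_LENGTH - 1)] + construct.spacer[hi:]
        seq = (
            construct.barcode
            + construct.watermark
            + construct.left_repeat
            + scarred
            + construct.right_repeat
        )
        return RepairProduct("NHEJ", seq, resolved_allele=None, repaired=True)
    if pathway != "SSA":
        raise ValueError(f"unknown pathway {pathway!r}")
    form_heteroduplex(construct, cut)  # validates the cut
    mm = construct.mismatch
    if not repaired:
        seq = (
            construct.barcode
            + construct.watermark
            + construct.repeat_with_top_base(mm.top_allele)
        )
        return RepairProduct(
            "SSA",
            seq,
            resolved_allele=None,
            repaired=False,
            top_strand_base=mm.top_allele,
            bottom_strand_base=mm.bottom_allele,
        )
    if resolved_strand not in ("top", "bottom"):
        raise ValueError("resolved_strand must be 'top' or 'bottom' for repaired SSA")
    allele = mm.top_allele if resolved_strand == "top" else mm.bottom_allele
    top_base = allele if resolved_strand == "top" else complement(allele)
    seq = construct.barcode + construct.watermark + construct.repeat_with_top_base(top_base)
    return RepairProduct(
        "SSA",
        seq,
        resolved_allele=allele,
        repaired=True,
        top_strand_base=top_base,
        bottom_strand_base=complement(top_base),
    )


def write_fasta(records: dict[str, str], path) -> None:
    """Minimal FASTA export of named sequences (60-column wrap)."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
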