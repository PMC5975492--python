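"""Quadripartite chloroplast genome container and small sequence utilities.

The chloroplast genome of most land plants is a circle with four regions:
a large single-copy region (LSC), a small single-copy region (SSC) and a
pair of inverted repeats (IRa, IRb) separating them, with IRb the reverse
complement of IRa at near-100% identity.  All coordinates in this package
are 1-based inclusive, matching GenBank convention; conversion to 0-based
half-open happens only at BED emission.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REGIONS = ("LSC", "IRa", "SSC", "IRb")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class QuadripartiteGenome:
    """A circular DNA sequence with annotated LSC/IRa/SSC/IRb boundaries.

    ``lsc_end``, ``ira_end`` and ``ssc_end`` are 1-based inclusive end
    coordinates of LSC, IRa and SSC; IRb runs from ``ssc_end + 1`` to the
    end of the sequence.
    """

    name: str
    sequence: str
    lsc_end: int
    ira_end: int
    ssc_end: int
    circular: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.lsc_end < self.ira_end < self.ssc_end < len(self.sequence)):
            raise ValueError(
                "region boundaries must satisfy "
                "1 <= lsc_end < ira_end < ssc_end < genome length"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValueError("sequence may contain only A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def lsc(self) -> str:
        return self.sequence[: self.lsc_end]

    @property
    def ira(self) -> str:
        return self.sequence[self.lsc_end : self.ira_end]

    @property
    def ssc(self) -> str:
        return self.sequence[self.ira_end : self.ssc_end]

    @property
    def irb(self) -> str:
        return self.sequence[self.ssc_end :]

    @property
    def ir_length(self) -> int:
        return self.ira_end - self.lsc_end

    @property
    def core_length(self) -> int:
        """Length of LSC + IRa + SSC (the genome minus one IR copy).

        Short-read assemblies and k-mer size estimates converge to this
        value because the two IR copies collapse into one.
        """
        return self.ssc_end

    def region_of(self, pos: int) -> str:
        """Region name for a 1-based position."""
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside [1, {self.length}]")
        if pos <= self.lsc_end:
            return "LSC"
        if pos <= self.ira_end:
            return "IRa"
        if pos <= self.ssc_end:
            return "SSC"
        return "IRb"

    def ir_symmetric(self) -> bool:
        """True iff IRb is exactly the reverse complement of IRa."""
        return self.irb == revcomp(self.ira)

    def mirror_ir_position(self, pos: int) -> int:
        """Map a position in IRa to its mirrored position in IRb (and back)."""
        region = self.region_of(pos)
        if region == "IRa":
            return self.ssc_end + 1 + (self.ira_end - pos)
        if region == "IRb":
            return self.lsc_end + 1 + (self.length - pos)
        raise ValueError(f"position {pos} is in {region}, not in an IR")


def rotations_equal(a: str, b: str) -> bool:
    """True iff two circular sequences are equal up to rotation or strand."""
    if len(a) != len(b):
        return False
    return b in a + a or revcomp(b) in a + a
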