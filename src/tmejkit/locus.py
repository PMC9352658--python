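"""Reference locus and read containers.

A :class:`LocusReference` describes one amplicon spanning a Cas9 cut site:
the amplicon sequence, the blunt-cut coordinate, and the two PCR primers that
define the amplicon ends. Coordinates are 0-based and half-open throughout;
``cut_site`` is the index of the first base to the right of the blunt cut
(Cas9 cuts 3 bp 5' of the PAM; the stored coordinate is the resolved cut
position, not the PAM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

_DNA = set("ACGT")


@dataclass(frozen=True)
class LocusReference:
    """An amplicon reference with a known Cas9 cut site.

    Parameters
    ----------
    name:
        Identifier for the locus (e.g. ``"toy_rosa26"``).
    sequence:
        Uppercase A/C/G/T amplicon sequence, starting with the forward
        primer and ending with the reverse complement of the reverse primer.
    cut_site:
        0-based index of the first base right of the blunt cut.
    primer_fwd, primer_rev:
        Primer oligo sequences locating the amplicon ends. May be empty for
        toy references used in direct junction-calling tests; when present,
        each must occur exactly once in the amplicon (the reverse primer via
        its reverse complement at the 3' end).
    """

    name: str
    sequence: str
    cut_site: int
    primer_fwd: str = ""
    primer_rev: str = ""

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - _DNA:
            raise ValueError("reference sequence must be non-empty A/C/G/T")
        if not 0 < self.cut_site < len(self.sequence):
            raise ValueError("cut_site must lie strictly inside the sequence")
        if self.primer_fwd:
            if self.sequence.count(self.primer_fwd) != 1 or not self.sequence.startswith(self.primer_fwd):
                raise ValueError("forward primer must occur exactly once, at the amplicon start")
        if self.primer_rev:
            tail = reverse_complement(self.primer_rev)
            if self.sequence.count(tail) != 1 or not self.sequence.endswith(tail):
                raise ValueError("reverse primer (revcomp) must occur exactly once, at the amplicon end")
        if self.primer_fwd and self.cut_site <= len(self.primer_fwd):
            raise ValueError("cut_site must lie downstream of the forward primer")

    @property
    def read_start(self) -> int:
        """Reference coordinate where trimmed reads begin (just after the forward primer)."""
        return len(self.primer_fwd)

    def validate_for_anchors(self, anchor_length: int) -> None:
        """Check the cut site leaves room for an exact anchor on each side."""
        if self.cut_site - self.read_start < anchor_length:
            raise ValueError("not enough sequence left of the cut for an anchor")
        if len(self.sequence) - self.cut_site < anchor_length:
            raise ValueError("not enough sequence right of the cut for an anchor")


@dataclass(frozen=True)
class ReadRecord:
    """A single (possibly trimmed) amplicon read."""

    read_id: str
    sequence: str
    sample_id: str = ""
    barcode: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")


@dataclass(frozen=True)
class ReadLayout:
    """Library layout of a raw read: barcode, variable spacer, locus primer.

    Raw reads begin with a fixed-length sample barcode, then a spacer of
    varying length (to increase base diversity on the sequencer), then the
    locus-specific forward primer, then the amplified repair junction.
    """

    primer: str
    barcode_length: int = 6
    spacer_min: int = 1
    spacer_max: int = 8

    def __post_init__(self) -> None:
        if not self.primer:
            raise ValueError("layout requires a locus primer sequence")
        if self.barcode_length <= 0 or self.spacer_min < 0 or self.spacer_max < self.spacer_min:
            raise ValueError("invalid barcode/spacer layout")
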