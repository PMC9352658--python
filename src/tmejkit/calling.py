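"""Junction reconstruction from amplicon reads.

Each read is aligned to the reference locus by a pair of exact anchor
matches (10 nt by default), one upstream and one downstream of the Cas9 cut,
chosen to minimize the total deletion implied by their reference placements.
The sequence between the anchors is the reconstructed junction: deletion
lengths on each side, any inserted sequence, and the microhomology (the
short repeat shared by the two deletion boundaries, over which the junction
register can slide).

Coordinate conventions: reference coordinates are 0-based half-open;
``cut_site`` is the index of the first base right of the blunt cut. Trimmed
reads are anchored at the reference — read position ``i`` corresponds to
reference position ``i + ref.read_start`` on the intact left flank.

Exclusion filters follow the amplicon-sequencing artifact model: junctions
whose reconstructed region contains IUPAC ambiguity codes are dropped, as are
net-zero "insertion" events explained by a lone PCR substitution error close
to the cut (a mismatched base 3-10 nt from the break whose neighbors match
the reference).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .locus import LocusReference, ReadLayout, ReadRecord

logger = logging.getLogger(__name__)

_UNAMBIGUOUS = set("ACGT")

#: Default exact-match anchor length, in nt.
DEFAULT_ANCHOR_LENGTH = 10

#: Default substitution-artifact window: distances from the cut, inclusive.
DEFAULT_ARTIFACT_WINDOW = (3, 10)


class CallStatus(str, Enum):
    PASS = "PASS"
    INTACT = "INTACT"
    AMBIGUOUS_BASE = "AMBIGUOUS_BASE"
    SUBSTITUTION_ARTIFACT = "SUBSTITUTION_ARTIFACT"
    UNALIGNABLE = "UNALIGNABLE"


# Severity order used to combine filter outcomes; a higher rank wins, which
# makes the final status independent of the order filters are applied in.
_SEVERITY = {
    CallStatus.PASS: 0,
    CallStatus.INTACT: 0,
    CallStatus.SUBSTITUTION_ARTIFACT: 1,
    CallStatus.AMBIGUOUS_BASE: 2,
    CallStatus.UNALIGNABLE: 3,
}


def _combine_status(current: CallStatus, new: CallStatus) -> CallStatus:
    return new if _SEVERITY[new] > _SEVERITY[current] else current


@dataclass(frozen=True)
class JunctionCall:
    """Reconstructed repair junction for one read.

    ``del_left``/``del_right`` are nucleotides deleted on each side of the
    cut in the canonical (left-aligned) register; ``microhomology_length``
    is the number of positions the deletion boundary can slide right from
    that register (0 whenever an insertion is present or nothing is deleted).
    """

    read_id: str
    status: CallStatus
    del_left: int = 0
    del_right: int = 0
    insertion: str = ""
    microhomology_length: int = 0
    microhomology_seq: str = ""
    sample_id: str = ""

    @property
    def deletion_length(self) -> int:
        return self.del_left + self.del_right

    @property
    def indel_length(self) -> int:
        """Total indel size: deleted plus inserted nucleotides."""
        return self.deletion_length + len(self.insertion)

    @property
    def junction_key(self) -> str:
        """Canonical junction identifier; registers of one event share a key."""
        return f"{self.del_left}|{self.del_right}|{self.insertion}"


@dataclass(frozen=True)
class AnchorPlacement:
    """Minimal-deletion anchor pair, before register canonicalization.

    ``left_end_read``/``left_end_ref`` locate the 3' end of the upstream
    anchor; ``right_start_read``/``right_start_ref`` the 5' start of the
    downstream anchor. ``overlap`` is the number of read bases claimed by
    both anchors (the raw microhomology); ``insertion`` the read sequence
    strictly between them.
    """

    left_end_read: int
    left_end_ref: int
    right_start_read: int
    right_start_ref: int
    overlap: int
    insertion: str

    @property
    def total_deletion(self) -> int:
        return (self.right_start_ref - self.left_end_ref) + self.overlap


def find_anchors(
    read: ReadRecord,
    ref: LocusReference,
    anchor_length: int = DEFAULT_ANCHOR_LENGTH,
) -> Optional[AnchorPlacement]:
    """Find the exact anchor pair minimizing the implied total deletion.

    Scans outward from the cut site on both sides for exact
    ``anchor_length``-mers shared between read and reference, enumerating
    upstream placements (read-anchored at the reference) against all
    occurrences of each downstream reference k-mer in the read. Candidates
    are ranked by (total deletion, insertion length, del_right, del_left);
    branch-and-bound pruning on the total deletion keeps the scan fast while
    remaining exhaustive. Returns ``None`` when no valid pair exists.
    """
    S = read.sequence
    R = ref.sequence
    c = ref.cut_site
    o = ref.read_start
    k = anchor_length
    ref.validate_for_anchors(k)

    max_dl = c - o - k
    max_dr = len(R) - c - k
    best_key: Optional[tuple] = None
    best: Optional[tuple] = None  # (dl, dr, q, v, ins)

    for dl in range(max_dl + 1):
        if best_key is not None and dl > best_key[0]:
            break
        jl = c - dl - o  # read coordinate of the left anchor 3' end
        if jl - k < 0 or jl > len(S):
            continue
        if S[jl - k : jl] != R[c - dl - k : c - dl]:
            continue
        for dr in range(max_dr + 1):
            if best_key is not None and dl + dr > best_key[0]:
                break
            kmer = R[c + dr : c + dr + k]
            q = S.find(kmer)
            while q != -1:
                if q >= jl:
                    cand = (dl + dr, q - jl, dr, dl)
                    cand_full = (dl, dr, q, 0, S[jl:q])
                elif jl - q <= k:
                    v = jl - q
                    cand = (dl + dr + v, 0, dr, dl)
                    cand_full = (dl, dr, q, v, "")
                else:
                    cand = None
                    cand_full = None
                if cand is not None and (best_key is None or cand < best_key):
                    best_key, best = cand, cand_full
                q = S.find(kmer, q + 1)

    if best is None:
        return None
    dl, dr, q, v, ins = best
    jl = c - dl - o
    return AnchorPlacement(
        left_end_read=jl,
        left_end_ref=c - dl,
        right_start_read=q,
        right_start_ref=c + dr,
        overlap=v,
        insertion=ins,
    )


def _canonicalize(
    placement: AnchorPlacement, ref: LocusReference, anchor_length: int
) -> tuple[int, int, int, str]:
    """Left-align the deletion register and measure microhomology.

    Returns (del_left, del_right, mh_length, mh_seq) relative to the cut.
    The boundary pair is slid as far left as the reference permits; the
    microhomology is the extent the boundary can slide back right, capped at
    the deletion length and the anchor length.
    """
    R = ref.sequence
    c = ref.cut_site
    d_total = placement.total_deletion
    if d_total == 0:
        return 0, 0, 0, ""
    if placement.insertion:
        # Compound deletion+insertion: register fixed, MH defined as 0.
        return c - placement.left_end_ref, placement.right_start_ref - c, 0, ""
    b1 = placement.left_end_ref - placement.overlap
    b2 = placement.right_start_ref
    while b1 > 0 and R[b1 - 1] == R[b2 - 1]:
        b1 -= 1
        b2 -= 1
    mh = 0
    cap = min(d_total, anchor_length)
    while mh < cap and b2 + mh < len(R) and R[b1 + mh] == R[b2 + mh]:
        mh += 1
    return c - b1, b2 - c, mh, R[b1 : b1 + mh]


def call_junction(
    read: ReadRecord,
    ref: LocusReference,
    anchor_length: int = DEFAULT_ANCHOR_LENGTH,
) -> JunctionCall:
    """Reconstruct the repair junction of a trimmed read.

    Returns an ``UNALIGNABLE`` call when no exact anchor pair exists, an
    ``INTACT`` call for reads matching the reference across the cut, and a
    ``PASS`` call otherwise (before exclusion filters).
    """
    placement = find_anchors(read, ref, anchor_length)
    if placement is None:
        return JunctionCall(read.read_id, CallStatus.UNALIGNABLE, sample_id=read.sample_id)
    del_left, del_right, mh, mh_seq = _canonicalize(placement, ref, anchor_length)
    if del_left + del_right == 0 and not placement.insertion:
        return JunctionCall(read.read_id, CallStatus.INTACT, sample_id=read.sample_id)
    return JunctionCall(
        read_id=read.read_id,
        status=CallStatus.PASS,
        del_left=del_left,
        del_right=del_right,
        insertion=placement.insertion,
        microhomology_length=mh,
        microhomology_seq=mh_seq,
        sample_id=read.sample_id,
    )


def _junction_region(
    call: JunctionCall, read: ReadRecord, ref: LocusReference, anchor_length: int
) -> str:
    """Read sequence between the 5' end of the upstream anchor and the 3'
    end of the downstream anchor (the reconstructed junction)."""
    c = ref.cut_site
    o = ref.read_start
    jl = (c - call.del_left) + call.microhomology_length - o
    q = jl - call.microhomology_length + len(call.insertion)
    lo = max(0, jl - anchor_length)
    hi = min(len(read.sequence), q + anchor_length)
    return read.sequence[lo:hi]


def filter_ambiguous(
    call: JunctionCall,
    read: ReadRecord,
    ref: LocusReference,
    anchor_length: int = DEFAULT_ANCHOR_LENGTH,
) -> JunctionCall:
    """Flag calls whose reconstructed junction contains IUPAC ambiguity codes."""
    if call.status is CallStatus.UNALIGNABLE:
        return call
    region = _junction_region(call, read, ref, anchor_length)
    if set(region) - _UNAMBIGUOUS:
        return replace(call, status=_combine_status(call.status, CallStatus.AMBIGUOUS_BASE))
    return call


def filter_substitution_artifact(
    call: JunctionCall,
    read: ReadRecord,
    ref: LocusReference,
    window: tuple[int, int] = DEFAULT_ARTIFACT_WINDOW,
) -> JunctionCall:
    """Flag net-zero junctions explained by amplification substitution error.

    A lone polymerase error near the cut breaks the adjacent anchor and is
    misattributed as a paired deletion+insertion of equal length. Such a call
    is flagged when, under the identity alignment, every mismatching read
    position inside the event interval lies ``window`` nt from the cut
    (distances inclusive, on either side) and both immediately adjacent read
    positions match the reference.
    """
    if call.status is CallStatus.UNALIGNABLE:
        return call
    if call.deletion_length == 0 or len(call.insertion) != call.deletion_length:
        return call
    S, R = read.sequence, ref.sequence
    c, o = ref.cut_site, ref.read_start
    lo_d, hi_d = window
    b1, b2 = c - call.del_left, c + call.del_right
    mismatches = []
    for p in range(b1, b2):
        i = p - o
        if i < 0 or i >= len(S):
            return call
        if S[i] != R[p]:
            mismatches.append(p)
    if not mismatches:
        return call
    for p in mismatches:
        dist = (c - p) if p < c else (p - c + 1)
        if not lo_d <= dist <= hi_d:
            return call
        for pn in (p - 1, p + 1):
            i = pn - o
            if i < 0 or i >= len(S) or pn >= len(R) or S[i] != R[pn]:
                return call
    return replace(
        call, status=_combine_status(call.status, CallStatus.SUBSTITUTION_ARTIFACT)
    )


def trim_read(
    raw_read: ReadRecord, layout: ReadLayout, anchor_length: int = DEFAULT_ANCHOR_LENGTH
) -> Optional[ReadRecord]:
    """Strip barcode, variable spacer, and locus primer from a raw read.

    The locus primer must occur exactly at one of the positions allowed by
    the barcode+spacer layout; the trimmed read starts immediately after the
    primer and carries the 6 bp barcode for sample assignment. Returns
    ``None`` when the primer is not found there or too little sequence
    remains (such reads are tallied as UNALIGNABLE downstream).
    """
    seq = raw_read.sequence
    b = layout.barcode_length
    for spacer in range(layout.spacer_min, layout.spacer_max + 1):
        start = b + spacer
        if seq.startswith(layout.primer, start):
            trimmed = seq[start + len(layout.primer) :]
            if len(trimmed) < 2 * anchor_length:
                return None
            return ReadRecord(
                read_id=raw_read.read_id,
                sequence=trimmed,
                sample_id=raw_read.sample_id,
                barcode=seq[:b],
            )
    return None


def demultiplex(
    reads: Iterable[ReadRecord], barcode_to_sample: dict[str, str]
) -> list[ReadRecord]:
    """Assign trimmed reads to samples by exact barcode match; discard the rest."""
    out = []
    for r in reads:
        sample = barcode_to_sample.get(r.barcode)
        if sample is not None:
            out.append(replace(r, sample_id=sample))
    return out


def call_read(
    raw_read: ReadRecord,
    ref: LocusReference,
    layout: Optional[ReadLayout] = None,
    anchor_length: int = DEFAULT_ANCHOR_LENGTH,
    artifact_window: tuple[int, int] = DEFAULT_ARTIFACT_WINDOW,
) -> JunctionCall:
    """Full per-read pipeline: optional trim, anchor call, exclusion filters."""
    read = raw_read
    if layout is not None:
        trimmed = trim_read(raw_read, layout, anchor_length)
        if trimmed is None:
            return JunctionCall(
                raw_read.read_id, CallStatus.UNALIGNABLE, sample_id=raw_read.sample_id
            )
        read = trimmed
    call = call_junction(read, ref, anchor_length)
    call = filter_ambiguous(call, read, ref, anchor_length)
    call = filter_substitution_artifact(call, read, ref, artifact_window)
    return call


@dataclass
class JunctionTable:
    """Per-sample counts of unique repair junctions.

    ``df`` holds one row per junction_key (PASS reads only) with the
    junction's canonical coordinates and its read count; intact reads and
    filter attrition are tracked separately. ``repair_total`` is the
    all-repair denominator (total PASS reads).
    """

    sample_id: str
    df: pd.DataFrame
    intact_count: int = 0
    repair_total: int = 0
    attrition: dict = field(default_factory=dict)

    COLUMNS = (
        "junction_key",
        "del_left",
        "del_right",
        "deletion_length",
        "insertion",
        "mh_length",
        "count",
    )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# tmejkit junction table\n")
            fh.write(f"# sample_id={self.sample_id}\n")
            fh.write(f"# intact={self.intact_count}\n")
            fh.write(f"# repair_total={self.repair_total}\n")
            for status, n in sorted(self.attrition.items()):
                fh.write(f"# attrition_{status}={n}\n")
            out = self.df.copy()
            out["insertion"] = out["insertion"].replace("", ".")
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "JunctionTable":
        meta: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
        df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, dtype={"insertion": str})
        df["insertion"] = df["insertion"].replace(".", "")
        attrition = {
            k[len("attrition_") :]: int(v) for k, v in meta.items() if k.startswith("attrition_")
        }
        return cls(
            sample_id=meta.get("sample_id", ""),
            df=df,
            intact_count=int(meta.get("intact", 0)),
            repair_total=int(meta.get("repair_total", 0)),
            attrition=attrition,
        )


def tabulate_junctions(calls: Sequence[JunctionCall], sample_id: str = "") -> JunctionTable:
    """Count PASS junctions per canonical key; intact and filtered reads are
    tallied separately and excluded from the all-repair denominator."""
    counts: Counter[str] = Counter()
    meta: dict[str, JunctionCall] = {}
    attrition: Counter[str] = Counter()
    intact = 0
    for call in calls:
        attrition[call.status.value] += 1
        if call.status is CallStatus.INTACT:
            intact += 1
        elif call.status is CallStatus.PASS:
            counts[call.junction_key] += 1
            meta.setdefault(call.junction_key, call)
    rows = [
        {
            "junction_key": key,
            "del_left": meta[key].del_left,
            "del_right": meta[key].del_right,
            "deletion_length": meta[key].deletion_length,
            "insertion": meta[key].insertion,
            "mh_length": meta[key].microhomology_length,
            "count": n,
        }
        for key, n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=list(JunctionTable.COLUMNS))
    if not df.empty:
        df = df.sort_values(["count", "junction_key"], ascending=[False, True]).reset_index(
            drop=True
        )
    repair_total = int(df["count"].sum()) if not df.empty else 0
    logger.info(
        "sample %s: %d repair reads over %d junctions, %d intact, attrition %s",
        sample_id,
        repair_total,
        len(df),
        intact,
        dict(attrition),
    )
    return JunctionTable(
        sample_id=sample_id,
        df=df,
        intact_count=intact,
        repair_total=repair_total,
        attrition=dict(attrition),
    )
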