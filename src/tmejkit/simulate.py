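"""Synthetic amplicon data with known ground truth.

Generates every input the pipeline consumes: a toy locus with planted
microhomology pairs flanking the cut, repair-event reads (FASTQ) with truth
labels, paired wild-type / Polq-null read sets in which TMEJ-class events are
depleted, and qPCR / ddPCR measurement tables.

Event classes emulate the repair-product taxonomy of Cas9 break repair:

- ``intact``: the unedited amplicon (uncut or perfectly rejoined).
- ``mhd``: microhomology-mediated deletion between a planted repeat pair
  (2-6 bp) flanking the cut, retaining one copy — the TMEJ deletion signature.
- ``tins``: templated insertion, 5-30 nt copied (direct or inverted) from
  within +/-50 nt of the cut — near-unique to TMEJ.
- ``nhej_ins1``: the +1 single-nucleotide insertion NHEJ signature.
- ``nhej_small_del``: 1-4 nt deletion without boundary microhomology.
- ``long_del_no_mh``: 8-30 nt deletion without microhomology, Polq-independent
  ("other" class).

Every generated event is checked to parse unambiguously under the exact
anchor-match model (no coincidental anchor placements with a smaller implied
deletion), so on error-free reads the caller's output equals the truth label
by construction. Substitution errors and IUPAC ambiguity bases are injected
at configurable per-base / per-read rates on top.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .calling import JunctionTable
from .locus import LocusReference, ReadRecord

BASES = "ACGT"
AMBIGUITY_CODES = "NWSRK"

#: Default planted microhomology pairs: (mh_length, left_start, right_start)
#: offsets relative to the cut; the left copy spans [cut+left_start,
#: cut+left_start+mh), the right copy [cut+right_start, cut+right_start+mh).
DEFAULT_PLANTED_MH = (
    (2, -6, 3),
    (3, -12, 7),
    (4, -20, 12),
    (5, -27, 18),
    (6, -35, 25),
)

#: Default event mixture. Conditional on repair (the non-intact 70%), the
#: composition matches the wild-type vehicle-treated repair spectrum at a
#: microhomology-rich Cas9 site: signature deletions 19% of repair, NHEJ-class
#: indels 63%, templated insertions plus long MH-less deletions 18%.
DEFAULT_EVENT_MIXTURE = {
    "intact": 0.30,
    "mhd": 0.133,
    "tins": 0.056,
    "nhej_ins1": 0.301,
    "nhej_small_del": 0.14,
    "long_del_no_mh": 0.07,
}

DEFAULT_BARCODES = {"wt": "ACGTCA", "polq_null": "GTACAG", "test": "CAGTAC"}

_TMEJ_CLASSES = ("mhd", "tins")
_NHEJ_CLASSES = ("nhej_ins1", "nhej_small_del")


@dataclass
class SimulationConfig:
    """Study conditions for read simulation.

    ``polq_null_depletion`` multiplies the probabilities of TMEJ-class events
    (mhd, tins) in the Polq-null condition; the removed probability mass is
    re-channeled onto the NHEJ classes proportionally, emulating compensation
    by nonhomologous end joining.
    """

    seed: int = 0
    n_reads: int = 10_000
    event_mixture: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_MIXTURE))
    polq_null_depletion: float = 0.25
    substitution_error_rate: float = 0.001
    ambiguity_rate: float = 0.002
    read_length: int = 150
    barcode_length: int = 6
    spacer_min: int = 1
    spacer_max: int = 8
    planted_mh: tuple = DEFAULT_PLANTED_MH

    def __post_init__(self) -> None:
        total = sum(self.event_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event mixture sums to {total}, not 1")
        if not 0.0 <= self.polq_null_depletion <= 1.0:
            raise ValueError("depletion factor must lie in [0, 1]")
        for rate in (self.substitution_error_rate, self.ambiguity_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")


def depleted_mixture(mixture: Mapping[str, float], factor: float) -> dict:
    """TMEJ-class probabilities scaled by ``factor``; lost mass moves to NHEJ."""
    m = dict(mixture)
    lost = sum(m.get(k, 0.0) for k in _TMEJ_CLASSES) * (1.0 - factor)
    for k in _TMEJ_CLASSES:
        if k in m:
            m[k] *= factor
    nhej_mass = sum(m.get(k, 0.0) for k in _NHEJ_CLASSES)
    if lost > 0 and nhej_mass <= 0:
        raise ValueError("no NHEJ class to re-channel depleted mass onto")
    for k in _NHEJ_CLASSES:
        if k in m:
            m[k] += lost * m[k] / nhej_mass
    return m


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def make_locus(
    seed: int,
    length: int = 200,
    planted_microhomologies: Sequence[tuple] = DEFAULT_PLANTED_MH,
    cut_site: Optional[int] = None,
    primer_length: int = 20,
    max_tries: int = 200,
    name: str = "synthetic_locus",
) -> LocusReference:
    """Build a synthetic amplicon with planted microhomology pairs at the cut.

    The returned locus contains each planted repeat at its stated offsets,
    with the flanking bases forced to differ so the repeat cannot extend
    (microhomology length is exactly as planted), and no duplicated 10-mer
    anywhere else (verified by exhaustive k-mer scan), so anchor matches are
    unique. Deterministic in ``seed``.
    """
    if length < 120:
        raise ValueError("locus length must be >= 120")
    c = length // 2 if cut_site is None else cut_site
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        seq = list(_random_dna(rng, length))
        ok = True
        for mh, l0, r0 in planted_microhomologies:
            if not (2 <= mh <= 6 and l0 + mh <= 0 and r0 >= 0):
                raise ValueError(f"invalid planted pair {(mh, l0, r0)}")
            if c + l0 - 1 < 0 or c + r0 + mh >= length:
                raise ValueError(f"planted pair {(mh, l0, r0)} outside the locus")
            seq[c + r0 : c + r0 + mh] = seq[c + l0 : c + l0 + mh]
            # forbid repeat extension on either side (exact planted MH)
            for pl, pr in ((c + l0 - 1, c + r0 - 1), (c + l0 + mh, c + r0 + mh)):
                if seq[pl] == seq[pr]:
                    seq[pr] = rng.choice([b for b in BASES if b != seq[pl]])
        s = "".join(seq)
        kmers = {s[i : i + 10] for i in range(len(s) - 9)}
        if len(kmers) != len(s) - 9:
            continue
        for mh, l0, r0 in planted_microhomologies:
            if s[c + l0 : c + l0 + mh] != s[c + r0 : c + r0 + mh]:
                ok = False
            if s[c + l0 - 1] == s[c + r0 - 1] or s[c + l0 + mh] == s[c + r0 + mh]:
                ok = False
        if not ok:
            continue
        primer_fwd = s[:primer_length]
        primer_rev = reverse_complement(s[-primer_length:])
        if s.count(primer_fwd) != 1 or s.count(s[-primer_length:]) != 1:
            continue
        locus = LocusReference(
            name=name, sequence=s, cut_site=c, primer_fwd=primer_fwd, primer_rev=primer_rev
        )
        return locus
    raise RuntimeError("could not satisfy locus constraints; relax planted pairs or length")


@dataclass(frozen=True)
class EventTruth:
    """Ground-truth junction of one simulated repair event (canonical register)."""

    event: str
    del_left: int
    del_right: int
    insertion: str
    mh_length: int

    @property
    def junction_key(self) -> str:
        return f"{self.del_left}|{self.del_right}|{self.insertion}"

    @property
    def deletion_length(self) -> int:
        return self.del_left + self.del_right


def planted_mhd_events(
    locus: LocusReference, planted: Sequence[tuple] = DEFAULT_PLANTED_MH
) -> list[EventTruth]:
    """Truth junctions for the planted microhomology-mediated deletions."""
    out = []
    c = locus.cut_site
    for mh, l0, r0 in planted:
        assert locus.sequence[c + l0 : c + l0 + mh] == locus.sequence[c + r0 : c + r0 + mh]
        out.append(EventTruth("mhd", -l0, r0, "", mh))
    return out


def _apply_event(R: str, c: int, truth: EventTruth) -> str:
    b1, b2 = c - truth.del_left, c + truth.del_right
    return R[:b1] + truth.insertion + R[b2:]


def _parses_unambiguously(variant: str, R: str, c: int, truth: EventTruth, k: int = 10) -> bool:
    """True when the exact-anchor minimal-deletion parse of ``variant`` must
    recover ``truth``: no smaller left/right anchor placement exists and the
    downstream anchor k-mer occurs only at the true junction."""
    dl_min = truth.del_left - truth.mh_length
    for dl in range(dl_min):
        lo = c - dl - k
        if lo >= 0 and variant[lo : c - dl] == R[lo : c - dl]:
            return False
    for dr in range(truth.del_right):
        if R[c + dr : c + dr + k] in variant:
            return False
    kmer = R[c + truth.del_right : c + truth.del_right + k]
    expected = c - truth.del_left + len(truth.insertion)
    hits = []
    start = variant.find(kmer)
    while start != -1:
        hits.append(start)
        start = variant.find(kmer, start + 1)
    return hits == [expected]


def _sample_event(
    rng: np.random.Generator,
    locus: LocusReference,
    event: str,
    planted: Sequence[EventTruth],
    max_tries: int = 100,
) -> EventTruth:
    R, c = locus.sequence, locus.cut_site
    if event == "intact":
        return EventTruth("intact", 0, 0, "", 0)
    if event == "mhd":
        return planted[rng.integers(len(planted))]
    for _ in range(max_tries):
        if event == "tins":
            n = int(rng.integers(5, 31))
            t0 = int(rng.integers(c - 50, c + 51 - n))
            seg = R[t0 : t0 + n]
            ins = seg if rng.random() < 0.5 else reverse_complement(seg)
            truth = EventTruth("tins", 0, 0, ins, 0)
        elif event == "nhej_ins1":
            truth = EventTruth("nhej_ins1", 0, 0, str(rng.choice(list(BASES))), 0)
        elif event in ("nhej_small_del", "long_del_no_mh"):
            d = int(rng.integers(1, 5)) if event == "nhej_small_del" else int(rng.integers(8, 31))
            dl = int(rng.integers(0, d + 1))
            dr = d - dl
            b1, b2 = c - dl, c + dr
            if R[b1 - 1] == R[b2 - 1] or R[b1] == R[b2]:
                continue  # boundary microhomology: resample for an MH-0 deletion
            truth = EventTruth(event, dl, dr, "", 0)
        else:
            raise ValueError(f"unknown event class {event!r}")
        if _parses_unambiguously(_apply_event(R, c, truth), R, c, truth):
            return truth
    raise RuntimeError(f"could not draw an unambiguous {event} event")


def _inject_errors(
    seq: str, rng: np.random.Generator, sub_rate: float, ambiguity_rate: float
) -> tuple[str, int, bool]:
    chars = list(seq)
    n_sub = 0
    if sub_rate > 0:
        hits = np.nonzero(rng.random(len(chars)) < sub_rate)[0]
        for i in hits:
            chars[i] = rng.choice([b for b in BASES if b != chars[i]])
        n_sub = len(hits)
    has_amb = False
    if ambiguity_rate > 0 and rng.random() < ambiguity_rate:
        i = int(rng.integers(len(chars)))
        chars[i] = rng.choice(list(AMBIGUITY_CODES))
        has_amb = True
    return "".join(chars), n_sub, has_amb


def simulate_reads(
    config: SimulationConfig,
    locus: LocusReference,
    condition: str = "wt",
    sample_id: Optional[str] = None,
    barcode: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate raw reads (barcode + spacer + primer + junction) with truth.

    The ``polq_null`` condition uses the depleted mixture. Returns the raw
    reads and a truth table with one row per read (event class, canonical
    junction coordinates and key, injected error counts).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sample_id = sample_id or condition
    barcode = barcode or DEFAULT_BARCODES.get(condition, "ACGTCA")
    if len(barcode) != config.barcode_length:
        raise ValueError("barcode length does not match the layout")

    mixture = config.event_mixture
    if condition == "polq_null":
        mixture = depleted_mixture(mixture, config.polq_null_depletion)
    classes = sorted(mixture)
    probs = np.array([mixture[k] for k in classes])
    probs = probs / probs.sum()
    planted = planted_mhd_events(locus, config.planted_mh)

    o = locus.read_start
    reads, truth_rows = [], []
    draws = rng.choice(len(classes), size=config.n_reads, p=probs)
    for i, ci in enumerate(draws):
        event = classes[ci]
        truth = _sample_event(rng, locus, event, planted)
        variant = _apply_event(locus.sequence, locus.cut_site, truth)
        insert = variant[o : o + config.read_length]
        spacer_len = int(rng.integers(config.spacer_min, config.spacer_max + 1))
        raw = barcode + _random_dna(rng, spacer_len) + locus.primer_fwd + insert
        raw, n_sub, has_amb = _inject_errors(
            raw, rng, config.substitution_error_rate, config.ambiguity_rate
        )
        read_id = f"{sample_id}:{i:06d}"
        reads.append(ReadRecord(read_id=read_id, sequence=raw, sample_id=sample_id))
        truth_rows.append(
            {
                "read_id": read_id,
                "sample_id": sample_id,
                "condition": condition,
                "event": event,
                "del_left": truth.del_left,
                "del_right": truth.del_right,
                "insertion": truth.insertion,
                "mh_length": truth.mh_length,
                "junction_key": "" if event == "intact" else truth.junction_key,
                "n_sub_errors": n_sub,
                "has_ambiguity": has_amb,
            }
        )
    return reads, pd.DataFrame(truth_rows)


def simulate_substitution_artifact_reads(
    locus: LocusReference,
    n: int,
    seed: int = 0,
    config: Optional[SimulationConfig] = None,
    window: tuple[int, int] = (3, 10),
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Intact reads carrying a single amplification-substitution artifact.

    Each read is the reference with one substituted base at a distance drawn
    uniformly from ``window`` (inclusive) on a random side of the cut; its
    neighbors match the reference, so every read satisfies the
    substitution-artifact exclusion rule.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    R, c, o = locus.sequence, locus.cut_site, locus.read_start
    reads, rows = [], []
    for i in range(n):
        dist = int(rng.integers(window[0], window[1] + 1))
        side = rng.choice(["left", "right"])
        p = c - dist if side == "left" else c + dist - 1
        variant = list(R)
        variant[p] = rng.choice([b for b in BASES if b != R[p]])
        insert = "".join(variant)[o : o + config.read_length]
        spacer_len = int(rng.integers(config.spacer_min, config.spacer_max + 1))
        raw = DEFAULT_BARCODES["wt"] + _random_dna(rng, spacer_len) + locus.primer_fwd + insert
        read_id = f"artifact:{i:05d}"
        reads.append(ReadRecord(read_id=read_id, sequence=raw, sample_id="artifact"))
        rows.append({"read_id": read_id, "distance": dist, "side": side})
    return reads, pd.DataFrame(rows)


@dataclass
class TwoConditionSim:
    """Paired wild-type / Polq-null simulation with per-condition truth."""

    reads_wt: list
    truth_wt: pd.DataFrame
    reads_polq_null: list
    truth_polq_null: pd.DataFrame
    mixture_wt: dict
    mixture_polq_null: dict
    planted_tmej_keys: frozenset


def simulate_two_conditions(
    config: SimulationConfig, locus: LocusReference
) -> TwoConditionSim:
    """Simulate matched wild-type and Polq-null read sets.

    TMEJ-class event probabilities are multiplied by
    ``config.polq_null_depletion`` in the null condition and the lost mass is
    re-channeled to NHEJ. ``planted_tmej_keys`` holds the canonical junction
    keys of the planted microhomology-mediated deletions — the keys a
    depletion analysis should recover (insertion-class TMEJ products cannot
    enter a deletion-only signature).
    """
    rng = np.random.default_rng(config.seed)
    reads_wt, truth_wt = simulate_reads(config, locus, "wt", rng=rng)
    reads_null, truth_null = simulate_reads(config, locus, "polq_null", rng=rng)
    keys = frozenset(e.junction_key for e in planted_mhd_events(locus, config.planted_mh))
    return TwoConditionSim(
        reads_wt=reads_wt,
        truth_wt=truth_wt,
        reads_polq_null=reads_null,
        truth_polq_null=truth_null,
        mixture_wt=dict(config.event_mixture),
        mixture_polq_null=depleted_mixture(config.event_mixture, config.polq_null_depletion),
        planted_tmej_keys=keys,
    )


def _junction_universe(
    config: SimulationConfig, locus: LocusReference, rng: np.random.Generator
) -> pd.DataFrame:
    """Fixed junction-key universe with per-key probabilities for count-level
    simulation (no read synthesis)."""
    planted = planted_mhd_events(locus, config.planted_mh)
    R, c = locus.sequence, locus.cut_site
    entries: list[tuple[str, EventTruth]] = [("mhd", e) for e in planted]
    tins, seen = [], set()
    while len(tins) < 8:
        e = _sample_event(rng, locus, "tins", planted)
        if e.junction_key not in seen:
            seen.add(e.junction_key)
            tins.append(e)
    entries += [("tins", e) for e in tins]
    entries += [("nhej_ins1", EventTruth("nhej_ins1", 0, 0, b, 0)) for b in BASES]
    small = []
    for d in range(1, 5):
        for dl in range(d + 1):
            dr = d - dl
            b1, b2 = c - dl, c + dr
            if R[b1 - 1] != R[b2 - 1] and R[b1] != R[b2]:
                small.append(EventTruth("nhej_small_del", dl, dr, "", 0))
    entries += [("nhej_small_del", e) for e in small]
    longs, seen = [], set()
    while len(longs) < 12:
        e = _sample_event(rng, locus, "long_del_no_mh", planted)
        if e.junction_key not in seen:
            seen.add(e.junction_key)
            longs.append(e)
    entries += [("long_del_no_mh", e) for e in longs]

    mix = config.event_mixture
    n_per_class: dict[str, int] = {}
    for cls, _ in entries:
        n_per_class[cls] = n_per_class.get(cls, 0) + 1
    rows = [
        {
            "event": cls,
            "junction_key": e.junction_key,
            "del_left": e.del_left,
            "del_right": e.del_right,
            "deletion_length": e.deletion_length,
            "insertion": e.insertion,
            "mh_length": e.mh_length,
            "prob": float(mix.get(cls, 0.0)) / n_per_class[cls],
        }
        for cls, e in entries
    ]
    return pd.DataFrame(rows)


def _counts_to_table(universe: pd.DataFrame, counts: np.ndarray, intact: int, sample_id: str) -> JunctionTable:
    df = universe.drop(columns=["prob", "event"]).copy()
    df["count"] = counts
    df = df[df["count"] > 0].reset_index(drop=True)
    df = df[[*JunctionTable.COLUMNS]]
    return JunctionTable(
        sample_id=sample_id,
        df=df,
        intact_count=intact,
        repair_total=int(counts.sum()),
        attrition={"PASS": int(counts.sum()), "INTACT": intact},
    )


def simulate_count_tables(
    config: SimulationConfig,
    locus: LocusReference,
    rng: Optional[np.random.Generator] = None,
) -> tuple[JunctionTable, JunctionTable, pd.DataFrame]:
    """Draw junction-count tables for both conditions directly (multinomial).

    Junction-resolved counts over a fixed key universe, without read
    synthesis — the generative model the depletion test assumes. Used for
    null-calibration studies where hundreds of replicate experiments are
    simulated.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    universe = _junction_universe(config, locus, rng)
    mix_null = depleted_mixture(config.event_mixture, config.polq_null_depletion)
    n_per_class = universe.groupby("event")["junction_key"].transform("count")
    p_null = universe["event"].map(mix_null).fillna(0.0).to_numpy() / n_per_class.to_numpy()

    def draw(probs: np.ndarray, intact_p: float, sample_id: str) -> JunctionTable:
        full = np.append(probs, intact_p)
        full = full / full.sum()
        counts = rng.multinomial(config.n_reads, full)
        return _counts_to_table(universe, counts[:-1], int(counts[-1]), sample_id)

    wt = draw(universe["prob"].to_numpy(), config.event_mixture["intact"], "wt")
    null = draw(p_null, mix_null["intact"], "polq_null")
    return wt, null, universe


@dataclass
class DdpcrTruth:
    """Ground truth for the droplet-digital resection assay.

    ssDNA fractions at the three flank distances default to the measured
    4-hour post-break values at a Cas9 cut: 9.1% of genomes resected >8 nt,
    3.8% >284 nt, 1.7% >527 nt. Two-strand deletion fractions, the broken
    fraction, the PstI-site (168 nt) ssDNA fraction, and the reference
    concentration (copies/droplet) are assay-realistic choices.
    """

    ssdna_by_distance: dict = field(default_factory=lambda: {8: 0.091, 284: 0.038, 527: 0.017})
    deletion_by_distance: dict = field(default_factory=lambda: {8: 0.02, 284: 0.01, 527: 0.005})
    broken_fraction: float = 0.30
    psti_ssdna_fraction: float = 0.06
    lambda_ref: float = 0.5


def simulate_ddpcr(
    truth: Optional[DdpcrTruth] = None,
    n_droplets: int = 20_000,
    seed: int = 0,
    sample_id: str = "sim",
) -> pd.DataFrame:
    """Simulate one ddPCR experiment: droplet counts per amplicon/treatment.

    Positives are Binomial(n, 1 - exp(-lambda)) with lambda set from truth:
    ExoI treatment removes the ssDNA-bearing fraction of flank templates;
    mock flank wells lose only two-strand deletions; the intact amplicon
    amplifies unbroken genomes; PstI digestion leaves the resected
    (single-stranded) fraction at its flank site.
    """
    truth = truth or DdpcrTruth()
    rng = np.random.default_rng(seed)
    lam_ref = truth.lambda_ref
    wells: list[tuple[str, str, float]] = [("ref1", "mock", lam_ref), ("ref1", "exoI", lam_ref)]
    for dist, ss in truth.ssdna_by_distance.items():
        dele = truth.deletion_by_distance.get(dist, 0.0)
        wells.append((f"flank_d{dist}", "mock", lam_ref * (1.0 - dele)))
        wells.append((f"flank_d{dist}", "exoI", lam_ref * (1.0 - dele - ss)))
    wells.append(("intact", "mock", lam_ref * (1.0 - truth.broken_fraction)))
    wells.append(("flank_psti", "psti", lam_ref * truth.psti_ssdna_fraction))
    wells.append(("ref1", "psti", lam_ref))
    rows = []
    for amplicon, treatment, lam in wells:
        p = 1.0 - np.exp(-lam)
        positives = int(rng.binomial(n_droplets, p))
        rows.append(
            {
                "sample_id": sample_id,
                "amplicon": amplicon,
                "treatment": treatment,
                "positives": positives,
                "total": n_droplets,
            }
        )
    return pd.DataFrame(rows)


def simulate_qpcr(
    levels: Mapping[str, float],
    calibrator: str,
    seed: int = 0,
    ct_ref: float = 20.0,
    calibrator_delta_ct: float = 8.0,
    noise_sd: float = 0.05,
    replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a tidy Ct table from true signature levels (calibrator = 1).

    Each sample's signature Ct sits ``calibrator_delta_ct - log2(level)``
    cycles above its reference Ct; Gaussian noise (SD in cycles) emulates
    technical replicate scatter.
    """
    if calibrator not in levels:
        raise KeyError("calibrator must appear in the level map")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, level in levels.items():
        if level <= 0:
            raise ValueError("true levels must be positive")
        dct = calibrator_delta_ct - np.log2(level / levels[calibrator])
        for rep in range(replicates):
            rows.append(
                {
                    "sample_id": sample,
                    "amplicon": "reference",
                    "replicate": rep,
                    "ct": ct_ref + rng.normal(0.0, noise_sd),
                }
            )
            rows.append(
                {
                    "sample_id": sample,
                    "amplicon": "signature",
                    "replicate": rep,
                    "ct": ct_ref + dct + rng.normal(0.0, noise_sd),
                }
            )
    return pd.DataFrame(rows)


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    """Write reads as FASTQ (gzip if the path ends in .gz); constant quality."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
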