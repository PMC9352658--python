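# Methods

## The junction model

A repaired amplicon is modeled as the reference `R` with a single junction
at the Cas9 cut site `c` (0-based index of the first base right of the blunt
cut): `read = R[0 : c − del_left] + insertion + R[c + del_right :]`. A read
is reconstructed by finding an exact upstream anchor match and an exact
downstream anchor match (length `anchor_length = 10` nt; configurable) whose
reference placements minimize the total implied deletion, scanning outward
from the cut. Reads are primer-anchored: after trimming, read coordinate
`i` corresponds to reference coordinate `i + read_start` along the intact
left flank. The downstream anchor k-mer is located by occurrence search in
the read; an overlap of up to 10 nt between the two anchor placements is the
raw microhomology, and the read sequence strictly between them is the
insertion.

Candidate decompositions are ranked by `(total deletion, insertion length,
del_right, del_left)`. The implementation enumerates upstream placements
with branch-and-bound pruning on the total deletion; this is exhaustively
equivalent to the naive enumeration over all anchor placements (verified
against a brute-force oracle on random loci, including loci with
coincidental repeated 10-mers), while running in microseconds per read.

**Register canonicalization.** A deletion flanked by a repeated sequence is
the same molecular event in several registers. After the minimal
decomposition is chosen, the boundary pair is slid as far left as the
reference permits (left-aligned register); the microhomology is the number
of positions the boundary can slide back right, capped at the deletion
length and the anchor length. `junction_key = del_left|del_right|insertion`
is computed from canonical coordinates, so all registers of one event
collapse to one key. For compound deletion+insertion events the register is
fixed and microhomology is defined as 0 (the overlap between anchor matches
is empty when intervening sequence exists).

**Assumptions and degenerate inputs.** Reads are single merged sequences
spanning both anchors (paired-end merging is upstream of this package);
junctions lie at the cut; deletions do not extend past the amplicon ends.
Reads with no exact 10-nt anchor on one or both sides are UNALIGNABLE and
excluded from both numerator and denominator of every fraction; attrition
counts are reported per status. Anchor ties across equal-deletion
decompositions are broken toward the smaller `del_right`, which selects the
full microhomology overlap rather than a zero-overlap placement of the same
event.

## Exclusion filters

Two artifact filters run after calling; each evaluates its condition
independently and the final status is the highest-severity flag
(UNALIGNABLE > ambiguous > substitution artifact), making the outcome
order-independent.

- **Ambiguity**: the reconstructed junction region (5' end of the upstream
  anchor through 3' end of the downstream anchor) contains any non-ACGT
  symbol.
- **Substitution artifact**: a lone polymerase error during library
  amplification breaks the anchor next to the cut and is misattributed as a
  deletion plus an equal-length insertion. A call is flagged when
  `deletion_length > 0`, `len(insertion) == deletion_length` (net-zero
  event), and — under the identity alignment over the event interval —
  every mismatching read position lies 3–10 nt from the cut (inclusive, in
  reference coordinates, on either side) with both adjacent read positions
  matching the reference. Clean junction reads can never satisfy this:
  deletion-only events have no insertion, insertion-only events have no
  deletion. Single substitutions 1–2 nt from the cut are deliberately kept
  (they are indistinguishable from genuine junction-proximal NHEJ edits);
  substitutions beyond 10 nt fall outside the reconstructed junction and
  leave the call intact. A compound event that combines a real indel with a
  nearby amplification error is not flagged — a known limitation shared with
  the net-zero formulation.

## Signature discovery and classification

Deletion-only junctions (positive deletion, empty insertion) present in
either condition are tested for depletion in Polθ-null samples. Replicates
are pooled by summing counts (no dispersion modeling). For a junction with
count `a` of `T_wt` repair reads in wild type and `b` of `T_null` in the
null, the p-value is the exact conditional lower tail
`P(X ≤ b)`, `X ~ Hypergeometric(T_wt + T_null, a + b, T_null)` — the
one-sided Fisher test for depletion. One-sided is used because the
signature is defined by loss in the Polθ-deficient condition. The
Benjamini–Hochberg step-up rule at FDR `q = 0.10` (default) defines the
signature membership.

Classification is rule-based and signature-first: a junction in the
signature is TMEJ regardless of size (a small depleted deletion counts as
TMEJ, since the signature is defined by depletion, not anatomy); otherwise
NHEJ when total indel (deleted + inserted nt) `< 5` and microhomology
`< 2` nt; otherwise "other". Templated insertions therefore land in
"other": a deletion-only signature cannot contain insertion products, and
admitting them by anatomy would contaminate the NHEJ/other split. Class
fractions are over PASS repair reads (intact excluded); contributions are
signed percentage-point deltas against a named calibrator condition, so the
three class deltas of any condition sum to zero.

## Assay arithmetic

- **ΔΔCt**: `efficiency^−[(Ct_sig−Ct_ref) − (Ct_sig−Ct_ref)_calibrator]`
  with amplification efficiency fixed at 2.0 (perfect doubling; assay
  linearity is validated upstream, and standard-curve fitting is not
  re-implemented). Technical replicates are averaged on the Ct scale.
- **Spike-in normalization**: `(TMEJ/NHEJ) / (TMEJ/NHEJ)_calibrator`; the
  co-transfected NHEJ substrate cancels transfection-efficiency variation.
- **ddPCR**: `λ = −ln(1 − positives/total)` copies per droplet; wells
  measuring one quantity are merged by summing droplet counts before the
  transform (merged-well estimator) rather than averaging per-well λ.
- **Resection**: ssDNA fraction past a flank distance =
  `(λ_flank/λ_ref)_mock − (λ_flank/λ_ref)_ExoI`. Ratios are normalized per
  treatment before subtraction, making the estimate invariant to common
  rescaling of droplet counts. Negative differences arising from sampling
  noise are clamped to 0 and logged (true fractions are non-negative).
  `broken = 1 − λ_intact/λ_ref`; `deleted = 1 − λ_flank,mock/λ_ref`.

## The synthetic-data generator

`make_locus` builds a 200-nt amplicon (cut at the midpoint) with five
planted microhomology pairs of lengths 2–6 bp at fixed offsets within
±35 nt of the cut, boundary bases forced to differ so each repeat's length
is exact, and all 10-mers unique (exhaustive scan) so anchor matches are
unambiguous. Primers are the terminal 20-mers.

The default event mixture is 30% intact; conditional on repair the
composition is signature deletions 19%, NHEJ-class products 63% (+1
insertions 43%, small MH-less deletions 20%), and 18% other (templated
insertions 8%, long MH-less deletions 10%) — the repair spectrum of a
vehicle-treated wild-type population at a microhomology-rich cut site. The
Polθ-null condition multiplies MHD and TINS probabilities by
`polq_null_depletion` (default 0.25, a 4-fold loss) and re-channels the
lost mass onto the NHEJ classes proportionally, emulating compensation by
NHEJ. Templated insertions copy 5–30 nt from within ±50 nt of the cut,
direct or inverted. Every sampled event is validated to parse unambiguously
under the anchor model (no accidental smaller-deletion decomposition, and
the downstream anchor k-mer occurs only at the true junction); ambiguous
draws are resampled. On error-free reads the caller therefore recovers
truth labels exactly, by construction — which is what makes the round-trip
tests sharp.

Error injection: substitutions at 0.001/base (uniform across the read,
including barcode and primer, so demultiplex and trim failures occur at
realistic rates) and one IUPAC ambiguity base per read at 0.002/read.
Quality strings are constant; PCR-cycle amplification bias, chimeric reads,
and base-quality modeling are deliberately out of scope. Passing tests on
these reads demonstrate correctness of the reconstruction and statistics,
not robustness to real-instrument error profiles.

The ddPCR generator draws `positives ~ Binomial(n, 1 − e^−λ)` per well with
λ set from truth: reference λ 0.5 copies/droplet; ssDNA fractions
{>8 nt: 9.1%, >284 nt: 3.8%, >527 nt: 1.7%} (the measured 4-hour
post-break values this assay is designed around); two-strand deletion
fractions {2%, 1%, 0.5%}; broken fraction 30%; PstI-site ssDNA 6%. At
20,000 droplets a single simulated experiment resolves the 9.1%
break-proximal fraction well, but the distal fractions sit near the
single-experiment noise floor — as in practice, where several technical
replicates are pooled. A count-level mode (`simulate_count_tables`) draws
junction counts directly from a fixed key universe via multinomials; it is
the generative model the depletion test assumes and is used for
null-calibration studies (hundreds of replicate experiments in seconds).

## Problem sizes and numerical choices

Signature recovery runs at 10⁴ reads per condition (5 planted signature
keys at ~270 wild-type reads each give overwhelming per-key power at a
4-fold depletion); null FDR calibration uses 200 count-level experiments of
4,000 reads; caller/oracle agreement uses 500 random loci of 50–90 nt with
events of up to 9+9 nt deletion and 6 nt insertion, plus mutated and
unrelated reads. Monte-Carlo acceptance checks use 3-standard-error bounds.
Fractions are exact rational counts divided by integer totals; the only
floating-point tolerance in the pipeline is the BH comparison, delegated to
the standard step-up implementation.

## Known limitations

- Junctions lacking an exact 10-nt anchor on both sides are dropped rather
  than rescued by inexact alignment; heavily mutated or clipped reads are
  invisible.
- Single-locus analysis; no multi-locus meta-analysis or dispersion-aware
  differential model (replicates are pooled).
- The deletion-only signature excludes templated insertions from the TMEJ
  class by construction; TMEJ contribution estimates are accordingly
  conservative at TINS-rich loci.
- Sample assignment requires exact barcode match; no error correction.
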