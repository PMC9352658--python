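"""Quantification arithmetic for qPCR, ddPCR, gene-targeting, and survival assays.

qPCR signature products are quantified by delta-delta-Ct against a reference
amplicon distal to the cut and expressed as a fraction of a calibrator
condition. ddPCR droplet counts are converted to mean copies per droplet by
the Poisson occupancy estimator lambda = -ln(1 - positives/total); wells
measuring one quantity are merged by summing droplet counts before the
transform. End resection is read out as the ExoI-sensitive fraction of
flank-amplicon signal: single-strand-specific exonuclease degrades the 3'
ssDNA tails resection produces, so the mock-vs-ExoI drop in the flank/ref
ratio estimates the fraction of genomes resected past the flank distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

WELL_COLUMNS = ("sample_id", "amplicon", "treatment", "positives", "total")

#: Flank amplicon names at increasing distance from the cut, plus controls.
FLANK_AMPLICONS = ("flank_d8", "flank_d284", "flank_d527")


def relative_signature(
    ct_sig: float,
    ct_ref: float,
    calibrator_ct_sig: float,
    calibrator_ct_ref: float,
    efficiency: float = 2.0,
) -> float:
    """Delta-delta-Ct level of a signature amplicon as a fraction of calibrator.

    ``efficiency`` is the per-cycle amplification factor (2.0 = perfect
    doubling). Scale-free: adding a constant to every Ct leaves the result
    unchanged.
    """
    for ct in (ct_sig, ct_ref, calibrator_ct_sig, calibrator_ct_ref):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_sig - ct_ref) - (calibrator_ct_sig - calibrator_ct_ref)
    return efficiency ** (-ddct)


def spike_in_normalized_tmej(
    tmej_efficiency: float,
    nhej_efficiency: float,
    calibrator_tmej: float,
    calibrator_nhej: float,
) -> float:
    """Extrachromosomal TMEJ joining efficiency, spike-in normalized.

    The co-transfected NHEJ substrate controls for transfection efficiency;
    the TMEJ/NHEJ ratio is expressed as a fraction of the calibrator pair.
    """
    if nhej_efficiency <= 0 or calibrator_nhej <= 0:
        raise ValueError("spike-in (NHEJ) efficiency must be positive")
    if tmej_efficiency < 0 or calibrator_tmej <= 0:
        raise ValueError("TMEJ efficiencies must be positive")
    return (tmej_efficiency / nhej_efficiency) / (calibrator_tmej / calibrator_nhej)


def poisson_concentration(positives: int, total: int) -> float:
    """Mean template copies per droplet from droplet counts.

    lambda = -ln(1 - positives/total); saturation (all droplets positive)
    has no finite estimate and raises.
    """
    if total <= 0 or positives < 0 or positives > total:
        raise ValueError("need 0 <= positives <= total with total > 0")
    if positives == total:
        raise ValueError("all droplets positive: concentration not estimable (saturated)")
    return -math.log1p(-positives / total)


def _merged_lambda(wells: pd.DataFrame, amplicon: str, treatment: str) -> float:
    """Poisson estimate from all wells of one amplicon/treatment, merged by
    summing droplet counts (merged-well estimator)."""
    sel = wells[(wells["amplicon"] == amplicon) & (wells["treatment"] == treatment)]
    if sel.empty:
        raise ValueError(f"no wells for amplicon={amplicon!r} treatment={treatment!r}")
    return poisson_concentration(int(sel["positives"].sum()), int(sel["total"].sum()))


def _clamp_fraction(x: float, label: str) -> float:
    if x < 0.0:
        logger.info("clamping %s from %.4g to 0 (sampling noise)", label, x)
        return 0.0
    if x > 1.0:
        logger.info("clamping %s from %.4g to 1", label, x)
        return 1.0
    return x


def ssdna_fraction(
    wells: pd.DataFrame, flank_amplicon: str = "flank_d8", ref_amplicon: str = "ref1"
) -> float:
    """Fraction of genomes resected past the flank distance (ExoI-sensitive).

    Computed as (lambda_flank/lambda_ref)_mock - (lambda_flank/lambda_ref)_ExoI,
    clamped to [0, 1]. Matched mock and ExoI wells are required for both the
    flank and the reference amplicon.
    """
    ratio_mock = _merged_lambda(wells, flank_amplicon, "mock") / _merged_lambda(
        wells, ref_amplicon, "mock"
    )
    ratio_exo = _merged_lambda(wells, flank_amplicon, "exoI") / _merged_lambda(
        wells, ref_amplicon, "exoI"
    )
    return _clamp_fraction(ratio_mock - ratio_exo, f"ssDNA fraction ({flank_amplicon})")


def psti_resistant_fraction(
    wells: pd.DataFrame, flank_amplicon: str = "flank_psti", ref_amplicon: str = "ref1"
) -> float:
    """ssDNA fraction by the restriction-resistance variant of the assay.

    PstI cuts dsDNA only, so the flank signal surviving digestion is the
    resected (single-stranded) fraction at the enzyme site.
    """
    ratio = _merged_lambda(wells, flank_amplicon, "psti") / _merged_lambda(
        wells, ref_amplicon, "psti"
    )
    return _clamp_fraction(ratio, "PstI-resistant fraction")


def broken_and_deleted_fractions(
    wells: pd.DataFrame,
    intact_amplicon: str = "intact",
    flank_amplicon: str = "flank_d8",
    ref_amplicon: str = "ref1",
) -> tuple[float, float]:
    """Fractions of genomes with a broken cut site and with two-strand deletions.

    broken = 1 - lambda_intact/lambda_ref (the cut-spanning amplicon fails on
    any unrepaired or indel-bearing chromosome); deleted = 1 -
    lambda_flank_mock/lambda_ref (the mock-treated flank amplicon fails only
    when both strands are gone past the flank). Both clamped to [0, 1].
    """
    lam_ref = _merged_lambda(wells, ref_amplicon, "mock")
    broken = 1.0 - _merged_lambda(wells, intact_amplicon, "mock") / lam_ref
    deleted = 1.0 - _merged_lambda(wells, flank_amplicon, "mock") / lam_ref
    return (
        _clamp_fraction(broken, "broken fraction"),
        _clamp_fraction(deleted, f"deletion fraction ({flank_amplicon})"),
    )


@dataclass(frozen=True)
class ResectionProfile:
    """ssDNA fractions at increasing flank distances, plus end-state fractions."""

    ssdna_by_distance: dict
    broken_fraction: float
    deletion_fraction: float


def resection_profile(
    wells: pd.DataFrame,
    flank_amplicons: tuple = FLANK_AMPLICONS,
    intact_amplicon: str = "intact",
    ref_amplicon: str = "ref1",
) -> ResectionProfile:
    """ExoI-sensitivity profile across all flank distances present."""
    ssdna = {}
    for amp in flank_amplicons:
        if (wells["amplicon"] == amp).any():
            dist = int(amp.rsplit("_d", 1)[1])
            ssdna[dist] = ssdna_fraction(wells, amp, ref_amplicon)
    broken, deleted = broken_and_deleted_fractions(
        wells, intact_amplicon, flank_amplicons[0], ref_amplicon
    )
    return ResectionProfile(ssdna, broken, deleted)


def gene_targeting_fraction(sensitive_intensity: float, resistant_intensity: float) -> float:
    """Fraction of gene targeting from restriction-digest band intensities:
    sensitive / (sensitive + resistant)."""
    if sensitive_intensity < 0 or resistant_intensity < 0:
        raise ValueError("band intensities must be non-negative")
    total = sensitive_intensity + resistant_intensity
    if total == 0:
        raise ValueError("both band intensities are zero")
    return sensitive_intensity / total


def clonogenic_survival(
    colonies_treated: int,
    plated_treated: int,
    colonies_untreated: int,
    plated_untreated: int,
) -> float:
    """Surviving fraction: plating efficiency of treated over untreated cells."""
    if plated_treated <= 0 or plated_untreated <= 0:
        raise ValueError("plated counts must be positive")
    if colonies_untreated <= 0:
        raise ValueError("untreated plating efficiency is zero")
    return (colonies_treated / plated_treated) / (colonies_untreated / plated_untreated)


def summarize_replicates(
    values: pd.DataFrame, value_col: str, group_cols: Optional[list] = None
) -> pd.DataFrame:
    """Mean +/- SD over technical replicates (no dispersion modeling)."""
    if group_cols is None:
        group_cols = ["sample_id"]
    g = values.groupby(group_cols)[value_col]
    return g.agg(mean="mean", sd="std", n="count").reset_index()


def relative_signature_table(
    ct_table: pd.DataFrame,
    calibrator: str,
    signature_amplicon: str = "signature",
    ref_amplicon: str = "reference",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Delta-delta-Ct levels for every sample in a tidy Ct table.

    ``ct_table`` columns: sample_id, amplicon, ct (technical replicates are
    averaged on the Ct scale before the transform).
    """
    means = ct_table.groupby(["sample_id", "amplicon"])["ct"].mean().unstack()
    for col in (signature_amplicon, ref_amplicon):
        if col not in means.columns:
            raise ValueError(f"Ct table lacks amplicon {col!r}")
    if calibrator not in means.index:
        raise KeyError(f"calibrator sample {calibrator!r} not in Ct table")
    cal_sig = means.loc[calibrator, signature_amplicon]
    cal_ref = means.loc[calibrator, ref_amplicon]
    rows = [
        {
            "sample_id": sample,
            "relative_level": relative_signature(
                means.loc[sample, signature_amplicon],
                means.loc[sample, ref_amplicon],
                cal_sig,
                cal_ref,
                efficiency,
            ),
        }
        for sample in means.index
    ]
    return pd.DataFrame(rows)
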