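"""TMEJ signature discovery and repair-pathway classification.

The TMEJ deletion signature is defined operationally: deletion junctions
significantly depleted in Polq-null samples relative to wild type, at a
Benjamini-Hochberg false-discovery rate of 10%. Every other junction is
classified by the size/microhomology rule — small indels (total indel < 5 nt)
without microhomology (MH < 2 nt) are attributed to NHEJ; everything else is
"other". Pathway contributions across drug/genotype conditions are reported
as signed percentage-point differences relative to a calibrator condition
(vehicle-treated wild type).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .calling import CallStatus, JunctionCall, JunctionTable

#: Classification thresholds: indel < 5 nt and MH < 2 nt define NHEJ.
NHEJ_MAX_INDEL = 5
NHEJ_MAX_MH = 2

DEFAULT_FDR = 0.10

TMEJ, NHEJ, OTHER = "TMEJ", "NHEJ", "OTHER"


def _pool(tables: Union[JunctionTable, Sequence[JunctionTable]]) -> tuple[pd.DataFrame, int]:
    """Sum junction counts and repair totals across replicate tables."""
    if isinstance(tables, JunctionTable):
        tables = [tables]
    frames = [t.df for t in tables if not t.df.empty]
    total = sum(t.repair_total for t in tables)
    if not frames:
        return pd.DataFrame(columns=list(JunctionTable.COLUMNS)), total
    cat = pd.concat(frames, ignore_index=True)
    meta_cols = ["junction_key", "del_left", "del_right", "deletion_length", "insertion", "mh_length"]
    pooled = cat.groupby(meta_cols, as_index=False, sort=False)["count"].sum()
    return pooled, total


def test_depletion(
    wt: Union[JunctionTable, Sequence[JunctionTable]],
    polq_null: Union[JunctionTable, Sequence[JunctionTable]],
) -> pd.DataFrame:
    """One-sided exact depletion test per deletion junction.

    Replicates are pooled; for each deletion-only junction (positive deletion,
    no insertion) present in either condition, the p-value is the exact
    hypergeometric lower tail for the junction's count in the Polq-null
    condition, conditioning on the margins of the 2x2 table
    (junction vs. all-other-repair, WT vs. null).
    """
    wt_df, wt_total = _pool(wt)
    null_df, null_total = _pool(polq_null)
    if wt_total <= 0 or null_total <= 0:
        raise ValueError("both conditions need repair_total > 0")

    meta_cols = ["junction_key", "del_left", "del_right", "deletion_length", "insertion", "mh_length"]
    merged = pd.merge(
        wt_df.rename(columns={"count": "count_wt"}),
        null_df.rename(columns={"count": "count_polq_null"}),
        on=meta_cols,
        how="outer",
    ).fillna({"count_wt": 0, "count_polq_null": 0})
    merged[["count_wt", "count_polq_null"]] = merged[["count_wt", "count_polq_null"]].astype(int)

    deletions = merged[
        (merged["deletion_length"] > 0) & (merged["insertion"] == "")
    ].reset_index(drop=True)

    a = deletions["count_wt"].to_numpy()
    b = deletions["count_polq_null"].to_numpy()
    # P(X <= b) for X ~ Hypergeom(population wt_total+null_total,
    # successes a+b, draws null_total): the exact conditional lower tail.
    pvals = hypergeom.cdf(b, wt_total + null_total, a + b, null_total)
    deletions["p_value"] = pvals
    deletions["total_wt"] = wt_total
    deletions["total_polq_null"] = null_total
    return deletions


def benjamini_hochberg(p_values: Iterable[float], fdr: float = DEFAULT_FDR) -> np.ndarray:
    """Step-up BH rule: reject all p(i) with i <= max{k : p(k) <= k*q/m}.

    Returns a boolean array aligned with the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, _, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return rejected


@dataclass
class SignatureSet:
    """BH-derived set of Polq-depleted deletion junctions.

    ``table`` carries one row per tested deletion junction with counts,
    p-value, BH rank at the threshold, and the rejection flag; ``members``
    is the set of rejected junction keys (the TMEJ deletion signature).
    """

    members: frozenset
    table: pd.DataFrame
    fdr: float = DEFAULT_FDR

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# tmejkit TMEJ deletion signature\n")
            fh.write(f"# fdr={self.fdr}\n")
            self.table.assign(
                insertion=self.table["insertion"].replace("", ".")
            ).to_csv(fh, sep="\t", index=False)


def build_signature(
    wt: Union[JunctionTable, Sequence[JunctionTable]],
    polq_null: Union[JunctionTable, Sequence[JunctionTable]],
    fdr: float = DEFAULT_FDR,
) -> SignatureSet:
    """Identify the TMEJ deletion signature by differential depletion."""
    table = test_depletion(wt, polq_null)
    if table.empty:
        return SignatureSet(frozenset(), table.assign(rejected=[], bh_threshold_rank=[]), fdr)
    rejected = benjamini_hochberg(table["p_value"].to_numpy(), fdr)
    table = table.copy()
    table["rejected"] = rejected
    order = table["p_value"].rank(method="first").astype(int)
    table["bh_threshold_rank"] = int(order[rejected].max()) if rejected.any() else 0
    members = frozenset(table.loc[table["rejected"], "junction_key"])
    return SignatureSet(members=members, table=table, fdr=fdr)


def classify_junction(
    call: JunctionCall,
    signature: SignatureSet,
    max_indel: int = NHEJ_MAX_INDEL,
    max_mh: int = NHEJ_MAX_MH,
) -> str:
    """Classify one repair junction as TMEJ, NHEJ, or OTHER.

    Signature membership takes precedence (the TMEJ set is defined by
    depletion, not size); the NHEJ rule is total indel < ``max_indel`` and
    microhomology < ``max_mh``.
    """
    if call.status is CallStatus.INTACT:
        raise ValueError("intact reads are not repair products")
    return _classify(
        call.junction_key, call.indel_length, call.microhomology_length, signature, max_indel, max_mh
    )


def _classify(key, indel_length, mh_length, signature, max_indel, max_mh) -> str:
    if key in signature.members:
        return TMEJ
    if indel_length < max_indel and mh_length < max_mh:
        return NHEJ
    return OTHER


def classify_table(
    table: JunctionTable,
    signature: SignatureSet,
    max_indel: int = NHEJ_MAX_INDEL,
    max_mh: int = NHEJ_MAX_MH,
) -> pd.DataFrame:
    """Return the junction table with a pathway class column added."""
    df = table.df.copy()
    if df.empty:
        df["pathway"] = pd.Series(dtype=str)
        return df
    df["pathway"] = [
        _classify(
            row.junction_key,
            row.deletion_length + len(row.insertion),
            row.mh_length,
            signature,
            max_indel,
            max_mh,
        )
        for row in df.itertuples()
    ]
    return df


@dataclass(frozen=True)
class PathwayFractions:
    """Class fractions of all PASS repair reads for one sample."""

    sample_id: str
    frac_tmej: float
    frac_nhej: float
    frac_other: float

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "frac_tmej": self.frac_tmej,
            "frac_nhej": self.frac_nhej,
            "frac_other": self.frac_other,
        }


def pathway_fractions(
    table: JunctionTable,
    signature: SignatureSet,
    max_indel: int = NHEJ_MAX_INDEL,
    max_mh: int = NHEJ_MAX_MH,
) -> PathwayFractions:
    """Fraction of repair reads in each pathway class; fractions sum to 1."""
    if table.repair_total <= 0:
        raise ValueError(f"sample {table.sample_id!r} has no repair reads")
    df = classify_table(table, signature, max_indel, max_mh)
    sums = df.groupby("pathway")["count"].sum()
    total = table.repair_total
    return PathwayFractions(
        sample_id=table.sample_id,
        frac_tmej=float(sums.get(TMEJ, 0)) / total,
        frac_nhej=float(sums.get(NHEJ, 0)) / total,
        frac_other=float(sums.get(OTHER, 0)) / total,
    )


def tmej_contribution(
    fractions: Mapping[str, PathwayFractions], calibrator: str
) -> pd.DataFrame:
    """Signed percentage-point deltas of each class relative to the calibrator.

    The calibrator is the vehicle-treated wild-type condition; a negative
    TMEJ delta in a Polq-deficient condition estimates the contribution of
    Pol theta to repair under the subtraction scheme.
    """
    if calibrator not in fractions:
        raise KeyError(f"calibrator sample {calibrator!r} not present")
    cal = fractions[calibrator]
    rows = []
    for sample_id, f in fractions.items():
        rows.append(
            {
                "sample_id": sample_id,
                "delta_tmej_pts": 100.0 * (f.frac_tmej - cal.frac_tmej),
                "delta_nhej_pts": 100.0 * (f.frac_nhej - cal.frac_nhej),
                "delta_other_pts": 100.0 * (f.frac_other - cal.frac_other),
            }
        )
    return pd.DataFrame(rows)
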