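"""Screen statistics to model-ready labels.

Guides with FDR-adjusted p below 0.05 are labelled significant, above 0.2
insignificant, and the gray zone in between is excluded from both training
and testing to avoid borderline mislabeling. The cell-fitness task
additionally drops guides with total counts below 125, where power to
detect an effect is poor. Promoter/enhancer classification uses an
explicit TSS-distance rule (default +/- 2 kb, closed interval).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIGNIFICANT = "significant"
INSIGNIFICANT = "insignificant"
EXCLUDED = "excluded"

DEFAULT_SIG_THRESH = 0.05
DEFAULT_INSIG_THRESH = 0.2
DEFAULT_MIN_TOTAL_COUNTS = 125
DEFAULT_PROMOTER_WINDOW = 2000


def derive_labels(
    outcomes: pd.DataFrame,
    sig_thresh: float = DEFAULT_SIG_THRESH,
    insig_thresh: float = DEFAULT_INSIG_THRESH,
) -> pd.DataFrame:
    """Attach the three-way label from FDR-adjusted p-values.

    adj_p < sig_thresh -> significant; adj_p > insig_thresh ->
    insignificant; the closed gray zone [sig_thresh, insig_thresh] ->
    excluded. The partition is exhaustive over adj_p in [0, 1].
    """
    p = outcomes["adj_p"].to_numpy(dtype=float)
    if np.isnan(p).any():
        raise ValueError("adj_p contains missing values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("adj_p outside [0, 1]")
    label = np.where(p < sig_thresh, SIGNIFICANT, np.where(p > insig_thresh, INSIGNIFICANT, EXCLUDED))
    out = outcomes.copy()
    out["label"] = label
    return out


def filter_low_count(
    outcomes: pd.DataFrame, min_total: int = DEFAULT_MIN_TOTAL_COUNTS
) -> pd.DataFrame:
    """Drop guides with total counts strictly below ``min_total``.

    Applied to the cell-fitness task, where low-count guides lack the
    power for their adjusted p-values to be meaningful. Lowering
    ``min_total`` never removes a previously retained row.
    """
    keep = outcomes["total_counts"] >= min_total
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_low_count: removed %d of %d guides (< %d total counts)",
                    removed, len(outcomes), min_total)
    return outcomes[keep].copy()


def training_rows(labeled: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for training/testing: gray-zone (excluded) guides dropped."""
    return labeled[labeled["label"] != EXCLUDED].copy()


def classify_region(
    records: pd.DataFrame,
    tss_table: pd.DataFrame,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> pd.Series:
    """Classify guides as promoter or enhancer by distance to the nearest TSS.

    A guide whose midpoint lies within ``promoter_window`` bp (closed
    interval) of any TSS on the same chromosome is a promoter guide; all
    others are enhancer guides. ``tss_table`` needs ``chrom`` and ``pos``
    columns (e.g. read from a BED of TSSs using the interval start).
    Chromosomes absent from the TSS table yield enhancer with a warning.
    """
    if len(tss_table) == 0:
        raise ValueError("TSS table is empty")
    tss_by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in tss_table.groupby("chrom")}
    mid = ((records["start"].to_numpy() + records["end"].to_numpy()) // 2).astype(np.int64)
    out = np.empty(len(records), dtype=object)
    missing_chroms = set()
    for i, (chrom, m) in enumerate(zip(records["chrom"], mid)):
        positions = tss_by_chrom.get(chrom)
        if positions is None:
            missing_chroms.add(chrom)
            out[i] = "enhancer"
            continue
        j = np.searchsorted(positions, m)
        dist = min(
            abs(m - positions[j - 1]) if j > 0 else np.inf,
            abs(positions[j] - m) if j < len(positions) else np.inf,
        )
        out[i] = "promoter" if dist <= promoter_window else "enhancer"
    if missing_chroms:
        warnings.warn(
            f"chromosomes absent from TSS table treated as enhancer: {sorted(missing_chroms)}",
            stacklevel=2,
        )
    return pd.Series(out, index=records.index, name="region_class")


def read_tss_bed(path) -> pd.DataFrame:
    """Read TSS positions from a BED file (interval start is the TSS)."""
    tss = pd.read_csv(path, sep="\t", header=None, comment="#")
    return pd.DataFrame({"chrom": tss[0], "pos": tss[1].astype(np.int64)})


def select_best_pair(pairs: pd.DataFrame) -> pd.DataFrame:
    """Keep the most significant gRNA-gene pair per guide.

    Per guide: minimum adj_p wins; ties broken by largest |log2FC|, then
    lexicographically smallest gene_id, so the result is deterministic.
    Exactly one row per guide survives.
    """
    for col in ("guide_id", "gene_id", "adj_p"):
        if col not in pairs.columns:
            raise ValueError(f"pair table missing column {col!r}")
    if len(pairs) == 0:
        warnings.warn("pair table is empty; no guides selected", stacklevel=2)
        return pairs.copy()
    df = pairs.copy()
    df["_abs_lfc"] = df["log2FC"].abs() if "log2FC" in df.columns else 0.0
    df = df.sort_values(
        ["guide_id", "adj_p", "_abs_lfc", "gene_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = df.groupby("guide_id", sort=False).head(1).drop(columns="_abs_lfc")
    return best.reset_index(drop=True)
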