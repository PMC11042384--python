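"""Functional-annotation features per guide.

Covers 1-kb tile read counting from interval files, the imputation rules
used by the models (zero imputation for every feature except the ploidy
covariate, which gets mode imputation), winsorization of continuous
features at the 95th percentile, and an optional nearest-neighbour
stand-in for the gRNA-DNA hybridization free energy dG_H.

Coordinates are 0-based half-open internally; BED input follows the BED
standard. dG_B (overall binding energy including the Cas9 contribution)
has no closed-form definition here and is accepted only as a precomputed
input column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence import validate_protospacer

#: Default tile width in bp for read counting.
DEFAULT_TILE_WIDTH = 1000

#: Feature imputed by mode rather than zero.
MODE_IMPUTED = ("ploidyZhou",)

#: Nearest-neighbour free-energy parameters (kcal/mol) for RNA/DNA hybrid
#: duplexes at 37 degrees C, keyed by the DNA-strand dinucleotide step read
#: 5'->3' (Sugimoto et al. 1995). An optional stand-in for precomputed dG_H
#: columns; users may supply any other table.
SUGIMOTO_1995_RNA_DNA: dict[str, float] = {
    "AA": -1.0, "AC": -2.1, "AG": -1.8, "AT": -0.9,
    "CA": -0.9, "CC": -2.1, "CG": -1.7, "CT": -0.9,
    "GA": -1.3, "GC": -2.7, "GG": -2.9, "GT": -1.1,
    "TA": -0.6, "TC": -1.5, "TG": -1.6, "TT": -0.2,
}


def read_bed_intervals(path) -> pd.DataFrame:
    """Read a BED3/BED6 file of read intervals.

    Returns a DataFrame with ``chrom``, ``start``, ``end`` and (when
    present) ``strand``. Malformed lines are rejected with their 1-based
    line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected >=3 BED fields, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ValueError(f"line {lineno}: require 0 <= start < end, got {start}..{end}")
            strand = parts[5] if len(parts) >= 6 else "+"
            rows.append((chrom, start, end, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def count_reads_in_tiles(
    intervals: pd.DataFrame,
    tile_width: int = DEFAULT_TILE_WIDTH,
    exclude_chroms: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Assign each read to the genome tile containing its 5' end.

    Tiles are non-overlapping half-open windows ``[i*w, (i+1)*w)`` per
    chromosome. A read on the minus strand has its 5' end at ``end - 1``;
    otherwise at ``start``. Reads on ``exclude_chroms`` are dropped.

    Returns a DataFrame with columns ``chrom``, ``tile_start``, ``count``,
    sorted by (chrom, tile_start). Total counts equal the number of input
    reads minus the excluded ones.
    """
    if tile_width <= 0:
        raise ValueError("tile_width must be positive")
    df = intervals
    if (df["start"] >= df["end"]).any():
        bad = int((df["start"] >= df["end"]).idxmax())
        raise ValueError(f"interval at row {bad}: start >= end")
    if exclude_chroms:
        df = df[~df["chrom"].isin(exclude_chroms)]
    strand = df["strand"] if "strand" in df.columns else "+"
    five_prime = np.where(np.asarray(strand) == "-", df["end"].to_numpy() - 1, df["start"].to_numpy())
    tile_start = (five_prime // tile_width) * tile_width
    out = (
        pd.DataFrame({"chrom": df["chrom"].to_numpy(), "tile_start": tile_start})
        .groupby(["chrom", "tile_start"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def impute_missing(
    table: pd.DataFrame, mode_columns: tuple[str, ...] = MODE_IMPUTED
) -> pd.DataFrame:
    """Fill missing annotation values: zeros everywhere except mode columns.

    ``mode_columns`` (the ploidy covariate by default) receive the mode of
    their observed values; ties take the smallest modal value. Observed
    entries are never altered. A mode column with no observed value at all
    is an error (its mode is undefined).
    """
    out = table.copy()
    for col in out.columns:
        if not out[col].isna().any():
            continue
        if col in mode_columns:
            observed = out[col].dropna()
            if observed.empty:
                raise ValueError(f"column {col!r} is entirely missing; mode undefined")
            out[col] = out[col].fillna(observed.mode().iloc[0])
        else:
            out[col] = out[col].fillna(0.0)
    return out


@dataclass(frozen=True)
class WinsorCaps:
    """Per-feature upper caps learned on a fit subset (e.g. training folds)."""

    caps: pd.Series
    quantile: float


def fit_winsor_caps(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    quantile: float = 0.95,
    fit_index=None,
) -> WinsorCaps:
    """Learn the per-feature winsorization caps (default 95th percentile).

    ``fit_index`` restricts the rows used to compute the caps so that caps
    learned on training folds can be reused on held-out data.
    """
    sub = table if fit_index is None else table.loc[fit_index]
    if len(sub) == 0:
        raise ValueError("fit set for winsorization is empty")
    cols = list(table.columns) if columns is None else columns
    caps = sub[cols].quantile(quantile)
    return WinsorCaps(caps=caps, quantile=quantile)


def apply_winsor_caps(table: pd.DataFrame, caps: WinsorCaps) -> pd.DataFrame:
    """Cap values above the learned thresholds. Idempotent; never raises values."""
    out = table.copy()
    for col, cap in caps.caps.items():
        if col in out.columns and not np.isnan(cap):
            out[col] = out[col].clip(upper=cap)
    return out


def winsorize_features(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    quantile: float = 0.95,
    fit_index=None,
) -> tuple[pd.DataFrame, WinsorCaps]:
    """Fit caps on ``fit_index`` rows (all rows if None) and apply to all rows."""
    caps = fit_winsor_caps(table, columns=columns, quantile=quantile, fit_index=fit_index)
    return apply_winsor_caps(table, caps), caps


def nn_hybridization_energy(
    sequence: str, params: dict[str, float] | None = None
) -> float:
    """Nearest-neighbour estimate of the gRNA-DNA hybridization energy dG_H.

    Sums stacking free energies over the 19 dinucleotide steps of the
    protospacer using the supplied parameter table (kcal/mol). With no
    table the feature is declared missing (NaN) rather than fabricated;
    precomputed dG_H / dG_B columns always take precedence when available.
    """
    seq = validate_protospacer(sequence)
    if params is None:
        return float("nan")
    missing = [seq[i : i + 2] for i in range(19) if seq[i : i + 2] not in params]
    if missing:
        raise ValueError(f"parameter table lacks steps: {sorted(set(missing))}")
    return float(sum(params[seq[i : i + 2]] for i in range(19)))


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read an annotation table (guide_id + named numeric columns, empty cell = missing)."""
    df = pd.read_csv(path, sep="\t", dtype={"guide_id": str})
    if "guide_id" not in df.columns:
        raise ValueError("annotation table must have a guide_id column")
    return df.set_index("guide_id")


def check_proportion_column(table: pd.DataFrame, column: str = "OGEE_prop_essential") -> None:
    """Validate that a proportion-valued column stays within [0, 1] where observed."""
    if column not in table.columns:
        return
    vals = table[column].dropna()
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError(f"{column} has values outside [0, 1]")


def warn_if_unnormalized(table: pd.DataFrame, threshold: float = 1e4) -> None:
    """Emit a warning when raw-count-scale annotation columns look untransformed."""
    big = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c]) and table[c].max() > threshold]
    if big:
        warnings.warn(f"columns look like raw counts (max > {threshold:g}): {big}; consider log1p", stacklevel=2)
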