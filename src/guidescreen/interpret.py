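"""Additive feature attributions for trained models.

Tabular (gradient-boosted) models are explained with exact TreeSHAP as
implemented inside XGBoost (``pred_contribs``): attributions per instance
sum to the margin prediction, with the booster's expected value in the
bias term. Sequence models are explained with an expected-gradients path
integral — the average over background references of the integrated
gradient along the straight path from reference to instance — computed on
the network's linear output and refined adaptively until per-instance
completeness (attributions sum to prediction minus background
expectation) holds within tolerance. Position-resolved summaries are
4 x 20 base-by-position matrices with across-fold mean and standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb

from .cnn import CnnModel
from .sequence import BASES, PROTOSPACER_LENGTH


@dataclass
class ShapSummary:
    """Per-feature attribution summary for one model / fold."""

    mean_abs: pd.Series  # feature -> mean |attribution|
    attributions: pd.DataFrame  # instances x features, signed
    expected_value: float
    predictions: np.ndarray

    def completeness_error(self) -> np.ndarray:
        """|sum of attributions + expected value - prediction| per instance."""
        total = self.attributions.sum(axis=1).to_numpy() + self.expected_value
        return np.abs(total - self.predictions)


def shap_tabular(booster: xgb.Booster, background: pd.DataFrame,
                 explain: pd.DataFrame) -> ShapSummary:
    """Exact TreeSHAP attributions for a gradient-boosted model.

    The tree-path-dependent algorithm conditions on the cover statistics
    stored in the trees, so ``background`` serves only as a non-emptiness
    contract and manifest check. Attributions are on the margin (log-odds
    or raw) scale.
    """
    if len(background) == 0:
        raise ValueError("background set is empty")
    if list(background.columns) != list(explain.columns):
        raise ValueError("background/explain feature mismatch")
    expected = booster.feature_names
    if expected is not None and list(explain.columns) != list(expected):
        raise ValueError(f"feature mismatch with model manifest: {expected}")
    contribs = booster.predict(xgb.DMatrix(explain), pred_contribs=True)
    margin = booster.predict(xgb.DMatrix(explain), output_margin=True)
    attr = pd.DataFrame(contribs[:, :-1], columns=list(explain.columns), index=explain.index)
    return ShapSummary(
        mean_abs=attr.abs().mean(axis=0),
        attributions=attr,
        expected_value=float(contribs[0, -1]),
        predictions=np.asarray(margin, dtype=float),
    )


def _path_integral(model: CnnModel, x_seq, x_ann, b_seq, b_ann, steps: int,
                   chunk: int = 2048):
    """Midpoint-rule integrated gradients from one reference to each instance.

    All step points for all instances are evaluated in chunked batches so
    the cost is a handful of forward/backward passes rather than one per
    quadrature node.
    """
    n = len(x_seq)
    t = ((np.arange(steps) + 0.5) / steps)[:, None, None, None]
    d_seq = x_seq - b_seq
    pts_seq = (b_seq[None] + t * d_seq[None]).reshape(steps * n, *x_seq.shape[1:])
    if x_ann is not None:
        d_ann = x_ann - b_ann
        pts_ann = (b_ann[None] + t[:, :, 0, 0, None] * d_ann[None]).reshape(steps * n, -1)
    g_seq = np.empty_like(pts_seq)
    g_ann = np.empty_like(pts_ann) if x_ann is not None else None
    for lo in range(0, steps * n, chunk):
        hi = min(lo + chunk, steps * n)
        gs_, ga_ = model.input_gradient(pts_seq[lo:hi],
                                        None if x_ann is None else pts_ann[lo:hi])
        g_seq[lo:hi] = gs_
        if x_ann is not None:
            g_ann[lo:hi] = ga_
    attr_seq = g_seq.reshape(steps, n, *x_seq.shape[1:]).mean(axis=0) * d_seq
    attr_ann = None
    if x_ann is not None:
        attr_ann = g_ann.reshape(steps, n, -1).mean(axis=0) * d_ann
    return attr_seq, attr_ann


def expected_gradients(
    model: CnnModel,
    background: tuple[np.ndarray, np.ndarray | None],
    explain: tuple[np.ndarray, np.ndarray | None],
    n_background: int = 100,
    tol: float = 1e-3,
    seed: int = 0,
    max_steps: int = 4096,
) -> dict:
    """Path-integral attributions for the CNN on its linear-output scale.

    Averages integrated gradients over ``n_background`` references sampled
    from the background set with a fixed seed. The number of integration
    steps doubles until every instance satisfies completeness —
    attributions sum to f(x) minus the mean background output — within
    ``tol`` (the network is piecewise linear up to the output, so the
    midpoint rule converges quickly).

    Returns a dict with ``seq`` (N x 4 x 20), ``ann`` (N x A or None),
    ``expected_value`` and ``predictions``.
    """
    b_seq, b_ann = background
    x_seq, x_ann = explain
    if len(b_seq) == 0:
        raise ValueError("background set is empty")
    if (x_ann is None) != (b_ann is None):
        raise ValueError("background/explain annotation mismatch")
    rng = np.random.default_rng(seed)
    take = rng.choice(len(b_seq), size=min(n_background, len(b_seq)), replace=False)
    b_seq = np.asarray(b_seq, dtype=float)[take]
    b_ann = None if b_ann is None else np.asarray(b_ann, dtype=float)[take]
    x_seq = np.asarray(x_seq, dtype=float)
    x_ann = None if x_ann is None else np.asarray(x_ann, dtype=float)

    preds = model.forward(x_seq, x_ann, rng=None)
    base = float(np.mean(model.forward(b_seq, b_ann, rng=None)))

    steps = 128
    while True:
        seq_total = np.zeros_like(x_seq)
        ann_total = None if x_ann is None else np.zeros_like(x_ann)
        for j in range(len(b_seq)):
            a_seq, a_ann = _path_integral(
                model, x_seq, x_ann,
                b_seq[j][None, :, :], None if b_ann is None else b_ann[j][None, :], steps,
            )
            seq_total += a_seq
            if x_ann is not None:
                ann_total += a_ann
        seq_total /= len(b_seq)
        if x_ann is not None:
            ann_total /= len(b_seq)
        total = seq_total.sum(axis=(1, 2)) + (0.0 if x_ann is None else ann_total.sum(axis=1))
        err = np.abs(total + base - preds)
        if err.max() <= tol or steps >= max_steps:
            break
        steps *= 2
    return {"seq": seq_total, "ann": ann_total, "expected_value": base,
            "predictions": preds, "steps": steps, "completeness_error": err}


def shap_sequence_positions(
    per_fold: list[dict],
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Aggregate per-fold sequence attributions into a 4 x 20 summary.

    ``per_fold`` holds :func:`expected_gradients` results (one per fold).
    Each fold's matrix is the mean attribution over its explain set,
    per (base, position). Positive values push the prediction up.

    Returns (across-fold mean, across-fold standard deviation, per-fold
    matrices).
    """
    mats = [np.asarray(r["seq"]).mean(axis=0) for r in per_fold]
    for m in mats:
        if m.shape != (len(BASES), PROTOSPACER_LENGTH):
            raise ValueError(f"attribution matrix must be 4 x 20, got {m.shape}")
    stack = np.stack(mats)
    return stack.mean(axis=0), stack.std(axis=0, ddof=0), mats


def attribution_matrix_frame(matrix: np.ndarray) -> pd.DataFrame:
    """4 x 20 matrix as a DataFrame (base rows, 1-based position columns)."""
    return pd.DataFrame(matrix, index=list(BASES),
                        columns=[f"pos_{p}" for p in range(1, PROTOSPACER_LENGTH + 1)])


def select_top_annotations(
    fold_summaries: list[ShapSummary],
    annotation_features: list[str],
    m: int = 6,
) -> list[str]:
    """Rank annotation features by across-fold mean of mean |attribution|.

    Used to build the reduced "top six annotations" model inputs. The
    summaries must come from training folds only so that the selection is
    frozen before any test-fold evaluation. Ties break lexicographically;
    if fewer than ``m`` annotation features exist, all are returned with a
    warning.
    """
    import warnings

    table = pd.DataFrame({i: s.mean_abs for i, s in enumerate(fold_summaries)})
    present = [f for f in annotation_features if f in table.index]
    scores = table.loc[present].mean(axis=1).to_frame("score")
    # lexicographic tie-break: stable sort by name first, then by score
    ranked = scores.loc[sorted(scores.index)].sort_values("score", ascending=False, kind="mergesort")
    if len(ranked) < m:
        warnings.warn(f"only {len(ranked)} annotation features available (< {m}); returning all",
                      stacklevel=2)
    return list(ranked.index[:m])


def plot_position_attributions(mean: np.ndarray, sd: np.ndarray | None, path) -> None:
    """Bar plot of per-position mean attribution (summed over bases).

    Error bars show one across-fold standard deviation when ``sd`` is
    given. Written to ``path`` (any matplotlib-supported format).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    positions = np.arange(1, PROTOSPACER_LENGTH + 1)
    per_pos = np.asarray(mean).sum(axis=0)
    err = None if sd is None else np.sqrt((np.asarray(sd) ** 2).sum(axis=0))
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(positions, per_pos, yerr=err, capsize=2, color="#4c72b0")
    ax.set_xlabel("protospacer position (5' to 3')")
    ax.set_ylabel("mean attribution")
    ax.set_xticks(positions)
    ax.axhline(0, color="black", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_feature_importance(summary: ShapSummary, path, top: int = 15) -> None:
    """Horizontal bar plot of the top features by mean |attribution|."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = summary.mean_abs.nlargest(top)[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(vals) + 1))
    ax.barh(vals.index, vals.to_numpy(), color="#55a868")
    ax.set_xlabel("mean |attribution|")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
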