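"""Convenience pipelines wiring the modules into end-to-end runs.

These helpers reproduce the standard preprocessing order: derive labels,
apply the count filter, drop gray-zone guides, featurize sequences, impute
and winsorize annotations (caps fit on training folds only), standardize,
and split by DHS-grouped folds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import labels as lab
from .annotations import impute_missing, winsorize_features
from .evaluation import make_grouped_folds
from .sequence import featurize_library
from .simulate import SimConfig, simulate_library, simulate_outcomes


def prepare_fitness_dataset(config: SimConfig, test_fold: int = 1, k: int = 5):
    """Simulate a screen and assemble model-ready fitness-task matrices.

    Returns a dict with the raw tables plus aligned arrays: ``one_hot``,
    ``tabular`` (BoW + standardized annotations), integer row indices
    ``tr``/``te`` into the library order, and labels ``y_tr``/``y_te``.
    The held-out set is one DHS-grouped fold, so no DHS appears on both
    sides. Winsorization caps and standardization moments are fit on the
    training side only.
    """
    records, ann, truth = simulate_library(config)
    outcomes = simulate_outcomes(records, truth, config)

    fitness = lab.derive_labels(outcomes["fitness"])
    fitness = lab.filter_low_count(fitness)
    usable = lab.training_rows(fitness).merge(records[["guide_id", "dhs_id"]], on="guide_id")

    folds = make_grouped_folds(usable, key="dhs_id", k=k, seed=config.seed)
    test_ids = set(folds.fold_ids(test_fold))
    usable["is_test"] = usable["guide_id"].isin(test_ids)

    one_hot, bow = featurize_library(records)
    ann_imputed = impute_missing(ann)
    train_ids = usable.loc[~usable["is_test"], "guide_id"]
    ann_wins, caps = winsorize_features(ann_imputed, fit_index=train_ids)
    mu, sd = ann_wins.loc[train_ids].mean(), ann_wins.loc[train_ids].std()
    ann_std = (ann_wins - mu) / sd

    row_of = pd.Series(np.arange(len(records)), index=pd.Index(records["guide_id"]))
    tr = row_of[usable.loc[~usable["is_test"], "guide_id"]].to_numpy()
    te = row_of[usable.loc[usable["is_test"], "guide_id"]].to_numpy()
    y = (usable.set_index("guide_id")["label"] == "significant").astype(float)

    return {
        "config": config,
        "records": records,
        "annotations_raw": ann,
        "annotations": ann_std,
        "winsor_caps": caps,
        "truth": truth,
        "outcomes": outcomes,
        "fitness_labels": fitness,
        "usable": usable,
        "one_hot": one_hot,
        "bow": bow,
        "tabular": pd.concat([bow, ann_std], axis=1),
        "tr": tr,
        "te": te,
        "y_tr": y[usable.loc[~usable["is_test"], "guide_id"]].to_numpy(),
        "y_te": y[usable.loc[usable["is_test"], "guide_id"]].to_numpy(),
    }


def prepare_wt_count_dataset(config: SimConfig, log1p: bool = True, standardize: bool = True):
    """Simulate a screen and return the wild-type-abundance regression target.

    The target is the mean of the four wild-type replicate counts,
    optionally log1p-transformed and standardized for stable optimization
    (rank metrics are unaffected).
    """
    records, ann, truth = simulate_library(config)
    outcomes = simulate_outcomes(records, truth, config)
    y = outcomes["wt_abundance"]["wt_mean_count"].to_numpy().astype(float)
    if log1p:
        y = np.log1p(y)
    if standardize:
        y = (y - y.mean()) / y.std()
    one_hot, bow = featurize_library(records)
    return {
        "records": records,
        "outcomes": outcomes,
        "truth": truth,
        "one_hot": one_hot,
        "bow": bow,
        "y": y,
    }
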