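"""Shared fixtures: a simulated screen and models trained on it.

The heavy artifacts (featurized library, trained CNN and XGBoost models)
are session-scoped so the recovery, interpretation and enrichment tests
share one training run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from guidescreen.boost import fit_xgb
from guidescreen.cnn import CnnSpec, TrainSpec, build_cnn, train_cnn
from guidescreen.simulate import SimConfig
from guidescreen.workflows import prepare_fitness_dataset

SEED = 20240917


@pytest.fixture(scope="session")
def screen():
    """Default planted-signal screen: 1,200 DHSs x 10 guides, featurized.

    Train/test split is DHS-grouped (fold 1 held out) so no DHS leaks
    between the sets.
    """
    return prepare_fitness_dataset(SimConfig(n_dhs=1200, guides_per_dhs=10, seed=SEED))


@pytest.fixture(scope="session")
def fitness_models(screen):
    """CNN and XGBoost fitness models trained on the shared screen."""
    tr = screen["tr"]
    oh, ann = screen["one_hot"], screen["annotations"].to_numpy()
    y_tr = screen["y_tr"]

    n_valid = len(tr) // 10
    rng = np.random.default_rng(SEED)
    order = rng.permutation(len(tr))
    va_rows, tr_rows = tr[order[:n_valid]], tr[order[n_valid:]]
    y_of = dict(zip(tr, y_tr))
    y_va = np.array([y_of[i] for i in va_rows])
    y_fit = np.array([y_of[i] for i in tr_rows])

    cnn = build_cnn(CnnSpec(), ann.shape[1], seed=SEED)
    train_cnn(
        cnn,
        (oh[tr_rows], ann[tr_rows], y_fit),
        (oh[va_rows], ann[va_rows], y_va),
        TrainSpec.for_task("fitness", seed=SEED),
    )
    booster = fit_xgb(screen["tabular"].iloc[tr], y_tr, "fitness", seed=SEED)
    return {"cnn": cnn, "xgb": booster}
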