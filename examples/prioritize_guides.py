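"""Rank guides within each DHS and test top-1 enrichment.

For DHSs with at least three significant guides, the guide with the
highest predicted probability is compared with its DHS neighbours on the
fraction of experimentally significant guides (adj_p < 0.05) and on
effect size (third quartile of |log2FC|). With informative predictions
the top-1 group should be strongly enriched.
"""

import pandas as pd

from guidescreen.boost import fit_xgb, predict_xgb
from guidescreen.evaluation import rank_within_dhs
from guidescreen.simulate import SimConfig
from guidescreen.workflows import prepare_fitness_dataset

data = prepare_fitness_dataset(SimConfig(n_dhs=400, guides_per_dhs=10, seed=5))
tr, te = data["tr"], data["te"]

booster = fit_xgb(data["tabular"].iloc[tr], data["y_tr"], task="fitness", seed=5)
te_ids = data["usable"].loc[data["usable"]["is_test"], "guide_id"].to_numpy()
preds = pd.DataFrame({"guide_id": te_ids,
                      "score": predict_xgb(booster, data["tabular"].iloc[te])})

outcomes = data["fitness_labels"].merge(
    data["records"][["guide_id", "dhs_id"]], on="guide_id")
outcomes = outcomes[outcomes["label"] != "excluded"]

table, stats = rank_within_dhs(preds, outcomes, min_sig=3, k=1)
print(f"DHSs considered (>= 3 significant guides): {stats['n_dhs']}")
print(f"top-1 guides significant:      {100 * stats['top_prop_sig']:.1f}%")
print(f"remaining guides significant:  {100 * stats['rest_prop_sig']:.1f}%")
print(f"Q3 |log2FC| top-1 vs rest:     {stats['top_q3_abs_log2fc']:.3f} vs "
      f"{stats['rest_q3_abs_log2fc']:.3f}")
print(f"Wilcoxon p (adj_p lower in top-1):    {stats['wilcoxon_p_adj_p']:.2e}")
print(f"Wilcoxon p (|log2FC| higher in top-1): {stats['wilcoxon_p_abs_log2fc']:.2e}")
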