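"""Synthetic CRISPRi screens with known ground truth.

The simulator emulates the data a pooled dCas9-KRAB screen produces — a
guide library tiled over DNase-hypersensitive sites, per-guide annotation
features, negative-binomial sequencing counts with four wild-type
replicates, log2 fold changes and FDR-adjusted p-values — while keeping
the generative rule in hand so recovery can be verified.

Effect model: each guide's probability of a significant effect is a
logistic function of the base identities at chosen protospacer positions
(default 1, 3 and 18) and of a chosen subset of annotation features
(default two informative ones among noise). Significant guides draw
adj_p ~ U(0, 0.05), null guides ~ U(0.2, 1), and an explicit borderline
fraction ~ U(0.05, 0.2) exercises the gray-zone exclusion rule. An
alternative "motif" effect model plants a 5-mer whose presence anywhere in
the protospacer drives the outcome, for probing long-k-mer sensitivity.

Counts use a negative binomial with mean 300 and dispersion 0.3 (typical
of screen count data and chosen so the <125 total-count filter removes a
nontrivial minority of guides).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence import BASES, PROTOSPACER_LENGTH

ANNOTATION_NAMES = (
    "H3K27ac", "H3K4me3", "ATAC", "GATA2", "TAL1", "MYC",
    "dG_H", "dG_B", "OGEE_prop_essential", "ploidyZhou",
)

#: Annotation features that carry signal by default; the rest are noise.
DEFAULT_INFORMATIVE = ("H3K27ac", "dG_H")


@dataclass(frozen=True)
class SimConfig:
    n_dhs: int = 500
    guides_per_dhs: int = 10
    guides_per_dhs_poisson: bool = False  # Poisson(guides_per_dhs), min 2
    promoter_fraction: float = 0.3
    n_chromosomes: int = 10

    # logistic effect model
    effect_positions: tuple[int, ...] = (1, 3, 18)  # 1-based
    position_effect_base: str = "G"
    position_coef: float = 3.0
    informative_annotations: tuple[str, ...] = DEFAULT_INFORMATIVE
    annotation_coef: float = 2.5
    intercept: float = -3.5
    effect_model: str = "logistic"  # or "motif"
    motif: str = "GCGTA"
    motif_coef: float = 4.0
    motif_fraction: float = 0.4  # guides that get the motif planted
    # optional: fraction of null guides carrying a one-mismatch decoy of
    # the motif, which removes most of the k-mer-composition signal and
    # leaves only exact matching (markedly harder to learn)
    motif_decoy_fraction: float = 0.0

    # count model
    count_mean: float = 300.0
    count_dispersion: float = 0.3
    n_wt_replicates: int = 4
    n_treat_replicates: int = 4

    # outcome model
    borderline_fraction: float = 0.1
    effect_log2fc_mean: float = 0.8
    effect_log2fc_sd: float = 0.3
    null_log2fc_sd: float = 0.1
    genes_per_guide: int = 3

    annotation_missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_dhs < 1:
            problems.append("n_dhs must be >= 1")
        if self.guides_per_dhs < 1:
            problems.append("guides_per_dhs must be >= 1")
        if not 0 <= self.promoter_fraction <= 1:
            problems.append("promoter_fraction must be in [0, 1]")
        if self.count_dispersion <= 0:
            problems.append("count_dispersion must be > 0")
        if not 0 <= self.borderline_fraction < 1:
            problems.append("borderline_fraction must be in [0, 1)")
        if any(p < 1 or p > PROTOSPACER_LENGTH for p in self.effect_positions):
            problems.append("effect_positions must be within 1..20")
        if self.effect_model not in ("logistic", "motif"):
            problems.append("effect_model must be 'logistic' or 'motif'")
        if set(self.motif) - set(BASES):
            problems.append("motif must be over ACGT")
        unknown = set(self.informative_annotations) - set(ANNOTATION_NAMES)
        if unknown:
            problems.append(f"unknown informative annotations: {sorted(unknown)}")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative binomial parameterized by mean and dispersion (var = m + d m^2)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_library(config: SimConfig):
    """Generate the guide library, annotation table and ground truth.

    Returns ``(records, annotations, truth)``:

    * ``records`` — guide table (guide_id, protospacer, chrom, start, end,
      strand, dhs_id, region_class);
    * ``annotations`` — per-guide annotation features with injected
      missingness;
    * ``truth`` — guide_id, true effect probability, the Bernoulli
      ``true_effect`` flag, and the ``borderline`` flag.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.guides_per_dhs_poisson:
        per_dhs = np.maximum(2, rng.poisson(config.guides_per_dhs, size=config.n_dhs))
    else:
        per_dhs = np.full(config.n_dhs, config.guides_per_dhs)
    n = int(per_dhs.sum())

    dhs_ids = np.repeat([f"DHS{i:05d}" for i in range(config.n_dhs)], per_dhs)
    dhs_chrom = rng.integers(1, config.n_chromosomes + 1, size=config.n_dhs)
    chrom = np.repeat([f"chr{c}" for c in dhs_chrom], per_dhs)
    dhs_is_promoter = rng.random(config.n_dhs) < config.promoter_fraction
    region = np.repeat(np.where(dhs_is_promoter, "promoter", "enhancer"), per_dhs)
    dhs_start = rng.integers(10_000, 100_000_000, size=config.n_dhs)
    start = np.repeat(dhs_start, per_dhs) + rng.integers(0, 500, size=n)
    strand = rng.choice(["+", "-"], size=n)

    seq_idx = rng.integers(0, 4, size=(n, PROTOSPACER_LENGTH))
    if config.effect_model == "motif":
        # plant the 5-mer at a uniform start position in a random subset;
        # presence anywhere in the 20-mer is what drives the outcome
        planted = rng.random(n) < config.motif_fraction
        starts = rng.integers(0, PROTOSPACER_LENGTH - len(config.motif) + 1, size=n)
        motif_idx = np.array([BASES.index(b) for b in config.motif])
        for i in np.flatnonzero(planted):
            seq_idx[i, starts[i] : starts[i] + len(motif_idx)] = motif_idx
        gets_decoy = ~planted & (rng.random(n) < config.motif_decoy_fraction)
        for i in np.flatnonzero(gets_decoy):
            decoy = motif_idx.copy()
            pos = rng.integers(0, len(decoy))
            decoy[pos] = (decoy[pos] + rng.integers(1, 4)) % 4  # guaranteed mismatch
            seq_idx[i, starts[i] : starts[i] + len(decoy)] = decoy
    base_arr = np.array(list(BASES))
    protospacers = ["".join(row) for row in base_arr[seq_idx]]

    records = pd.DataFrame({
        "guide_id": [f"g{i:06d}" for i in range(n)],
        "protospacer": protospacers,
        "chrom": chrom,
        "start": start,
        "end": start + PROTOSPACER_LENGTH,
        "strand": strand,
        "dhs_id": dhs_ids,
        "region_class": region,
    })

    # annotation features: log-normal signal-like marks, thermodynamic
    # energies, a proportion and a categorical ploidy covariate
    ann = pd.DataFrame(index=records["guide_id"])
    for name in ("H3K27ac", "H3K4me3", "ATAC", "GATA2", "TAL1", "MYC"):
        ann[name] = rng.lognormal(mean=2.0, sigma=0.8, size=n)
    ann["dG_H"] = rng.normal(-25.0, 5.0, size=n)
    ann["dG_B"] = rng.normal(-10.0, 3.0, size=n)
    ann["OGEE_prop_essential"] = rng.beta(1.5, 4.0, size=n)
    ann["ploidyZhou"] = rng.choice([2.0, 3.0, 4.0], size=n, p=[0.6, 0.3, 0.1])

    # linear predictor of true effect
    eta = np.full(n, config.intercept)
    if config.effect_model == "logistic":
        for p in config.effect_positions:
            hit = seq_idx[:, p - 1] == BASES.index(config.position_effect_base)
            eta += config.position_coef * hit
        for name in config.informative_annotations:
            col = ann[name].to_numpy()
            z = (col - col.mean()) / col.std()
            # lower hybridization energy binds better -> more likely effective
            sign = -1.0 if name.startswith("dG") else 1.0
            eta += config.annotation_coef * sign * z
    else:
        has_motif = np.array([config.motif in s for s in protospacers])
        eta += config.motif_coef * has_motif

    prob = 1.0 / (1.0 + np.exp(-eta))
    true_effect = rng.random(n) < prob
    borderline = rng.random(n) < config.borderline_fraction
    truth = pd.DataFrame({
        "guide_id": records["guide_id"],
        "effect_prob": prob,
        "true_effect": true_effect,
        "borderline": borderline,
    })

    if config.annotation_missing_rate > 0:
        mask = rng.random(ann.shape) < config.annotation_missing_rate
        ann = ann.mask(mask)

    return records, ann, truth


def simulate_outcomes(records: pd.DataFrame, truth: pd.DataFrame, config: SimConfig) -> dict:
    """Generate the three per-task outcome tables from a simulated library.

    * ``fitness`` — total counts over all replicates, log2FC, adj_p;
    * ``wt_abundance`` — mean of the four wild-type replicate counts, with
      a sequence-driven mean so the count-regression task is learnable
      (guanine at position 1 lowers the expected count);
    * ``expression`` — a gRNA-gene pair table (``genes_per_guide`` genes in
      the +/- 1 Mb-style neighbourhood per guide) plus the per-guide
      best-pair outcome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n = len(records)
    effect = truth["true_effect"].to_numpy()
    borderline = truth["borderline"].to_numpy()

    def draw_adj_p(eff, border):
        p = np.where(eff, rng.uniform(0.0, 0.05, size=n), rng.uniform(0.2, 1.0, size=n))
        return np.where(border, rng.uniform(0.05, 0.2, size=n), p)

    def draw_log2fc(eff):
        null = rng.normal(0.0, config.null_log2fc_sd, size=n)
        signed = rng.choice([-1.0, 1.0], size=n) * rng.normal(
            config.effect_log2fc_mean, config.effect_log2fc_sd, size=n
        )
        return np.where(eff, signed, null)

    # --- cell fitness -----------------------------------------------------
    n_reps = config.n_wt_replicates + config.n_treat_replicates
    counts = _nb_draw(rng, config.count_mean, config.count_dispersion, (n, n_reps))
    fitness = pd.DataFrame({
        "guide_id": records["guide_id"],
        "total_counts": counts.sum(axis=1),
        "log2FC": draw_log2fc(effect),
        "adj_p": draw_adj_p(effect, borderline),
    })

    # --- wild-type abundance ---------------------------------------------
    # sequence-driven expected count: in the default model guanine at
    # position 1 halves the mean; in motif mode the planted 5-mer does
    if config.effect_model == "motif":
        seq_low = np.array([config.motif in s for s in records["protospacer"]])
    else:
        seq_low = np.array([s[0] == "G" for s in records["protospacer"]])
    wt_mu = config.count_mean * np.exp(-0.7 * seq_low)
    wt_counts = np.stack(
        [_nb_draw_vec(rng, wt_mu, config.count_dispersion)
         for _ in range(config.n_wt_replicates)], axis=1,
    )
    wt_mean = wt_counts.mean(axis=1)
    wt_effect = wt_mean < np.median(wt_mean)  # low-count guides
    wt = pd.DataFrame({
        "guide_id": records["guide_id"],
        "wt_mean_count": wt_mean,
        "total_counts": wt_counts.sum(axis=1),
        "log2FC": draw_log2fc(wt_effect),
        "adj_p": draw_adj_p(wt_effect, borderline),
    })

    # --- nearby gene expression -------------------------------------------
    g = config.genes_per_guide
    pair_guide = np.repeat(records["guide_id"].to_numpy(), g)
    gene_rank = np.tile(np.arange(g), n)
    gene_id = np.array([f"GENE_{gid}_{r}" for gid, r in zip(pair_guide, gene_rank)])
    pair_effect = np.repeat(effect, g) & (rng.random(n * g) < 0.6)
    pair_border = np.repeat(borderline, g)
    pair_p = np.where(pair_effect, rng.uniform(0.0, 0.05, size=n * g),
                      rng.uniform(0.2, 1.0, size=n * g))
    pair_p = np.where(pair_border, rng.uniform(0.05, 0.2, size=n * g), pair_p)
    null_fc = rng.normal(0.0, config.null_log2fc_sd, size=n * g)
    eff_fc = rng.choice([-1.0, 1.0], size=n * g) * rng.normal(
        config.effect_log2fc_mean, config.effect_log2fc_sd, size=n * g)
    pairs = pd.DataFrame({
        "guide_id": pair_guide,
        "gene_id": gene_id,
        "log2FC": np.where(pair_effect, eff_fc, null_fc),
        "adj_p": pair_p,
    })

    return {"fitness": fitness, "wt_abundance": wt, "expression_pairs": pairs}


def _nb_draw_vec(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def write_fixture_dir(path, config: SimConfig | None = None) -> dict:
    """Write a complete simulated screen as the TSV dialects the pipeline reads."""
    config = config or SimConfig()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    records, ann, truth = simulate_library(config)
    outcomes = simulate_outcomes(records, truth, config)
    records.to_csv(path / "library.tsv", sep="\t", index=False)
    ann.to_csv(path / "annotations.tsv", sep="\t")
    truth.to_csv(path / "truth.tsv", sep="\t", index=False)
    for task, df in outcomes.items():
        df.to_csv(path / f"{task}.tsv", sep="\t", index=False)
    return {"records": records, "annotations": ann, "truth": truth, **outcomes}
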