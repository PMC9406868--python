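"""Seeded synthetic prostate-cancer cohort generator.

Emulates the statistical structure the downstream analysis assumes, so
that every stage (regulator screen, consensus subtyping, DEG signature,
PCA score, outcome statistics) can be exercised and validated against
known ground truth without external data:

* a panel of m6A-regulator genes plus null background genes, with
  log2-scale Gaussian noise around per-gene baselines;
* a tumor-vs-normal shift τ on a designated regulator subset;
* K latent tumor subtypes, each elevating a disjoint block of regulators
  by δ (blocks partition the regulator panel);
* a metastasis label drawn from a logistic model on the mean z-expression
  of a regulator subset (the last block, so the metastasis-prone subtype
  is also the poor-prognosis one);
* subtype-dependent Gleason grades via a cumulative-logit model;
* exponential recurrence-free and overall survival with subtype hazard
  multipliers and uniform censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CohortAnnotations, ExpressionMatrix

__all__ = ["M6A_REGULATORS", "SimConfig", "simulate_cohort"]

# The canonical 21-gene m6A regulator panel: 8 writers, 2 erasers, 11 readers.
M6A_REGULATORS = (
    "METTL3", "METTL14", "RBM15", "RBM15B", "WTAP", "KIAA1429", "CBLL1",
    "ZC3H13",            # writers
    "ALKBH5", "FTO",     # erasers
    "YTHDC1", "YTHDC2", "YTHDF1", "YTHDF2", "YTHDF3", "IGF2BP1",
    "HNRNPA2B1", "HNRNPC", "FMR1", "LRPPRC", "ELAVL1",  # readers
)

# Baseline Gleason 6..10 marginal (cumulative-logit cutpoints derived below).
_GLEASON_BASE_PROBS = (0.25, 0.35, 0.20, 0.12, 0.08)


@dataclass
class SimConfig:
    """Parameters of the generative model. All shifts are in log2 units."""

    n_tumor: int = 150
    n_normal: int = 30
    n_regulators: int = 21
    n_tumor_normal_shifted: int = 18
    n_background_genes: int = 500
    k_subtypes: int = 3
    subtype_proportions: tuple[float, ...] | None = None  # uniform if None
    subtype_shift: float = 2.0        # δ, subtype block elevation
    tumor_normal_shift: float = 1.0   # τ, tumor-vs-normal elevation
    gene_baseline_range: tuple[float, float] = (2.0, 8.0)
    gene_noise_sd: float = 1.0        # σ
    metastasis_gene_count: int = 7
    metastasis_beta: float = 1.0      # slope per z-unit of the mean-z index
    metastasis_intercept: float = -1.0
    gleason_slopes: tuple[float, ...] | None = None  # per-subtype shift; default (0, 0.5, 2, ...)
    rfs_hazard_ratios: tuple[float, ...] | None = None  # default (1, ..., 1, 2.5)
    os_hazard_ratios: tuple[float, ...] | None = None   # default all 1
    baseline_hazard: float = 0.02     # events per month
    censoring_horizon: float = 120.0  # months
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subtype_proportions is None:
            self.subtype_proportions = tuple([1.0 / self.k_subtypes] * self.k_subtypes)
        if self.gleason_slopes is None:
            slopes = [0.0] * self.k_subtypes
            if self.k_subtypes >= 2:
                slopes[-2] = 0.5
            if self.k_subtypes >= 1:
                slopes[-1] = 2.0
            self.gleason_slopes = tuple(slopes)
        if self.rfs_hazard_ratios is None:
            hrs = [1.0] * self.k_subtypes
            hrs[-1] = 2.5
            self.rfs_hazard_ratios = tuple(hrs)
        if self.os_hazard_ratios is None:
            self.os_hazard_ratios = tuple([1.0] * self.k_subtypes)
        self.validate()

    def validate(self) -> None:
        for name in ("n_tumor", "n_normal", "n_regulators", "k_subtypes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be non-negative")
        if not 0 <= self.n_tumor_normal_shifted <= self.n_regulators:
            raise ValueError("n_tumor_normal_shifted must be <= n_regulators")
        if not 0 <= self.metastasis_gene_count <= self.n_regulators:
            raise ValueError("metastasis_gene_count must be <= n_regulators")
        props = np.asarray(self.subtype_proportions, dtype=float)
        if props.size != self.k_subtypes or (props < 0).any() or abs(props.sum() - 1) > 1e-8:
            raise ValueError("subtype_proportions must be a simplex vector of length k_subtypes")
        if self.k_subtypes > self.n_regulators:
            raise ValueError("need at least one regulator per subtype block")
        lo, hi = self.gene_baseline_range
        if not lo <= hi:
            raise ValueError("gene_baseline_range must be (lo, hi) with lo <= hi")
        if self.gene_noise_sd <= 0:
            raise ValueError("gene_noise_sd must be positive")
        for name in ("gleason_slopes", "rfs_hazard_ratios", "os_hazard_ratios"):
            if len(getattr(self, name)) != self.k_subtypes:
                raise ValueError(f"{name} must have one entry per subtype")
        if min(self.rfs_hazard_ratios) <= 0 or min(self.os_hazard_ratios) <= 0:
            raise ValueError("hazard ratios must be positive")
        if self.baseline_hazard <= 0 or self.censoring_horizon <= 0:
            raise ValueError("baseline_hazard and censoring_horizon must be positive")


def _gene_names(cfg: SimConfig) -> tuple[list[str], list[str]]:
    regs = list(M6A_REGULATORS[: cfg.n_regulators])
    regs += [f"REG{i:03d}" for i in range(len(regs), cfg.n_regulators)]
    bg = [f"BG{i:04d}" for i in range(cfg.n_background_genes)]
    return regs, bg


def _gleason_cutpoints() -> np.ndarray:
    cum = np.cumsum(_GLEASON_BASE_PROBS)[:-1]
    return np.log(cum / (1 - cum))


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, CohortAnnotations, dict[str, pd.DataFrame]]:
    """Draw one cohort from the generative model.

    Returns the log2-scale expression matrix, clinical annotations, and a
    ``truth`` dict with per-sample latent labels (``samples``: subtype,
    metastasis probability) and per-gene roles (``genes``: regulator /
    background, tumor-normal shifted, subtype block, metastasis-set flag).
    Identical configs (including seed) give identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    regs, bg = _gene_names(cfg)
    genes = regs + bg
    n_genes = len(genes)
    n = cfg.n_tumor + cfg.n_normal
    tumor_ids = [f"T{i:04d}" for i in range(cfg.n_tumor)]
    normal_ids = [f"N{i:04d}" for i in range(cfg.n_normal)]
    samples = tumor_ids + normal_ids
    is_tumor = np.array([True] * cfg.n_tumor + [False] * cfg.n_normal)

    lo, hi = cfg.gene_baseline_range
    mu = rng.uniform(lo, hi, n_genes)
    values = mu[:, None] + rng.normal(0.0, cfg.gene_noise_sd, (n_genes, n))

    # tumor-vs-normal shift on the first n_tumor_normal_shifted regulators
    tn_shifted = np.zeros(n_genes, dtype=bool)
    tn_shifted[: cfg.n_tumor_normal_shifted] = True
    values[np.ix_(tn_shifted, is_tumor)] += cfg.tumor_normal_shift

    # latent subtypes for tumors; blocks partition the regulator panel
    subtype = rng.choice(cfg.k_subtypes, size=cfg.n_tumor, p=cfg.subtype_proportions) + 1
    blocks = np.array_split(np.arange(cfg.n_regulators), cfg.k_subtypes)
    block_of_gene = np.full(n_genes, 0, dtype=int)
    for j, b in enumerate(blocks, start=1):
        block_of_gene[b] = j
    tumor_cols = np.where(is_tumor)[0]
    for j, b in enumerate(blocks, start=1):
        cols = tumor_cols[subtype == j]
        if cols.size:
            values[np.ix_(b, cols)] += cfg.subtype_shift

    # metastasis: logistic on the mean generative z of the last block's genes
    met_genes = np.arange(cfg.n_regulators - cfg.metastasis_gene_count, cfg.n_regulators)
    met_flag = np.zeros(n_genes, dtype=bool)
    met_flag[met_genes] = True
    expected = mu[met_genes, None] + cfg.tumor_normal_shift * tn_shifted[met_genes, None]
    z = (values[np.ix_(met_genes, tumor_cols)] - expected) / cfg.gene_noise_sd
    met_index = z.mean(axis=0) if met_genes.size else np.zeros(cfg.n_tumor)
    met_prob = 1.0 / (1.0 + np.exp(-(cfg.metastasis_intercept + cfg.metastasis_beta * met_index)))
    met_draw = rng.random(cfg.n_tumor) < met_prob

    # Gleason 6..10: cumulative-logit with subtype-specific shift
    cut = _gleason_cutpoints()
    eta = np.asarray(cfg.gleason_slopes)[subtype - 1]
    cdf = 1.0 / (1.0 + np.exp(-(cut[None, :] - eta[:, None])))
    u = rng.random(cfg.n_tumor)
    gleason = 6 + (u[:, None] > cdf).sum(axis=1)

    # survival: exponential event times with subtype hazard ratios, uniform censoring
    def _survival(hrs: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
        rate = cfg.baseline_hazard * np.asarray(hrs)[subtype - 1]
        t_event = rng.exponential(1.0 / rate)
        t_cens = rng.uniform(0.0, cfg.censoring_horizon, cfg.n_tumor)
        event = (t_event <= t_cens).astype(int)
        return np.minimum(t_event, t_cens), event

    rfs_time, rfs_event = _survival(cfg.rfs_hazard_ratios)
    os_time, os_event = _survival(cfg.os_hazard_ratios)

    expr = ExpressionMatrix(genes, samples, values)
    nan = np.nan
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "tissue": ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal,
            "metastasis": [("yes" if m else "no") for m in met_draw]
            + ["unknown"] * cfg.n_normal,
            "gleason": list(gleason) + [nan] * cfg.n_normal,
            "os_time": list(os_time) + [nan] * cfg.n_normal,
            "os_event": list(os_event) + [nan] * cfg.n_normal,
            "rfs_time": list(rfs_time) + [nan] * cfg.n_normal,
            "rfs_event": list(rfs_event) + [nan] * cfg.n_normal,
            "subtype": [nan] * n,
        }
    )
    ann = CohortAnnotations(clinical)

    truth_samples = pd.DataFrame(
        {
            "sample_id": tumor_ids,
            "subtype": subtype,
            "metastasis_index": met_index,
            "metastasis_prob": met_prob,
        }
    )
    truth_genes = pd.DataFrame(
        {
            "gene_id": genes,
            "is_regulator": [True] * len(regs) + [False] * len(bg),
            "tumor_normal_shifted": tn_shifted,
            "subtype_block": block_of_gene,
            "metastasis_gene": met_flag,
        }
    )
    return expr, ann, {"samples": truth_samples, "genes": truth_genes}
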