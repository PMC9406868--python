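"""The PCA-based m6A score.

The score of a sample is the sum of its coordinates on the first two
principal components of the z-scored metastasis-associated regulator
signature. The intrinsic sign ambiguity of principal components is fixed
by an orientation rule: each component is flipped, if necessary, so that
its sample coordinates correlate non-positively with the mean z-scored
signature expression. High aggregate regulator expression therefore maps
to a *low* score, reproducing the published direction conventions (the
metastasis-prone group scores lower, and the score is inversely
correlated with most regulators).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionMatrix

__all__ = ["PcaModel", "fit_score_model", "compute_scores", "score_cohort"]


@dataclass
class PcaModel:
    """Frozen score model: per-gene standardization plus oriented loadings."""

    signature_genes: list[str]
    mean: np.ndarray  # per-gene centering, log2 scale
    sd: np.ndarray    # per-gene scaling (n−1 denominator)
    loadings: np.ndarray  # (2, n_genes), unit rows, orientation applied
    explained_variance_ratio: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.explained_variance_ratio = np.asarray(self.explained_variance_ratio, dtype=float)
        g = len(self.signature_genes)
        if self.loadings.shape != (2, g) or self.mean.shape != (g,) or self.sd.shape != (g,):
            raise ValueError("model field shapes inconsistent with the signature gene list")
        norms = np.linalg.norm(self.loadings, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("loading vectors must have unit norm")
        if abs(float(self.loadings[0] @ self.loadings[1])) > 1e-8:
            raise ValueError("loading vectors must be orthogonal")

    def to_json(self, path) -> None:
        obj = {
            "signature_genes": self.signature_genes,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PcaModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            signature_genes=list(obj["signature_genes"]),
            mean=np.array(obj["mean"]),
            sd=np.array(obj["sd"]),
            loadings=np.array(obj["loadings"]),
            explained_variance_ratio=np.array(obj["explained_variance_ratio"]),
        )


def fit_score_model(m: ExpressionMatrix, signature_genes) -> PcaModel:
    """Fit the score model on a cohort.

    Signature gene rows are z-scored (mean 0, sd 1, n−1 denominator) and
    the top-2 eigenvectors of the resulting gene-gene covariance are the
    loadings, each oriented so its sample coordinates correlate ≤ 0 with
    the mean z-scored signature expression.
    """
    signature_genes = list(signature_genes)
    if len(signature_genes) < 2:
        raise ValueError("need at least 2 signature genes")
    sub = m.subset(genes=signature_genes)
    if sub.n_samples < 3:
        raise ValueError("need at least 3 samples to fit the score model")
    mu = sub.values.mean(axis=1)
    sd = sub.values.std(axis=1, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance signature genes: {[signature_genes[i] for i in bad]}")
    z = (sub.values - mu[:, None]) / sd[:, None]
    n = sub.n_samples
    cov = (z @ z.T) / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    loadings = eigvec[:, order[:2]].T.copy()  # (2, g)
    mean_z = z.mean(axis=0)
    for j in range(2):
        coords = loadings[j] @ z
        c = np.corrcoef(coords, mean_z)[0, 1] if np.std(coords) > 0 and np.std(mean_z) > 0 else 0.0
        if c > 0:
            loadings[j] = -loadings[j]
    total = eigval.sum()
    evr = eigval[:2] / total if total > 0 else np.zeros(2)
    return PcaModel(
        signature_genes=signature_genes,
        mean=mu,
        sd=sd,
        loadings=loadings,
        explained_variance_ratio=evr,
    )


def compute_scores(model: PcaModel, m: ExpressionMatrix) -> pd.Series:
    """Score samples: center/scale by the stored model, project, sum PC1+PC2.

    Applying a fitted model to a new cohort reuses the stored centering
    and loadings (frozen-model transfer).
    """
    sub = m.subset(genes=model.signature_genes)  # raises listing missing genes
    z = (sub.values - model.mean[:, None]) / model.sd[:, None]
    coords = model.loadings @ z  # (2, n_samples)
    return pd.Series(
        coords.sum(axis=0), index=pd.Index(sub.sample_ids, name="sample_id"), name="m6a_score"
    )


def score_cohort(
    m: ExpressionMatrix,
    signature_genes,
    mode: str = "refit",
    model: PcaModel | None = None,
) -> tuple[pd.Series, PcaModel]:
    """Score a cohort, refitting by default.

    ``mode="refit"`` fits the PCA on this cohort (appropriate when
    transferring the signature across platforms); ``mode="project"``
    applies a previously fitted model unchanged.
    """
    if mode == "refit":
        model = fit_score_model(m, signature_genes)
    elif mode == "project":
        if model is None:
            raise ValueError("mode='project' requires a fitted model")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return compute_scores(model, m), model
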