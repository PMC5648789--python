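"""Scoring confounder removal: k-means clustering recovery (adjusted
Rand index), PVE-estimation error, and simple internal baselines
(all-gene PCA correction and control-only factor correction)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .model import ExpressionPair

__all__ = [
    "EvalReport",
    "adjusted_rand_index",
    "cluster_and_score",
    "baseline_pca_correct",
    "baseline_control_only",
    "pve_error",
]


@dataclass
class EvalReport:
    """Clustering-recovery report for one corrected matrix.

    ``ari_runs`` holds the ARI of each seeded k-means run against the
    true labels; ``ari_mean`` is their mean."""

    ari_mean: float
    ari_runs: np.ndarray
    method: str = ""
    pde: Optional[float] = None
    scenario: Optional[str] = None
    pve_error: Optional[np.ndarray] = None

    def to_frame(self):
        """One row per run, for TSV serialization."""
        import pandas as pd

        return pd.DataFrame({
            "method": self.method,
            "scenario": self.scenario,
            "pde": self.pde,
            "run": np.arange(len(self.ari_runs)),
            "ari": self.ari_runs,
        })


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same
    cells: 1 for identical partitions (up to relabeling), about 0 for
    random ones."""
    labels_a = np.asarray(labels_a).ravel()
    labels_b = np.asarray(labels_b).ravel()
    if labels_a.shape != labels_b.shape:
        raise ValueError("partitions must have equal length")
    if labels_a.size < 2:
        raise ValueError("need at least two cells")
    return float(adjusted_rand_score(labels_a, labels_b))


def cluster_and_score(data: np.ndarray, true_labels, n_clusters: int = 2,
                      n_runs: int = 10, seed: int = 0,
                      method: str = "", pde=None,
                      scenario=None) -> EvalReport:
    """Run seeded k-means ``n_runs`` times on a cells × genes matrix and
    score each run's partition against the true labels by ARI.

    Each run uses multiple random restarts with best-inertia selection;
    per-run seeds are derived from the master seed."""
    data = np.asarray(data, dtype=float)
    true_labels = np.asarray(true_labels).ravel()
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2 ** 31 - 1, size=n_runs)
    aris = np.empty(n_runs)
    for r, s in enumerate(run_seeds):
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=int(s))
        pred = km.fit_predict(data)
        aris[r] = adjusted_rand_index(true_labels, pred)
    return EvalReport(ari_mean=float(aris.mean()), ari_runs=aris,
                      method=method, pde=pde, scenario=scenario)


def _regress_out(Y: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Residuals of each column of Y after least-squares regression on
    the factor-score columns F."""
    if F.shape[1] == 0:
        return Y.copy()
    coef, *_ = linalg.lstsq(F, Y)
    return Y - F @ coef


def baseline_pca_correct(data: ExpressionPair, k: int) -> np.ndarray:
    """All-gene PCA correction: the top-``k`` principal components of the
    concatenated [X Y] matrix stand in for the confounding factors and
    are regressed out of every target gene.

    This treats control and target genes identically, so any structured
    biological variation strong enough to enter the top components is
    removed along with the confounding."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k == 0:
        return data.Y.copy()
    W = data.W
    U, s, _ = linalg.svd(W, full_matrices=False)
    F = U[:, :k] * s[:k]
    return _regress_out(data.Y, F)


def baseline_control_only(data: ExpressionPair, k: int) -> np.ndarray:
    """Control-only correction: factors are inferred from the control
    matrix X alone (top-``k`` principal components) and regressed out of
    the target genes.

    Immune to removing biological signal, but the factor estimates use
    only the q control genes and are correspondingly noisier."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k == 0:
        return data.Y.copy()
    U, s, _ = linalg.svd(data.X, full_matrices=False)
    F = U[:, :k] * s[:k]
    return _regress_out(data.Y, F)


def pve_error(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Elementwise estimation error (estimated minus true proportion)."""
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimated.shape != truth.shape:
        raise ValueError("estimate and truth must have equal shape")
    return estimated - truth
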