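"""EM inference: naive and chunked EM fits, BIC model selection,
confounder removal, and per-gene variance decomposition.

The latent factors are treated as missing data.  The E-step computes the
posterior moments of the stacked factors ``v_i = (z_i, u_i)`` given each
cell's observation; the M-step solves the zero-gradient equations of the
expected complete-data log-likelihood for the loading matrices (the
coupled target-gene loadings are solved as one stacked linear system)
and then maximizes over the residual variances.  The chunked variant
computes the E-step on random subsets of target genes and averages the
posterior moments across chunks, which divides the E-step cost by the
number of chunks while leaving the M-step unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .model import (
    VARIANCE_FLOOR,
    ExpressionPair,
    LatentMoments,
    ScplsParams,
    marginal_loglik,
    posterior_moments,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScPLSResults",
    "FitResult",
    "initialize",
    "em_step_naive",
    "fit_naive",
    "fit_chunks",
    "select_model",
    "correct",
    "pve_decompose",
]


@dataclass
class ScPLSResults:
    """Results of an EM fit.

    Carries the fitted parameters, the per-iteration marginal
    log-likelihood trace, the BIC, the posterior confounding-factor
    means, the corrected target matrix (confounding effects removed,
    biological effects retained), and the per-gene variance
    decomposition.
    """

    params: ScplsParams
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    bic: float
    Ez: np.ndarray
    corrected_Y: np.ndarray
    pve_confounding: np.ndarray
    pve_biological: np.ndarray
    data: ExpressionPair = field(repr=False, default=None)
    bic_grid: "object" = field(repr=False, default=None)

    @property
    def kz(self) -> int:
        return self.params.kz

    @property
    def ku(self) -> int:
        return self.params.ku

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def summary(self) -> str:
        """Plain-text fit summary."""
        p = self.params
        lines = [
            "scPLS fit results",
            "=" * 46,
            f"cells                 {self.data.n if self.data is not None else '?'}",
            f"control genes (q)     {p.q}",
            f"target genes (p)      {p.p}",
            f"confounding factors   kz = {p.kz}",
            f"biological factors    ku = {p.ku}",
            f"log-likelihood        {self.loglik:.4f}",
            f"BIC                   {self.bic:.4f}",
            f"EM iterations         {self.n_iter}"
            + ("" if self.converged else "  (NOT converged)"),
            f"median PVE confounding  {np.median(self.pve_confounding):.3f}",
            f"median PVE biological   {np.median(self.pve_biological):.3f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Plot the EM log-likelihood trace."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(len(self.loglik_trace)), self.loglik_trace,
                marker=".", lw=1)
        ax.set_xlabel("EM iteration")
        ax.set_ylabel("marginal log-likelihood")
        return ax

    def plot_pve(self, ax=None, bins=30):
        """Histogram the per-gene confounding and biological PVE."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.pve_confounding, bins=bins, alpha=0.6,
                label="confounding")
        ax.hist(self.pve_biological, bins=bins, alpha=0.6,
                label="biological")
        ax.set_xlabel("proportion of variance explained")
        ax.set_ylabel("genes")
        ax.legend()
        return ax


# spec-facing alias
FitResult = ScPLSResults


def initialize(data: ExpressionPair, kz: int, ku: int,
               seed: int = 0) -> ScplsParams:
    """Initialize parameters by sequential singular value decompositions.

    The control loadings come from the top-``kz`` singular structure of
    X; provisional factor scores from that decomposition; the target
    confounding loadings from least-squares regression of Y on those
    scores; the biological loadings from the top-``ku`` singular
    structure of the resulting Y residuals; residual variances from the
    remaining column variances (floored).
    """
    n, q, p = data.n, data.q, data.p
    if kz < 0 or ku < 0:
        raise ValueError("factor counts must be nonnegative")
    if kz > min(n, q):
        raise ValueError(f"kz={kz} exceeds the rank bound min(n, q)="
                         f"{min(n, q)} of the control matrix")
    if ku > min(n, p):
        raise ValueError(f"ku={ku} exceeds the rank bound min(n, p)="
                         f"{min(n, p)} of the target matrix")
    X, Y = data.X, data.Y
    if kz > 0:
        U, s, Vt = linalg.svd(X, full_matrices=False)
        Lambda_x = Vt[:kz].T * (s[:kz] / np.sqrt(n))
        Z = np.sqrt(n) * U[:, :kz]  # unit-variance provisional scores
        Lambda_y = linalg.lstsq(Z, Y)[0].T
        resid_y = Y - Z @ Lambda_y.T
        resid_x = X - Z @ Lambda_x.T
    else:
        Lambda_x = np.zeros((q, 0))
        Lambda_y = np.zeros((p, 0))
        resid_y = Y
        resid_x = X
    if ku > 0:
        Ur, sr, Vrt = linalg.svd(resid_y, full_matrices=False)
        Lambda_u = Vrt[:ku].T * (sr[:ku] / np.sqrt(n))
        Uscore = np.sqrt(n) * Ur[:, :ku]
        resid_y = resid_y - Uscore @ Lambda_u.T
    else:
        Lambda_u = np.zeros((p, 0))
    psi_x = np.maximum((resid_x ** 2).mean(axis=0), VARIANCE_FLOOR)
    psi_y = np.maximum((resid_y ** 2).mean(axis=0), VARIANCE_FLOOR)
    return ScplsParams(Lambda_x, Lambda_y, Lambda_u, psi_x, psi_y)


def _solve_spd(A: np.ndarray, rhs: np.ndarray, what: str) -> np.ndarray:
    """Solve the symmetric positive-definite system A x = rhs, falling
    back to a ridge-stabilized solve on near-singular moment matrices."""
    try:
        c, low = linalg.cho_factor(A)
        return linalg.cho_solve((c, low), rhs)
    except linalg.LinAlgError:
        warnings.warn(
            f"singular moment matrix in {what}; using ridge-stabilized solve",
            RuntimeWarning,
        )
        logger.debug("%s: condition number %.3g", what, np.linalg.cond(A))
        ridge = 1e-8 * max(np.trace(A) / max(A.shape[0], 1), 1.0)
        return linalg.solve(A + ridge * np.eye(A.shape[0]), rhs,
                            assume_a="sym")


def _make_chunks(p: int, chunk_size: int, rng: np.random.Generator):
    """Seeded random partition of target-gene indices into
    ceil(p / chunk_size) chunks.  A single chunk is the identity
    (unpermuted) partition so that the chunked path reproduces the naive
    one bit-for-bit."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if chunk_size >= p:
        return [np.arange(p)]
    perm = rng.permutation(p)
    n_chunks = int(np.ceil(p / chunk_size))
    return np.array_split(perm, n_chunks)


def _sub_params(params: ScplsParams, idx: np.ndarray) -> ScplsParams:
    return ScplsParams(
        params.Lambda_x,
        params.Lambda_y[idx],
        params.Lambda_u[idx],
        params.psi_x,
        params.psi_y[idx],
    )


def _e_step(params: ScplsParams, data: ExpressionPair,
            chunks) -> LatentMoments:
    """Posterior moments of v, averaged with equal weight across chunks.

    With a single full chunk this is the exact E-step."""
    if len(chunks) == 1 and chunks[0].size == data.p:
        return posterior_moments(params, data)
    k = params.k
    Ev = np.zeros((data.n, k))
    Vv = np.zeros((k, k))
    for idx in chunks:
        sub = ExpressionPair(data.X, data.Y[:, idx])
        mom = posterior_moments(_sub_params(params, idx), sub)
        Ev += mom.Ev
        Vv += mom.Vv
    K = len(chunks)
    return LatentMoments(Ev=Ev / K, Vv=Vv / K, kz=params.kz)


def _m_step(params: ScplsParams, data: ExpressionPair,
            moments: LatentMoments) -> ScplsParams:
    """Maximize the expected complete-data log-likelihood.

    Loadings solve the zero-gradient equations (the Lambda_y/Lambda_u
    coupling handled as one stacked system per gene block); residual
    variances take the expected residual second moment, floored."""
    n, q, p = data.n, data.q, data.p
    kz, ku = params.kz, params.ku
    X, Y = data.X, data.Y
    if kz + ku == 0:
        psi_x = np.maximum((X ** 2).mean(axis=0), VARIANCE_FLOOR)
        psi_y = np.maximum((Y ** 2).mean(axis=0), VARIANCE_FLOOR)
        return ScplsParams(params.Lambda_x, params.Lambda_y,
                           params.Lambda_u, psi_x, psi_y)
    Svv = moments.sum_Evv()
    Ev = moments.Ev
    if kz > 0:
        Szz = Svv[:kz, :kz]
        Sxz = X.T @ moments.Ez  # q × kz
        Lambda_x = _solve_spd(Szz, Sxz.T, "control-loading update").T
        psi_x = (
            (X ** 2).sum(axis=0)
            - 2.0 * (Lambda_x * Sxz).sum(axis=1)
            + ((Lambda_x @ Szz) * Lambda_x).sum(axis=1)
        ) / n
    else:
        Lambda_x = params.Lambda_x
        psi_x = (X ** 2).mean(axis=0)
    Syv = Y.T @ Ev  # p × k
    L_stack = _solve_spd(Svv, Syv.T, "target-loading update").T
    psi_y = (
        (Y ** 2).sum(axis=0)
        - 2.0 * (L_stack * Syv).sum(axis=1)
        + ((L_stack @ Svv) * L_stack).sum(axis=1)
    ) / n
    Lambda_y = L_stack[:, :kz]
    Lambda_u = L_stack[:, kz:]
    return ScplsParams(
        Lambda_x, Lambda_y, Lambda_u,
        np.maximum(psi_x, VARIANCE_FLOOR),
        np.maximum(psi_y, VARIANCE_FLOOR),
    )


def em_step_naive(params: ScplsParams, data: ExpressionPair) -> ScplsParams:
    """One exact EM step: full E-step posterior moments followed by the
    M-step.  The marginal log-likelihood never decreases across a step
    (up to numerical tolerance)."""
    moments = posterior_moments(params, data)
    return _m_step(params, data, moments)


def _bic(loglik: float, params: ScplsParams, n: int) -> float:
    return -2.0 * loglik + params.n_free_parameters() * np.log(n)


def _finish(data, params, trace, converged, n_iter) -> ScPLSResults:
    moments = posterior_moments(params, data)
    Ez = moments.Ez
    corrected = data.Y - Ez @ params.Lambda_y.T
    pve_conf, pve_bio = pve_decompose(params)
    return ScPLSResults(
        params=params,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
        bic=_bic(trace[-1], params, data.n),
        Ez=Ez,
        corrected_Y=corrected,
        pve_confounding=pve_conf,
        pve_biological=pve_bio,
        data=data,
    )


def _fit(data: ExpressionPair, kz: int, ku: int, chunks, tol: float,
         max_iter: int, seed: int) -> ScPLSResults:
    params = initialize(data, kz, ku, seed=seed)
    trace = [marginal_loglik(params, data)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        moments = _e_step(params, data, chunks)
        params = _m_step(params, data, moments)
        trace.append(marginal_loglik(params, data))
        logger.info("EM iter %d: loglik %.6f", n_iter, trace[-1])
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations "
            f"(last change {abs(trace[-1] - trace[-2]):.3g})",
            RuntimeWarning,
        )
    return _finish(data, params, trace, converged, n_iter)


def fit_naive(data: ExpressionPair, kz: int, ku: int, tol: float = 1e-4,
              max_iter: int = 500, seed: int = 0) -> ScPLSResults:
    """Fit by the exact (naive) EM algorithm from the SVD initializer.

    Stops when the absolute log-likelihood change drops below ``tol``.
    """
    return _fit(data, kz, ku, [np.arange(data.p)], tol, max_iter, seed)


def fit_chunks(data: ExpressionPair, kz: int, ku: int,
               chunk_size: int = 500, tol: float = 1e-4,
               max_iter: int = 500, seed: int = 0) -> ScPLSResults:
    """Fit by EM with a chunked E-step.

    Target genes are randomly partitioned (seeded) into
    ``ceil(p / chunk_size)`` chunks; each E-step computes posterior
    moments per chunk from (X, Y_chunk) with the corresponding parameter
    sub-blocks and averages them (equal weights) before the usual
    M-step.  ``chunk_size >= p`` reproduces :func:`fit_naive` exactly.
    """
    if not (1 <= chunk_size):
        raise ValueError("chunk_size must be >= 1")
    if chunk_size < kz + ku:
        warnings.warn(
            f"chunk_size={chunk_size} below the factor count "
            f"kz+ku={kz + ku}: per-chunk posteriors may be "
            "ill-conditioned; proceeding (ridge-stabilized solves)",
            RuntimeWarning,
        )
    rng = np.random.default_rng(seed)
    chunks = _make_chunks(data.p, chunk_size, rng)
    return _fit(data, kz, ku, chunks, tol, max_iter, seed)


def select_model(data: ExpressionPair, kz_grid=(1, 2, 3),
                 ku_grid=tuple(range(1, 11)), method: str = "naive",
                 chunk_size: int = 500, tol: float = 1e-4,
                 max_iter: int = 500, seed: int = 0) -> ScPLSResults:
    """Fit every (kz, ku) grid cell and return the minimum-BIC fit.

    BIC = -2 loglik + m log(n) with m = q·kz + p·kz + p·ku + p + q free
    parameters.  Ties break toward smaller kz + ku, then smaller kz.
    """
    kz_grid = list(kz_grid)
    ku_grid = list(ku_grid)
    if not kz_grid or not ku_grid:
        raise ValueError("factor-count grids must be non-empty")
    results = []
    failures = []
    for kz in kz_grid:
        for ku in ku_grid:
            try:
                if method == "chunks":
                    res = fit_chunks(data, kz, ku, chunk_size=chunk_size,
                                     tol=tol, max_iter=max_iter, seed=seed)
                else:
                    res = fit_naive(data, kz, ku, tol=tol,
                                    max_iter=max_iter, seed=seed)
            except (ValueError, FloatingPointError, linalg.LinAlgError) as exc:
                failures.append((kz, ku, str(exc)))
                continue
            results.append(res)
    if not results:
        detail = "; ".join(f"(kz={a}, ku={b}): {m}" for a, b, m in failures)
        raise RuntimeError(f"all grid fits failed: {detail}")
    best = min(results, key=lambda r: (r.bic, r.kz + r.ku, r.kz))
    import pandas as pd

    best.bic_grid = pd.DataFrame(
        [(r.kz, r.ku, r.loglik, r.bic, r.converged) for r in results],
        columns=["kz", "ku", "loglik", "bic", "converged"],
    )
    return best


def correct(data: ExpressionPair, params: ScplsParams) -> np.ndarray:
    """Remove the estimated confounding effects from the target genes.

    Returns the residuals ``Y - E(z|w) Lambda_y^T``.  Only the
    confounding component is removed; structured biological effects are
    deliberately retained in the output.
    """
    if params.kz == 0:
        return data.Y.copy()
    Ez = posterior_moments(params, data).Ez
    return data.Y - Ez @ params.Lambda_y.T


def pve_decompose(params: ScplsParams):
    """Per-target-gene proportion of variance explained by the
    confounding and biological components.

    For gene j with confounding loadings row ``Lambda_y[j]``, biological
    loadings row ``Lambda_u[j]`` and residual variance ``psi_y[j]`` the
    model-implied total variance is the sum of the three squared terms,
    and each PVE is its component's share.
    """
    conf = (params.Lambda_y ** 2).sum(axis=1)
    bio = (params.Lambda_u ** 2).sum(axis=1)
    total = conf + bio + params.psi_y
    return conf / total, bio / total
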