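"""Core probabilistic model: a partial-least-squares latent factor model
over a control gene set and a target gene set.

The model for cell ``i`` with control expression ``x_i`` (length ``q``) and
target expression ``y_i`` (length ``p``), both log-transformed and per-gene
mean-centered, is

.. math::

    x_i = \\Lambda_x z_i + \\varepsilon_{xi},\\qquad
    \\varepsilon_{xi} \\sim \\mathrm{MVN}(0, \\Psi_x)

    y_i = \\Lambda_y z_i + \\Lambda_u u_i + \\varepsilon_{yi},\\qquad
    \\varepsilon_{yi} \\sim \\mathrm{MVN}(0, \\Psi_y)

where ``z_i`` (length ``kz``) are hidden confounding factors shared by both
gene sets, ``u_i`` (length ``ku``) are hidden structured (biological)
factors affecting target genes only, both with standard-normal priors, and
``Psi_x``/``Psi_y`` are diagonal residual covariances.  Stacking
``w_i = (x_i, y_i)`` and ``v_i = (z_i, u_i)`` gives ``w_i = B v_i + eps``
with the block loading matrix ``B = [[Λx, 0], [Λy, Λu]]``; the controls
carry a structural zero block because they are assumed free of the
structured biological variation.

Orientation convention: cells are rows, genes are columns; loading
matrices are genes × factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "VARIANCE_FLOOR",
    "ExpressionPair",
    "ScplsParams",
    "LatentMoments",
    "assemble_joint_covariance",
    "marginal_loglik",
    "posterior_moments",
    "ScPLS",
]

#: Lower bound on every residual variance, preventing Heywood-case
#: collapse (EM for factor models can drive residual variances to zero).
VARIANCE_FLOOR = 1e-6


class InvalidParameterError(ValueError):
    """Raised when model parameters contain non-finite or inconsistent
    entries."""


def _as_labels(labels, n, prefix):
    if labels is None:
        return np.array([f"{prefix}{i}" for i in range(n)], dtype=object)
    labels = np.asarray(labels, dtype=object)
    if labels.shape != (n,):
        raise ValueError(f"expected {n} {prefix} labels, got {labels.shape}")
    return labels


@dataclass
class ExpressionPair:
    """Centered control matrix ``X`` (n × q) and target matrix ``Y``
    (n × p) for the same ``n`` cells.

    Parameters
    ----------
    X, Y
        Control and target expression, cells as rows.  Expected to be on
        a continuous scale (e.g. log(count + 1)) with per-gene mean zero;
        use :meth:`from_counts` or ``center=True`` to get there.
    cell_ids, control_ids, target_ids
        Optional row/column labels; synthesized when omitted.
    """

    X: np.ndarray
    Y: np.ndarray
    cell_ids: np.ndarray = None
    control_ids: np.ndarray = None
    target_ids: np.ndarray = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X and Y must share cells (rows): {self.X.shape[0]} != "
                f"{self.Y.shape[0]}"
            )
        if self.X.shape[1] < 1 or self.Y.shape[1] < 1:
            raise ValueError("need at least one control and one target gene")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("expression matrices must be finite")
        self.cell_ids = _as_labels(self.cell_ids, self.n, "cell")
        self.control_ids = _as_labels(self.control_ids, self.q, "control")
        self.target_ids = _as_labels(self.target_ids, self.p, "target")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]

    @property
    def p(self) -> int:
        return self.Y.shape[1]

    @property
    def W(self) -> np.ndarray:
        """Concatenated n × (q + p) matrix, controls first."""
        return np.hstack([self.X, self.Y])

    def centered(self) -> "ExpressionPair":
        """Return a copy with each gene (column) mean-centered."""
        return ExpressionPair(
            self.X - self.X.mean(axis=0),
            self.Y - self.Y.mean(axis=0),
            cell_ids=self.cell_ids,
            control_ids=self.control_ids,
            target_ids=self.target_ids,
        )

    def is_centered(self, tol: float = 1e-8) -> bool:
        return (
            np.abs(self.X.mean(axis=0)).max() < tol
            and np.abs(self.Y.mean(axis=0)).max() < tol
        )

    @classmethod
    def from_counts(cls, counts, n_controls=None, control_ids=None,
                    gene_ids=None, cell_ids=None):
        """Build a centered pair from a count matrix via log(c + 1).

        Either the first ``n_controls`` columns are taken as controls, or
        ``control_ids`` selects them by name from ``gene_ids``.
        """
        counts = np.asarray(counts, dtype=float)
        n, g = counts.shape
        if gene_ids is None:
            gene_ids = np.array([f"gene{i}" for i in range(g)], dtype=object)
        else:
            gene_ids = np.asarray(gene_ids, dtype=object)
        if control_ids is not None:
            control_ids = [str(c) for c in control_ids]
            is_control = np.isin(gene_ids.astype(str), control_ids)
            if not is_control.any():
                raise ValueError("no control genes found in gene_ids")
        elif n_controls is not None:
            is_control = np.zeros(g, dtype=bool)
            is_control[:n_controls] = True
        else:
            raise ValueError("provide n_controls or control_ids")
        logged = np.log1p(counts)
        logged = logged - logged.mean(axis=0)
        return cls(
            logged[:, is_control],
            logged[:, ~is_control],
            cell_ids=cell_ids,
            control_ids=gene_ids[is_control],
            target_ids=gene_ids[~is_control],
        )


@dataclass
class ScplsParams:
    """Model parameters: loading matrices and diagonal residual variances.

    ``Lambda_x`` is q × kz, ``Lambda_y`` p × kz, ``Lambda_u`` p × ku;
    ``psi_x``/``psi_y`` are per-gene residual variances (constant across
    cells).  ``kz = 0`` and/or ``ku = 0`` are permitted degenerate models.
    """

    Lambda_x: np.ndarray
    Lambda_y: np.ndarray
    Lambda_u: np.ndarray
    psi_x: np.ndarray
    psi_y: np.ndarray

    def __post_init__(self):
        self.Lambda_x = np.atleast_2d(np.asarray(self.Lambda_x, dtype=float))
        self.Lambda_y = np.atleast_2d(np.asarray(self.Lambda_y, dtype=float))
        self.Lambda_u = np.atleast_2d(np.asarray(self.Lambda_u, dtype=float))
        self.psi_x = np.asarray(self.psi_x, dtype=float).ravel()
        self.psi_y = np.asarray(self.psi_y, dtype=float).ravel()
        q, kz = self.Lambda_x.shape
        p, kz2 = self.Lambda_y.shape
        p2, ku = self.Lambda_u.shape
        # empty loading matrices may come in as (1, 0) from atleast_2d
        if kz == 0 and kz2 != 0:
            self.Lambda_x = np.zeros((self.psi_x.size, 0))
        if kz2 == 0 and kz != 0:
            self.Lambda_y = np.zeros((self.psi_y.size, 0))
        if ku == 0 and p2 != self.psi_y.size:
            self.Lambda_u = np.zeros((self.psi_y.size, 0))
        q, kz = self.Lambda_x.shape
        p, kz2 = self.Lambda_y.shape
        p2, ku = self.Lambda_u.shape
        if kz != kz2:
            raise InvalidParameterError(
                f"Lambda_x and Lambda_y disagree on kz: {kz} != {kz2}"
            )
        if p != p2:
            raise InvalidParameterError(
                f"Lambda_y and Lambda_u disagree on p: {p} != {p2}"
            )
        if self.psi_x.shape != (q,) or self.psi_y.shape != (p,):
            raise InvalidParameterError("psi shapes inconsistent with loadings")
        for arr in (self.Lambda_x, self.Lambda_y, self.Lambda_u,
                    self.psi_x, self.psi_y):
            if not np.isfinite(arr).all():
                raise InvalidParameterError("non-finite parameter entries")
        if (self.psi_x < VARIANCE_FLOOR - 1e-12).any() or (
            self.psi_y < VARIANCE_FLOOR - 1e-12
        ).any():
            raise InvalidParameterError(
                f"residual variances below the floor {VARIANCE_FLOOR}"
            )

    @property
    def q(self) -> int:
        return self.Lambda_x.shape[0]

    @property
    def p(self) -> int:
        return self.Lambda_y.shape[0]

    @property
    def kz(self) -> int:
        return self.Lambda_x.shape[1]

    @property
    def ku(self) -> int:
        return self.Lambda_u.shape[1]

    @property
    def k(self) -> int:
        return self.kz + self.ku

    @property
    def B(self) -> np.ndarray:
        """Stacked (q+p) × (kz+ku) loading matrix with the structural zero
        block (controls do not load on u)."""
        top = np.hstack([self.Lambda_x, np.zeros((self.q, self.ku))])
        bottom = np.hstack([self.Lambda_y, self.Lambda_u])
        return np.vstack([top, bottom])

    @property
    def psi(self) -> np.ndarray:
        """Concatenated residual-variance vector, controls first."""
        return np.concatenate([self.psi_x, self.psi_y])

    def n_free_parameters(self) -> int:
        """Free-parameter count used for BIC: both loading matrices, the
        biological loadings, and both variance vectors."""
        return (self.q * self.kz + self.p * self.kz + self.p * self.ku
                + self.p + self.q)


@dataclass
class LatentMoments:
    """Posterior moments of the stacked factors ``v = (z, u)`` given data.

    ``Ev`` is n × (kz+ku) with row i = E(v_i | w_i); ``Vv`` is the shared
    (kz+ku) × (kz+ku) posterior covariance (identical across cells for
    fixed parameters); ``Evv`` materializes the per-cell second moments
    E(v_i v_i^T | w_i) = Vv + Ev_i Ev_i^T on demand.  The first ``kz``
    coordinates correspond to z, the last ``ku`` to u.
    """

    Ev: np.ndarray
    Vv: np.ndarray
    kz: int

    @property
    def Ez(self) -> np.ndarray:
        return self.Ev[:, : self.kz]

    @property
    def Eu(self) -> np.ndarray:
        return self.Ev[:, self.kz:]

    @property
    def Evv(self) -> np.ndarray:
        """n × k × k array of per-cell second moments."""
        return self.Vv[None, :, :] + np.einsum(
            "ia,ib->iab", self.Ev, self.Ev
        )

    def sum_Evv(self) -> np.ndarray:
        """Sum over cells of E(v_i v_i^T | w_i), computed without
        materializing the per-cell array."""
        n = self.Ev.shape[0]
        return n * self.Vv + self.Ev.T @ self.Ev


def assemble_joint_covariance(params: ScplsParams) -> np.ndarray:
    """Marginal covariance of the stacked observation ``w = (x, y)``:
    ``blockdiag(Psi_x, Psi_y) + B B^T``.  Symmetric positive definite for
    valid parameters."""
    B = params.B
    cov = B @ B.T
    cov[np.diag_indices_from(cov)] += params.psi
    return cov


def _capacitance(params: ScplsParams):
    """Cholesky factor of M = I_k + B^T Psi^{-1} B (the k × k capacitance
    matrix of the Woodbury identity), plus Psi^{-1} B."""
    B = params.B
    PiB = B / params.psi[:, None]
    M = B.T @ PiB
    M[np.diag_indices_from(M)] += 1.0
    try:
        chol = linalg.cholesky(M, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - floor prevents this
        raise FloatingPointError(
            "capacitance matrix not positive definite; residual variances "
            f"may have collapsed (min psi = {params.psi.min():.3g})"
        ) from exc
    return chol, PiB


def marginal_loglik(params: ScplsParams, data: ExpressionPair,
                    method: str = "woodbury") -> float:
    """Marginal log-likelihood of the data with the latent factors
    integrated out: each cell's ``w_i`` is MVN(0, Psi + B B^T).

    ``method="woodbury"`` uses the low-rank form (O(n(q+p)k)), the
    default; ``method="dense"`` is the reference path through the
    explicitly assembled covariance.  Both agree to high precision.
    """
    if data.q != params.q or data.p != params.p:
        raise ValueError(
            f"data dimensions (q={data.q}, p={data.p}) do not match "
            f"params (q={params.q}, p={params.p})"
        )
    W = data.W
    n, d = W.shape
    if method == "dense":
        cov = assemble_joint_covariance(params)
        chol = linalg.cholesky(cov, lower=True)
        half = linalg.solve_triangular(chol, W.T, lower=True)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        quad = (half ** 2).sum()
        return float(-0.5 * (n * d * np.log(2 * np.pi) + n * logdet + quad))
    if method != "woodbury":
        raise ValueError(f"unknown method {method!r}")
    psi = params.psi
    if params.k == 0:
        logdet = np.log(psi).sum()
        quad = ((W ** 2) / psi).sum()
        return float(-0.5 * (n * d * np.log(2 * np.pi) + n * logdet + quad))
    chol, PiB = _capacitance(params)
    logdet = np.log(psi).sum() + 2.0 * np.log(np.diag(chol)).sum()
    G = W @ PiB  # n × k, rows B^T Psi^{-1} w_i
    half = linalg.solve_triangular(chol, G.T, lower=True)
    quad = ((W ** 2) / psi).sum() - (half ** 2).sum()
    return float(-0.5 * (n * d * np.log(2 * np.pi) + n * logdet + quad))


def posterior_moments(params: ScplsParams, data: ExpressionPair) -> LatentMoments:
    """Posterior mean and covariance of ``v_i = (z_i, u_i)`` given
    ``w_i`` by Gaussian conditioning.

    With standard-normal factor priors the posterior covariance is
    ``Vv = (I + B^T Psi^{-1} B)^{-1}`` (shared across cells) and the
    posterior mean ``E(v_i|w_i) = Vv B^T Psi^{-1} w_i`` — the familiar
    low-rank form of ``B^T (Psi + B B^T)^{-1} w_i``.
    """
    if data.q != params.q or data.p != params.p:
        raise ValueError("data dimensions do not match params")
    k = params.k
    if k == 0:
        return LatentMoments(np.zeros((data.n, 0)), np.zeros((0, 0)), 0)
    chol, PiB = _capacitance(params)
    eye = np.eye(k)
    Vv = linalg.cho_solve((chol, True), eye)
    Vv = 0.5 * (Vv + Vv.T)
    Ev = (data.W @ PiB) @ Vv.T
    return LatentMoments(Ev=Ev, Vv=Vv, kz=params.kz)


class ScPLS:
    """Joint latent-factor model over control and target genes.

    The model infers hidden confounding factors from both gene sets
    while shielding structured biological variation in the targets, and
    removes the confounding component from the target genes.

    Parameters
    ----------
    data : ExpressionPair
        Centered control/target expression.  Pass ``center=True`` (the
        default) to center in the constructor.

    Examples
    --------
    >>> pair = ExpressionPair.from_counts(counts, control_ids=spikeins,
    ...                                   gene_ids=genes)     # doctest: +SKIP
    >>> res = ScPLS(pair).fit(kz=2, ku=5, seed=0)             # doctest: +SKIP
    >>> cleaned = res.corrected_Y                             # doctest: +SKIP
    """

    def __init__(self, data: ExpressionPair, center: bool = True):
        if not isinstance(data, ExpressionPair):
            raise TypeError("data must be an ExpressionPair")
        self.data = data.centered() if center and not data.is_centered() else data

    @classmethod
    def from_dataframe(cls, frame, control_ids, center: bool = True):
        """Build the model from a cells × genes DataFrame and a list of
        control gene names (the remaining columns become targets)."""
        control_ids = [str(c) for c in control_ids]
        cols = frame.columns.astype(str)
        is_control = cols.isin(control_ids)
        if not is_control.any():
            raise ValueError("none of the control genes are in the frame")
        pair = ExpressionPair(
            frame.loc[:, is_control].to_numpy(dtype=float),
            frame.loc[:, ~is_control].to_numpy(dtype=float),
            cell_ids=frame.index.to_numpy(dtype=object),
            control_ids=cols[is_control].to_numpy(dtype=object),
            target_ids=cols[~is_control].to_numpy(dtype=object),
        )
        return cls(pair, center=center)

    # -- delegation to the inference machinery (scpls.em) ---------------

    def loglik(self, params: ScplsParams, method: str = "woodbury") -> float:
        return marginal_loglik(params, self.data, method=method)

    def posterior(self, params: ScplsParams) -> LatentMoments:
        return posterior_moments(params, self.data)

    def fit(self, kz: int, ku: int, method: str = "naive",
            chunk_size: int = 500, tol: float = 1e-4, max_iter: int = 500,
            seed: int = 0):
        """Fit by EM at fixed factor counts.

        ``method="naive"`` runs the exact EM; ``method="chunks"`` the
        chunked E-step variant (target genes randomly partitioned into
        ``ceil(p / chunk_size)`` chunks, posterior moments averaged
        across chunks).  Returns a :class:`~scpls.em.ScPLSResults`.
        """
        from . import em

        if method == "naive":
            return em.fit_naive(self.data, kz, ku, tol=tol,
                                max_iter=max_iter, seed=seed)
        if method == "chunks":
            return em.fit_chunks(self.data, kz, ku, chunk_size=chunk_size,
                                 tol=tol, max_iter=max_iter, seed=seed)
        raise ValueError(f"unknown method {method!r}")

    def select(self, kz_grid=(1, 2, 3), ku_grid=tuple(range(1, 11)),
               **fit_kwargs):
        """Fit over a (kz, ku) grid and return the minimum-BIC fit."""
        from . import em

        return em.select_model(self.data, kz_grid, ku_grid, **fit_kwargs)
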