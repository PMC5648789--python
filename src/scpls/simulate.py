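"""Synthetic scRNA-seq data with known confounding structure.

The generator produces two equal-sized cell groups whose signature is a
set of differentially expressed (DE) target genes, overlays Gaussian
confounding factors (loading on both control and target genes) and
structured biological factors (targets only), converts the continuous
values to over-dispersed counts through a Poisson observation model, and
optionally adds logistic dropout.  Three scenarios cover the cases of
confounding independent of the groups (I), confounding correlated with
the groups (II), and no structured biological variation at all (III).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .model import ExpressionPair

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "simulate_continuous",
    "apply_pde",
    "to_counts",
    "apply_dropout",
    "log_center",
    "simulate_dataset",
    "write_simulation",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulation.

    Defaults: 200 cells in two equal groups; 50 control and 1000 target
    genes of which 200 are DE with the group label explaining 20% of
    each DE gene's variance; kz=2 confounding and ku=5 biological
    factors with loading elements from N(-0.25, 0.4) (controls),
    N(0.25, 0.4) (targets) and N(0, 0.6) (biological); unit residual
    variance; Poisson conversion with library size 500000 and baseline
    log-mean log(10/500000) so a gene at w=0 averages 10 reads.

    ``loading_mode="raw"`` draws loadings exactly as above;
    ``"target_pve"`` rescales each loading matrix so the confounding
    component averages 20% of variance (controls and targets) and the
    biological component 30% (targets) — the nominal shares, which the
    raw variances do not exactly imply at ku=5.
    """

    n_cells: int = 200
    q_controls: int = 50
    p_targets: int = 1000
    n_de: int = 200
    pve_de: float = 0.20
    kz: int = 2
    ku: int = 5
    sigma2_l: float = 0.4
    sigma2_b: float = 0.6
    scenario: str = "I"
    lib_size: float = 500000.0
    mu: float = math.log(10.0 / 500000.0)
    dropout: bool = False
    dropout_link: int = -1
    pde: Optional[float] = None
    loading_mode: str = "raw"
    seed: int = 0

    def __post_init__(self):
        if self.n_de > self.p_targets:
            raise ValueError("n_de cannot exceed p_targets")
        if self.n_cells % 2 != 0:
            raise ValueError("n_cells must be even (two equal groups)")
        if self.scenario not in {"I", "II", "III"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0 < self.pve_de < 1):
            raise ValueError("pve_de must be in (0, 1)")
        if self.sigma2_l <= 0 or self.sigma2_b < 0:
            raise ValueError("loading variances must be positive")
        if self.pde is not None and not (0 < self.pde <= 1):
            raise ValueError("pde must be in (0, 1]")
        if self.loading_mode not in {"raw", "target_pve"}:
            raise ValueError(f"unknown loading_mode {self.loading_mode!r}")
        if self.dropout_link not in {-1, 1}:
            raise ValueError("dropout_link must be +1 or -1")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset.

    ``W`` holds the continuous (log-scale) expression, controls first;
    ``counts`` and ``dropout_mask`` are filled once the Poisson / dropout
    stages have run.  ``beta`` is nonzero only at ``de_flags``.
    """

    config: SimConfig
    labels: np.ndarray          # n, group 0/1 (equal sizes)
    de_flags: np.ndarray        # p, bool
    beta: np.ndarray            # p, DE effect sizes (0 for non-DE)
    Z: np.ndarray               # n × kz
    U: np.ndarray               # n × ku
    Lambda_x: np.ndarray        # q × kz
    Lambda_y: np.ndarray        # p × kz
    Lambda_u: np.ndarray        # p × ku
    W: np.ndarray               # n × (q + p)
    counts: Optional[np.ndarray] = None
    dropout_mask: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def q(self) -> int:
        return self.Lambda_x.shape[0]

    @property
    def p(self) -> int:
        return self.Lambda_y.shape[0]

    @property
    def W_controls(self) -> np.ndarray:
        return self.W[:, : self.q]

    @property
    def W_targets(self) -> np.ndarray:
        return self.W[:, self.q:]

    def target_variances(self) -> np.ndarray:
        """Theoretical per-target-gene variance: DE term (group coding
        ±1/2 contributes beta²/4) + confounding + biological + unit
        residual."""
        return (
            0.25 * self.beta ** 2
            + (self.Lambda_y ** 2).sum(axis=1)
            + (self.Lambda_u ** 2).sum(axis=1)
            + 1.0
        )

    def true_pve_confounding(self) -> np.ndarray:
        """Per-target-gene share of variance from the confounding
        component, against the gene's total theoretical variance."""
        return (self.Lambda_y ** 2).sum(axis=1) / self.target_variances()


def simulate_continuous(config: SimConfig) -> SimulationTruth:
    """Draw the continuous (log-scale) expression matrix.

    DE effect sizes are drawn from a standard normal and rescaled per
    gene so the group label explains ``pve_de`` of that gene's total
    variance.  Scenario II shifts the mean of every confounding-factor
    element by -0.25 for group-2 cells; scenario III drops the
    biological factors entirely.
    """
    rng = np.random.default_rng(config.seed)
    n, q, p = config.n_cells, config.q_controls, config.p_targets
    kz = config.kz
    ku = 0 if config.scenario == "III" else config.ku

    labels = np.repeat([0, 1], n // 2)
    s = labels - 0.5  # centered group coding, variance 1/4

    Z = rng.standard_normal((n, kz))
    if config.scenario == "II":
        Z[labels == 1] -= 0.25
    U = rng.standard_normal((n, ku))

    Lambda_x = rng.normal(-0.25, math.sqrt(config.sigma2_l), size=(q, kz))
    Lambda_y = rng.normal(0.25, math.sqrt(config.sigma2_l), size=(p, kz))
    Lambda_u = rng.normal(0.0, math.sqrt(config.sigma2_b), size=(p, ku))

    if config.loading_mode == "target_pve":
        # rescale so the average confounding share is 20% (both sets)
        # and the biological share 30% (targets), with unit residuals
        Lambda_x *= _pve_scale(Lambda_x, 0.25)
        Lambda_y *= _pve_scale(Lambda_y, 0.40)
        Lambda_u *= _pve_scale(Lambda_u, 0.60)

    de_flags = np.zeros(p, dtype=bool)
    de_flags[rng.choice(p, size=config.n_de, replace=False)] = True
    beta = np.zeros(p)
    raw = rng.standard_normal(config.n_de)
    base_var = (
        (Lambda_y[de_flags] ** 2).sum(axis=1)
        + (Lambda_u[de_flags] ** 2).sum(axis=1)
        + 1.0
    )
    # beta^2/4 = pve_de/(1-pve_de) * base_var per gene; keep the drawn sign
    magnitude = np.sqrt(4.0 * config.pve_de / (1.0 - config.pve_de) * base_var)
    beta[de_flags] = np.sign(raw) * magnitude

    Wx = Z @ Lambda_x.T + rng.standard_normal((n, q))
    Wy = (
        np.outer(s, beta)
        + Z @ Lambda_y.T
        + U @ Lambda_u.T
        + rng.standard_normal((n, p))
    )
    return SimulationTruth(
        config=config, labels=labels, de_flags=de_flags, beta=beta,
        Z=Z, U=U, Lambda_x=Lambda_x, Lambda_y=Lambda_y, Lambda_u=Lambda_u,
        W=np.hstack([Wx, Wy]),
    )


def _pve_scale(L: np.ndarray, target_sq_norm: float) -> float:
    if L.size == 0:
        return 1.0
    mean_sq = (L ** 2).sum(axis=1).mean()
    return math.sqrt(target_sq_norm / mean_sq)


def apply_pde(truth: SimulationTruth, pde: float,
              seed: Optional[int] = None) -> SimulationTruth:
    """Subset target genes so the DE genes' share of total theoretical
    target variance is as close as possible to ``pde``.

    All DE genes are retained; non-DE genes are dropped in a seeded
    random order until the retained-count whose variance ratio is
    closest to ``pde``.  ``pde=1`` keeps only the DE genes.
    """
    if not (0 < pde <= 1):
        raise ValueError("pde must be in (0, 1]")
    var = truth.target_variances()
    de = truth.de_flags
    s_de = var[de].sum()
    nonde_idx = np.flatnonzero(~de)
    rng = np.random.default_rng(truth.config.seed if seed is None else seed)
    order = rng.permutation(nonde_idx)
    cum = np.concatenate([[0.0], np.cumsum(var[order])])
    ratios = s_de / (s_de + cum)  # ratio(m) for m = 0..len(order)
    if pde < ratios[-1] - 1e-12:
        raise ValueError(
            f"pde={pde} below the minimum achievable "
            f"{ratios[-1]:.4f} with all non-DE genes retained"
        )
    m = int(np.argmin(np.abs(ratios - pde)))
    keep = np.zeros(truth.p, dtype=bool)
    keep[de] = True
    keep[order[:m]] = True

    q = truth.q
    keep_w = np.concatenate([np.ones(q, dtype=bool), keep])
    return SimulationTruth(
        config=replace(truth.config, pde=pde),
        labels=truth.labels,
        de_flags=truth.de_flags[keep],
        beta=truth.beta[keep],
        Z=truth.Z,
        U=truth.U,
        Lambda_x=truth.Lambda_x,
        Lambda_y=truth.Lambda_y[keep],
        Lambda_u=truth.Lambda_u[keep],
        W=truth.W[:, keep_w],
        counts=None if truth.counts is None else truth.counts[:, keep_w],
        dropout_mask=(None if truth.dropout_mask is None
                      else truth.dropout_mask[:, keep_w]),
    )


def to_counts(W: np.ndarray, N: float = 500000.0,
              mu: float = math.log(10.0 / 500000.0),
              seed: int = 0) -> np.ndarray:
    """Convert continuous values to counts via independent Poisson draws
    with rate ``N * exp(mu + w)`` per entry.

    At ``w = 0`` the rate is exactly ``N * exp(mu)`` (10 reads with the
    defaults).  Residual noise in ``w`` makes the marginal counts
    over-dispersed relative to a Poisson.
    """
    W = np.asarray(W, dtype=float)
    if not np.isfinite(W).all():
        raise ValueError("continuous matrix must be finite")
    rng = np.random.default_rng(seed)
    rate = N * np.exp(mu + W)
    return rng.poisson(rate)


def apply_dropout(counts: np.ndarray, link_sign: int = -1, seed: int = 0):
    """Zero each count independently with probability
    ``pi = sigmoid(link_sign * c)``.

    The default ``link_sign=-1`` makes dropout rarer for highly
    expressed genes (higher expression, lower dropout); ``+1`` is the
    literal increasing link.  Returns ``(dropped_counts, mask)`` where
    ``mask`` marks entries set to zero.
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be integers")
    if link_sign not in (-1, 1):
        raise ValueError("link_sign must be +1 or -1")
    rng = np.random.default_rng(seed)
    with np.errstate(over="ignore"):
        pi = 1.0 / (1.0 + np.exp(-link_sign * counts.astype(float)))
    mask = rng.random(counts.shape) < pi
    dropped = counts.copy()
    dropped[mask] = 0
    return dropped, mask


def log_center(counts: np.ndarray, n_controls: int,
               cell_ids=None, gene_ids=None) -> ExpressionPair:
    """Transform counts as log(c + 1), center each gene to mean zero,
    and split into control (first ``n_controls`` columns) and target
    blocks."""
    counts = np.asarray(counts, dtype=float)
    logged = np.log1p(counts)
    logged = logged - logged.mean(axis=0)
    if gene_ids is None:
        control_ids = None
        target_ids = None
    else:
        gene_ids = np.asarray(gene_ids, dtype=object)
        control_ids = gene_ids[:n_controls]
        target_ids = gene_ids[n_controls:]
    return ExpressionPair(
        logged[:, :n_controls], logged[:, n_controls:],
        cell_ids=cell_ids, control_ids=control_ids, target_ids=target_ids,
    )


def simulate_dataset(config: SimConfig):
    """Run the full pipeline: continuous draw, optional PDE subsetting,
    Poisson counts, optional dropout, log(c+1) transform and centering.

    Returns ``(truth, pair)`` with all stages recorded on ``truth``.
    Stage seeds are derived from ``config.seed`` so the whole dataset is
    reproducible from the one seed.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]
    truth = simulate_continuous(replace(config, seed=seeds[0]))
    if config.pde is not None:
        truth = apply_pde(truth, config.pde, seed=seeds[0])
    counts = to_counts(truth.W, N=config.lib_size, mu=config.mu,
                       seed=seeds[1])
    if config.dropout:
        counts, mask = apply_dropout(counts, link_sign=config.dropout_link,
                                     seed=seeds[2])
        truth.dropout_mask = mask
    truth.counts = counts
    pair = log_center(counts, truth.q)
    return truth, pair


def write_simulation(truth: SimulationTruth, outdir) -> None:
    """Write the counts and truth tables as TSVs (counts also as MTX)
    plus a flat key=value config snapshot."""
    import pandas as pd
    from scipy import io as spio
    from scipy import sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    q, p = truth.q, truth.p
    gene_ids = [f"control{i}" for i in range(q)] + [
        f"target{i}" for i in range(p)
    ]
    cell_ids = [f"cell{i}" for i in range(truth.n)]
    if truth.counts is not None:
        counts = pd.DataFrame(truth.counts, index=cell_ids, columns=gene_ids)
        counts.to_csv(outdir / "counts.tsv", sep="\t")
        spio.mmwrite(outdir / "counts.mtx",
                     sparse.csr_matrix(truth.counts))
        Path(outdir / "counts.mtx.rows").write_text(
            "\n".join(cell_ids) + "\n")
        Path(outdir / "counts.mtx.cols").write_text(
            "\n".join(gene_ids) + "\n")
    pd.DataFrame(truth.W, index=cell_ids, columns=gene_ids).to_csv(
        outdir / "continuous.tsv", sep="\t")
    pd.DataFrame({
        "cell": cell_ids, "group": truth.labels,
    }).to_csv(outdir / "cells.tsv", sep="\t", index=False)
    pd.DataFrame({
        "gene": gene_ids[q:], "de": truth.de_flags.astype(int),
        "beta": truth.beta,
        "pve_confounding_true": truth.true_pve_confounding(),
    }).to_csv(outdir / "target_truth.tsv", sep="\t", index=False)
    for name, mat in (("Lambda_x", truth.Lambda_x),
                      ("Lambda_y", truth.Lambda_y),
                      ("Lambda_u", truth.Lambda_u)):
        np.savetxt(outdir / f"{name}.tsv", mat, delimiter="\t")
    Path(outdir / "controls.txt").write_text("\n".join(gene_ids[:q]) + "\n")
    cfg = truth.config
    lines = [f"{k}={getattr(cfg, k)}" for k in cfg.__dataclass_fields__]
    Path(outdir / "config.txt").write_text("\n".join(lines) + "\n")
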