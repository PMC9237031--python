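"""Beta-uniform mixture (BUM) modelling of p-values and node scoring.

The observed p-value distribution from a differential-expression analysis is
modelled as a two-component mixture of uniform noise and a Beta(a, 1) signal
component:

    f(x) = lambda + (1 - lambda) * a * x**(a - 1),   x in (0, 1],  0 < a < 1

where ``lambda`` is the mixing weight of the uniform (noise) component.  The
density of the signal component decreases in x, so small p-values carry
evidence of true signal.  Given a significance threshold ``tau`` (by default
the Bonferroni-adjusted level 0.05 / #genes), every gene is scored with the
log signal-to-noise ratio of its p-value relative to the threshold,

    s(x) = (a - 1) * (ln x - ln tau)

which is zero at ``x = tau``, positive below it and negative above it, and —
being a log ratio — additive across genes.  These scores weight the nodes of
a protein-protein interaction network for the maximum-weight connected
subgraph search in :mod:`ppimodules.mwcs`.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import optimize, special

from ._rng import as_rng
from .io import GeneTable

logger = logging.getLogger(__name__)

__all__ = [
    "BumFit",
    "NodeScores",
    "fit_bum",
    "bum_density",
    "bum_log_likelihood",
    "bonferroni_threshold",
    "score_nodes",
    "score_pvalues",
]

# Mixture parameters are kept strictly inside the open unit interval so the
# density stays finite and the score stays defined.
_EPS = 1e-4


@dataclasses.dataclass(frozen=True)
class BumFit:
    """Maximum-likelihood fit of the beta-uniform mixture.

    Attributes
    ----------
    lambda_mix
        Weight of the uniform (noise) component, in (0, 1).
    alpha
        Shape of the Beta(alpha, 1) signal component, in (0, 1).
    n_obs
        Number of p-values fitted.
    log_likelihood
        Maximised log-likelihood.
    """

    lambda_mix: float
    alpha: float
    n_obs: int
    log_likelihood: float

    @property
    def pi0_upper(self) -> float:
        """Upper bound on the noise fraction, f(1) = lambda + (1-lambda)*alpha."""
        return self.lambda_mix + (1.0 - self.lambda_mix) * self.alpha

    def density(self, x) -> np.ndarray:
        return bum_density(x, self)

    def to_dict(self) -> dict:
        return {
            "lambda_mix": self.lambda_mix,
            "alpha": self.alpha,
            "n_obs": self.n_obs,
            "log_likelihood": self.log_likelihood,
            "pi0_upper": self.pi0_upper,
        }


@dataclasses.dataclass(frozen=True)
class NodeScores:
    """Per-gene additive scores around the threshold ``tau``."""

    tau: float
    alpha_used: float
    scores: dict[str, float]

    def __len__(self) -> int:
        return len(self.scores)

    def array_for(self, genes) -> np.ndarray:
        return np.array([self.scores[g] for g in genes], dtype=float)


def bum_density(x, fit_or_params) -> np.ndarray | float:
    """Evaluate the mixture density f(x) = lambda + (1-lambda)*alpha*x**(alpha-1).

    ``fit_or_params`` is a :class:`BumFit` or a ``(lambda_mix, alpha)`` pair.
    Raises on x outside (0, 1].
    """
    if isinstance(fit_or_params, BumFit):
        lam, alpha = fit_or_params.lambda_mix, fit_or_params.alpha
    else:
        lam, alpha = fit_or_params
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x > 1):
        raise ValueError("density is defined on (0, 1]")
    out = lam + (1.0 - lam) * alpha * x ** (alpha - 1.0)
    return float(out) if out.ndim == 0 else out


def bum_log_likelihood(p_values: np.ndarray, lambda_mix: float, alpha: float) -> float:
    """Log-likelihood of the mixture at fixed parameters."""
    p = np.asarray(p_values, dtype=float)
    # log(lam + (1-lam)*a*x**(a-1)) computed stably via logaddexp
    log_signal = np.log1p(-lambda_mix) + np.log(alpha) + (alpha - 1.0) * np.log(p)
    return float(np.logaddexp(np.log(lambda_mix), log_signal).sum())


def _nll(z: np.ndarray, logp: np.ndarray) -> float:
    # z = (logit lambda, logit alpha), both squashed into (_EPS, 1-_EPS)
    lam = _EPS + (1 - 2 * _EPS) * special.expit(z[0])
    alpha = _EPS + (1 - 2 * _EPS) * special.expit(z[1])
    log_signal = np.log1p(-lam) + np.log(alpha) + (alpha - 1.0) * logp
    return -float(np.logaddexp(np.log(lam), log_signal).sum())


def fit_bum(
    p_values,
    n_starts: int = 8,
    seed=None,
    min_n: int = 100,
    force: bool = False,
) -> BumFit:
    """Fit the beta-uniform mixture to p-values by multi-start maximum likelihood.

    The likelihood can be multimodal when signal is weak, so the optimiser is
    run from a fixed grid of starting points plus seeded random starts and
    the best converged solution is returned.  Deterministic given ``seed``.

    Parameters
    ----------
    p_values
        Observed p-values, all strictly in (0, 1].  Fewer than ``min_n``
        observations is refused (the fit is unstable) unless ``force=True``.
    n_starts
        Total number of optimiser starts.
    seed
        Seed for the random starts.

    Returns
    -------
    BumFit
        Maximum-likelihood ``(lambda_mix, alpha)`` with diagnostics.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("all p-values must lie in (0, 1]")
    if p.size < min_n:
        msg = f"only {p.size} p-values (< {min_n}); the mixture fit is unreliable"
        if not force:
            raise ValueError(msg + "; pass force=True to fit anyway")
        warnings.warn(msg, stacklevel=2)
    if np.all(p == p[0]):
        raise ValueError("degenerate input: all p-values are identical")

    logp = np.log(p)
    rng = as_rng(seed)

    # Fixed low-discrepancy starts first, then seeded random starts.
    grid = [(0.2, 0.2), (0.2, 0.7), (0.5, 0.45), (0.8, 0.2), (0.8, 0.7), (0.95, 0.9)]
    starts = grid[: min(n_starts, len(grid))]
    while len(starts) < n_starts:
        starts.append(tuple(rng.uniform(0.05, 0.95, size=2)))

    best = None
    for lam0, a0 in starts:
        z0 = np.array([special.logit(lam0), special.logit(a0)])
        res = optimize.minimize(_nll, z0, args=(logp,), method="L-BFGS-B")
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("BUM optimisation failed to converge from every start")

    lam = float(_EPS + (1 - 2 * _EPS) * special.expit(best.x[0]))
    alpha = float(_EPS + (1 - 2 * _EPS) * special.expit(best.x[1]))
    return BumFit(
        lambda_mix=lam,
        alpha=alpha,
        n_obs=int(p.size),
        log_likelihood=-float(best.fun),
    )


def bonferroni_threshold(n_genes: int, alpha_level: float = 0.05) -> float:
    """Bonferroni-adjusted significance threshold: ``alpha_level / n_genes``.

    ``n_genes`` is the number of genes expressed (i.e. tested); the returned
    value is the score-zero threshold ``tau`` separating positively and
    negatively scoring genes.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be a positive integer")
    if not (0 < alpha_level <= 1):
        raise ValueError("alpha_level must lie in (0, 1]")
    return alpha_level / n_genes


def score_pvalues(p_values, alpha: float, tau: float) -> np.ndarray:
    """Score p-values as s(x) = (alpha - 1) * (ln x - ln tau).

    Natural logarithms are used; any other base rescales every score by the
    same constant and cannot change which connected subgraph is optimal.
    """
    if not (0 < tau < 1):
        raise ValueError("tau must lie strictly in (0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie strictly in (0, 1)")
    x = np.asarray(p_values, dtype=float)
    if np.any(x <= 0) or np.any(x > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return (alpha - 1.0) * (np.log(x) - np.log(tau))


def score_nodes(table: GeneTable, fit: BumFit, tau: float) -> NodeScores:
    """Convert a gene table's p-values to additive node scores.

    Genes with p below ``tau`` score positive, genes above score negative;
    s(tau) = 0 exactly.
    """
    s = score_pvalues(table.p_values, fit.alpha, tau)
    return NodeScores(
        tau=float(tau),
        alpha_used=float(fit.alpha),
        scores=dict(zip(table.gene_ids.tolist(), s.tolist())),
    )
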