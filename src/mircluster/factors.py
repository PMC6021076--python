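"""Exploratory factor analysis and cluster factor variables.

Provides minimum-residual (minres/ULS) exploratory factor analysis with
oblimin rotation, factor-retention by Horn's parallel analysis combined
with BIC, and the simple row-mean "cluster score" variables used as
predictors in the outcome models.

Minres fits loadings by minimizing the squared off-diagonal residuals of
the correlation matrix: for uniquenesses ψ the reduced matrix R − diag(ψ)
is eigendecomposed, loadings are the scaled top-k eigenvectors, and ψ is
optimized so the residual off-diagonals are as small as possible. Unlike
maximum likelihood it makes no multivariate-normality assumption, which
suits small qPCR panels with pairwise-complete correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .clustering import ClusterMap
from .comatrix import _pairwise_pearson, nearest_positive_definite
from .io_types import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """The minres optimizer failed to converge."""


@dataclass
class FactorSolution:
    """An (optionally oblique) factor solution.

    ``loadings`` is the miRNA × factor pattern matrix;
    ``factor_correlations`` is the factor intercorrelation Φ (identity for
    an unrotated/orthogonal solution). ``fit`` carries BIC, the root mean
    squared off-diagonal residual, model df and the ML chi-square used for
    BIC comparison across candidate dimensions.
    """

    loadings: pd.DataFrame
    n_factors: int
    rotation: str
    factor_correlations: np.ndarray
    uniquenesses: pd.Series
    fit: dict = field(default_factory=dict)

    def dominant_factor(self) -> pd.Series:
        """Index of the factor with the largest |loading| per variable."""
        return pd.Series(
            np.argmax(np.abs(self.loadings.to_numpy()), axis=1),
            index=self.loadings.index,
        )

    def reproduced_correlation(self) -> np.ndarray:
        L = self.loadings.to_numpy()
        return L @ self.factor_correlations @ L.T + np.diag(self.uniquenesses)

    def to_frame(self, cluster_of: dict[str, str] | None = None) -> pd.DataFrame:
        df = self.loadings.copy()
        df.columns = [f"factor{k + 1}" for k in range(self.n_factors)]
        if cluster_of:
            df["assigned_cluster"] = [cluster_of.get(m, "") for m in df.index]
        df["dominant_factor"] = self.dominant_factor() + 1
        return df


@dataclass
class ClusterScores:
    """Row-mean cluster factor variables (sample × cluster).

    Each score is the arithmetic mean of the non-missing −∆CT values of the
    cluster's member miRNAs in that sample, which tolerates sporadically
    undetected miRNAs without imputation.
    """

    sample_ids: list[str]
    cluster_names: list[str]
    scores: np.ndarray
    n_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.sample_ids, columns=self.cluster_names
        )


# ---------------------------------------------------------------------------
# correlation input


def expression_correlation(
    expr: ExpressionMatrix, min_pairs: int = 3, repair: bool = True
) -> np.ndarray:
    """Pairwise-complete correlation matrix of an expression matrix.

    Entries with too few complete pairs are set to 0 with a warning (a
    neutral value that keeps the matrix usable); near-singular matrices are
    repaired to the nearest positive-definite correlation matrix.
    """
    R, _ = _pairwise_pearson(expr.dct, min_pairs)
    bad = ~np.isfinite(R)
    if bad.any():
        logger.warning(
            "%d correlation entries had <%d complete pairs; set to 0",
            int(bad.sum()) // 2,
            min_pairs,
        )
        R = np.where(bad, 0.0, R)
        np.fill_diagonal(R, 1.0)
    if repair and np.linalg.eigvalsh(R).min() < 1e-8:
        R = nearest_positive_definite(R)
    return R


# ---------------------------------------------------------------------------
# parallel analysis


def parallel_analysis(
    expr: ExpressionMatrix | np.ndarray,
    n_sim: int = 500,
    quantile: float | None = None,
    seed: int = 0,
    n_samples: int | None = None,
) -> int:
    """Suggested number of factors by Horn's parallel analysis.

    Compares the observed correlation-matrix eigenvalues with eigenvalues
    from ``n_sim`` simulated uncorrelated normal datasets of identical
    dimensions. ``quantile=None`` uses the classic mean-eigenvalue
    threshold; e.g. 0.95 uses the 95th percentile. Accepts either an
    expression matrix or a precomputed correlation matrix (then
    ``n_samples`` is required).
    """
    if isinstance(expr, ExpressionMatrix):
        R = expression_correlation(expr)
        n = expr.n_samples
    else:
        R = np.asarray(expr, dtype=float)
        if n_samples is None:
            raise ValidationError("n_samples required with a precomputed matrix")
        n = n_samples
    p = R.shape[0]
    if n_sim < 50:
        logger.warning("n_sim=%d < 50: parallel-analysis thresholds unstable", n_sim)
    observed = np.sort(np.linalg.eigvalsh(R))[::-1]
    rng = np.random.default_rng(seed)
    sim_eigs = np.empty((n_sim, p))
    for b in range(n_sim):
        x = rng.standard_normal((n, p))
        sim_eigs[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    if quantile is None:
        thresholds = sim_eigs.mean(axis=0)
    else:
        thresholds = np.quantile(sim_eigs, quantile, axis=0)
    above = observed > thresholds
    # count the leading run: a later eigenvalue above threshold after a
    # failure does not add an interpretable factor
    k = 0
    for flag in above:
        if not flag:
            break
        k += 1
    return k


# ---------------------------------------------------------------------------
# minres EFA


def _minres_objective(psi: np.ndarray, R: np.ndarray, k: int) -> float:
    p = R.shape[0]
    Rr = R.copy()
    Rr[np.diag_indices(p)] = 1.0 - psi
    w, V = np.linalg.eigh(Rr)
    w, V = w[::-1][:k], V[:, ::-1][:, :k]
    L = V * np.sqrt(np.clip(w, 0, None))
    resid = R - L @ L.T
    resid[np.diag_indices(p)] = 0.0
    return float(np.sum(resid**2))


def _minres_loadings(psi: np.ndarray, R: np.ndarray, k: int) -> np.ndarray:
    p = R.shape[0]
    Rr = R.copy()
    Rr[np.diag_indices(p)] = 1.0 - psi
    w, V = np.linalg.eigh(Rr)
    w, V = w[::-1][:k], V[:, ::-1][:, :k]
    return V * np.sqrt(np.clip(w, 0, None))


def _ml_fit_stats(R: np.ndarray, L: np.ndarray, psi: np.ndarray, n: int) -> dict:
    """ML discrepancy-based chi-square/BIC for comparing factor counts."""
    p, k = L.shape
    Sigma = L @ L.T + np.diag(np.clip(psi, 1e-6, None))
    sign, logdet_s = np.linalg.slogdet(Sigma)
    _, logdet_r = np.linalg.slogdet(R)
    f_ml = float(logdet_s - logdet_r + np.trace(R @ np.linalg.inv(Sigma)) - p)
    f_ml = max(f_ml, 0.0)
    dof = ((p - k) ** 2 - (p + k)) // 2
    correction = n - 1 - (2 * p + 5) / 6 - (2 * k) / 3
    chi2 = max(correction, 1.0) * f_ml
    bic = chi2 - dof * np.log(n)
    return {"chi2_ml": chi2, "dof": dof, "bic": bic}


def fit_efa(
    expr: ExpressionMatrix | np.ndarray,
    n_factors: int,
    method: str = "minres",
    rotation: str = "oblimin",
    n_samples: int | None = None,
    max_iter: int = 1000,
) -> FactorSolution:
    """Minimum-residual EFA with optional oblimin rotation.

    Sign indeterminacy is resolved deterministically: each factor is flipped
    so its largest-magnitude loading is positive.
    """
    if method != "minres":
        raise ValidationError(f"unsupported method {method!r}")
    if isinstance(expr, ExpressionMatrix):
        R = expression_correlation(expr)
        n = expr.n_samples
        var_ids = list(expr.mirna_ids)
    else:
        R = np.asarray(expr, dtype=float)
        if n_samples is None:
            raise ValidationError("n_samples required with a precomputed matrix")
        n = n_samples
        var_ids = [f"v{i}" for i in range(R.shape[0])]
    p = R.shape[0]
    if not 1 <= n_factors < p:
        raise ValidationError(f"n_factors must be in [1, {p - 1}]")

    # start at 1 − SMC (squared multiple correlation), the standard start
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 0.005, 1.0)
    res = optimize.minimize(
        _minres_objective,
        psi0,
        args=(R, n_factors),
        method="L-BFGS-B",
        bounds=[(0.001, 1.0)] * p,
        options={"maxiter": max_iter},
    )
    if not res.success and res.fun > 1e-4:
        raise ConvergenceError(
            f"minres failed after {res.nit} iterations: {res.message} "
            f"(objective {res.fun:.3e})"
        )
    psi = res.x
    L = _minres_loadings(psi, R, n_factors)

    Phi = np.eye(n_factors)
    if rotation == "oblimin" and n_factors > 1:
        from statsmodels.multivariate.factor_rotation import rotate_factors

        L_rot, T = rotate_factors(L, "oblimin", 0.0, "oblique")
        L, Phi = L_rot, T.T @ T
    elif rotation not in ("oblimin", "none"):
        raise ValidationError(f"unsupported rotation {rotation!r}")

    # deterministic sign convention
    for k in range(n_factors):
        j = int(np.argmax(np.abs(L[:, k])))
        if L[j, k] < 0:
            L[:, k] = -L[:, k]
            Phi[k, :] *= -1
            Phi[:, k] *= -1
    np.fill_diagonal(Phi, 1.0)

    resid = R - (L @ Phi @ L.T + np.diag(psi))
    off = resid[~np.eye(p, dtype=bool)]
    fit = {
        "rmsr": float(np.sqrt(np.mean(off**2))),
        "objective": float(res.fun),
        "n_iter": int(res.nit),
        **_ml_fit_stats(R, _minres_loadings(psi, R, n_factors), psi, n),
    }
    return FactorSolution(
        loadings=pd.DataFrame(
            L, index=var_ids, columns=[f"F{k + 1}" for k in range(n_factors)]
        ),
        n_factors=n_factors,
        rotation=rotation if n_factors > 1 else "none",
        factor_correlations=Phi,
        uniquenesses=pd.Series(psi, index=var_ids),
        fit=fit,
    )


def select_n_factors(
    expr: ExpressionMatrix,
    n_sim: int = 500,
    quantile: float | None = None,
    seed: int = 0,
) -> tuple[int, dict]:
    """Combine parallel analysis with BIC to choose the dimension.

    Rule: take the parallel-analysis count unless the BIC of a neighbouring
    dimension (PA−1 or PA+1) is strictly lower; the full decision trail is
    returned for logging.
    """
    pa = parallel_analysis(expr, n_sim=n_sim, quantile=quantile, seed=seed)
    candidates = sorted(
        {k for k in (pa - 1, pa, pa + 1) if 1 <= k < expr.n_mirnas}
    )
    bics = {}
    for k in candidates:
        try:
            bics[k] = fit_efa(expr, k, rotation="none").fit["bic"]
        except (ConvergenceError, np.linalg.LinAlgError):
            bics[k] = np.inf
    chosen = max(pa, 1)
    if bics:
        best = min(bics, key=lambda k: bics[k])
        if chosen not in bics or bics[best] < bics.get(chosen, np.inf):
            chosen = best
    detail = {"parallel_analysis": pa, "bic": bics, "chosen": chosen}
    logger.info("factor dimension: %s", detail)
    return chosen, detail


# ---------------------------------------------------------------------------
# cluster factor variables


def cluster_scores(
    expr: ExpressionMatrix,
    cluster_map: ClusterMap,
    clusters: Sequence[str] | None = None,
) -> ClusterScores:
    """Row-mean cluster factor variables.

    ``scores[s, c]`` is the mean of the non-missing −∆CT values of cluster
    c's members in sample s (missing only when no member was observed).
    """
    names = list(clusters) if clusters is not None else cluster_map.cluster_names()
    n_s = expr.n_samples
    scores = np.full((n_s, len(names)), np.nan)
    n_used = np.zeros((n_s, len(names)), dtype=int)
    for c, name in enumerate(names):
        members = [m for m in cluster_map.members(name) if m in expr.mirna_ids]
        if not members:
            logger.warning("cluster %s has no members in the expression matrix", name)
            continue
        idx = [expr.mirna_ids.index(m) for m in members]
        block = expr.dct[:, idx]
        obs = np.isfinite(block)
        n_used[:, c] = obs.sum(axis=1)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(np.where(obs, block, np.nan), axis=1)
        scores[:, c] = np.where(n_used[:, c] > 0, means, np.nan)
    return ClusterScores(
        sample_ids=list(expr.sample_ids),
        cluster_names=names,
        scores=scores,
        n_used=n_used,
    )
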