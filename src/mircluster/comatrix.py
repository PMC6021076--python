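"""Group-wise correlation-structure analysis of miRNA clusters.

Builds cluster-ordered Pearson correlation matrices per pregnancy group,
tests equality of the term and PTB matrices with the Jennrich chi-square
test, extracts within-cluster and between-cluster coefficient sets, and
compares those sets between groups by one-way ANOVA.

The Jennrich statistic for two correlation matrices R1, R2 estimated from
independent samples of sizes n1, n2 is::

    R̄ = (n1·R1 + n2·R2) / (n1 + n2)
    c  = n1·n2 / (n1 + n2)
    Z  = √c · R̄⁻¹ (R1 − R2)
    S  = I + R̄ ∘ R̄⁻¹          (elementwise product)
    χ² = ½·tr(Z²) − diag(Z)ᵀ S⁻¹ diag(Z)

distributed as chi-square with p(p−1)/2 degrees of freedom under equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterMap
from .io_types import ExpressionMatrix, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_PAIRS = 10


class NumericalError(ArithmeticError):
    """A required matrix inverse does not exist (with diagnostics)."""


@dataclass
class GroupCorrelation:
    """Cluster-ordered Pearson correlation matrix for one sample group."""

    group: str
    mirna_ids: list[str]
    R: np.ndarray
    n_pairs: np.ndarray
    n_nominal: int
    cluster_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        p = len(self.mirna_ids)
        if self.R.shape != (p, p):
            raise ValidationError("R shape does not match mirna_ids")
        finite = np.isfinite(self.R)
        if np.any(np.abs(self.R[finite]) > 1 + 1e-12):
            raise ValidationError("|r| > 1 in correlation matrix")

    def submatrix(self, mirnas: Sequence[str]) -> np.ndarray:
        idx = [self.mirna_ids.index(m) for m in mirnas]
        return self.R[np.ix_(idx, idx)]


@dataclass
class AnovaComparison:
    """One Fig-2-style region comparison of term vs PTB coefficient sets."""

    region_a: str
    region_b: str
    F: float
    df1: int
    df2: int
    p_value: float
    mean_r_term: float
    mean_r_ptb: float
    n_term: int
    n_ptb: int


@dataclass
class JennrichResult:
    region: str
    chi2: float
    df: int
    p_value: float
    n1: int
    n2: int
    pd_repaired: bool = False


@dataclass
class MatrixComparison:
    """Full two-group correlation-structure comparison report."""

    jennrich: list[JennrichResult]
    anova_results: list[AnovaComparison]
    n1: int
    n2: int

    def anova_frame(self) -> pd.DataFrame:
        rows = []
        m = len(self.anova_results)
        for a in self.anova_results:
            rows.append(
                {
                    "region_a": a.region_a,
                    "region_b": a.region_b,
                    "F": a.F,
                    "df1": a.df1,
                    "df2": a.df2,
                    "p": a.p_value,
                    "p_bonferroni": min(1.0, a.p_value * m),
                    "mean_r_term": a.mean_r_term,
                    "mean_r_ptb": a.mean_r_ptb,
                }
            )
        return pd.DataFrame(rows)

    def jennrich_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": [j.region for j in self.jennrich],
                "chi2": [j.chi2 for j in self.jennrich],
                "df": [j.df for j in self.jennrich],
                "p": [j.p_value for j in self.jennrich],
                "pd_repaired": [j.pd_repaired for j in self.jennrich],
            }
        )


# ---------------------------------------------------------------------------
# correlation matrices


def _pairwise_pearson(
    x: np.ndarray, min_pairs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson correlation with per-entry pair counts."""
    n, p = x.shape
    obs = np.isfinite(x)
    R = np.full((p, p), np.nan)
    n_pairs = np.zeros((p, p), dtype=int)
    for i in range(p):
        R[i, i] = 1.0
        n_pairs[i, i] = int(obs[:, i].sum())
        for j in range(i + 1, p):
            mask = obs[:, i] & obs[:, j]
            k = int(mask.sum())
            n_pairs[i, j] = n_pairs[j, i] = k
            if k < max(min_pairs, 3):
                continue
            xi, xj = x[mask, i], x[mask, j]
            sx, sy = xi.std(), xj.std()
            if sx == 0 or sy == 0:
                continue
            r = float(np.corrcoef(xi, xj)[0, 1])
            R[i, j] = R[j, i] = np.clip(r, -1.0, 1.0)
    return R, n_pairs


def correlation_matrix(
    expr: ExpressionMatrix,
    cluster_map: ClusterMap,
    group: str = "all",
    metadata: SampleMetadata | None = None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    clusters: Sequence[str] | None = None,
) -> GroupCorrelation:
    """Cluster-ordered pairwise-complete Pearson matrix for one group.

    Rows/columns follow the cluster map's order (cluster by cluster, members
    in genomic order); only miRNAs present in both ``expr`` and the map are
    used. ``group`` is ``"all"`` or a metadata group label (requires
    ``metadata``).
    """
    if group == "all":
        sample_ids = list(expr.sample_ids)
    else:
        if metadata is None:
            raise ValidationError("metadata required to select a group")
        wanted = set(metadata.group_samples(group))
        sample_ids = [s for s in expr.sample_ids if s in wanted]
    if not sample_ids:
        raise ValidationError(f"group {group!r} matches no samples")
    if len(sample_ids) < 3:
        raise ValidationError(f"group {group!r} has fewer than 3 samples")
    ordered = [m for m in cluster_map.ordered_mirnas(clusters) if m in expr.mirna_ids]
    if not ordered:
        raise ValidationError("no clustered miRNAs present in the expression matrix")
    sub = expr.subset_samples(sample_ids).subset_mirnas(ordered)
    R, n_pairs = _pairwise_pearson(sub.dct, min_pairs)
    return GroupCorrelation(
        group=group,
        mirna_ids=ordered,
        R=R,
        n_pairs=n_pairs,
        n_nominal=len(sample_ids),
        cluster_of={m: cluster_map.membership[m] for m in ordered},
    )


# ---------------------------------------------------------------------------
# Jennrich test


def nearest_positive_definite(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipping repair to the nearest correlation-like PD matrix."""
    R = (R + R.T) / 2
    w, V = np.linalg.eigh(R)
    w = np.clip(w, eps, None)
    A = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return (A + A.T) / 2


def jennrich_test(
    R1: np.ndarray,
    R2: np.ndarray,
    n1: int,
    n2: int,
    *,
    region: str = "",
    repair: bool = True,
) -> JennrichResult:
    """Chi-square test of equality of two correlation matrices.

    ``n1`` and ``n2`` are the sample counts behind each matrix. Inputs must
    be positive definite; with ``repair=True`` a near-singular matrix is
    replaced by its nearest positive-definite correlation matrix and the
    repair is recorded on the result.
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    if R1.shape != R2.shape or R1.ndim != 2 or R1.shape[0] != R1.shape[1]:
        raise ValidationError(f"dimension mismatch: {R1.shape} vs {R2.shape}")
    p = R1.shape[0]
    if p < 2:
        raise ValidationError("need at least 2 variables")
    if not (np.isfinite(R1).all() and np.isfinite(R2).all()):
        raise ValidationError("correlation matrices contain non-finite entries")

    repaired = False
    mats = [R1, R2]
    for k, R in enumerate(mats):
        w = np.linalg.eigvalsh((R + R.T) / 2)
        if w.min() < 1e-8:
            if not repair:
                raise NumericalError(
                    f"matrix {k + 1} not positive definite "
                    f"(min eigenvalue {w.min():.3e})"
                )
            mats[k] = nearest_positive_definite(R)
            repaired = True
    R1, R2 = mats

    Rbar = (n1 * R1 + n2 * R2) / (n1 + n2)
    cond = np.linalg.cond(Rbar)
    if cond > 1e12:
        raise NumericalError(f"pooled matrix singular (condition number {cond:.3e})")
    Rbar_inv = np.linalg.inv(Rbar)
    c = n1 * n2 / (n1 + n2)
    Z = np.sqrt(c) * Rbar_inv @ (R1 - R2)
    S = np.eye(p) + Rbar * Rbar_inv
    cond_s = np.linalg.cond(S)
    if cond_s > 1e12:
        raise NumericalError(f"S matrix singular (condition number {cond_s:.3e})")
    dZ = np.diag(Z)
    chi2 = 0.5 * float(np.trace(Z @ Z)) - float(dZ @ np.linalg.solve(S, dZ))
    chi2 = max(chi2, 0.0)
    df = p * (p - 1) // 2
    p_value = float(stats.chi2.sf(chi2, df))
    return JennrichResult(
        region=region,
        chi2=chi2,
        df=df,
        p_value=p_value,
        n1=n1,
        n2=n2,
        pd_repaired=repaired,
    )


# ---------------------------------------------------------------------------
# coefficient sets and their comparison


def submatrix_coefficients(
    gc: GroupCorrelation,
    region_a: str,
    region_b: str | None = None,
) -> np.ndarray:
    """Correlation coefficients of a within- or between-cluster region.

    Within (``region_b`` None or equal to ``region_a``): the strictly upper
    triangle of the cluster's submatrix — k(k−1)/2 values for k members.
    Between: all kA·kB coefficients of the rectangular block. Missing
    entries are excluded (their count is logged).
    """
    clusters = set(gc.cluster_of.values())
    for region in (region_a, region_b):
        if region is not None and region not in clusters:
            raise ValidationError(f"unknown region {region!r}")
    idx_a = [i for i, m in enumerate(gc.mirna_ids) if gc.cluster_of[m] == region_a]
    if region_b is None or region_b == region_a:
        block = gc.R[np.ix_(idx_a, idx_a)]
        vals = block[np.triu_indices(len(idx_a), k=1)]
    else:
        idx_b = [i for i, m in enumerate(gc.mirna_ids) if gc.cluster_of[m] == region_b]
        vals = gc.R[np.ix_(idx_a, idx_b)].ravel()
    n_missing = int(np.sum(~np.isfinite(vals)))
    if n_missing:
        logger.info(
            "%s/%s region %s-%s: %d missing coefficient(s) excluded",
            gc.group,
            gc.n_nominal,
            region_a,
            region_b or region_a,
            n_missing,
        )
    return vals[np.isfinite(vals)]


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def compare_coefficient_sets(
    r_term: np.ndarray,
    r_ptb: np.ndarray,
    transform: str = "none",
) -> tuple[float, int, int, float, tuple[float, float]]:
    """One-way two-group ANOVA on correlation-coefficient sets.

    Returns ``(F, df1, df2, p, (mean_r_term, mean_r_ptb))``; means are always
    on the r scale, the ANOVA optionally on Fisher-z transformed values.
    F here is identical to the square of the pooled-variance two-sample t.
    """
    r_term = np.asarray(r_term, dtype=float)
    r_ptb = np.asarray(r_ptb, dtype=float)
    if len(r_term) < 2 or len(r_ptb) < 2:
        raise ValidationError("need at least 2 coefficients per group")
    if transform == "fisher_z":
        a, b = fisher_z(r_term), fisher_z(r_ptb)
    elif transform == "none":
        a, b = r_term, r_ptb
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    k1, k2 = len(a), len(b)
    df1, df2 = 1, k1 + k2 - 2
    means = (float(np.mean(r_term)), float(np.mean(r_ptb)))
    pooled = np.concatenate([a, b])
    if np.allclose(pooled.var(), 0):
        logger.warning("zero variance in pooled coefficients; F undefined")
        return (np.nan, df1, df2, np.nan, means)
    F, p = stats.f_oneway(a, b)
    return (float(F), df1, df2, float(p), means)


# ---------------------------------------------------------------------------
# orchestration


def compare_groups(
    expr: ExpressionMatrix,
    cluster_map: ClusterMap,
    metadata: SampleMetadata,
    regions: Sequence[str],
    *,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    transform: str = "none",
    include_full_matrix_jennrich: bool = True,
    group_a: str = "term",
    group_b: str = "PTB",
) -> MatrixComparison:
    """Full term-vs-PTB correlation-structure comparison.

    Computes the per-group cluster-ordered matrices, runs the Jennrich test
    on each region's within-cluster submatrix (and optionally the full
    ordered matrix), and compares all within-region and between-region
    coefficient sets by ANOVA.
    """
    gc_a = correlation_matrix(
        expr, cluster_map, group_a, metadata, min_pairs, clusters=regions
    )
    gc_b = correlation_matrix(
        expr, cluster_map, group_b, metadata, min_pairs, clusters=regions
    )
    jennrich_results: list[JennrichResult] = []
    for region in regions:
        members = [m for m in cluster_map.members(region) if m in gc_a.mirna_ids]
        if len(members) < 2:
            logger.warning("region %s has <2 present members; Jennrich skipped", region)
            continue
        R1 = gc_a.submatrix(members)
        R2 = gc_b.submatrix(members)
        if not (np.isfinite(R1).all() and np.isfinite(R2).all()):
            logger.warning("region %s has missing correlations; Jennrich skipped", region)
            continue
        jennrich_results.append(
            jennrich_test(R1, R2, gc_a.n_nominal, gc_b.n_nominal, region=region)
        )
    if include_full_matrix_jennrich and np.isfinite(gc_a.R).all() and np.isfinite(gc_b.R).all():
        jennrich_results.append(
            jennrich_test(
                gc_a.R, gc_b.R, gc_a.n_nominal, gc_b.n_nominal, region="full_matrix"
            )
        )

    anova_results: list[AnovaComparison] = []
    pairs = [(r, r) for r in regions]
    pairs += [
        (regions[i], regions[j])
        for i in range(len(regions))
        for j in range(i + 1, len(regions))
    ]
    for ra, rb in pairs:
        va = submatrix_coefficients(gc_a, ra, rb)
        vb = submatrix_coefficients(gc_b, ra, rb)
        if len(va) < 2 or len(vb) < 2:
            logger.warning("region pair (%s, %s) has <2 coefficients; skipped", ra, rb)
            continue
        F, df1, df2, p, (m_a, m_b) = compare_coefficient_sets(va, vb, transform)
        anova_results.append(
            AnovaComparison(
                region_a=ra,
                region_b=rb,
                F=F,
                df1=df1,
                df2=df2,
                p_value=p,
                mean_r_term=m_a,
                mean_r_ptb=m_b,
                n_term=len(va),
                n_ptb=len(vb),
            )
        )
    return MatrixComparison(
        jennrich=jennrich_results,
        anova_results=anova_results,
        n1=gc_a.n_nominal,
        n2=gc_b.n_nominal,
    )


def plot_correlation_dots(gc: GroupCorrelation, path: str, title: str | None = None):
    """Minimal correlation-dot plot: blue = positive r, red = negative."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = len(gc.mirna_ids)
    fig, ax = plt.subplots(figsize=(max(4, p * 0.12),) * 2)
    ii, jj = np.meshgrid(range(p), range(p))
    r = gc.R[ii, jj]
    ok = np.isfinite(r)
    ax.scatter(
        jj[ok],
        p - 1 - ii[ok],
        s=40 * np.abs(r[ok]),
        c=np.where(r[ok] >= 0, "tab:blue", "tab:red"),
    )
    boundaries = []
    last = None
    for k, m in enumerate(gc.mirna_ids):
        c = gc.cluster_of[m]
        if c != last and last is not None:
            boundaries.append(k - 0.5)
        last = c
    for b in boundaries:
        ax.axvline(b, color="grey", lw=0.5)
        ax.axhline(p - 1 - b, color="grey", lw=0.5)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title or f"{gc.group} (n={gc.n_nominal})")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
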