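"""Per-miRNA group tests, miRNA–outcome correlations, and matched-pair
mixed-effects models of birth outcomes on cluster scores.

The mixed models regress one outcome (gestational age at birth, birth
weight, or infant head circumference) on one cluster score at a time,
adjusting for pre-pregnancy BMI, gravida, history of preterm birth and
fetal sex, with a random intercept shared by each matched term/PTB pair.
Coefficients are reported with normal-approximation (z) 95% intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .clustering import ClusterMap
from .factors import ClusterScores
from .io_types import PTB, TERM, ExpressionMatrix, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["bmi", "gravida", "history_ptb", "fetal_sex"]
DEFAULT_OUTCOMES = ["gestational_age_birth", "birth_weight", "head_circumference"]


@dataclass
class OutcomeModelResult:
    """One row of the cluster-score → outcome model table."""

    outcome: str
    cluster: str
    estimate: float
    std_err: float
    z: float
    ci95_low: float
    ci95_high: float
    p_value: float
    covariates_used: list[str]
    n_samples: int
    n_pairs: int
    family: str = "linear"
    degraded: bool = False
    random_effect_var: float | None = None

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "cluster": self.cluster,
            "estimate": self.estimate,
            "std_err": self.std_err,
            "z": self.z,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "p": self.p_value,
            "family": self.family,
            "n_samples": self.n_samples,
            "n_pairs": self.n_pairs,
            "degraded": self.degraded,
        }


# ---------------------------------------------------------------------------
# per-miRNA comparisons


def per_mirna_ttest(
    expr: ExpressionMatrix,
    metadata: SampleMetadata,
    variant: str = "student",
) -> pd.DataFrame:
    """Two-sample t-test of each miRNA's −∆CT between term and PTB.

    ``variant`` is ``"student"`` (pooled variance, default) or ``"welch"``.
    The last row (``mirna_id == "__total__"``) compares total expression
    (per-sample mean −∆CT) between groups.
    """
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "student"
    term_ids = [s for s in expr.sample_ids if s in set(metadata.group_samples(TERM))]
    ptb_ids = [s for s in expr.sample_ids if s in set(metadata.group_samples(PTB))]
    a_idx = [expr.sample_ids.index(s) for s in term_ids]
    b_idx = [expr.sample_ids.index(s) for s in ptb_ids]
    rows = []

    def _one(label: str, a: np.ndarray, b: np.ndarray) -> dict:
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            return {
                "mirna_id": label,
                "t": np.nan,
                "df": np.nan,
                "p": np.nan,
                "mean_term": np.nan,
                "mean_ptb": np.nan,
                "note": "insufficient data",
            }
        if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
            # degenerate but well-defined: no difference, no evidence
            return {
                "mirna_id": label,
                "t": 0.0,
                "df": len(a) + len(b) - 2,
                "p": 1.0,
                "mean_term": float(a.mean()),
                "mean_ptb": float(b.mean()),
                "note": "zero variance",
            }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(a, b, equal_var=equal_var)
        df = len(a) + len(b) - 2 if equal_var else float(res.df)
        return {
            "mirna_id": label,
            "t": float(res.statistic),
            "df": df,
            "p": float(res.pvalue),
            "mean_term": float(a.mean()),
            "mean_ptb": float(b.mean()),
            "note": "",
        }

    for j, m in enumerate(expr.mirna_ids):
        rows.append(_one(m, expr.dct[a_idx, j], expr.dct[b_idx, j]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        total_a = np.nanmean(expr.dct[a_idx, :], axis=1)
        total_b = np.nanmean(expr.dct[b_idx, :], axis=1)
    rows.append(_one("__total__", total_a, total_b))
    return pd.DataFrame(rows)


def outcome_correlations(
    expr: ExpressionMatrix,
    metadata: SampleMetadata,
    cluster_map: ClusterMap,
    outcomes: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlations of each miRNA's −∆CT with birth outcomes.

    One row per miRNA with its cluster label, r and two-sided p per outcome,
    significance flags at 0.05/0.01 (unadjusted, as conventionally printed)
    plus Benjamini–Hochberg q-values per outcome for transparency.
    """
    outcomes = outcomes or DEFAULT_OUTCOMES
    meta = metadata.aligned(expr.sample_ids)
    membership = cluster_map.membership
    rows = []
    for j, m in enumerate(expr.mirna_ids):
        row: dict = {"mirna_id": m, "cluster": membership.get(m, "unclustered")}
        x = expr.dct[:, j]
        for out in outcomes:
            y = pd.to_numeric(meta[out], errors="coerce").to_numpy()
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3 or np.std(y[mask]) == 0 or np.std(x[mask]) == 0:
                row[f"r_{out}"], row[f"p_{out}"] = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x[mask], y[mask])
                row[f"r_{out}"], row[f"p_{out}"] = float(r), float(p)
            row[f"sig05_{out}"] = bool(row[f"p_{out}"] < 0.05) if np.isfinite(
                row[f"p_{out}"]
            ) else False
            row[f"sig01_{out}"] = bool(row[f"p_{out}"] < 0.01) if np.isfinite(
                row[f"p_{out}"]
            ) else False
        rows.append(row)
    df = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests

    for out in outcomes:
        p = df[f"p_{out}"].to_numpy()
        q = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        df[f"q_{out}"] = q
    return df


# ---------------------------------------------------------------------------
# mixed models


def _design(
    scores: ClusterScores,
    metadata: SampleMetadata,
    cluster: str,
    outcome: str,
    covariates: list[str],
) -> pd.DataFrame:
    meta = metadata.aligned(scores.sample_ids)
    df = pd.DataFrame(
        {
            "sample_id": scores.sample_ids,
            "score": scores.to_frame()[cluster].to_numpy(),
            "pair_id": meta["pair_id"].to_numpy(),
            "group": meta["group"].to_numpy(),
        }
    )
    if outcome == "ptb_status":
        df["outcome"] = (meta["group"] == PTB).astype(float).to_numpy()
    else:
        if outcome not in meta.columns:
            raise ValidationError(f"outcome {outcome!r} not in metadata")
        df["outcome"] = pd.to_numeric(meta[outcome], errors="coerce").to_numpy()
    for cov in covariates:
        if cov not in meta.columns:
            raise ValidationError(f"covariate {cov!r} not in metadata")
        col = meta[cov]
        if cov == "fetal_sex":
            # 0/1 indicator; accept either coded or labelled values
            if col.dtype == object:
                col = col.map({"male": 1, "female": 0, "M": 1, "F": 0})
        df[cov] = pd.to_numeric(col, errors="coerce").astype(float).to_numpy()
    df = df.dropna(subset=["outcome", "score"] + covariates)
    return df


def _drop_constant(df: pd.DataFrame, covariates: list[str]) -> list[str]:
    """Covariates with zero variance carry no information and make the
    design singular; drop them with a warning."""
    kept = []
    for cov in covariates:
        if df[cov].nunique(dropna=True) <= 1:
            logger.warning("covariate %r is constant; dropped from the model", cov)
        else:
            kept.append(cov)
    return kept


def fit_mixed_outcome(
    scores: ClusterScores,
    metadata: SampleMetadata,
    outcome: str,
    cluster: str | None = None,
    family: str = "linear",
    covariates: list[str] | None = None,
) -> list[OutcomeModelResult]:
    """Matched-pair mixed model of an outcome on cluster scores.

    Fits ``outcome ~ score + bmi + gravida + history_ptb + fetal_sex`` with
    a random intercept per matched pair, one model per cluster (clusters
    entered separately). ``family="logistic"`` (for the PTB label) uses a
    variational Bayes binomial mixed model; if a mixed fit fails the model
    degrades to the fixed-effects-only fit and flags it.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else list(covariates)
    clusters = [cluster] if cluster else scores.cluster_names
    results = []
    for cl in clusters:
        df = _design(scores, metadata, cl, outcome, covariates)
        used = _drop_constant(df, covariates)
        n_pairs = df["pair_id"].nunique()
        exog = sm.add_constant(df[["score"] + used])
        degraded = False
        re_var: float | None = None
        if family == "linear":
            est = se = np.nan
            # the pair variance often sits at the zero boundary, where some
            # optimizers hit a singular Hessian; try several before degrading
            for method in ("lbfgs", "powell", "nm"):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fit = sm.MixedLM(
                            df["outcome"], exog, groups=df["pair_id"]
                        ).fit(reml=True, method=method)
                    if np.isfinite(fit.bse["score"]):
                        re_var = float(np.asarray(fit.cov_re).ravel()[0])
                        if re_var <= 1e-3 * float(fit.scale):
                            # at the zero-variance boundary the mixed model
                            # reduces to OLS; the boundary Hessian is not
                            # trustworthy, so take the exact OLS inference
                            ols = sm.OLS(df["outcome"], exog).fit()
                            est = float(ols.params["score"])
                            se = float(ols.bse["score"])
                            re_var = 0.0
                        else:
                            est = float(fit.params["score"])
                            se = float(fit.bse["score"])
                        break
                except Exception:
                    continue
            if not np.isfinite(se):
                logger.warning(
                    "mixed fit failed for %s/%s; falling back to OLS", outcome, cl
                )
                degraded = True
                fit = sm.OLS(df["outcome"], exog).fit()
                est = float(fit.params["score"])
                se = float(fit.bse["score"])
        elif family == "logistic":
            est, se, degraded, re_var = _fit_logistic_mixed(df, exog, covariates)
        else:
            raise ValidationError(f"unknown family {family!r}")
        z = est / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        results.append(
            OutcomeModelResult(
                outcome=outcome,
                cluster=cl,
                estimate=est,
                std_err=se,
                z=float(z),
                ci95_low=est - 1.96 * se,
                ci95_high=est + 1.96 * se,
                p_value=float(p),
                covariates_used=used,
                n_samples=len(df),
                n_pairs=int(n_pairs),
                family=family,
                degraded=degraded,
                random_effect_var=re_var,
            )
        )
    return results


def _fit_logistic_mixed(
    df: pd.DataFrame, exog: pd.DataFrame, covariates: list[str]
) -> tuple[float, float, bool, float | None]:
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    y = df["outcome"].to_numpy()
    # perfect separation check on the score alone
    s1 = df.loc[y == 1, "score"]
    s0 = df.loc[y == 0, "score"]
    if len(s1) and len(s0) and (s1.min() > s0.max() or s0.min() > s1.max()):
        warnings.warn(
            "cluster score perfectly separates the outcome groups; "
            "logistic estimates are unbounded",
            stacklevel=3,
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            codes, _ = pd.factorize(df["pair_id"])
            ident = np.zeros(len(np.unique(codes)), dtype=int)
            vcp = np.eye(len(np.unique(codes)))[codes]
            model = BinomialBayesMixedGLM(
                y, exog.to_numpy(), exog_vc=vcp, ident=ident
            )
            fit = model.fit_vb()
        i = list(exog.columns).index("score")
        return float(fit.fe_mean[i]), float(fit.fe_sd[i]), False, None
    except Exception as exc:
        logger.warning("logistic mixed fit failed (%s); falling back to GLM", exc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, exog, family=sm.families.Binomial()).fit()
        return float(fit.params["score"]), float(fit.bse["score"]), True, None


def results_frame(results: list[OutcomeModelResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


# ---------------------------------------------------------------------------
# term-only regression


@dataclass
class RegressionSummary:
    r_squared: float
    F: float
    df_num: int
    df_den: int
    p_value: float
    coefficients: pd.DataFrame = field(repr=False, default=None)

    def format(self) -> str:
        return (
            f"R^2 = {self.r_squared:.3f}, "
            f"F({self.df_num},{self.df_den}) = {self.F:.2f}, "
            f"p = {self.p_value:.3g}"
        )


def term_only_regression(
    scores: ClusterScores,
    metadata: SampleMetadata,
    cluster: str,
    outcome: str = "head_circumference",
    extra_covariates: list[str] | None = None,
    covariates: list[str] | None = None,
) -> RegressionSummary:
    """OLS on the term subset, adding gestational age and birth weight.

    Used to ask whether a cluster–outcome association is independent of
    pregnancy duration and infant size among term deliveries only.
    """
    extra = (
        ["gestational_age_birth", "birth_weight"]
        if extra_covariates is None
        else list(extra_covariates)
    )
    covariates = DEFAULT_COVARIATES if covariates is None else list(covariates)
    meta = metadata.aligned(scores.sample_ids)
    term_mask = (meta["group"] == TERM).to_numpy()
    if term_mask.sum() < 8:
        raise ValidationError(f"only {int(term_mask.sum())} term samples (< 8)")
    df = _design(scores, metadata, cluster, outcome, covariates)
    for col in extra:
        aligned = meta.set_index("sample_id")[col]
        df[col] = pd.to_numeric(
            aligned.loc[df["sample_id"]], errors="coerce"
        ).to_numpy()
    df = df[df["group"] == TERM].dropna()
    predictors = ["score"] + _drop_constant(df, extra + covariates)
    X = sm.add_constant(df[predictors])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns for the error message
        bad = []
        cols = X.to_numpy()
        for j, name in enumerate(X.columns):
            others = np.delete(cols, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(cols):
                bad.append(name)
        raise ValidationError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(df["outcome"], X).fit()
    return RegressionSummary(
        r_squared=float(fit.rsquared),
        F=float(fit.fvalue),
        df_num=int(fit.df_model),
        df_den=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        coefficients=pd.DataFrame(
            {"estimate": fit.params, "std_err": fit.bse, "p": fit.pvalues}
        ),
    )
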