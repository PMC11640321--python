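"""Count-data regression on sweep output.

Both simulation outcomes — the number of clusters a run ends with and the
run's (rounded) mean number of individuals per cluster — are overdispersed
counts, so the primary model is a negative-binomial GLM with a log link and
estimated dispersion ``theta`` (variance ``mu + mu^2 / theta``); a Poisson
mode is available as a cross-check, since for ``theta -> inf`` the two
coincide.  Collinearity among the factorial predictors is screened with
variance inflation factors, and model selection is backward–forward
stepwise on AIC or BIC over the main effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

logger = logging.getLogger(__name__)

RESPONSES = ("n_clusters", "individuals_per_cluster")
ALL_PREDICTORS = ("join_threshold", "leave_threshold", "temperature",
                  "group_size")
DEFAULT_GROUP_SIZES = (70, 100, 130, 160)


@dataclass(frozen=True)
class GlmDesign:
    """Specification of one regression: response, predictors, family, rows.

    ``drop_no_cluster`` controls whether runs that ended with no cluster are
    excluded; it defaults to ``True`` for the per-cluster response (whose
    value is undefined there) and ``False`` for the cluster count (those runs
    are genuine zeros).
    """

    response: str
    predictors: tuple[str, ...] = ALL_PREDICTORS
    family: str = "negative_binomial"  # or "poisson"
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    drop_no_cluster: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if not self.predictors:
            raise ValueError("at least one predictor required")
        bad = set(self.predictors) - set(ALL_PREDICTORS)
        if bad:
            raise ValueError(f"unknown predictors: {sorted(bad)}")
        if self.family not in ("negative_binomial", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def excludes_no_cluster(self) -> bool:
        if self.drop_no_cluster is not None:
            return self.drop_no_cluster
        return self.response == "individuals_per_cluster"


@dataclass(frozen=True)
class GlmFitResult:
    """Fitted GLM: per-term table plus dispersion and fit diagnostics.

    ``terms`` has one row per model term (index = term name) with columns
    estimate, std_error, z_value, p_value.  ``theta`` is the NB dispersion
    (None in Poisson mode).
    """

    design: GlmDesign
    terms: pd.DataFrame
    theta: Optional[float]
    theta_se: Optional[float]
    log_likelihood: float
    null_deviance: float
    deviance: float
    df_null: int
    df_resid: int
    aic: float
    bic: float
    n_obs: int

    def coefficient(self, term: str) -> float:
        return float(self.terms.loc[term, "estimate"])

    def summary(self) -> str:
        fam = ("negative binomial (theta=%.4g)" % self.theta
               if self.theta is not None else "poisson")
        lines = [
            f"GLM: {self.design.response} ~ "
            + " + ".join(self.design.predictors),
            f"family: {fam}, log link; n = {self.n_obs}",
            self.terms.to_string(float_format=lambda v: f"{v:.6g}"),
            f"null deviance {self.null_deviance:.1f} on {self.df_null} df; "
            f"residual deviance {self.deviance:.1f} on {self.df_resid} df",
            f"logLik {self.log_likelihood:.1f}  AIC {self.aic:.1f}  "
            f"BIC {self.bic:.1f}",
        ]
        return "\n".join(lines)


def prepare_glm_table(table: pd.DataFrame, design: GlmDesign) -> pd.DataFrame:
    """Build the model table: one row per run, integer response column ``y``.

    For the per-cluster response, runs with no cluster are dropped and the
    per-run mean cluster size is rounded half-to-even to make it a count;
    for the cluster-count response all runs are kept (zeros included) unless
    the design says otherwise.
    """
    present = sorted(set(table["group_size"].unique()))
    want = [g for g in design.group_sizes if g in present]
    missing = sorted(set(design.group_sizes) - set(present))
    if missing:
        logger.warning("group sizes %s absent from sweep table", missing)
    sub = table[table["group_size"].isin(want)].copy()
    if design.excludes_no_cluster:
        sub = sub[sub["no_cluster"] == 0]
    if design.response == "individuals_per_cluster":
        sub["y"] = np.rint(sub["mean_cluster_size"].astype(float)).astype(int)
    else:
        sub["y"] = sub["n_clusters"].astype(int)
    if len(sub) == 0:
        raise ValueError("no rows left after filtering; check the design")
    return sub[["y", *ALL_PREDICTORS]].reset_index(drop=True)


def _design_matrix(model_table: pd.DataFrame,
                   predictors: Sequence[str]) -> pd.DataFrame:
    X = model_table[list(predictors)].astype(float)
    return sm.add_constant(X, has_constant="add")


def _estimate_theta(y: np.ndarray, X: pd.DataFrame) -> tuple[float, float]:
    """ML estimate of the NB dispersion via the NB2 likelihood.

    Returns (theta, theta_se); statsmodels parameterises by alpha = 1/theta,
    so the standard error follows by the delta method.
    """
    nb = sm.NegativeBinomial(y, X, loglike_method="nb2")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        res = nb.fit(disp=False, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        logger.warning("NB alpha estimation did not converge: %s",
                       res.mle_retvals)
    alpha = float(np.asarray(res.params)[-1])
    alpha = max(alpha, 1e-8)
    se_alpha = float(np.asarray(res.bse)[-1])
    theta = 1.0 / alpha
    theta_se = se_alpha / alpha**2 if np.isfinite(se_alpha) else np.nan
    return theta, theta_se


def fit_glm(model_table: pd.DataFrame, design: GlmDesign) -> GlmFitResult:
    """Maximum-likelihood fit of the designed GLM on a prepared table."""
    min_rows = 10 * (len(design.predictors) + 2)
    if len(model_table) < min_rows:
        raise ValueError(
            f"need at least {min_rows} rows to fit {len(design.predictors)}"
            f" predictors, got {len(model_table)}"
        )
    y = model_table["y"].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise ValueError("degenerate response: all values identical")
    X = _design_matrix(model_table, design.predictors)

    theta = theta_se = None
    if design.family == "negative_binomial":
        theta, theta_se = _estimate_theta(y, X)
        family = sm.families.NegativeBinomial(alpha=1.0 / theta)
        extra_params = 1  # the dispersion is estimated too
    else:
        family = sm.families.Poisson()
        extra_params = 0

    glm = sm.GLM(y, X, family=family)
    res = glm.fit()
    k = X.shape[1] + extra_params
    llf = float(res.llf)
    n = len(y)
    aic = -2 * llf + 2 * k
    bic = -2 * llf + np.log(n) * k

    terms = pd.DataFrame(
        {
            "estimate": res.params,
            "std_error": res.bse,
            "z_value": res.tvalues,
            "p_value": res.pvalues,
        }
    )
    terms.index = ["(Intercept)", *design.predictors]

    return GlmFitResult(
        design=design,
        terms=terms,
        theta=theta,
        theta_se=theta_se,
        log_likelihood=llf,
        null_deviance=float(res.null_deviance),
        deviance=float(res.deviance),
        df_null=n - 1,
        df_resid=int(res.df_resid),
        aic=float(aic),
        bic=float(bic),
        n_obs=n,
    )


def fit_nb_glm(table: pd.DataFrame, design: GlmDesign) -> GlmFitResult:
    """Prepare the model table from a sweep table and fit in one step."""
    return fit_glm(prepare_glm_table(table, design), design)


def compute_vif(model_table: pd.DataFrame,
                predictors: Sequence[str] = ALL_PREDICTORS) -> pd.Series:
    """Variance inflation factor of each predictor (main effects only).

    ``VIF_k = 1 / (1 - R^2_k)`` from regressing predictor k on the others;
    exact collinearity surfaces as ``inf``.
    """
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    X = _design_matrix(model_table, predictors)
    vals = {}
    with np.errstate(divide="ignore"):
        for idx, name in enumerate(X.columns):
            if name == "const":
                continue
            vals[name] = float(variance_inflation_factor(X.to_numpy(), idx))
    out = pd.Series(vals, name="vif")
    if np.isinf(out).any():
        logger.warning("exactly collinear predictors: %s",
                       list(out.index[np.isinf(out)]))
    return out


def stepwise_select(table: pd.DataFrame, design: GlmDesign,
                    criterion: str = "AIC",
                    ) -> tuple[pd.DataFrame, GlmFitResult]:
    """Backward–forward stepwise selection over main effects.

    Starts from the full design, at each step trying every single-term
    removal and re-addition, and moves to the candidate that lowers the
    criterion most; stops at a local minimum.  Returns the step trace and
    the fit of the selected model.
    """
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    base_table = prepare_glm_table(table, design)

    def crit(fit: GlmFitResult) -> float:
        return fit.aic if criterion == "AIC" else fit.bic

    def fit_with(preds: tuple[str, ...]) -> GlmFitResult:
        return fit_glm(base_table, replace(design, predictors=preds))

    current = tuple(design.predictors)
    current_fit = fit_with(current)
    trace = [{"step": 0, "action": "start",
              "predictors": "+".join(current), criterion: crit(current_fit)}]
    step = 0
    while True:
        step += 1
        candidates: list[tuple[float, str, tuple[str, ...], GlmFitResult]] = []
        for p in current:
            if len(current) > 1:
                preds = tuple(q for q in current if q != p)
                f = fit_with(preds)
                candidates.append((crit(f), f"- {p}", preds, f))
        for p in design.predictors:
            if p not in current:
                preds = tuple([*current, p])
                f = fit_with(preds)
                candidates.append((crit(f), f"+ {p}", preds, f))
        if not candidates:
            break
        candidates.sort(key=lambda c: c[0])
        best_val, action, preds, f = candidates[0]
        if best_val >= crit(current_fit) - 1e-9:
            break
        current, current_fit = preds, f
        trace.append({"step": step, "action": action,
                      "predictors": "+".join(current), criterion: best_val})
    return pd.DataFrame(trace), current_fit


def coefficient_summary(fit: GlmFitResult, z: float = 1.96) -> pd.DataFrame:
    """Per-term estimates with Wald confidence intervals (default 95%)."""
    out = fit.terms.copy()
    if (out["std_error"] == 0).any():
        logger.warning("zero-width interval for terms with SE = 0: %s",
                       list(out.index[out["std_error"] == 0]))
    out["ci_low"] = out["estimate"] - z * out["std_error"]
    out["ci_high"] = out["estimate"] + z * out["std_error"]
    return out


def plot_coefficients(fit: GlmFitResult, path) -> None:
    """Dot-and-whisker plot of the coefficient table (95% Wald intervals)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = coefficient_summary(fit)
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(tab) + 1.5))
    ypos = np.arange(len(tab))[::-1]
    ax.errorbar(tab["estimate"], ypos,
                xerr=[tab["estimate"] - tab["ci_low"],
                      tab["ci_high"] - tab["estimate"]],
                fmt="o", capsize=3)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ypos, tab.index)
    ax.set_xlabel("coefficient (log link)")
    ax.set_title(fit.design.response)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
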