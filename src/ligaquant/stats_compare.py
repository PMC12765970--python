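"""Group comparison with linear mixed-effects models.

Outcomes (per-sample band integrals or crimp morphometrics) are
compared across experimental groups with ligament type and group as
fixed effects and random intercepts per animal (optionally with a knee-
within-animal component), fitted by REML.  Estimated marginal means are
model-based cell means on an equal-weight factor grid; post-hoc group
contrasts within each ligament use t statistics with between-animal
degrees of freedom and a Tukey (studentized range) family adjustment by
default.  qPLM outcomes are natural-log transformed before fitting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LMESpec",
    "LMEFit",
    "PairwiseComparison",
    "validate_sample_table",
    "fit_lme",
    "estimated_marginal_means",
    "pairwise_posthoc",
    "significance_stars",
]

FACTOR_LEVELS = {
    "ligament": ("LCL", "MCL"),
    "group": ("ACLT", "contralateral", "control"),
    "knee": ("L", "R"),
}


@dataclass(frozen=True)
class LMESpec:
    """Model specification for one outcome.

    ``random`` selects the random structure: ``"animal"`` (random
    intercept per animal) or ``"animal_knee"`` (adds a knee-within-
    animal variance component).  ``transform="natural_log"`` fits the
    model on log outcomes (required for the crimp morphometrics, which
    are right-skewed).
    """

    outcome: str
    interaction: bool = False
    random: str = "animal"
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.random not in ("animal", "animal_knee"):
            raise ValueError(f"unknown random structure {self.random!r}")
        if self.transform not in ("identity", "natural_log"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class LMEFit:
    """A fitted mixed model plus the bookkeeping needed for marginal
    means and contrasts."""

    spec: LMESpec
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    var_components: dict[str, float]
    loglike: float
    converged: bool = True
    result: object | None = None
    data: pd.DataFrame | None = None
    n_obs: int = 0
    n_animals: int = 0
    rank: int = 0


@dataclass(frozen=True)
class PairwiseComparison:
    contrast: str
    ligament: str
    estimate: float
    se: float
    df: float
    t: float
    p_value: float
    p_adjusted: float

    def __post_init__(self) -> None:
        for p in (self.p_value, self.p_adjusted):
            # NaN marks a contrast whose standard error was undefined
            # (degenerate boundary fit); otherwise p must be a probability
            if not np.isnan(p) and not 0 <= p <= 1:
                raise ValueError("p-values must lie in [0, 1]")


def validate_sample_table(df: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Check factor levels and outcome presence of a long-format table."""
    required = {"sample_id", "animal_id", "knee", "ligament", "group", outcome}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"sample table lacks columns {sorted(missing)}")
    for col in ("ligament", "group", "knee"):
        bad = set(df[col]) - set(FACTOR_LEVELS[col])
        if bad:
            raise ValueError(f"unknown {col} level(s): {sorted(bad)}")
    if df.duplicated(["sample_id"]).any():
        raise ValueError("duplicate sample_id rows")
    return df


def _formula(spec: LMESpec) -> str:
    fixed = "C(ligament) * C(group)" if spec.interaction else "C(ligament) + C(group)"
    return f"__y ~ {fixed}"


def fit_lme(table: pd.DataFrame, spec: LMESpec) -> LMEFit:
    """REML fit of the specified random-intercept model.

    Raises on non-positive outcome values under the log transform
    (naming the offending samples).  A singular fit (a variance
    component estimated at zero) is returned as a valid fit.
    """
    df = validate_sample_table(table, spec.outcome).copy()
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 groups to compare")
    y = pd.to_numeric(df[spec.outcome])
    if spec.transform == "natural_log":
        bad = df.loc[y <= 0, "sample_id"].tolist()
        if bad:
            raise ValueError(
                f"natural_log transform needs positive values; offending "
                f"samples: {bad}"
            )
        y = np.log(y)
    df["__y"] = y

    vc = {"knee": "0 + C(knee)"} if spec.random == "animal_knee" else None
    model = smf.mixedlm(
        _formula(spec), df, groups=df["animal_id"], re_formula="1", vc_formula=vc
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        result = model.fit(reml=True)

    fe_names = list(result.fe_params.index)
    var_components = {"residual": float(result.scale)}
    var_components["animal"] = float(np.asarray(result.cov_re)[0, 0])
    if vc is not None and len(result.vcomp):
        var_components["knee_in_animal"] = float(result.vcomp[0])
    return LMEFit(
        spec=spec,
        params=result.fe_params,
        bse=result.bse_fe,
        cov_params=result.cov_params().loc[fe_names, fe_names],
        var_components=var_components,
        loglike=float(result.llf),
        converged=bool(result.converged),
        result=result,
        data=df,
        n_obs=len(df),
        n_animals=df["animal_id"].nunique(),
        rank=len(fe_names),
    )


def _design_row(fit: LMEFit, ligament: str, group: str) -> np.ndarray:
    """Fixed-effect design row for one (ligament, group) cell, built
    from the fitted model's design info so coding stays consistent."""
    import patsy

    di = fit.result.model.data.design_info
    cell = pd.DataFrame({"ligament": [ligament], "group": [group]})
    return np.asarray(patsy.dmatrix(di, cell))[0]


def estimated_marginal_means(
    fit: LMEFit,
    by: tuple[str, ...] = ("ligament", "group"),
) -> pd.DataFrame:
    """Model-based means on the factor grid.

    For each requested cell, factors not listed in ``by`` are averaged
    over their levels with equal weight.  Cells absent from the data
    yield a missing value with a warning.  Log-transformed outcomes are
    reported on both the log scale (``emmean``) and the response scale
    (``response`` = exp(emmean)).
    """
    factors = {"ligament": FACTOR_LEVELS["ligament"], "group": FACTOR_LEVELS["group"]}
    for f in by:
        if f not in factors:
            raise KeyError(f"unknown factor {f!r}")
    free = [f for f in factors if f not in by]
    rows = []
    observed = set(zip(fit.data["ligament"], fit.data["group"]))
    for combo in itertools.product(*(factors[f] for f in by)):
        cell = dict(zip(by, combo))
        grid = [
            {**cell, **dict(zip(free, other))}
            for other in itertools.product(*(factors[f] for f in free))
        ]
        X = np.mean(
            [_design_row(fit, g["ligament"], g["group"]) for g in grid], axis=0
        )
        est = float(X @ fit.params.to_numpy())
        se = float(np.sqrt(X @ fit.cov_params.to_numpy() @ X))
        present = all(
            (g["ligament"], g["group"]) in observed for g in grid
        ) or any((g["ligament"], g["group"]) in observed for g in grid)
        if not present:
            warnings.warn(f"cell {cell} is empty in the data")
            est, se = float("nan"), float("nan")
        row = {**cell, "emmean": est, "se": se}
        if fit.spec.transform == "natural_log":
            row["response"] = float(np.exp(est))
        rows.append(row)
    return pd.DataFrame(rows)


def _model_blocks(fit: LMEFit):
    """Per-animal design blocks (X_i, y_i, knee labels) in model order."""
    model = fit.result.model
    X = np.asarray(model.exog)
    y = np.asarray(model.endog)
    labels = np.asarray(fit.data["animal_id"])
    knees = np.asarray(fit.data["knee"])
    blocks = []
    for animal in pd.unique(labels):
        idx = np.nonzero(labels == animal)[0]
        blocks.append((X[idx], y[idx], knees[idx]))
    return blocks


def _block_v(theta: np.ndarray, n_i: int, knees: np.ndarray, structure: str) -> np.ndarray:
    """Marginal covariance of one animal's observations.

    ``theta`` holds (animal variance, [knee variance,] residual
    variance) depending on the random structure.
    """
    if structure == "animal_knee":
        va, vk, ve = theta
    else:
        va, ve = theta
        vk = 0.0
    V = np.full((n_i, n_i), va) + ve * np.eye(n_i)
    if vk > 0:
        same_knee = knees[:, None] == knees[None, :]
        V += vk * same_knee
    return V


def _reml_pieces(theta: np.ndarray, blocks, structure: str):
    """REML log-likelihood and fixed-effect covariance at ``theta``."""
    XtVX = 0.0
    XtVy = 0.0
    logdet = 0.0
    yVy = 0.0
    for X_i, y_i, knees in blocks:
        V = _block_v(theta, len(y_i), knees, structure)
        Vinv = np.linalg.inv(V)
        XtVX = XtVX + X_i.T @ Vinv @ X_i
        XtVy = XtVy + X_i.T @ Vinv @ y_i
        sign, ld = np.linalg.slogdet(V)
        logdet += ld
        yVy += float(y_i @ Vinv @ y_i)
    cov_fe = np.linalg.inv(XtVX)
    beta = cov_fe @ XtVy
    rss = yVy - float(XtVy @ beta)
    sign, ld_x = np.linalg.slogdet(XtVX)
    llf = -0.5 * (logdet + ld_x + rss)
    return llf, cov_fe


def satterthwaite_df(fit: LMEFit, L: np.ndarray) -> float:
    """Satterthwaite degrees of freedom for the contrast ``L @ beta``.

    ``df = 2 f(theta)^2 / (g' Sigma_theta g)`` where ``f(theta) =
    L cov_fe(theta) L'`` is the contrast variance, ``g`` its gradient
    in the variance parameters, and ``Sigma_theta`` the inverse of the
    negative REML-likelihood Hessian.  Both derivatives are taken by
    central finite differences; the result is clamped to
    ``[3, n_obs - rank]``.  Boundary fits (a variance component at
    zero) fall back to the residual-df clamp.
    """
    structure = fit.spec.random
    blocks = _model_blocks(fit)
    if structure == "animal_knee":
        theta = np.array(
            [
                fit.var_components["animal"],
                fit.var_components.get("knee_in_animal", 0.0),
                fit.var_components["residual"],
            ]
        )
    else:
        theta = np.array([fit.var_components["animal"], fit.var_components["residual"]])
    df_max = float(max(fit.n_obs - fit.rank, 3))
    floor = 1e-8 * max(theta[-1], 1.0)
    theta = np.maximum(theta, floor)

    def f_var(th):
        _, cov = _reml_pieces(th, blocks, structure)
        return float(L @ cov @ L)

    def llf(th):
        val, _ = _reml_pieces(np.maximum(th, floor), blocks, structure)
        return val

    h = np.maximum(1e-4 * theta, 1e-6)
    k = len(theta)
    grad = np.zeros(k)
    for j in range(k):
        e = np.zeros(k)
        e[j] = h[j]
        grad[j] = (f_var(theta + e) - f_var(np.maximum(theta - e, floor))) / (
            theta[j] + h[j] - max(theta[j] - h[j], floor)
        )
    hess = np.zeros((k, k))
    for j in range(k):
        for m in range(j, k):
            ej = np.zeros(k)
            em = np.zeros(k)
            ej[j] = h[j]
            em[m] = h[m]
            hess[j, m] = hess[m, j] = (
                llf(theta + ej + em)
                - llf(theta + ej - em)
                - llf(theta - ej + em)
                + llf(theta - ej - em)
            ) / (4 * h[j] * h[m])
    try:
        sigma_theta = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        return df_max
    denom = float(grad @ sigma_theta @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return df_max
    df = 2.0 * f_var(theta) ** 2 / denom
    if not np.isfinite(df):
        return df_max
    return float(np.clip(df, 3.0, df_max))


def pairwise_posthoc(fit: LMEFit, adjust: str = "tukey") -> list[PairwiseComparison]:
    """All group-pair contrasts within each ligament.

    Contrast estimates are differences of estimated marginal means;
    ``adjust`` selects the familywise correction over the group pairs
    within a ligament: ``"tukey"`` (studentized range, default),
    ``"bonferroni"``, ``"holm"`` or ``"none"``.
    """
    groups = [g for g in FACTOR_LEVELS["group"] if g in set(fit.data["group"])]
    if len(groups) < 2:
        return []
    out: list[PairwiseComparison] = []
    for ligament in FACTOR_LEVELS["ligament"]:
        raws = []
        for a, b in itertools.combinations(groups, 2):
            L = _design_row(fit, ligament, a) - _design_row(fit, ligament, b)
            est = float(L @ fit.params.to_numpy())
            var = float(L @ fit.cov_params.to_numpy() @ L)
            se = float(np.sqrt(var)) if var > 0 else float("nan")
            df_dof = satterthwaite_df(fit, L)
            t = est / se if np.isfinite(se) and se > 0 else float("nan")
            p = float(2 * sps.t.sf(abs(t), df_dof)) if np.isfinite(t) else float("nan")
            raws.append((f"{a} - {b}", est, se, t, p, df_dof))
        k = len(raws)
        n_means = len(groups)
        for i, (label, est, se, t, p, df_dof) in enumerate(raws):
            if adjust == "tukey":
                p_adj = float(
                    sps.studentized_range.sf(abs(t) * np.sqrt(2), n_means, df_dof)
                )
            elif adjust == "bonferroni":
                p_adj = min(1.0, p * k)
            elif adjust == "holm":
                # step-down with enforced monotonicity
                sorted_ps = np.sort([r[4] for r in raws])
                order = np.argsort([r[4] for r in raws])
                rank = int(np.where(order == i)[0][0])
                adj_sorted = np.maximum.accumulate(
                    [min(1.0, sp * (k - j)) for j, sp in enumerate(sorted_ps)]
                )
                p_adj = float(adj_sorted[rank])
            elif adjust == "none":
                p_adj = p
            else:
                raise ValueError(f"unknown adjustment {adjust!r}")
            out.append(
                PairwiseComparison(
                    contrast=label,
                    ligament=ligament,
                    estimate=est,
                    se=se,
                    df=df_dof,
                    t=t,
                    p_value=p,
                    p_adjusted=max(p_adj, p),
                )
            )
    return out


def significance_stars(p: float) -> str:
    """Conventional star markers: * p<0.05, ** p<0.01, *** p<0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
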