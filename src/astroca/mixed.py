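"""Trial-level linear mixed-effects models of the genotype analyses.

The response (ROA density rise rate, max/mean density, or GRAB_NE change)
is modeled with fixed effects of genotype (TG is the reference level, so
the intercept is the TG mean), magnification (µm/pixel, entered as a
binary indicator when only two magnifications occur), recording depth,
maximum wheel speed, and — in the pupil models — pupil dilation and its
interaction with genotype. Each mouse contributes a random intercept.
Where residual plots indicate heteroscedasticity, the residual variance is
allowed to differ between genotypes.

Estimation is restricted maximum likelihood (REML). Because each mouse has
a single genotype, the marginal covariance is block diagonal with
exchangeable blocks ``sigma_g^2 I + sigma_mouse^2 11'``, inverted in closed
form; the 2–3 variance parameters are profiled out numerically. p-values
are two-sided from the t-distribution with a conservative containment
approximation, ``df = n_obs - n_fixed - n_mice + 1``. No multiple-testing
adjustment is applied anywhere.

The WT pupil slope is the TG slope plus the interaction term, reported at
two significant figures as in the published tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "ModelFit",
    "fit_response_model",
    "fit_pupil_model",
    "wt_slope",
    "wt_slope_from_components",
    "robustness_check",
    "residual_diagnostics",
    "ResidualDiagnostics",
    "round_sig",
]

GENOTYPES = ("TG", "WT")

# printed-table display names for each design term
TERM_LABELS = {
    "intercept_tg": "Intercept (TG)",
    "genotype_wt": "Genotype (WT)",
    "pupil_tg": "Pupil dilation (TG)",
    "pupil_x_genotype_wt": "Pupil dilation x genotype (WT)",
    "um_per_pixel": "um per pixel",
    "depth_um": "Depth",
    "max_speed": "Maximum speed",
}


@dataclass
class ModelSpec:
    """What to fit: response column, pupil terms, residual-variance structure."""

    response: str = "response"
    compartment: str | None = None
    include_pupil: bool = False
    residual_variance_by_genotype: bool = False
    #: per-genotype residual-SD ratio above which diagnostics recommend the
    #: heteroscedastic refit
    heteroscedasticity_ratio: float = 1.5


@dataclass
class ModelFit:
    """Fixed-effect table, variance components, and fit bookkeeping."""

    coefficients: pd.DataFrame  # term, estimate, se, t, df, p
    sigma_mouse: float
    sigma_resid: dict[str, float]  # per genotype (identical when homoscedastic)
    n_obs: int
    n_mice: int
    converged: bool
    reml_criterion: float
    spec: ModelSpec
    # per-observation quantities for diagnostics / robustness
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)  # conditional (BLUP-adjusted)
    genotype: np.ndarray = field(repr=False, default=None)

    def estimate(self, term: str) -> float:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in model")
        return float(row["estimate"].iloc[0])

    def pvalue(self, term: str) -> float:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in model")
        return float(row["p"].iloc[0])


def _design(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Build the fixed-effects design matrix with TG-reference coding."""
    geno = table["genotype"].to_numpy()
    unknown = set(geno) - set(GENOTYPES)
    if unknown:
        raise ValueError(f"unknown genotype labels: {sorted(unknown)}")
    wt = (geno == "WT").astype(float)
    umpp = table["um_per_pixel"].to_numpy(dtype=float)
    levels = np.unique(umpp)
    if levels.size == 2:  # binary indicator for the high-magnification level
        umpp = (umpp == levels.max()).astype(float)
    cols = [np.ones(len(table)), wt]
    names = ["intercept_tg", "genotype_wt"]
    if spec.include_pupil:
        pupil = table["pupil_dilation"].to_numpy(dtype=float)
        cols += [pupil, pupil * wt]
        names += ["pupil_tg", "pupil_x_genotype_wt"]
    cols += [umpp, table["depth_um"].to_numpy(dtype=float), table["max_speed"].to_numpy(dtype=float)]
    names += ["um_per_pixel", "depth_um", "max_speed"]
    X = np.column_stack(cols)
    return X, names, wt


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[i] for i in range(len(names)) if diag[i] <= tol]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")


class _RemlProblem:
    """Profiled REML for a random-intercept model with exchangeable blocks."""

    def __init__(self, y, X, mouse_ids, genotype_wt, het: bool):
        self.y, self.X = y, X
        self.het = het
        self.groups = []
        for m in pd.unique(mouse_ids):
            idx = np.flatnonzero(mouse_ids == m)
            g = int(genotype_wt[idx[0]])  # 0 = TG, 1 = WT (one genotype per mouse)
            self.groups.append((idx, g, self.y[idx], self.X[idx]))

    def _variances(self, theta):
        m2 = math.exp(min(theta[0], 50.0))
        if self.het:
            s2 = (math.exp(min(theta[1], 50.0)), math.exp(min(theta[2], 50.0)))
        else:
            s2 = (math.exp(min(theta[1], 50.0)),) * 2
        return m2, s2

    def _assemble(self, theta):
        """X'V^-1 X, X'V^-1 y, y'V^-1 y and log|V| via the Woodbury identity."""
        m2, s2 = self._variances(theta)
        p = self.X.shape[1]
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        logdet = 0.0
        for idx, g, yj, Xj in self.groups:
            sg = max(s2[g], 1e-12)
            nj = len(idx)
            denom = sg + nj * m2
            c = m2 / (sg * denom)
            x1 = Xj.sum(axis=0)
            y1 = yj.sum()
            xtvx += Xj.T @ Xj / sg - c * np.outer(x1, x1)
            xtvy += Xj.T @ yj / sg - c * x1 * y1
            ytvy += yj @ yj / sg - c * y1 * y1
            logdet += (nj - 1) * math.log(sg) + math.log(denom)
        return xtvx, xtvy, ytvy, logdet

    def deviance(self, theta) -> float:
        try:
            xtvx, xtvy, ytvy, logdet = self._assemble(theta)
            sign, logdet_xx = np.linalg.slogdet(xtvx)
            if sign <= 0:
                return 1e12
            beta = np.linalg.solve(xtvx, xtvy)
            rss = ytvy - beta @ xtvy
            return logdet + logdet_xx + max(rss, 1e-300)
        except (np.linalg.LinAlgError, ValueError, OverflowError):
            return 1e12

    def solve_beta(self, theta):
        xtvx, xtvy, _, _ = self._assemble(theta)
        cov = np.linalg.inv(xtvx)
        return cov @ xtvy, cov

    def blups(self, theta, beta) -> np.ndarray:
        """Predicted random intercept per observation."""
        m2, s2 = self._variances(theta)
        out = np.zeros(len(self.y))
        for idx, g, yj, Xj in self.groups:
            sg = max(s2[g], 1e-12)
            r = yj - Xj @ beta
            out[idx] = m2 * r.sum() / (sg + len(idx) * m2)
        return out


def _fit(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    required = ["genotype", "mouse", "um_per_pixel", "depth_um", "max_speed", spec.response]
    if spec.include_pupil:
        required.append("pupil_dilation")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if spec.include_pupil:
        n0 = len(table)
        table = table.dropna(subset=["pupil_dilation"])
        if len(table) < n0:
            warnings.warn(
                f"dropped {n0 - len(table)} trials with missing pupil measurements",
                stacklevel=3,
            )
    if table[required].isna().any().any():
        raise ValueError("missing covariate or response values")
    mice_per_geno = table.groupby("genotype")["mouse"].nunique()
    if len(mice_per_geno) < 2 or (mice_per_geno < 2).any():
        raise ValueError("need at least 2 mice in each genotype")

    y = table[spec.response].to_numpy(dtype=float)
    X, names, wt = _design(table, spec)
    _check_rank(X, names)
    mouse_ids = table["mouse"].to_numpy()
    problem = _RemlProblem(y, X, mouse_ids, wt, het=spec.residual_variance_by_genotype)

    # moment-based start: OLS residual variance split between levels
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2_0 = max(float(np.var(y - X @ beta0, ddof=X.shape[1])), 1e-10)
    theta0 = np.log([s2_0 / 2] + [s2_0] * (2 if spec.residual_variance_by_genotype else 1))
    res = optimize.minimize(
        problem.deviance, theta0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    theta = res.x
    beta, cov = problem.solve_beta(theta)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    n_mice = int(table["mouse"].nunique())
    dof = max(len(y) - X.shape[1] - n_mice + 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pval = 2 * stats.t.sf(np.abs(tval), dof)
    coef = pd.DataFrame(
        {
            "term": names,
            "label": [TERM_LABELS[n] for n in names],
            "estimate": beta,
            "se": se,
            "t": tval,
            "df": dof,
            "p": pval,
        }
    )
    m2, s2 = problem._variances(theta)
    blup = problem.blups(theta, beta)
    fitted = X @ beta + blup
    return ModelFit(
        coefficients=coef,
        sigma_mouse=math.sqrt(m2),
        sigma_resid={"TG": math.sqrt(s2[0]), "WT": math.sqrt(s2[1])},
        n_obs=len(y),
        n_mice=n_mice,
        converged=bool(res.success),
        reml_criterion=float(res.fun),
        spec=spec,
        fitted=fitted,
        residuals=y - fitted,
        genotype=table["genotype"].to_numpy(),
    )


def fit_response_model(table: pd.DataFrame, spec: ModelSpec | None = None) -> ModelFit:
    """Genotype model without pupil terms (the Table 1/3-style analyses)."""
    spec = spec or ModelSpec()
    if spec.include_pupil:
        raise ValueError("use fit_pupil_model for pupil specifications")
    return _fit(table, spec)


def fit_pupil_model(table: pd.DataFrame, spec: ModelSpec | None = None) -> ModelFit:
    """Pupil-coupling model with the pupil x genotype interaction.

    Trials with missing pupil dilation are dropped before fitting.
    """
    spec = spec or ModelSpec(include_pupil=True)
    if not spec.include_pupil:
        spec = ModelSpec(
            response=spec.response,
            compartment=spec.compartment,
            include_pupil=True,
            residual_variance_by_genotype=spec.residual_variance_by_genotype,
            heteroscedasticity_ratio=spec.heteroscedasticity_ratio,
        )
    return _fit(table, spec)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def wt_slope_from_components(pupil_slope_tg: float, interaction_wt: float) -> float:
    """WT pupil slope: TG slope plus interaction, at two significant figures."""
    return round_sig(pupil_slope_tg + interaction_wt, 2)


def wt_slope(fit: ModelFit) -> float:
    """WT pupil slope derived from a fitted pupil model."""
    try:
        return wt_slope_from_components(
            fit.estimate("pupil_tg"), fit.estimate("pupil_x_genotype_wt")
        )
    except KeyError as err:
        raise ValueError("model has no pupil x genotype interaction term") from err


@dataclass
class ResidualDiagnostics:
    """Per-genotype conditional-residual summaries of a fit."""

    summary: pd.DataFrame  # genotype, n, resid_sd, resid_mean
    sd_ratio: float
    refit_heteroscedastic: bool
    residuals_vs_fitted: pd.DataFrame


def residual_diagnostics(fit: ModelFit) -> ResidualDiagnostics:
    """Summarize conditional residuals by genotype.

    When the larger per-genotype residual SD exceeds the smaller by more
    than the spec's ratio (default 1.5), the heteroscedastic refit (residual
    variance varying by genotype) is recommended.
    """
    df = pd.DataFrame({"genotype": fit.genotype, "resid": fit.residuals, "fitted": fit.fitted})
    summary = (
        df.groupby("genotype")["resid"]
        .agg(n="size", resid_sd=lambda r: r.std(ddof=1), resid_mean="mean")
        .reset_index()
    )
    sds = summary["resid_sd"].to_numpy()
    ratio = float(sds.max() / sds.min()) if sds.min() > 0 else float("inf")
    return ResidualDiagnostics(
        summary=summary,
        sd_ratio=ratio,
        refit_heteroscedastic=ratio > fit.spec.heteroscedasticity_ratio,
        residuals_vs_fitted=df,
    )


def robustness_check(
    table: pd.DataFrame,
    spec: ModelSpec,
    mode: str = "leave_one_mouse_out",
) -> pd.DataFrame:
    """Leave-one-unit-out refits: the published sensitivity analysis.

    ``mode`` is ``leave_one_mouse_out`` or ``leave_one_trial_out``. Each
    deletion refits the model and reports every term's estimate and
    p-value. Deletions that leave fewer than 2 mice in a genotype are
    skipped with a warning.
    """
    if mode not in ("leave_one_mouse_out", "leave_one_trial_out"):
        raise ValueError(f"unknown mode {mode!r}")
    unit_col = "mouse" if mode == "leave_one_mouse_out" else "trial"
    if unit_col not in table.columns:
        raise ValueError(f"missing column {unit_col!r}")
    fitter = fit_pupil_model if spec.include_pupil else fit_response_model
    rows = []
    for unit in pd.unique(table[unit_col]):
        sub = table[table[unit_col] != unit]
        per_geno = sub.groupby("genotype")["mouse"].nunique()
        if len(per_geno) < 2 or (per_geno < 2).any():
            warnings.warn(
                f"skipping deletion of {unit_col} {unit!r}: a genotype would have < 2 mice",
                stacklevel=2,
            )
            continue
        fit = fitter(sub, spec)
        for _, row in fit.coefficients.iterrows():
            rows.append(
                {
                    "left_out": unit,
                    "mode": mode,
                    "term": row["term"],
                    "estimate": row["estimate"],
                    "p": row["p"],
                }
            )
    return pd.DataFrame(rows)
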