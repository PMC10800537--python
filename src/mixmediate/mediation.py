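"""Regression-based single-mediator causal mediation with delta-method CIs.

The disparity in outcome Y across groups X (reference-coded indicators),
adjusting for covariates C, is decomposed through a single numeric mediator M
(a mixture index, one congener, or a quantile score) using the standard
two-regression system

    E[M | X, C] = b0 + b1 X + b2 C
    E[Y | X, M, C] = t0 + t1 X + t2 M + t3 X*M + t4 C        (identity link)
    logit Pr[Y=1 | X, M, C] = same linear predictor           (logit link)

For the contrast x=1 vs x*=0 the closed-form effects are

    identity:  CDE(m) = t1 + t3 m
               NDE    = t1 + t3 (b0 + b2 cbar)
               NIE    = (t2 + t3) b1
               TE     = NDE + NIE,  PM = 100 NIE / TE
    logit (rare outcome, odds-ratio scale):
               log CDE(m) = t1 + t3 m
               log NDE    = t1 + t3 (b0 + b2 cbar + t2 s2) + 0.5 t3^2 s2
               log NIE    = (t2 + t3) b1
               log TE     = log NDE + log NIE,  PM = 100 log NIE / log TE

where s2 is the mediator residual variance and cbar the covariate
conditioning point (sample means unless given). Standard errors come from
the delta method: a central-difference gradient of each effect in the
stacked (outcome, mediator) coefficient vector, sandwiched with the
block-diagonal joint covariance of the two fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .results import ContrastEffects, Effect, MediationEffects

__all__ = [
    "fit_total_effect",
    "mediate",
    "MediationFit",
    "binary_mediator_transform",
]

_Z975 = stats.norm.ppf(0.975)
_GRAD_STEP = 1e-6


def _complete_cases(data: pd.DataFrame, cols) -> pd.DataFrame:
    return data.dropna(subset=list(cols))


def _group_dummies(series: pd.Series, reference: str) -> pd.DataFrame:
    levels = [g for g in pd.unique(series) if g != reference]
    if reference not in set(series):
        raise ValueError(f"reference group {reference!r} not present in data")
    return pd.DataFrame({g: (series == g).astype(float) for g in sorted(levels)})


def _pick_link(y: np.ndarray, link: str) -> str:
    if link != "auto":
        return link
    return "logit" if set(np.unique(y)) <= {0, 1, 0.0, 1.0} else "identity"


def fit_total_effect(
    data: pd.DataFrame,
    outcome: str,
    covariates=(),
    group: str = "group",
    reference: str = "white",
    link: str = "auto",
) -> pd.DataFrame:
    """Total group disparity in the outcome, per non-reference contrast.

    Returns a DataFrame indexed by group with columns ``est``, ``se``,
    ``lo``, ``hi`` and attribute ``attrs["scale"]``: the linear coefficient
    in outcome units, or the odds ratio for a binary outcome.
    """
    cols = [group, outcome, *covariates]
    df = _complete_cases(data, cols).reset_index(drop=True)
    y = df[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")
    use_link = _pick_link(y, link)
    dummies = _group_dummies(df[group], reference)
    X = sm.add_constant(
        pd.concat([dummies, df[list(covariates)].astype(float)], axis=1)
        if covariates
        else dummies
    )
    if use_link == "identity":
        fit = sm.OLS(y, np.asarray(X)).fit()
    else:
        fit = sm.Logit(y, np.asarray(X)).fit(disp=0)
    names = list(X.columns)
    rows = {}
    for g in dummies.columns:
        i = names.index(g)
        est, se = fit.params[i], fit.bse[i]
        lo, hi = est - _Z975 * se, est + _Z975 * se
        if use_link == "logit":
            est, lo, hi = math.exp(est), math.exp(lo), math.exp(hi)
        rows[g] = {"est": est, "se": se, "lo": lo, "hi": hi}
    out = pd.DataFrame(rows).T
    out.attrs["scale"] = "difference" if use_link == "identity" else "OR"
    return out


@dataclass
class MediationFit:
    """Fitted single-mediator mediation system with closed-form effects."""

    effects: MediationEffects
    link: str
    reference: str
    sigma2: float
    theta_names: list
    beta_names: list
    params: np.ndarray  # stacked [theta, beta]
    cov: np.ndarray  # block-diagonal joint covariance
    cbar: dict[str, float]
    contrast_groups: list = field(default_factory=list)
    mediator_levels: dict[str, float] = field(default_factory=dict)

    def _effect_fn(self, group: str, name: str, m: float | None = None):
        ti = {n: k for k, n in enumerate(self.theta_names)}
        bi = {n: k + len(self.theta_names) for k, n in enumerate(self.beta_names)}
        inter = f"{group}:m" in ti
        cov_names = [n for n in self.beta_names if n not in ("const", *self.contrast_groups)]

        def parts(z):
            th1 = z[ti[group]]
            th2 = z[ti["m"]]
            th3 = z[ti[f"{group}:m"]] if inter else 0.0
            b0 = z[bi["const"]]
            b1 = z[bi[group]]
            b2c = sum(z[bi[c]] * self.cbar[c] for c in cov_names)
            return th1, th2, th3, b0, b1, b2c

        def f(z):
            th1, th2, th3, b0, b1, b2c = parts(z)
            if self.link == "identity":
                nie = (th2 + th3) * b1
                nde = th1 + th3 * (b0 + b2c)
            else:
                nie = (th2 + th3) * b1
                nde = th1 + th3 * (b0 + b2c + th2 * self.sigma2) + 0.5 * th3**2 * self.sigma2
            te = nde + nie
            if name == "nie":
                return nie
            if name == "nde":
                return nde
            if name == "te":
                return te
            if name == "cde":
                return th1 + th3 * m
            if name == "pm":
                return 100.0 * nie / te
            raise KeyError(name)

        return f

    def _delta(self, fn) -> tuple[float, float]:
        z = self.params
        est = fn(z)
        grad = np.empty_like(z)
        for k in range(z.size):
            zp, zm = z.copy(), z.copy()
            zp[k] += _GRAD_STEP
            zm[k] -= _GRAD_STEP
            grad[k] = (fn(zp) - fn(zm)) / (2 * _GRAD_STEP)
        se = float(np.sqrt(grad @ self.cov @ grad))
        return float(est), se

    def _wrap(self, est: float, se: float, log_scale: bool) -> Effect:
        lo, hi = est - _Z975 * se, est + _Z975 * se
        if log_scale:
            return Effect(math.exp(est), se, (math.exp(lo), math.exp(hi)))
        return Effect(est, se, (lo, hi))

    def cde_at(self, m: float, group: str) -> Effect:
        """Controlled direct effect with the mediator fixed at level ``m``."""
        if not np.isfinite(m):
            raise ValueError("mediator level must be finite")
        est, se = self._delta(self._effect_fn(group, "cde", m))
        return self._wrap(est, se, self.link == "logit")


def mediate(
    data: pd.DataFrame,
    mediator: str,
    outcome: str,
    covariates=(),
    group: str = "group",
    reference: str = "white",
    interaction: bool = False,
    cde_quantiles=(0.25, 0.50, 0.75),
    cvals: dict[str, float] | None = None,
    link: str = "auto",
) -> MediationFit:
    """Single-mediator mediation decomposition with delta-method 95% CIs.

    ``cde_quantiles`` give the full-cohort mediator percentiles at which
    controlled direct effects are evaluated (labelled p25/p50/p75 etc.).
    ``cvals`` optionally fixes covariate conditioning values (default:
    complete-case sample means). PM is undefined (NaN) when TE is zero.
    """
    covariates = list(covariates)
    cols = [group, mediator, outcome, *covariates]
    df = _complete_cases(data, cols).reset_index(drop=True)
    y = df[outcome].to_numpy(dtype=float)
    mvals = df[mediator].to_numpy(dtype=float)
    use_link = _pick_link(y, link)

    dummies = _group_dummies(df[group], reference)
    contrast_groups = list(dummies.columns)
    covf = df[covariates].astype(float)

    # mediator model: M ~ 1 + groups + C
    Xm = pd.concat([dummies, covf], axis=1)
    Xm.insert(0, "const", 1.0)
    med_fit = sm.OLS(mvals, np.asarray(Xm)).fit()
    sigma2 = float(med_fit.scale)

    # outcome model: Y ~ 1 + groups + M (+ groups:M) + C
    Xo = dummies.copy()
    Xo["m"] = mvals
    if interaction:
        for g in contrast_groups:
            Xo[f"{g}:m"] = dummies[g] * mvals
    Xo = pd.concat([Xo, covf], axis=1)
    Xo.insert(0, "const", 1.0)
    if use_link == "identity":
        out_fit = sm.OLS(y, np.asarray(Xo)).fit()
    else:
        out_fit = sm.Logit(y, np.asarray(Xo)).fit(disp=0)

    params = np.concatenate([out_fit.params, med_fit.params])
    p_out = out_fit.params.size
    cov = np.zeros((params.size, params.size))
    cov[:p_out, :p_out] = np.asarray(out_fit.cov_params())
    cov[p_out:, p_out:] = np.asarray(med_fit.cov_params())

    cbar = {c: float(covf[c].mean()) for c in covariates}
    if cvals:
        cbar.update({k: float(v) for k, v in cvals.items()})

    levels = {f"p{int(round(100 * q))}": float(np.quantile(mvals, q)) for q in cde_quantiles}

    fit = MediationFit(
        effects=None,  # filled below
        link=use_link,
        reference=reference,
        sigma2=sigma2,
        theta_names=list(Xo.columns),
        beta_names=list(Xm.columns),
        params=params,
        cov=cov,
        cbar=cbar,
        contrast_groups=contrast_groups,
        mediator_levels=levels,
    )

    log_scale = use_link == "logit"
    contrasts: dict[str, ContrastEffects] = {}
    for g in contrast_groups:
        eff = {}
        for name in ("te", "nde", "nie"):
            est, se = fit._delta(fit._effect_fn(g, name))
            eff[name] = fit._wrap(est, se, log_scale)
        te_raw = fit._effect_fn(g, "te")(params)
        if abs(te_raw) < 1e-12:
            pm = Effect(math.nan)
        else:
            est, se = fit._delta(fit._effect_fn(g, "pm"))
            pm = Effect(est, se, (est - _Z975 * se, est + _Z975 * se))
        cdes = {}
        for lbl, m in levels.items():
            est, se = fit._delta(fit._effect_fn(g, "cde", m))
            cdes[lbl] = fit._wrap(est, se, log_scale)
        contrasts[g] = ContrastEffects(g, te=eff["te"], nde=eff["nde"], nie=eff["nie"], pm=pm, cdes=cdes)

    fit.effects = MediationEffects(
        scale="difference" if use_link == "identity" else "OR",
        reference=reference,
        contrasts=contrasts,
        meta={"n": len(df), "interaction": interaction, "mediator": mediator},
    )
    # keep effects contrasts accessible for _effect_fn's covariate-name filter
    return fit


def binary_mediator_transform(values) -> np.ndarray:
    """Dichotomize a mediator at its sample median (>= median -> 1)."""
    vals = np.asarray(values, dtype=float)
    if np.ptp(vals) == 0:
        raise ValueError("mediator is constant")
    return (vals >= np.median(vals)).astype(int)
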