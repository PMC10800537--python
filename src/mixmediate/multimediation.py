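"""Multiple-mediator mediation by direct counterfactual imputation, and the
g-formula generalization with exposure-induced mediator-outcome confounders.

With J mediators modeled jointly,

    E[M_j | X, C] = b0_j + b1_j X + b2_j C    (multivariate normal residuals
                                               with the empirical residual
                                               covariance)
    E[Y | X, M, C] = t0 + t1 X + t2 . M + t4 C  (+ optional interactions)

the natural effects are estimated by Monte-Carlo counterfactual imputation:
for every subject, mediator vectors M(x) and M(x*) are drawn from the fitted
mediator models at the two exposure levels, outcomes are imputed from the
outcome model at (x, M(x)), (x, M(x*)) and (x*, M(x*)), and the three means
are differenced (TE / NIE / NDE). Controlled direct effects fix all
mediators at a percentile vector. Percentile-bootstrap CIs refit every model
on cohort resamples. For a binary outcome the imputed event probabilities
are compared on the odds-ratio or risk-difference scale.

The g-formula variant adds a vector L of mediator-outcome confounders that
may themselves be affected by the exposure: L(x) is simulated first, then
M | (X, L, C), then Y, yielding randomized-interventional analogues of the
direct and indirect effects. With L empty it reduces to the plain
counterfactual-imputation estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .results import ContrastEffects, Effect, MediationEffects

__all__ = ["mediate_joint", "gformula_effects"]

_Z975 = stats.norm.ppf(0.975)


def _lstsq_fit(X: np.ndarray, Y: np.ndarray):
    """OLS coefficients and residuals for (possibly multi-response) Y."""
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    resid = Y - X @ coef
    return coef, resid


def _logit_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm

    return np.asarray(sm.Logit(y, X).fit(disp=0, maxiter=100).params)


def _psd_cholesky(cov: np.ndarray) -> np.ndarray:
    """Cholesky-like factor tolerating semidefinite covariances (e.g. the
    degenerate zero-residual-variance case)."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        return vecs * np.sqrt(np.clip(vals, 0.0, None))


@dataclass
class _JointModels:
    """Fitted outcome + mediator system on one (re)sample."""

    out_coef: np.ndarray
    med_coef: np.ndarray  # (p_med, J)
    chol: np.ndarray  # residual covariance Cholesky factor (J, J)
    binary: bool


def _design_info(df, group, reference, mediators, covariates, interactions):
    groups = sorted(g for g in pd.unique(df[group]) if g != reference)
    if reference not in set(df[group]):
        raise ValueError(f"reference group {reference!r} not present")
    return groups


def _build_matrices(df, group, reference, contrast_groups, mediators, covariates):
    n = len(df)
    D = np.column_stack([(df[group] == g).to_numpy(dtype=float) for g in contrast_groups])
    M = df[list(mediators)].to_numpy(dtype=float)
    C = (
        df[list(covariates)].to_numpy(dtype=float)
        if covariates
        else np.empty((n, 0))
    )
    ones = np.ones((n, 1))
    X_med = np.hstack([ones, D, C])
    X_out = np.hstack([ones, D, M, C])
    return D, M, C, X_med, X_out


def _fit_system(D, M, C, y, binary) -> _JointModels:
    n = D.shape[0]
    ones = np.ones((n, 1))
    X_med = np.hstack([ones, D, C])
    X_out = np.hstack([ones, D, M, C])
    med_coef, med_resid = _lstsq_fit(X_med, M)
    # residual covariance with the empirical correlation between mediators
    dof = max(n - X_med.shape[1], 1)
    cov = med_resid.T @ med_resid / dof
    chol = _psd_cholesky(cov)
    if binary:
        out_coef = _logit_fit(X_out, y)
    else:
        out_coef, _ = _lstsq_fit(X_out, y)
    return _JointModels(out_coef, med_coef, chol, binary)


def _impute_means(models: _JointModels, gi: int, n_groups: int, C, mc_draws, rng, cde_vectors):
    """Mean imputed outcomes under (x,M(x)), (x,M(x*)), (x*,M(x*)) and CDEs.

    Returns (y_xx, y_xm, y_ss, {label: (y_x_cde, y_s_cde)}), where x is the
    contrast group and x* the reference, averaged over all subjects'
    covariates and ``mc_draws`` mediator draws per subject.
    """
    n = C.shape[0]
    j = models.chol.shape[0]
    ones = np.ones((n, 1))
    D_x = np.zeros((n, n_groups))
    D_x[:, gi] = 1.0
    D_s = np.zeros((n, n_groups))
    Xm_x = np.hstack([ones, D_x, C])
    Xm_s = np.hstack([ones, D_s, C])
    mu_x = Xm_x @ models.med_coef
    mu_s = Xm_s @ models.med_coef

    p = models.out_coef.size
    t0 = models.out_coef[0]
    t1 = models.out_coef[1 : 1 + n_groups]
    t2 = models.out_coef[1 + n_groups : 1 + n_groups + j]
    t4 = models.out_coef[1 + n_groups + j :]
    base = t0 + C @ t4  # (n,)
    lin_x = base + t1[gi]
    lin_s = base

    # The imputed outcome depends on the mediator residual vector eps only
    # through eps @ t2 ~ N(0, t2' Sigma t2); draw that scalar projection
    # directly (exact distributional identity, not an approximation).
    s_proj = float(np.sqrt(t2 @ (models.chol @ models.chol.T) @ t2))

    def mean_y(lin, mu):
        """MC average over mediator draws and subjects of the imputed outcome."""
        acc = 0.0
        chunk = max(1, int(20_000_000 // max(n, 1)))
        done = 0
        base_eta = lin + mu @ t2
        while done < mc_draws:
            d = min(chunk, mc_draws - done)
            eta = base_eta[None, :] + s_proj * rng.standard_normal((d, n))
            if models.binary:
                eta = _expit(eta)
            acc += float(np.sum(eta)) / n
            done += d
        return acc / mc_draws

    y_xx = mean_y(lin_x, mu_x)
    y_xm = mean_y(lin_x, mu_s)
    y_ss = mean_y(lin_s, mu_s)

    cdes = {}
    for label, mvec in cde_vectors.items():
        contrib = float(np.asarray(mvec) @ t2)
        if not models.binary:
            cdes[label] = (float(np.mean(lin_x)) + contrib, float(np.mean(lin_s)) + contrib)
        else:
            cdes[label] = (
                float(np.mean(_expit(lin_x + contrib))),
                float(np.mean(_expit(lin_s + contrib))),
            )
    return y_xx, y_xm, y_ss, cdes


def _expit(x):
    from scipy.special import expit

    return expit(x)


def _effects_from_means(y_xx, y_xm, y_ss, cdes, scale):
    if scale == "difference" or scale == "RD":
        te, nde, nie = y_xx - y_ss, y_xm - y_ss, y_xx - y_xm
        cde = {k: a - b for k, (a, b) in cdes.items()}
    elif scale == "OR":
        odds = lambda p: p / (1 - p)
        te = odds(y_xx) / odds(y_ss)
        nde = odds(y_xm) / odds(y_ss)
        nie = odds(y_xx) / odds(y_xm)
        cde = {k: odds(a) / odds(b) for k, (a, b) in cdes.items()}
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if scale == "OR":
        pm = math.nan if te == 1 else 100.0 * math.log(nie) / math.log(te)
    else:
        pm = math.nan if te == 0 else 100.0 * nie / te
    return te, nde, nie, pm, cde


def mediate_joint(
    data: pd.DataFrame,
    mediators,
    outcome: str,
    covariates=(),
    group: str = "group",
    reference: str = "white",
    mc_draws: int = 1000,
    n_boot: int = 1000,
    seed: int | None = None,
    scale: str = "auto",
    cde_quantiles=(0.25, 0.50, 0.75),
    boot_mc_draws: int | None = None,
    only_groups=None,
) -> MediationEffects:
    """Joint mediation through J mediators by counterfactual imputation.

    ``n_boot=0`` returns point estimates only. ``scale`` is ``"difference"``
    for a continuous outcome and ``"OR"`` or ``"RD"`` for a binary one
    (``"auto"`` picks difference/OR). ``boot_mc_draws`` trades precision for
    speed inside the bootstrap (defaults to ``mc_draws``). ``only_groups``
    restricts which contrasts are imputed (all groups stay in the fits).
    """
    if seed is None:
        raise ValueError("a seed is required")
    if mc_draws < 1:
        raise ValueError("mc_draws must be positive")
    mediators = list(mediators)
    covariates = list(covariates)
    df = data.dropna(subset=[group, outcome, *mediators, *covariates]).reset_index(drop=True)
    contrast_groups = _design_info(df, group, reference, mediators, covariates, None)
    y = df[outcome].to_numpy(dtype=float)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if scale == "auto":
        scale = "OR" if binary else "difference"
    if scale in {"OR", "RD"} and not binary:
        raise ValueError(f"scale {scale!r} requires a binary outcome")

    D, M, C, _, _ = _build_matrices(df, group, reference, contrast_groups, mediators, covariates)
    cde_vectors = {
        f"p{int(round(100 * q))}": np.quantile(M, q, axis=0) for q in cde_quantiles
    }
    rng = np.random.default_rng(seed)
    models = _fit_system(D, M, C, y, binary)
    report_groups = list(only_groups) if only_groups else contrast_groups

    point = {}
    for gi, g in enumerate(contrast_groups):
        if g not in report_groups:
            continue
        means = _impute_means(models, gi, len(contrast_groups), C, mc_draws, rng, cde_vectors)
        point[g] = _effects_from_means(*means, scale)

    boot: dict[str, list] = {g: [] for g in report_groups}
    bdraws = boot_mc_draws or mc_draws
    n = len(df)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if len(set(df[group].iloc[idx])) < len(contrast_groups) + 1:
            raise RuntimeError("bootstrap resample lost a group; increase n")
        bm = _fit_system(D[idx], M[idx], C[idx], y[idx], binary)
        for gi, g in enumerate(contrast_groups):
            if g not in report_groups:
                continue
            means = _impute_means(bm, gi, len(contrast_groups), C[idx], bdraws, rng, cde_vectors)
            boot[g].append(_effects_from_means(*means, scale))

    contrasts = {}
    for g in report_groups:
        te, nde, nie, pm, cde = point[g]
        if n_boot:
            reps = boot[g]
            def pci(k):
                vals = np.array([r[k] for r in reps])
                return tuple(np.percentile(vals, [2.5, 97.5]))
            eff = ContrastEffects(
                g,
                te=Effect(te, ci=pci(0)),
                nde=Effect(nde, ci=pci(1)),
                nie=Effect(nie, ci=pci(2)),
                pm=Effect(pm, ci=pci(3)),
                cdes={
                    k: Effect(v, ci=tuple(np.percentile([r[4][k] for r in reps], [2.5, 97.5])))
                    for k, v in cde.items()
                },
            )
        else:
            eff = ContrastEffects(
                g,
                te=Effect(te),
                nde=Effect(nde),
                nie=Effect(nie),
                pm=Effect(pm),
                cdes={k: Effect(v) for k, v in cde.items()},
            )
        contrasts[g] = eff
    return MediationEffects(
        scale,
        reference,
        contrasts,
        meta={"n": n, "mc_draws": mc_draws, "n_boot": n_boot, "seed": seed, "mediators": mediators},
    )


def gformula_effects(
    data: pd.DataFrame,
    mediators,
    outcome: str,
    covariates=(),
    post_exposure_confounders=(),
    group: str = "group",
    reference: str = "white",
    scale: str = "auto",
    mc_draws: int = 1000,
    n_boot: int = 0,
    seed: int | None = None,
    cde_quantiles=(0.25, 0.50, 0.75),
) -> MediationEffects:
    """Monte-Carlo g-formula with exposure-induced mediator-outcome confounders.

    L-variables are modeled linearly given (X, C); mediators given (X, L, C);
    the outcome given (X, M, L, C). Randomized-interventional analogues of
    NDE/NIE are reported. With no L this equals :func:`mediate_joint` up to
    Monte-Carlo error.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if mc_draws < 1:
        raise ValueError("mc_draws must be positive")
    mediators = list(mediators)
    covariates = list(covariates)
    lvars = list(post_exposure_confounders)
    if not lvars:
        return mediate_joint(
            data, mediators, outcome, covariates, group, reference,
            mc_draws=mc_draws, n_boot=n_boot, seed=seed, scale=scale,
            cde_quantiles=cde_quantiles,
        )
    df = data.dropna(subset=[group, outcome, *mediators, *lvars, *covariates]).reset_index(drop=True)
    contrast_groups = _design_info(df, group, reference, mediators, covariates, None)
    y = df[outcome].to_numpy(dtype=float)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    if scale == "auto":
        scale = "OR" if binary else "difference"

    n = len(df)
    D = np.column_stack([(df[group] == g).to_numpy(dtype=float) for g in contrast_groups])
    L = df[lvars].to_numpy(dtype=float)
    M = df[mediators].to_numpy(dtype=float)
    C = df[covariates].to_numpy(dtype=float) if covariates else np.empty((n, 0))
    ones = np.ones((n, 1))

    X_l = np.hstack([ones, D, C])
    l_coef, l_resid = _lstsq_fit(X_l, L)
    l_chol = _psd_cholesky(l_resid.T @ l_resid / max(n - X_l.shape[1], 1))
    X_m = np.hstack([ones, D, L, C])
    m_coef, m_resid = _lstsq_fit(X_m, M)
    m_chol = _psd_cholesky(m_resid.T @ m_resid / max(n - X_m.shape[1], 1))
    X_o = np.hstack([ones, D, M, L, C])
    if binary:
        o_coef = _logit_fit(X_o, y)
    else:
        o_coef, _ = _lstsq_fit(X_o, y)

    rng = np.random.default_rng(seed)
    jm, jl = M.shape[1], L.shape[1]
    ng = len(contrast_groups)
    t0, t1 = o_coef[0], o_coef[1 : 1 + ng]
    t2 = o_coef[1 + ng : 1 + ng + jm]
    t_l = o_coef[1 + ng + jm : 1 + ng + jm + jl]
    t4 = o_coef[1 + ng + jm + jl :]
    base_c = t0 + C @ t4

    cde_vectors = {f"p{int(round(100 * q))}": np.quantile(M, q, axis=0) for q in cde_quantiles}

    def run_contrast(gi):
        acc = np.zeros(3)
        cde_acc = {k: np.zeros(2) for k in cde_vectors}
        Dx = np.zeros((n, ng)); Dx[:, gi] = 1.0
        Ds = np.zeros((n, ng))
        mu_l_x = np.hstack([ones, Dx, C]) @ l_coef
        mu_l_s = np.hstack([ones, Ds, C]) @ l_coef
        chunk = max(1, int(1_000_000 // max(n, 1)))
        done = 0
        while done < mc_draws:
            d = min(chunk, mc_draws - done)
            zl = rng.standard_normal((d, n, jl))
            L_x = mu_l_x[None] + zl @ l_chol.T
            L_s = mu_l_s[None] + zl @ l_chol.T  # common draws: shared L noise
            zm = rng.standard_normal((d, n, jm)) @ m_chol.T
            zm2 = rng.standard_normal((d, n, jm)) @ m_chol.T

            def mu_m(Dmat, Lmat):
                return (
                    m_coef[0][None, None, :]
                    + np.tensordot(Dmat, m_coef[1 : 1 + ng], axes=(1, 0))[None]
                    + Lmat @ m_coef[1 + ng : 1 + ng + jl]
                    + (C @ m_coef[1 + ng + jl :])[None]
                )

            M_x = mu_m(Dx, L_x) + zm
            M_s = mu_m(Ds, L_s) + zm2  # draw from the x* mediator distribution

            def ev(Dmat, Mmat, Lmat):
                eta = (
                    base_c[None]
                    + (Dmat @ t1)[None]
                    + Mmat @ t2
                    + Lmat @ t_l
                )
                return _expit(eta) if binary else eta

            y_xx = ev(Dx, M_x, L_x)
            y_xm = ev(Dx, M_s, L_x)
            y_ss = ev(Ds, M_s, L_s)
            acc += np.array([y_xx.mean(), y_xm.mean(), y_ss.mean()]) * d
            for k, mvec in cde_vectors.items():
                contrib = float(np.asarray(mvec) @ t2)
                e_x = base_c[None] + (Dx @ t1)[None] + contrib + L_x @ t_l
                e_s = base_c[None] + (Ds @ t1)[None] + contrib + L_s @ t_l
                if binary:
                    e_x, e_s = _expit(e_x), _expit(e_s)
                cde_acc[k] += np.array([e_x.mean(), e_s.mean()]) * d
            done += d
        acc /= mc_draws
        cdes = {k: tuple(v / mc_draws) for k, v in cde_acc.items()}
        return _effects_from_means(acc[0], acc[1], acc[2], cdes, scale)

    contrasts = {}
    for gi, g in enumerate(contrast_groups):
        te, nde, nie, pm, cde = run_contrast(gi)
        contrasts[g] = ContrastEffects(
            g, te=Effect(te), nde=Effect(nde), nie=Effect(nie), pm=Effect(pm),
            cdes={k: Effect(v) for k, v in cde.items()},
        )
    return MediationEffects(
        scale, reference, contrasts,
        meta={"n": n, "mc_draws": mc_draws, "seed": seed, "post_exposure_confounders": lvars},
    )
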