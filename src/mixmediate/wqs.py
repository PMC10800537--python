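"""Mixture indices: weighted quantile sum (WQS) and quantile g-computation.

WQS collapses a set of correlated exposures into one index
``WQS_i = sum_j w_j q_ij`` with quantile scores ``q_ij`` in ``0..q-1`` and
weights constrained to the simplex (``w_j >= 0``, ``sum w_j = 1``), the index
coefficient constrained to one direction. Weights are estimated on bootstrap
resamples of a training split and averaged; the index association is then
re-estimated on the held-out validation split.

Writing ``b_j = beta1 * w_j`` turns each bootstrap fit into a convex
sign-constrained regression (all ``b_j <= 0`` for the negative direction),
solved exactly with bounded least squares (identity link) or a bounded
quasi-Newton on the logistic likelihood — no restarts are required since the
optimum is global.

Quantile g-computation drops the unidirectionality assumption: a single
joint fit on all quantile scores gives per-exposure slopes, their sum
``psi`` (the mixture effect per joint quantile increase) and
sign-partitioned weights; the negatively-weighted exposures can be re-formed
into a direction-specific index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit

from .prep import quantize

__all__ = ["WQSFit", "QGCompFit", "fit_wqs", "wqs_index", "fit_qgcomp", "negative_index"]

_Z975 = stats.norm.ppf(0.975)


@dataclass
class WQSFit:
    """Fitted weighted quantile sum index."""

    exposures: tuple[str, ...]
    weights: np.ndarray  # simplex, averaged over valid bootstrap iterates
    direction: str
    q: int
    split: float
    n_boot: int
    n_valid_boot: int
    boot_weights: np.ndarray  # (n_valid_boot, J)
    boot_beta1: np.ndarray
    beta1: float  # validation-set index coefficient
    beta1_se: float
    beta1_ci: tuple[float, float]
    index: np.ndarray  # per-subject index, full cohort
    quantized: pd.DataFrame = field(repr=False, default=None)


def _quantize_frame(data: pd.DataFrame, exposures, q: int) -> pd.DataFrame:
    out = {}
    for e in exposures:
        vals = data[e].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            raise ValueError(f"exposure {e!r} is constant")
        out[e] = quantize(vals, q=q)
    return pd.DataFrame(out, index=data.index)


def _bounded_fit(Q: np.ndarray, C: np.ndarray, y: np.ndarray, direction: str, binary: bool) -> np.ndarray | None:
    """Solve the sign-constrained WQS likelihood; returns b (J exposure
    coefficients) or None when the fit is degenerate (all-zero b)."""
    j = Q.shape[1]
    X = np.column_stack([Q, C])
    if direction == "negative":
        ub = np.concatenate([np.zeros(j), np.full(C.shape[1], np.inf)])
        lb = np.full(X.shape[1], -np.inf)
    else:
        lb = np.concatenate([np.zeros(j), np.full(C.shape[1], -np.inf)])
        ub = np.full(X.shape[1], np.inf)
    if not binary:
        res = optimize.lsq_linear(X, y, bounds=(lb, ub), tol=1e-10)
        b = res.x[:j]
    else:
        def nll_grad(beta):
            eta = X @ beta
            p = expit(eta)
            return -(y @ eta - np.logaddexp(0, eta).sum()), X.T @ (p - y)

        x0 = np.zeros(X.shape[1])
        res = optimize.minimize(
            nll_grad, x0, jac=True, method="L-BFGS-B",
            bounds=list(zip(lb, ub)), options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if not res.success:
            return None
        b = res.x[:j]
    beta1 = b.sum()
    if abs(beta1) < 1e-10:
        return None  # constraint collapsed: no correctly-signed signal
    return b


def fit_wqs(
    data: pd.DataFrame,
    exposures,
    outcome: str,
    covariates=(),
    q: int = 4,
    split: float = 0.4,
    n_boot: int = 500,
    direction: str = "negative",
    seed: int | None = None,
) -> WQSFit:
    """Estimate WQS weights on bootstrapped training fits, validate the index.

    ``split`` is the training fraction (default 40% train / 60% validation).
    Bootstrap iterates whose constrained fit collapses to a zero index
    coefficient are dropped from the weight average; if all collapse a
    ``RuntimeError`` is raised (the data carry no association in the
    requested direction). The returned index covers the full cohort.
    """
    if direction not in {"negative", "positive"}:
        raise ValueError("direction must be 'negative' or 'positive'")
    exposures = tuple(exposures)
    if len(exposures) < 1:
        raise ValueError("at least one exposure required")
    if seed is None:
        raise ValueError("a seed is required")
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    covariates = list(covariates)
    df = data.dropna(subset=[outcome, *exposures, *covariates]).reset_index(drop=True)
    rng = np.random.default_rng(seed)

    Qf = _quantize_frame(df, exposures, q)
    y = df[outcome].to_numpy(dtype=float)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    C = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates])

    n = len(df)
    perm = rng.permutation(n)
    n_train = int(round(split * n))
    train, valid = perm[:n_train], perm[n_train:]

    Qt = Qf.to_numpy(dtype=float)[train]
    yt, Ct = y[train], C[train]
    boot_w, boot_b1 = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, len(train), len(train))
        b = _bounded_fit(Qt[idx], Ct[idx], yt[idx], direction, binary)
        if b is None:
            continue
        beta1 = b.sum()
        boot_w.append(b / beta1)
        boot_b1.append(beta1)
    if not boot_w:
        raise RuntimeError(
            "no bootstrap iterate yielded a correctly-signed index coefficient; "
            "the outcome-exposure association may run opposite to `direction`"
        )
    boot_w = np.asarray(boot_w)
    weights = boot_w.mean(axis=0)
    weights = weights / weights.sum()

    index = Qf.to_numpy(dtype=float) @ weights
    Xv = np.column_stack([np.ones(valid.size), index[valid], C[valid, 1:]])
    if binary:
        vfit = sm.Logit(y[valid], Xv).fit(disp=0)
    else:
        vfit = sm.OLS(y[valid], Xv).fit()
    beta1, se = float(vfit.params[1]), float(vfit.bse[1])

    return WQSFit(
        exposures=exposures,
        weights=weights,
        direction=direction,
        q=q,
        split=split,
        n_boot=n_boot,
        n_valid_boot=len(boot_b1),
        boot_weights=boot_w,
        boot_beta1=np.asarray(boot_b1),
        beta1=beta1,
        beta1_se=se,
        beta1_ci=(beta1 - _Z975 * se, beta1 + _Z975 * se),
        index=index,
        quantized=Qf,
    )


def wqs_index(fit: WQSFit, quantized: pd.DataFrame) -> np.ndarray:
    """Apply fitted weights to quantile scores: ``sum_j w_j q_ij``."""
    missing = [e for e in fit.exposures if e not in quantized.columns]
    if missing:
        raise KeyError(f"quantized exposures missing column(s): {missing}")
    return quantized[list(fit.exposures)].to_numpy(dtype=float) @ fit.weights


@dataclass
class QGCompFit:
    """Quantile g-computation fit: joint quantile slopes and psi."""

    exposures: tuple[str, ...]
    coefs: np.ndarray
    psi: float
    psi_se: float
    psi_ci: tuple[float, float]
    pos_weights: dict[str, float]
    neg_weights: dict[str, float]
    q: int
    quantized: pd.DataFrame = field(repr=False, default=None)


def fit_qgcomp(
    data: pd.DataFrame,
    exposures,
    outcome: str,
    covariates=(),
    q: int = 4,
) -> QGCompFit:
    """One joint (linear or logistic) fit on all quantile-scored exposures.

    ``psi`` is the sum of the exposure coefficients — the expected outcome
    change for a simultaneous one-quantile increase in every exposure.
    Weights are coefficients normalized within their sign partition.
    """
    exposures = tuple(exposures)
    covariates = list(covariates)
    df = data.dropna(subset=[outcome, *exposures, *covariates]).reset_index(drop=True)
    Qf = _quantize_frame(df, exposures, q)
    y = df[outcome].to_numpy(dtype=float)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    X = np.column_stack(
        [np.ones(len(df)), Qf.to_numpy(dtype=float)]
        + [df[c].to_numpy(dtype=float) for c in covariates]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design is rank-deficient after quantization")
    fit = sm.Logit(y, X).fit(disp=0) if binary else sm.OLS(y, X).fit()
    j = len(exposures)
    coefs = np.asarray(fit.params[1 : 1 + j])
    contrast = np.zeros(X.shape[1])
    contrast[1 : 1 + j] = 1.0
    psi = float(coefs.sum())
    psi_se = float(np.sqrt(contrast @ np.asarray(fit.cov_params()) @ contrast))
    pos = {e: c for e, c in zip(exposures, coefs) if c > 0}
    neg = {e: c for e, c in zip(exposures, coefs) if c < 0}
    pos_total = sum(pos.values())
    neg_total = sum(neg.values())
    return QGCompFit(
        exposures=exposures,
        coefs=coefs,
        psi=psi,
        psi_se=psi_se,
        psi_ci=(psi - _Z975 * psi_se, psi + _Z975 * psi_se),
        pos_weights={e: c / pos_total for e, c in pos.items()},
        neg_weights={e: c / neg_total for e, c in neg.items()},
        q=q,
        quantized=Qf,
    )


def negative_index(fit: QGCompFit, quantized: pd.DataFrame) -> np.ndarray:
    """Weighted index over the negatively-associated exposure partition."""
    if not fit.neg_weights:
        raise ValueError("negative partition is empty")
    names = list(fit.neg_weights)
    missing = [e for e in names if e not in quantized.columns]
    if missing:
        raise KeyError(f"quantized exposures missing column(s): {missing}")
    w = np.array([fit.neg_weights[e] for e in names])
    return quantized[names].to_numpy(dtype=float) @ w
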