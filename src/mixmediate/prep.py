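"""Deterministic transforms from raw chemical measurements to analysis-ready mediators.

Plasma concentrations of persistent organic pollutants are conventionally
reported per volume of plasma (ng/mL) but partition into circulating lipids, so
descriptive summaries use lipid-adjusted concentrations (ng/g lipid) and a
molar sum across congeners (pmol/g lipid).  Regression mediators instead use
the natural-log-transformed, standardized machine-observed plasma values,
keeping values below the limit of quantification (LOQ) unsubstituted.

All functions here are pure and operate on numpy arrays / pandas Series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChemicalMeta",
    "PBDE_METADATA",
    "total_lipids",
    "lipid_adjust",
    "molar_sum",
    "geometric_mean",
    "log_standardize",
    "quantize",
]


@dataclass(frozen=True)
class ChemicalMeta:
    """Per-congener metadata: name, limit of quantification, molecular weight.

    Parameters
    ----------
    name : str
        Congener label, e.g. ``"pbde_47"``.
    loq : float
        Limit of quantification in ng/mL plasma. Must be positive.
    mw : float
        Molecular weight in g/mol. Must be positive.
    """

    name: str
    loq: float
    mw: float

    def __post_init__(self) -> None:
        if not self.loq > 0:
            raise ValueError(f"LOQ must be positive, got {self.loq}")
        if not self.mw > 0:
            raise ValueError(f"molecular weight must be positive, got {self.mw}")


# Default metadata for the six flame-retardant congeners handled by the
# built-in scenarios. Molecular weights are config data and overridable;
# LOQs are nominal values for a typical GC-MS/MS assay.
PBDE_METADATA: tuple[ChemicalMeta, ...] = (
    ChemicalMeta("pbde_28", loq=0.002, mw=406.90),
    ChemicalMeta("pbde_47", loq=0.004, mw=485.79),
    ChemicalMeta("pbde_99", loq=0.004, mw=564.69),
    ChemicalMeta("pbde_100", loq=0.002, mw=564.69),
    ChemicalMeta("pbde_153", loq=0.002, mw=643.58),
    ChemicalMeta("pbde_154", loq=0.002, mw=643.58),
)


def total_lipids(total_cholesterol, triglycerides):
    """Total plasma lipids (mg/dL) from the enzymatic summary formula.

    ``TL = TC * 2.27 + TG + 62.3`` with both inputs in mg/dL.
    """
    tc = np.asarray(total_cholesterol, dtype=float)
    tg = np.asarray(triglycerides, dtype=float)
    if np.any(tc < 0) or np.any(tg < 0):
        raise ValueError("cholesterol and triglycerides must be non-negative")
    out = tc * 2.27 + tg + 62.3
    return out if out.ndim else float(out)


def lipid_adjust(conc, lipids):
    """Convert a plasma concentration (ng/mL) to a lipid basis (ng/g lipid).

    Total lipids in mg/dL equal ``lipids * 1e-5`` g/mL, so
    ``ng/g = conc * 1e5 / lipids``.
    """
    c = np.asarray(conc, dtype=float)
    lip = np.asarray(lipids, dtype=float)
    if np.any(lip <= 0):
        raise ValueError("total lipids must be positive")
    out = c * 1.0e5 / lip
    return out if out.ndim else float(out)


def molar_sum(lipid_adjusted: pd.DataFrame | dict, meta: Sequence[ChemicalMeta]) -> pd.Series | float:
    """Molar sum of detectable congeners, in pmol/g lipid.

    Each lipid-adjusted concentration (ng/g) is divided by its molecular
    weight (g/mol) and the detectable (strictly positive machine values)
    contributions are summed; ng/g / (g/mol) = nmol/g, hence the factor 1000.

    Parameters
    ----------
    lipid_adjusted : DataFrame or mapping congener name -> values (ng/g lipid)
    meta : sequence of :class:`ChemicalMeta` covering every congener present.
    """
    frame = pd.DataFrame(lipid_adjusted, index=None if isinstance(lipid_adjusted, pd.DataFrame) else [0])
    mw = {m.name: m.mw for m in meta}
    missing = [c for c in frame.columns if c not in mw]
    if missing:
        raise KeyError(f"no molecular weight for congener(s): {missing}")
    total = pd.Series(0.0, index=frame.index)
    for col in frame.columns:
        vals = frame[col].to_numpy(dtype=float)
        detectable = vals > 0
        total += np.where(detectable, vals / mw[col] * 1000.0, 0.0)
    if not isinstance(lipid_adjusted, pd.DataFrame):
        return float(total.iloc[0])
    return total


def _substitute_nonpositive(values: np.ndarray) -> np.ndarray:
    """Replace zero/negative machine values by (lowest positive value)/2."""
    pos = values[values > 0]
    if pos.size == 0:
        raise ValueError("no positive values to anchor the substitution rule")
    return np.where(values > 0, values, pos.min() / 2.0)


def geometric_mean(values, with_ci: bool = False, alpha: float = 0.05):
    """Geometric mean of concentrations, with optional t-based 95% CI.

    Zero and negative machine values are assigned half the lowest positive
    value before log-transforming. The CI is a t-interval on the log scale,
    exponentiated.
    """
    vals = np.asarray(values, dtype=float).ravel()
    vals = _substitute_nonpositive(vals)
    logs = np.log(vals)
    gm = float(np.exp(logs.mean()))
    if not with_ci:
        return gm
    n = logs.size
    if n < 2:
        return gm, (float("nan"), float("nan"))
    half = stats.t.ppf(1 - alpha / 2, n - 1) * logs.std(ddof=1) / np.sqrt(n)
    return gm, (float(np.exp(logs.mean() - half)), float(np.exp(logs.mean() + half)))


def log_standardize(values) -> np.ndarray:
    """Natural-log-transform then z-score (sample sd, ddof=1).

    Non-positive machine values are first assigned half the lowest positive
    value so the log is defined; constant input is an error.
    """
    vals = np.asarray(values, dtype=float).ravel()
    logs = np.log(_substitute_nonpositive(vals))
    sd = logs.std(ddof=1)
    if not sd > 0:
        raise ValueError("cannot standardize constant values")
    return (logs - logs.mean()) / sd


def quantize(values, q: int = 4, loq: float | None = None) -> np.ndarray:
    """Score values into ordinal quantile categories.

    Without ``loq``: integer scores ``0..q-1`` from type-7 empirical quantile
    cut points; a value equal to a cut point falls in the lower category.
    With ``loq``: category 0 for values below the LOQ and categories ``1..q``
    for the q-tiles of the values at or above it (so q=4 yields the
    "<LOQ + quartiles above LOQ" coding with 5 levels).
    """
    if q < 2:
        raise ValueError("q must be at least 2")
    vals = np.asarray(values, dtype=float).ravel()
    if loq is None:
        cuts = np.quantile(vals, np.arange(1, q) / q)
        return np.searchsorted(cuts, vals, side="left").astype(int)
    above = vals >= loq
    if not above.any():
        raise ValueError("all values fall below the LOQ")
    cuts = np.quantile(vals[above], np.arange(1, q) / q)
    cats = np.zeros(vals.size, dtype=int)
    cats[above] = 1 + np.searchsorted(cuts, vals[above], side="left")
    return cats


def load_chemical_meta(path) -> list[ChemicalMeta]:
    """Read congener metadata (name, loq, mw) from a YAML file."""
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [ChemicalMeta(e["name"], float(e["loq"]), float(e["mw"])) for e in entries]
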