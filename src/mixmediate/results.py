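"""Containers for mediation effect estimates.

A mediation analysis reports, for each group contrast against the reference,
the total effect (TE), natural direct effect (NDE), natural indirect effect
(NIE), controlled direct effects (CDE) with the mediator(s) fixed at chosen
levels, and the proportion mediated PM = (NIE/TE) x 100%. Effects are on the
mean-difference scale for continuous outcomes and on the odds-ratio (or
risk-difference) scale for binary outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Effect", "ContrastEffects", "MediationEffects"]


@dataclass
class Effect:
    """A point estimate with optional standard error and 95% CI."""

    est: float
    se: float | None = None
    ci: tuple[float, float] = (math.nan, math.nan)

    def __repr__(self) -> str:  # compact: "-0.263 (-0.51, -0.01)"
        if math.isnan(self.ci[0]):
            return f"{self.est:.4g}"
        return f"{self.est:.4g} ({self.ci[0]:.4g}, {self.ci[1]:.4g})"


@dataclass
class ContrastEffects:
    """All effect measures for one group-vs-reference contrast."""

    group: str
    te: Effect
    nde: Effect
    nie: Effect
    pm: Effect
    cdes: dict[str, Effect] = field(default_factory=dict)


@dataclass
class MediationEffects:
    """Effect estimates for every non-reference group contrast.

    ``scale`` is ``"difference"`` (weeks, for gestational age),
    ``"OR"`` (odds ratios, rare binary outcome) or ``"RD"`` (risk
    differences). On the OR scale multiplicativity replaces additivity:
    ``log TE = log NDE + log NIE`` and PM is computed on the log-OR scale.
    """

    scale: str
    reference: str
    contrasts: dict[str, ContrastEffects]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, group: str) -> ContrastEffects:
        return self.contrasts[group]

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per contrast, effect columns with CIs."""
        rows = []
        for g, c in self.contrasts.items():
            row: dict = {"group": g, "scale": self.scale}
            for name, eff in (("NDE", c.nde), ("NIE", c.nie), ("TE", c.te), ("PM", c.pm)):
                row[name] = eff.est
                row[f"{name}_lo"], row[f"{name}_hi"] = eff.ci
            for label, eff in c.cdes.items():
                row[f"CDE({label})"] = eff.est
                row[f"CDE({label})_lo"], row[f"CDE({label})_hi"] = eff.ci
            rows.append(row)
        return pd.DataFrame(rows).set_index("group")
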