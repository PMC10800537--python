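"""End-to-end analysis pipeline: prep -> mixture index -> mediation forms.

Drives the full disparity-decomposition workflow from a YAML config:
descriptive geometric-mean tables of lipid-adjusted congener concentrations,
a weighted-quantile-sum mixture index, and mediation through the index, a
single congener, or all congeners jointly, with the sensitivity variants
(binary index, quantile-scored mediators, quantile-g-computation index).

Model mediators are the log-standardized plasma concentrations (plasma
lipids can be included as a covariate); lipid-adjusted concentrations are
used for descriptives only.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import prep
from .mediation import binary_mediator_transform, fit_total_effect, mediate
from .multimediation import mediate_joint
from .wqs import fit_qgcomp, fit_wqs, negative_index

__all__ = ["AnalysisConfig", "run", "descriptives"]


@dataclass
class AnalysisConfig:
    """Configuration for :func:`run`. Loadable from YAML via ``from_yaml``."""

    input: str
    outdir: str
    seed: int
    congeners: list = field(default_factory=list)
    covariates: list = field(default_factory=list)
    group_col: str = "group"
    reference: str = "white"
    ga_col: str = "ga_weeks"
    ptb_col: str = "ptb"
    lipids_col: str | None = None
    chemical_meta: str | None = None
    outcome: str = "both"  # GA | PTB | both
    ptb_cutoff: float = 37.0
    mediator_forms: list = field(default_factory=lambda: ["wqs"])
    q: int = 4
    n_boot: int = 1000
    wqs_n_boot: int = 500
    mc_draws: int = 1000

    def __post_init__(self) -> None:
        if not 20 < self.ptb_cutoff < 42:
            raise ValueError("ptb_cutoff must lie in (20, 42) weeks")
        if self.outcome not in {"GA", "PTB", "both"}:
            raise ValueError("outcome must be GA, PTB or both")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def descriptives(
    cohort: pd.DataFrame,
    congeners,
    meta=None,
    group_col: str = "group",
    ptb_col: str | None = "ptb",
    lipids_col: str | None = None,
) -> pd.DataFrame:
    """Geometric means (95% CI) of lipid-adjusted congener concentrations and
    their molar sum, stratified by group and by preterm status.

    When ``lipids_col`` is None concentrations are summarized as given.
    """
    meta = list(meta) if meta is not None else list(prep.PBDE_METADATA)
    congeners = [c for c in congeners]
    rows = []

    def strata():
        yield "overall", pd.Series(True, index=cohort.index)
        for g in pd.unique(cohort[group_col]):
            yield f"group:{g}", cohort[group_col] == g
        if ptb_col is not None and ptb_col in cohort:
            yield "ptb:yes", cohort[ptb_col] == 1
            yield "ptb:no", cohort[ptb_col] == 0

    for label, mask in strata():
        sub = cohort[mask]
        if sub.empty:
            continue
        if lipids_col is not None:
            adj = pd.DataFrame(
                {c: prep.lipid_adjust(sub[c].to_numpy(float), sub[lipids_col].to_numpy(float)) for c in congeners}
            )
        else:
            adj = sub[congeners].astype(float).reset_index(drop=True)
        for c in congeners:
            gm, ci = prep.geometric_mean(adj[c], with_ci=True)
            rows.append({"stratum": label, "chemical": c, "gm": gm, "lo": ci[0], "hi": ci[1], "n": len(sub)})
        msum = prep.molar_sum(adj, meta)
        gm, ci = prep.geometric_mean(msum, with_ci=True)
        rows.append({"stratum": label, "chemical": "molar_sum", "gm": gm, "lo": ci[0], "hi": ci[1], "n": len(sub)})
    return pd.DataFrame(rows)


def _child_seed(seed: int, offset: int) -> int:
    return (seed * 97 + offset) % (2**31 - 1)


def run(config: AnalysisConfig) -> dict:
    """Execute the configured stages; write CSV tables, JSON bundle and log.

    Returns the results bundle (also written to ``<outdir>/results.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"started {time.strftime('%Y-%m-%d %H:%M:%S')}", f"seed {config.seed}"]
    data = pd.read_csv(config.input)

    needed = {config.group_col, *config.covariates, *config.congeners}
    if config.outcome in {"GA", "both"}:
        needed.add(config.ga_col)
    if config.outcome in {"PTB", "both"}:
        needed.add(config.ptb_col if config.ptb_col in data.columns else config.ga_col)
    missing_cols = sorted(c for c in needed if c not in data.columns)
    if missing_cols:
        raise KeyError(f"input is missing column(s): {missing_cols}")

    n_raw = len(data)
    model_cols = [config.group_col, *config.covariates, *config.congeners]
    data = data.dropna(subset=[c for c in model_cols if c in data.columns]).reset_index(drop=True)
    log.append(f"complete-case exclusions: {n_raw - len(data)} of {n_raw}")
    for g, cnt in data[config.group_col].value_counts().items():
        log.append(f"n[{g}] = {cnt}")
        if cnt == 0:
            raise ValueError(f"group {g!r} empty after complete-case filtering")

    if config.ptb_col not in data.columns and config.ga_col in data.columns:
        data[config.ptb_col] = (data[config.ga_col] < config.ptb_cutoff).astype(int)

    meta = prep.load_chemical_meta(config.chemical_meta) if config.chemical_meta else list(prep.PBDE_METADATA)
    bundle: dict = {"config": asdict(config), "tables": {}}

    # log-standardized model mediators
    zcols = {}
    for c in config.congeners:
        z = prep.log_standardize(data[c].to_numpy(float))
        data[f"z_{c}"] = z
        zcols[c] = f"z_{c}"

    if config.congeners:
        desc = descriptives(
            data, config.congeners, meta, config.group_col, config.ptb_col, config.lipids_col
        )
        desc.to_csv(outdir / "descriptives.csv", index=False)
        bundle["tables"]["descriptives"] = "descriptives.csv"

    outcomes = []
    if config.outcome in {"GA", "both"}:
        outcomes.append((config.ga_col, "GA"))
    if config.outcome in {"PTB", "both"}:
        outcomes.append((config.ptb_col, "PTB"))

    wqs_fit = None
    forms = list(config.mediator_forms)
    needs_wqs = any(f in {"wqs", "binary-wqs", "quantile-mediators"} for f in forms)
    if needs_wqs:
        if not config.congeners:
            raise ValueError("WQS forms require congener columns")
        wqs_fit = fit_wqs(
            data, config.congeners, config.ga_col, config.covariates,
            q=config.q, n_boot=config.wqs_n_boot,
            direction="negative", seed=_child_seed(config.seed, 1),
        )
        data["wqs_index"] = wqs_fit.index
        bundle["wqs"] = {
            "weights": dict(zip(wqs_fit.exposures, wqs_fit.weights.tolist())),
            "validation_beta1": wqs_fit.beta1,
            "validation_ci": list(wqs_fit.beta1_ci),
            "n_valid_boot": wqs_fit.n_valid_boot,
        }
        log.append(f"wqs: {wqs_fit.n_valid_boot}/{wqs_fit.n_boot} valid bootstrap iterates")

    def run_single(mediator_col, tag, offset):
        for ycol, yname in outcomes:
            fit = mediate(
                data, mediator_col, ycol, config.covariates,
                group=config.group_col, reference=config.reference,
            )
            frame = fit.effects.to_frame()
            fname = f"mediation_{tag}_{yname}.csv"
            frame.to_csv(outdir / fname)
            bundle["tables"][f"{tag}:{yname}"] = fname
            bundle.setdefault("effects", {})[f"{tag}:{yname}"] = json.loads(frame.to_json(orient="index"))

    for form in forms:
        if form == "wqs":
            run_single("wqs_index", "wqs", 2)
        elif form == "binary-wqs":
            data["wqs_binary"] = binary_mediator_transform(data["wqs_index"])
            run_single("wqs_binary", "binary_wqs", 3)
        elif form == "quantile-mediators":
            data["wqs_quintile"] = prep.quantize(data["wqs_index"].to_numpy(float), q=5)
            run_single("wqs_quintile", "wqs_quintile", 4)
            loqs = {m.name: m.loq for m in meta}
            for c in config.congeners:
                data[f"q_{c}"] = prep.quantize(data[c].to_numpy(float), q=4, loq=loqs.get(c))
                run_single(f"q_{c}", f"quantile_{c}", 5)
        elif form.startswith("single:"):
            col = form.split(":", 1)[1]
            if col not in data.columns and col not in zcols:
                raise KeyError(f"mediator column {col!r} not in input")
            run_single(zcols.get(col, col), f"single_{col}", 6)
        elif form == "multi":
            missing = [c for c in config.congeners if c not in data.columns]
            if missing:
                raise KeyError(f"multi-mediator form missing column(s): {missing}")
            for ycol, yname in outcomes:
                eff = mediate_joint(
                    data, [zcols[c] for c in config.congeners], ycol, config.covariates,
                    group=config.group_col, reference=config.reference,
                    mc_draws=config.mc_draws, n_boot=config.n_boot,
                    boot_mc_draws=max(50, config.mc_draws // 10),
                    seed=_child_seed(config.seed, 7),
                )
                frame = eff.to_frame()
                fname = f"mediation_multi_{yname}.csv"
                frame.to_csv(outdir / fname)
                bundle["tables"][f"multi:{yname}"] = fname
                bundle.setdefault("effects", {})[f"multi:{yname}"] = json.loads(frame.to_json(orient="index"))
        elif form == "qgcomp-index":
            qg = fit_qgcomp(data, config.congeners, config.ga_col, config.covariates, q=config.q)
            bundle["qgcomp"] = {
                "psi": qg.psi, "psi_ci": list(qg.psi_ci),
                "neg_weights": qg.neg_weights, "pos_weights": qg.pos_weights,
            }
            data["qgc_neg_index"] = negative_index(qg, qg.quantized)
            run_single("qgc_neg_index", "qgcomp_index", 8)
        else:
            raise ValueError(f"unknown mediator form {form!r}")

    # total effects table
    for ycol, yname in outcomes:
        te = fit_total_effect(
            data, ycol, config.covariates, group=config.group_col, reference=config.reference
        )
        bundle.setdefault("total_effects", {})[yname] = json.loads(te.to_json(orient="index"))

    log.append(f"finished {time.strftime('%Y-%m-%d %H:%M:%S')}")
    (outdir / "analysis.log").write_text("\n".join(log) + "\n")
    with open(outdir / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=float)
    return bundle
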