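"""End-to-end orchestration of the solubility analysis.

:func:`run_analysis` reproduces the study's complete workflow on the
built-in fixtures (or user CSV datasets): per-model parameter/deviation
tables, AIC comparison per solvent system, van't Hoff dissolution
thermodynamics, and the Hansen-solubility-parameter mismatch table.

Monosolvent datasets are fitted with the modified Apelblat, λh, NRTL and
UNIQUAC models; equal-mass binary datasets with the modified Wilson,
Wilson–van't Hoff and λh models.  The Wilson rules need the pure-solvent
solubility of each mixture component: the modified Wilson rule evaluates
it from the pure solvent's Apelblat correlation (the best monosolvent
model), the Wilson–van't Hoff rule from the pure solvent's van't Hoff
parameters, both fitted on the corresponding monosolvent dataset.

The modified Wilson rule is a composition-mixing model, so its λ12/λ21 are
calibrated on the matching composition-scan dataset (solvent mass fraction
varying) when one is available, and the fixed-composition curve is then
scored as an out-of-sample prediction — the workflow of correlating part
of the data to predict other compositions.  Without a scan the rule is
fitted to the fixed-composition dataset directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .data import (
    SolubilityDataset,
    SoluteProperties,
    DEHYDROABIETIC_ACID,
    builtin_fixtures,
    load_dataset,
)
from .fitting import FitResult, fit_model, deviation_metrics
from .models import apelblat_x, modified_wilson_xm, WilsonParams
from .selection import ModelComparison, rank_models
from .thermo import ThermoSummary, analyze_dataset
from .hsp import hsp_from_groups, mismatch_table

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "MONO_MODELS", "BINARY_MODELS"]

MONO_MODELS = ("apelblat", "lambda_h", "nrtl", "uniquac")
BINARY_MODELS = ("wilson", "wilson_vanthoff", "lambda_h")


class ConfigError(ValueError):
    """Unresolvable dataset, model or option in an analysis configuration."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Declarative description of one analysis run.

    ``datasets`` maps labels to CSV paths, or is the string ``"builtin"``
    to analyse the shipped study data.  ``models`` optionally overrides the
    model list per dataset label.
    """

    datasets: str | Mapping[str, str] = "builtin"
    models: Mapping[str, Sequence[str]] = field(default_factory=dict)
    solute: SoluteProperties = DEHYDROABIETIC_ACID
    include_thermo: bool = True
    include_hsp: bool = True

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AnalysisConfig":
        known = {"datasets", "models", "solute", "include_thermo", "include_hsp"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        solute = DEHYDROABIETIC_ACID
        if "solute" in raw:
            base = vars(DEHYDROABIETIC_ACID).copy()
            base.update(raw["solute"])
            solute = SoluteProperties(**base)
        return cls(
            datasets=raw.get("datasets", "builtin"),
            models={k: tuple(v) for k, v in raw.get("models", {}).items()},
            solute=solute,
            include_thermo=raw.get("include_thermo", True),
            include_hsp=raw.get("include_hsp", True),
        )


@dataclass(frozen=True)
class AnalysisReport:
    """Tables produced by one analysis run."""

    fits: pd.DataFrame
    comparisons: dict[str, ModelComparison]
    thermo: pd.DataFrame | None
    hsp: pd.DataFrame | None
    fit_results: dict[str, list[FitResult]]
    log: tuple[str, ...]

    def best_models(self) -> dict[str, str]:
        return {label: cmp.best for label, cmp in self.comparisons.items()}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fits.to_csv(outdir / "model_fits.csv", index=False)
        rows = []
        for label, cmp in self.comparisons.items():
            for row in cmp.rows():
                rows.append({"system": label, **row})
        pd.DataFrame(rows).to_csv(outdir / "model_comparison.csv", index=False)
        if self.thermo is not None:
            self.thermo.to_csv(outdir / "thermodynamics.csv", index=False)
        if self.hsp is not None:
            self.hsp.to_csv(outdir / "hsp.csv", index=False)
        (outdir / "analysis.log").write_text("\n".join(self.log) + "\n")


def _resolve_datasets(config: AnalysisConfig) -> dict[str, SolubilityDataset]:
    if config.datasets == "builtin":
        return builtin_fixtures()
    if isinstance(config.datasets, str):
        raise ConfigError(f"datasets must be 'builtin' or a mapping, got {config.datasets!r}")
    if not config.datasets:
        raise ConfigError("empty dataset list")
    out = {}
    for label, path in config.datasets.items():
        if not Path(path).exists():
            raise ConfigError(f"dataset {label!r}: no such file {path}")
        out[label] = load_dataset(path)
    return out


def _models_for(config: AnalysisConfig, label: str, ds: SolubilityDataset) -> tuple[str, ...]:
    if label in config.models:
        return tuple(config.models[label])
    if not ds.system.is_binary:
        return MONO_MODELS
    if ds.system.w1 is not None:  # fixed-composition binary
        return BINARY_MODELS
    return ()  # composition scans are prediction inputs, not fitting targets


def _pure_curve(fit: FitResult):
    params = fit.params
    return lambda T, p=params: apelblat_x(p, T)


def _find_scan(ds, datasets):
    names = frozenset(ds.system.names)
    for other in datasets.values():
        if other.system.is_binary and other.system.w1 is None and frozenset(other.system.names) == names:
            return other
    return None


def _fit_wilson(ds, datasets, pure_apelblat, solute, log):
    """Modified Wilson on a fixed-composition binary, scan-calibrated if possible."""
    s1, s2 = ds.system.names
    kwargs = {"x1_pure": _pure_curve(pure_apelblat[s1]), "x2_pure": _pure_curve(pure_apelblat[s2])}
    scan = _find_scan(ds, datasets)
    if scan is None:
        return fit_model(ds, "wilson", solute=solute, **kwargs)
    t1, t2 = scan.system.names
    scan_fit = fit_model(
        scan, "wilson", solute=solute,
        x1_pure=_pure_curve(pure_apelblat[t1]), x2_pure=_pure_curve(pure_apelblat[t2]),
    )
    p = scan_fit.params
    if (t1, t2) != (s1, s2):  # scan lists the components in the other order
        p = WilsonParams(lam12=p.lam21, lam21=p.lam12)
    x_cal = modified_wilson_xm(p, ds.system.w1, kwargs["x1_pure"](ds.T), kwargs["x2_pure"](ds.T))
    rd, ard, rmsd, rss = deviation_metrics(ds.x_exp, x_cal)
    log.append(f"{ds.label} | wilson calibrated on scan {scan.label!r}")
    return FitResult(
        "wilson", p, x_cal, rd, ard, rmsd, rss, len(ds), scan_fit.n_params,
        scan_fit.k_aic, scan_fit.converged, scan_fit.objective, ds.label,
    )


def run_analysis(config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Fit, compare and summarise every dataset in the configuration."""
    datasets = _resolve_datasets(config)
    solute = config.solute
    log: list[str] = [f"solute: {solute.name}, Tm={solute.Tm} K, dHfus={solute.dHfus} J/mol"]

    # pure-solvent correlations backing the Wilson mixing rules
    pure_apelblat: dict[str, FitResult] = {}
    pure_vanthoff: dict[str, FitResult] = {}
    for label, ds in datasets.items():
        if not ds.system.is_binary:
            pure_apelblat[ds.system.names[0]] = fit_model(ds, "apelblat", solute=solute)
            pure_vanthoff[ds.system.names[0]] = fit_model(ds, "vanthoff", solute=solute)

    fit_rows: list[dict] = []
    comparisons: dict[str, ModelComparison] = {}
    fit_results: dict[str, list[FitResult]] = {}
    for label, ds in datasets.items():
        model_list = _models_for(config, label, ds)
        if not model_list:
            continue
        results = []
        for name in model_list:
            if name in ("wilson", "wilson_vanthoff") and ds.system.is_binary:
                s1, s2 = ds.system.names
                missing = [s for s in (s1, s2) if s not in pure_apelblat]
                if missing:
                    raise ConfigError(
                        f"{label}: Wilson rules need monosolvent datasets for {missing}"
                    )
                if name == "wilson":
                    fr = _fit_wilson(ds, datasets, pure_apelblat, solute, log)
                else:
                    fr = fit_model(
                        ds, name, solute=solute,
                        vanthoff_pure=(pure_vanthoff[s1].params, pure_vanthoff[s2].params),
                    )
            else:
                fr = fit_model(ds, name, solute=solute)
            results.append(fr)
            fit_rows.append(fr.summary_row())
            log.append(
                f"{label} | {name}: rss={fr.rss:.6e} 100ARD={100 * fr.ard:.5f} "
                f"1e3RMSD={1e3 * fr.rmsd:.5f} converged={fr.converged}"
            )
        fit_results[label] = results
        if len(results) > 1:
            comparisons[label] = rank_models(results)
            log.append(f"{label} | best model by AIC: {comparisons[label].best}")

    thermo_df = None
    if config.include_thermo:
        rows = []
        for label, ds in datasets.items():
            if ds.system.w1 is None:
                continue  # composition scans have no single ln x vs 1/T curve
            rows.append(analyze_dataset(ds).row())
        thermo_df = pd.DataFrame(rows)

    hsp_df = None
    if config.include_hsp:
        delta1 = hsp_from_groups(solute.hsp_groups)
        rows = [{"system": solute.name, "delta_t": round(delta1, 4), "mismatch": 0.0}]
        for name, (d, dd) in mismatch_table(delta1).items():
            rows.append({"system": name, "delta_t": round(d, 4), "mismatch": round(dd, 4)})
        hsp_df = pd.DataFrame(rows)

    return AnalysisReport(
        fits=pd.DataFrame(fit_rows),
        comparisons=comparisons,
        thermo=thermo_df,
        hsp=hsp_df,
        fit_results=fit_results,
        log=tuple(log),
    )
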