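"""Scenario assembly: RBE curves with uncertainty bands, and the pipeline.

An RBE band propagates the spread of per-experiment domain radii into the
predicted RBE: the model is evaluated at the mean radius and at mean +/- one
SD.  Because the domain radius and RBE are anti-correlated (z* scales as
1/r_d^2), the radius ``mean + sd`` gives the lower edge of the band and
``mean - sd`` the upper edge.

``run_pipeline`` drives the whole analysis from a single YAML config:
build or load spectra, fit every experiment, summarize the radii, compare
against another disease group if configured, and evaluate scenario bands —
writing tidy CSVs, a run log and an echo of the exact config.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import (
    DEFAULT_BOUNDS,
    DEFAULT_TOL,
    DiseaseSummary,
    ExperimentRecord,
    compare_diseases,
    fit_domain_radius,
    fit_results_frame,
    load_observations,
    make_synthetic_experiment,
    pooled_r_squared,
    summarize_disease,
)
from .microdosimetry import SaturationParams, z_star
from .mk_model import FieldTriplet, MKParameters, rbe
from .spectra import LinealEnergySpectrum, make_synthetic_field, read_spectrum

__all__ = ["ScenarioPoint", "RBEBand", "rbe_band", "run_pipeline", "ConfigError"]

logger = logging.getLogger("mkrbe")


class ConfigError(ValueError):
    """Configuration schema violation; message names the offending key path."""


@dataclass(frozen=True)
class ScenarioPoint:
    """One condition to evaluate: a labelled test-field spectrum at a
    reference-radiation dose (Gy)."""

    condition_label: str
    spectrum: LinealEnergySpectrum
    dose_ref: float

    def __post_init__(self) -> None:
        if self.dose_ref <= 0:
            raise ValueError("dose_ref must be > 0")


@dataclass(frozen=True)
class RBEBand:
    """RBE at the mean radius and at mean -/+ one SD (upper/lower edge)."""

    rbe_mean: float
    rbe_hi: float  # radius mean - sd
    rbe_lo: float  # radius mean + sd


def rbe_band(
    point: ScenarioPoint,
    ref_spectrum: LinealEnergySpectrum,
    clin_spectrum: LinealEnergySpectrum,
    summary: DiseaseSummary,
    params_base: MKParameters | None = None,
    sat: SaturationParams | None = None,
) -> RBEBand:
    """Evaluate RBE at domain radii mean, mean - sd and mean + sd.

    Raises if ``mean - sd`` is non-positive (nonphysical radius) or if the
    band ordering ``rbe_lo <= rbe_mean <= rbe_hi`` fails, which happens
    only when the test field is softer than the reference field.
    """
    params_base = params_base or MKParameters()
    sat = sat or SaturationParams(y0=params_base.y0)
    r_lo = summary.mean - summary.sd
    if r_lo <= 0:
        raise ValueError(
            f"mean - sd = {r_lo:.4g} um is not a physical domain radius"
        )

    def at_radius(r_d: float) -> float:
        fields = FieldTriplet(
            z_test=z_star(point.spectrum, r_d, sat),
            z_ref=z_star(ref_spectrum, r_d, sat),
            z_clin=z_star(clin_spectrum, r_d, sat),
        )
        return float(rbe(point.dose_ref, fields, params_base.with_r_d(r_d)))

    band = RBEBand(
        rbe_mean=at_radius(summary.mean),
        rbe_hi=at_radius(r_lo),
        rbe_lo=at_radius(summary.mean + summary.sd),
    )
    eps = 1e-12
    if not (band.rbe_lo <= band.rbe_mean + eps and band.rbe_mean <= band.rbe_hi + eps):
        raise ValueError(
            f"band ordering violated for {point.condition_label!r}: the test "
            "field appears softer than the reference field"
        )
    return band


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _derive_seed(base_seed: int, name: str) -> int:
    """Stable per-name child seed (< 2^31)."""
    return (int(base_seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)


def _require(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise ConfigError(f"missing key '{path}.{key}'")
    return mapping[key]


def _build_spectra(
    cfg: dict, base_dir: Path, seed: int
) -> dict[str, LinealEnergySpectrum]:
    spectra: dict[str, LinealEnergySpectrum] = {}
    for name, entry in cfg.items():
        path = f"spectra.{name}"
        if not isinstance(entry, dict):
            raise ConfigError(f"'{path}' must be a mapping")
        if "file" in entry:
            fpath = base_dir / entry["file"]
            if not fpath.exists():
                raise ConfigError(f"'{path}.file': spectrum file not found: {fpath}")
            spectra[name] = read_spectrum(fpath)
        else:
            kind = _require(entry, "kind", path)
            spectra[name] = make_synthetic_field(
                kind, entry.get("params"), seed=_derive_seed(seed, name)
            )
        logger.info("spectrum %-20s integral=%.6f label=%s",
                    name, spectra[name].integral, spectra[name].label)
    return spectra


def _spectrum_ref(spectra: dict, name: str, path: str) -> LinealEnergySpectrum:
    if name not in spectra:
        raise ConfigError(f"'{path}' references unknown spectrum '{name}'")
    return spectra[name]


def _build_experiments(
    cfg: list, spectra: dict, base_dir: Path, params: MKParameters, seed: int
) -> list[ExperimentRecord]:
    experiments = []
    for i, entry in enumerate(cfg):
        path = f"experiments[{i}]"
        exp_id = _require(entry, "id", path)
        triple = tuple(
            _spectrum_ref(spectra, _require(entry, k, path), f"{path}.{k}")
            for k in ("test", "ref", "clin")
        )
        if "data" in entry:
            fpath = base_dir / entry["data"]
            if not fpath.exists():
                raise ConfigError(f"'{path}.data': experiment file not found: {fpath}")
            experiments.append(
                ExperimentRecord(exp_id, load_observations(fpath), *triple)
            )
        elif "synthetic" in entry:
            syn = entry["synthetic"]
            experiments.append(
                make_synthetic_experiment(
                    exp_id,
                    true_r_d=float(_require(syn, "true_r_d", f"{path}.synthetic")),
                    doses=_require(syn, "doses", f"{path}.synthetic"),
                    test_spectrum=triple[0],
                    ref_spectrum=triple[1],
                    clin_spectrum=triple[2],
                    params_base=params,
                    noise_sigma=float(syn.get("noise_sigma", 0.0)),
                    seed=_derive_seed(seed, exp_id),
                )
            )
        else:
            raise ConfigError(f"'{path}' needs either 'data' or 'synthetic'")
    return experiments


def run_pipeline(config_path, out_dir=None, seed: int | None = None) -> Path:
    """Execute fit -> summarize -> compare -> scenario as configured.

    Returns the results directory, containing ``fits.csv``, ``summary.csv``,
    ``bands.csv`` (if a scenario is configured), ``comparison.csv`` (if a
    comparison group is configured), ``config_echo.yaml`` and ``run.log``.
    """
    config_path = Path(config_path)
    with open(config_path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("top-level config must be a mapping")
    base_dir = config_path.parent
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)

    out = Path(out_dir) if out_dir is not None else base_dir / "results"
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        pcfg = cfg.get("parameters", {})
        params = MKParameters(
            y0=float(pcfg.get("y0_keV_um", 100.0)),
            d_t=float(pcfg.get("d_t_Gy", 7.0)),
            alpha_beta_clinical=float(pcfg.get("alpha_beta_clinical_Gy", 10.0)),
        )
        sat = SaturationParams(
            y0=params.y0,
            density_mass=float(pcfg.get("density_g_cm3", 1.0)),
            kev_um_to_gy=float(pcfg.get("kev_um_to_gy", 0.16022)),
        )
        bounds = tuple(pcfg.get("bounds_um", DEFAULT_BOUNDS))
        tol = float(pcfg.get("tol_um", DEFAULT_TOL))
        logger.info(
            "parameters y0=%g keV/um d_t=%g Gy (a/b)_c=%g Gy K=%g bounds=%s tol=%g seed=%d",
            params.y0, params.d_t, params.alpha_beta_clinical,
            sat.kev_um_to_gy, bounds, tol, seed,
        )

        spectra = _build_spectra(_require(cfg, "spectra", "config"), base_dir, seed)

        summary = None
        if cfg.get("experiments"):
            experiments = _build_experiments(
                cfg["experiments"], spectra, base_dir, params, seed
            )
            fits = [
                fit_domain_radius(exp, params, bounds=bounds, tol=tol, sat=sat)
                for exp in experiments
            ]
            for f in fits:
                logger.info(
                    "fit %-12s r_d_hat=%.6f um sse=%.4g R2=%.4f converged=%s",
                    f.experiment_id, f.r_d_hat, f.sse, f.r_squared, f.converged,
                )
            fit_results_frame(fits).to_csv(out / "fits.csv", index=False)
            if len(fits) >= 2:
                summary = summarize_disease(
                    [f.r_d_hat for f in fits], label=cfg.get("disease_label", "")
                )
                pd.DataFrame(
                    [
                        {
                            "label": summary.label,
                            "n": summary.r_d_values.size,
                            "r_d_mean_um": summary.mean,
                            "r_d_sd_um": summary.sd,
                            "r_squared_pooled": pooled_r_squared(
                                experiments, summary.mean, params, sat
                            ),
                        }
                    ]
                ).to_csv(out / "summary.csv", index=False)

        if "summary" in cfg:  # explicit radii override the fitted summary
            scfg = cfg["summary"]
            summary = summarize_disease(
                _require(scfg, "r_d_values", "summary"),
                label=scfg.get("label", ""),
            )

        if "compare" in cfg:
            ccfg = cfg["compare"]
            if summary is None:
                raise ConfigError("'compare' requires experiments or a 'summary'")
            other = summarize_disease(
                _require(ccfg, "r_d_values", "compare"),
                label=ccfg.get("label", "other"),
            )
            variant = ccfg.get("variant", "pooled")
            test = compare_diseases(summary, other, variant=variant)
            logger.info("compare vs %s: t=%.4f p=%.4f (%s)",
                        other.label, test.statistic, test.p_value, test.variant)
            pd.DataFrame(
                [
                    {
                        "group_a": summary.label,
                        "group_b": other.label,
                        "variant": test.variant,
                        "t_statistic": test.statistic,
                        "df": test.df,
                        "p_value": test.p_value,
                    }
                ]
            ).to_csv(out / "comparison.csv", index=False)

        if "scenario" in cfg:
            scfg = cfg["scenario"]
            if summary is None:
                raise ConfigError("'scenario' requires experiments or a 'summary'")
            ref = _spectrum_ref(spectra, _require(scfg, "ref", "scenario"),
                                "scenario.ref")
            clin = _spectrum_ref(spectra, _require(scfg, "clin", "scenario"),
                                 "scenario.clin")
            doses = [float(d) for d in scfg.get("doses_Gy", [0.5, 5.0])]
            rows = []
            for j, pt in enumerate(scfg.get("points", [])):
                label = _require(pt, "label", f"scenario.points[{j}]")
                spec = _spectrum_ref(
                    spectra, _require(pt, "spectrum", f"scenario.points[{j}]"),
                    f"scenario.points[{j}].spectrum",
                )
                for dose in doses:
                    band = rbe_band(
                        ScenarioPoint(label, spec, dose), ref, clin, summary,
                        params, sat,
                    )
                    logger.info(
                        "band %-20s D=%g Gy rbe=[%.4f, %.4f, %.4f]",
                        label, dose, band.rbe_lo, band.rbe_mean, band.rbe_hi,
                    )
                    rows.append(
                        {
                            "condition": label,
                            "dose_ref_Gy": dose,
                            "rbe_lo": band.rbe_lo,
                            "rbe_mean": band.rbe_mean,
                            "rbe_hi": band.rbe_hi,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "bands.csv", index=False)

        echo = dict(cfg)
        echo["seed"] = seed
        with open(out / "config_echo.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(echo, fh, sort_keys=False)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
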