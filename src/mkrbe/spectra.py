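"""Lineal-energy dose probability densities d(y): container, I/O, synthesis.

The central object is :class:`LinealEnergySpectrum`, a discretized dose
probability density ``d(y)`` over a strictly increasing lineal-energy grid
(keV/um).  ``d(y) dy`` is the fraction of absorbed dose delivered by events
of lineal energy in ``[y, y + dy]``, so the trapezoidal integral of the
density over the grid is 1.

Real spectra of this kind come out of microdosimetric tally functions of
radiation-transport codes; this module also provides parametric synthetic
stand-ins (photon-like, neutron-like, ion-like fields) so that the whole
RBE pipeline can be exercised and tested without any transport simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LinealEnergySpectrum",
    "read_spectrum",
    "write_spectrum",
    "make_delta_spectrum",
    "make_synthetic_field",
    "NORMALIZATION_TOL",
]

#: Tolerance on |trapezoid integral - 1| for a spectrum to count as normalized.
NORMALIZATION_TOL = 1e-6

#: Column names used by the 2-column CSV/TSV spectrum files.
COLUMN_Y = "y_keV_um"
COLUMN_D = "d_y_per_keV_um"


@dataclass(frozen=True)
class LinealEnergySpectrum:
    """Dose probability density of lineal energy on a fixed grid.

    Parameters
    ----------
    y_grid : array-like
        Lineal-energy values in keV/um; strictly increasing, all > 0.
    density : array-like
        Dose probability density d(y) at each grid point, (keV/um)^-1,
        all finite and >= 0.
    label : str
        Free-text identifier of the radiation field (e.g. "Co-60 gamma").
    site_radius_nominal : float
        Site radius (um) assumed when the spectrum was produced.  Metadata
        only: downstream computations treat d(y) as independent of the
        fitted domain radius.
    """

    y_grid: np.ndarray
    density: np.ndarray
    label: str = ""
    site_radius_nominal: float = 0.25
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.y_grid, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if y.ndim != 1 or d.ndim != 1 or y.shape != d.shape:
            raise ValueError("y_grid and density must be 1-D arrays of equal length")
        if y.size < 2:
            raise ValueError("spectrum needs at least 2 grid points")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(d)):
            raise ValueError("y_grid and density must be finite")
        if np.any(y <= 0.0):
            raise ValueError("lineal energies must be > 0")
        if np.any(np.diff(y) <= 0.0):
            bad = int(np.flatnonzero(np.diff(y) <= 0.0)[0]) + 1
            raise ValueError(f"y grid not strictly increasing at row {bad}")
        if np.any(d < 0.0):
            bad = int(np.flatnonzero(d < 0.0)[0])
            raise ValueError(f"negative density at row {bad}")
        object.__setattr__(self, "y_grid", y)
        object.__setattr__(self, "density", d)

    @property
    def integral(self) -> float:
        """Trapezoidal integral of d(y) over the stored grid."""
        return float(np.trapezoid(self.density, self.y_grid))

    @property
    def is_normalized(self) -> bool:
        return abs(self.integral - 1.0) <= NORMALIZATION_TOL

    def normalized(self) -> "LinealEnergySpectrum":
        """Return a copy rescaled so the trapezoid integral equals 1."""
        total = self.integral
        if total <= 0.0:
            raise ValueError("cannot normalize a spectrum with zero integral")
        if abs(total - 1.0) <= NORMALIZATION_TOL:
            return self
        return replace(self, density=self.density / total)

    def resample_log(self, n_points: int = 512) -> "LinealEnergySpectrum":
        """Resample onto a log-spaced grid spanning the stored range.

        Explicit opt-in only; no internal computation resamples silently.
        """
        grid = np.geomspace(self.y_grid[0], self.y_grid[-1], n_points)
        dens = np.interp(grid, self.y_grid, self.density)
        return replace(self, y_grid=grid, density=dens).normalized()


def read_spectrum(path) -> LinealEnergySpectrum:
    """Read a 2-column CSV/TSV spectrum file and return a normalized spectrum.

    The first column is lineal energy (keV/um), the second the dose
    probability density ((keV/um)^-1).  A header row is detected by a
    non-numeric first line; lines starting with ``#`` are ignored.  The
    delimiter (comma, tab or whitespace) is sniffed per line.  If the raw
    integral deviates from 1 by more than 1e-3 the original normalization
    is recorded in the spectrum's ``provenance`` note.
    """
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            for delim in (",", "\t", None):
                parts = [p for p in text.split(delim) if p != ""]
                if len(parts) >= 2:
                    break
            try:
                y, d = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                if not rows and lineno <= 2:
                    continue  # header row
                raise ValueError(f"{path}: cannot parse line {lineno}: {text!r}")
            rows.append((y, d))
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    y = np.array([r[0] for r in rows])
    d = np.array([r[1] for r in rows])
    if np.any(np.diff(y) <= 0.0):
        bad = int(np.flatnonzero(np.diff(y) <= 0.0)[0]) + 2
        raise ValueError(f"{path}: y grid not strictly increasing at data row {bad}")
    if np.any(d < 0.0):
        bad = int(np.flatnonzero(d < 0.0)[0]) + 1
        raise ValueError(f"{path}: negative density at data row {bad}")
    raw = LinealEnergySpectrum(y, d, label=str(path))
    note = ""
    if abs(raw.integral - 1.0) > 1e-3:
        note = f"raw integral was {raw.integral:.6g}; renormalized on read"
    spec = raw.normalized()
    return replace(spec, provenance=note)


def write_spectrum(spectrum: LinealEnergySpectrum, path) -> None:
    """Write a spectrum as 2-column CSV with header; 17-digit round-trip safe."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{COLUMN_Y},{COLUMN_D}\n")
        for y, d in zip(spectrum.y_grid, spectrum.density):
            fh.write(f"{y:.17g},{d:.17g}\n")


def make_delta_spectrum(
    y1: float, grid_width: float = 1e-3, n_points: int = 41
) -> LinealEnergySpectrum:
    """Narrow normalized peak at ``y1`` approximating a delta function.

    ``grid_width`` is the relative half-width of the support,
    ``[y1 (1 - w), y1 (1 + w)]``.  The peak is a raised-cosine bump, so the
    density vanishes smoothly at the edges and saturation-functional values
    converge to the analytic delta-function result as ``grid_width -> 0``.
    """
    if y1 <= 0.0:
        raise ValueError("y1 must be > 0")
    if not (0.0 < grid_width < 1.0):
        raise ValueError("grid_width must be in (0, 1)")
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    grid = np.linspace(y1 * (1.0 - grid_width), y1 * (1.0 + grid_width), n_points)
    x = (grid - y1) / (y1 * grid_width)  # in [-1, 1]
    dens = 1.0 + np.cos(np.pi * x)
    return LinealEnergySpectrum(
        grid, dens, label=f"delta({y1:g} keV/um)"
    ).normalized()


def _lognormal_density(y: np.ndarray, median: float, sigma_log: float) -> np.ndarray:
    """Log-normal pdf in y with the given median and log-space sigma."""
    mu = np.log(median)
    return np.exp(-((np.log(y) - mu) ** 2) / (2.0 * sigma_log**2)) / (
        y * sigma_log * np.sqrt(2.0 * np.pi)
    )


_KIND_DEFAULTS = {
    # median (keV/um), log-space sigma of the main component
    "photon-like": (1.0, 0.7),
    "neutron-like": (30.0, 0.6),
    "ion-like": (120.0, 0.35),
}


def make_synthetic_field(
    kind: str,
    params: dict | None = None,
    seed: int = 0,
) -> LinealEnergySpectrum:
    """Generate a parametric synthetic lineal-energy spectrum.

    Kinds
    -----
    ``photon-like``
        Unimodal log-normal-shaped d(y) with median near 0.3-2 keV/um,
        emulating a low-LET field (X- or gamma-rays).
    ``neutron-like``
        Mixture of a photon-like component (weight ``admixture``, the
        secondary-gamma dose fraction) and a recoil-proton-like log-normal
        component centered near 10-100 keV/um (weight ``1 - admixture``).
    ``ion-like``
        Narrow high-LET log-normal peak (heavy-ion track core).

    ``params`` keys (all optional): ``median`` and ``sigma_log`` of the main
    component, ``photon_median``/``photon_sigma_log`` for the admixed photon
    component, ``admixture`` in [0, 1], ``n_points``, ``y_min``, ``y_max``,
    ``jitter`` (log-scale sd of the seed-driven median perturbation,
    default 0.05; set 0 for exactly the nominal shape).

    Identical ``(kind, params, seed)`` give bit-identical spectra.
    """
    if kind not in _KIND_DEFAULTS:
        raise ValueError(
            f"unknown kind {kind!r}; expected one of {sorted(_KIND_DEFAULTS)}"
        )
    p = dict(params or {})
    median0, sigma0 = _KIND_DEFAULTS[kind]
    median = float(p.get("median", median0))
    sigma_log = float(p.get("sigma_log", sigma0))
    admixture = float(p.get("admixture", 0.2 if kind == "neutron-like" else 0.0))
    photon_median = float(p.get("photon_median", _KIND_DEFAULTS["photon-like"][0]))
    photon_sigma = float(p.get("photon_sigma_log", _KIND_DEFAULTS["photon-like"][1]))
    n_points = int(p.get("n_points", 400))
    y_min = float(p.get("y_min", 1e-2))
    y_max = float(p.get("y_max", 1e3))
    jitter = float(p.get("jitter", 0.05))
    if median <= 0 or sigma_log <= 0 or photon_median <= 0 or photon_sigma <= 0:
        raise ValueError("shape parameters must be positive")
    if not (0.0 <= admixture <= 1.0):
        raise ValueError("admixture fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    # Draw order is fixed so a neutron-like field with admixture=1 matches
    # the photon-like field generated from the same seed and photon params.
    photon_jitter = float(rng.normal(0.0, 1.0))
    main_jitter = float(rng.normal(0.0, 1.0))

    grid = np.geomspace(y_min, y_max, n_points)
    if kind == "photon-like":
        med = median * np.exp(jitter * photon_jitter)
        dens = _lognormal_density(grid, med, sigma_log)
        label = f"photon-like (median {median:g} keV/um, seed {seed})"
    elif kind == "neutron-like":
        photon_med = photon_median * np.exp(jitter * photon_jitter)
        proton_med = median * np.exp(jitter * main_jitter)
        dens = admixture * _lognormal_density(grid, photon_med, photon_sigma) + (
            1.0 - admixture
        ) * _lognormal_density(grid, proton_med, sigma_log)
        label = f"neutron-like (gamma fraction {admixture:g}, seed {seed})"
    else:  # ion-like
        med = median * np.exp(jitter * main_jitter)
        dens = _lognormal_density(grid, med, sigma_log)
        label = f"ion-like (median {median:g} keV/um, seed {seed})"
    tail = np.trapezoid(dens, grid)
    if tail <= 0.99:
        warnings.warn(
            f"{label}: {100 * (1 - tail):.1f}% of the density falls outside "
            f"[{y_min:g}, {y_max:g}] keV/um and is renormalized away",
            stacklevel=2,
        )
    return LinealEnergySpectrum(grid, dens, label=label).normalized()
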