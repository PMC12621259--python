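"""Stick spectra, line-shape convolution, ensemble averaging and convergence.

The universal currency between per-snapshot quantum output and final
spectra is the stick spectrum: a list of delta lines (position, signed
intensity) on a declared axis.  Ensemble spectra are built by convolving
each snapshot's sticks with a unit-area Gaussian or Lorentzian kernel and
averaging over snapshots; because both steps are linear the order does not
matter, a property the tests exercise explicitly.

Convergence with the number of snapshots is monitored by the normalized L1
distance between successive running averages; signed observables (ECD,
ROA), whose positive and negative lines partially cancel, converge more
slowly than their unsigned counterparts.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import EV_NM, EV_TO_WAVENUMBER
from .errors import ContractError, UnitError

SUPPORTED_UNITS = ("eV", "nm", "cm-1", "ppm", "Hz")
SIGNED_OBSERVABLES = ("ecd", "roa")

__all__ = [
    "StickSpectrum",
    "LineShapeKernel",
    "Spectrum",
    "ConvergenceReport",
    "ScalarSeries",
    "convolve",
    "ensemble_average",
    "convergence_curve",
    "axis_convert",
    "scalar_stats",
    "default_grid",
]


@dataclass
class StickSpectrum:
    """Signed delta lines on a declared axis.

    ``lines`` is a sequence of ``(position, intensity)`` pairs; negative
    intensities are only meaningful for signed observables (ecd, roa) but
    are not rejected elsewhere, since differences of spectra arise
    naturally in analysis.
    """

    axis_unit: str
    lines: list
    snapshot_id: int | str | None = None
    observable: str = "uv"

    def __post_init__(self):
        if self.axis_unit not in SUPPORTED_UNITS:
            raise UnitError(f"unsupported axis unit {self.axis_unit!r}")
        arr = np.asarray([(p, i) for p, i in self.lines], dtype=float).reshape(-1, 2)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ContractError("stick positions/intensities must be finite")
        self.lines = [tuple(row) for row in arr]

    @property
    def positions(self):
        return np.array([p for p, _ in self.lines])

    @property
    def intensities(self):
        return np.array([i for _, i in self.lines])


@dataclass(frozen=True)
class LineShapeKernel:
    """Unit-area broadening kernel: ``shape`` in {gaussian, lorentzian}, FWHM in axis units."""

    shape: str
    fwhm: float

    def __post_init__(self):
        if self.shape not in ("gaussian", "lorentzian"):
            raise ContractError(f"unknown line shape {self.shape!r}")
        if self.fwhm <= 0:
            raise ContractError("fwhm must be positive")

    def profile(self, x):
        """Evaluate the unit-area kernel at offsets ``x`` from the line center."""
        x = np.asarray(x, dtype=float)
        if self.shape == "gaussian":
            a = 4.0 * math.log(2.0) / self.fwhm**2
            return (2.0 / self.fwhm) * math.sqrt(math.log(2.0) / math.pi) * np.exp(-a * x * x)
        half = self.fwhm / 2.0
        return (half / math.pi) / (x * x + half * half)


@dataclass
class Spectrum:
    """Broadened spectrum on a strictly increasing grid, plus provenance."""

    grid: np.ndarray
    values: np.ndarray
    axis_unit: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or np.any(np.diff(self.grid) <= 0):
            raise ContractError("grid must be strictly increasing")
        if self.values.shape != self.grid.shape or not np.all(np.isfinite(self.values)):
            raise ContractError("values must be finite and match the grid")

    def integral(self):
        return float(np.trapezoid(self.values, self.grid))

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([f"position_{self.axis_unit}", "intensity"])
            for x, y in zip(self.grid, self.values):
                w.writerow([x, y])

    def to_json_provenance(self, path):
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)


@dataclass
class ConvergenceReport:
    """Running-average convergence diagnostic over snapshot counts."""

    increments: list
    distances: list
    tolerance: float
    converged_n: int | None

    @property
    def converged(self):
        return self.converged_n is not None


@dataclass
class ScalarSeries:
    """Per-snapshot scalar observable (e.g. optical rotation per frame)."""

    values: np.ndarray
    label: str = "scalar"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()

    def running_mean(self):
        return np.cumsum(self.values) / np.arange(1, len(self.values) + 1)


def default_grid(observable):
    """Default spectral grids per observable family (overridable everywhere)."""
    if observable in ("uv", "ecd"):
        return np.arange(150.0, 350.0 + 1e-9, 0.5), "nm"
    if observable in ("ir", "raman", "roa"):
        return np.arange(400.0, 2000.0 + 1e-9, 1.0), "cm-1"
    if observable == "nmr":
        return np.arange(0.0, 12.0 + 1e-12, 0.001), "ppm"
    raise ContractError(f"no default grid for observable {observable!r}")


def convolve(sticks, kernel, grid):
    """Broaden a stick spectrum onto a grid: S(x) = Σ_k I_k K(x − x_k).

    The kernel has unit area, so the integrated intensity of S equals the
    summed stick intensity whenever the grid extends well past the extreme
    lines (≈8 FWHM is enough for 1e-6 relative conservation).
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ContractError("grid must be strictly increasing")
    values = np.zeros_like(grid)
    for x0, inten in sticks.lines:
        values += inten * kernel.profile(grid - x0)
    return Spectrum(
        grid=grid,
        values=values,
        axis_unit=sticks.axis_unit,
        provenance={
            "kernel": {"shape": kernel.shape, "fwhm": kernel.fwhm},
            "snapshot_ids": [sticks.snapshot_id],
            "observable": sticks.observable,
        },
    )


def ensemble_average(spectra, weights=None):
    """Pointwise (weighted) mean of spectra sharing one grid and unit."""
    spectra = list(spectra)
    if not spectra:
        raise ContractError("nothing to average")
    g0, u0 = spectra[0].grid, spectra[0].axis_unit
    for s in spectra[1:]:
        if s.axis_unit != u0:
            raise UnitError("spectra carry different axis units")
        if s.grid.shape != g0.shape or not np.allclose(s.grid, g0, rtol=0, atol=0):
            raise ContractError("spectra are not on a common grid")
    vals = np.stack([s.values for s in spectra])
    if weights is None:
        mean = vals.mean(axis=0)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != len(spectra):
            raise ContractError("one weight per spectrum required")
        mean = np.einsum("s,sg->g", w, vals) / w.sum()
    ids = [i for s in spectra for i in s.provenance.get("snapshot_ids", [None])]
    return Spectrum(grid=g0, values=mean, axis_unit=u0,
                    provenance={"snapshot_ids": ids, "averaged": len(spectra)})


def convergence_curve(stick_sets, kernel, grid, increment, tolerance):
    """Running-average convergence of an ensemble of stick spectra.

    ``distance(n) = ‖S̄_n − S̄_{n−inc}‖₁ / ‖S̄_n‖₁`` on the grid, where S̄_n
    averages the first n convolved snapshots.  ``converged_n`` is the first
    n whose distance and the next one are both ≤ tolerance.
    """
    stick_sets = list(stick_sets)
    if increment <= 0:
        raise ContractError("increment must be positive")
    counts = list(range(increment, len(stick_sets) + 1, increment))
    if len(counts) < 2:
        raise ContractError("need at least two increments of snapshots")
    grid = np.asarray(grid, dtype=float)
    dx = np.gradient(grid)

    running = np.zeros_like(grid)
    averages = {}
    for n, sticks in enumerate(stick_sets, start=1):
        running += convolve(sticks, kernel, grid).values
        if n in set(counts):
            averages[n] = running / n

    distances = []
    for prev, cur in zip(counts[:-1], counts[1:]):
        num = float(np.sum(np.abs(averages[cur] - averages[prev]) * dx))
        den = float(np.sum(np.abs(averages[cur]) * dx))
        if den == 0.0:
            raise ContractError("all-zero ensemble average: convergence metric undefined")
        distances.append(num / den)

    converged_n = None
    for k in range(len(distances) - 1):
        if distances[k] <= tolerance and distances[k + 1] <= tolerance:
            converged_n = counts[k + 1]
            break
    return ConvergenceReport(
        increments=counts[1:], distances=distances,
        tolerance=tolerance, converged_n=converged_n,
    )


_EV = "eV"


def axis_convert(values, from_unit, to_unit):
    """Convert axis positions between eV, nm, cm⁻¹, ppm and Hz.

    Only positions are converted (nm = 1239.841984/eV, 1 eV = 8065.544
    cm⁻¹); intensities are never re-binned.  ppm↔Hz require a spectrometer
    frequency and are deliberately unsupported here (see the nmr module).
    """
    v = np.asarray(values, dtype=float)
    if from_unit not in SUPPORTED_UNITS or to_unit not in SUPPORTED_UNITS:
        raise UnitError(f"unsupported unit pair ({from_unit!r}, {to_unit!r})")
    if from_unit == to_unit:
        return v.copy()

    def to_ev(x, unit):
        if unit == _EV:
            return x
        if unit == "nm":
            return EV_NM / x
        if unit == "cm-1":
            return x / EV_TO_WAVENUMBER
        raise UnitError(f"cannot convert {unit!r} to an energy axis")

    def from_ev(x, unit):
        if unit == _EV:
            return x
        if unit == "nm":
            return EV_NM / x
        if unit == "cm-1":
            return x * EV_TO_WAVENUMBER
        raise UnitError(f"cannot convert an energy axis to {unit!r}")

    return from_ev(to_ev(v, from_unit), to_unit)


def scalar_stats(series, bootstrap_n=1000, seed=0, ci=0.95):
    """Frame-to-frame statistics of a per-snapshot scalar observable.

    Returns a dict with the exact running mean, the standard error of the
    mean, a seeded bootstrap percentile confidence interval, and the
    sign-consensus fraction (share of frames agreeing with the sign of the
    mean).  A ``bootstrap_n`` below 100 is accepted but flagged.
    """
    import logging

    vals = series.values if isinstance(series, ScalarSeries) else np.asarray(series, float).ravel()
    if vals.size < 2:
        raise ContractError("need at least two values")
    if bootstrap_n < 100:
        logging.getLogger(__name__).warning(
            "bootstrap_n=%d is small; confidence interval will be noisy", bootstrap_n
        )
    running = np.cumsum(vals) / np.arange(1, vals.size + 1)
    mean = float(running[-1])
    se = float(vals.std(ddof=1) / math.sqrt(vals.size))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(bootstrap_n, vals.size))
    boot_means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    sign = np.sign(mean) if mean != 0 else 1.0
    consensus = float(np.mean(np.sign(vals) == sign))
    return {
        "running_mean": running,
        "mean": mean,
        "se": se,
        "ci": (float(lo), float(hi)),
        "ci_level": ci,
        "sign_consensus": consensus,
    }


# ---------------------------------------------------------------------------
# plain-text IO for stick tables
# ---------------------------------------------------------------------------

def read_stick_table(path, axis_unit, observable="uv"):
    """Read a ``snapshot_id,position,intensity`` CSV into StickSpectrum list."""
    by_snapshot = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip().lower() for h in header[:3]] != ["snapshot_id", "position", "intensity"]:
            raise ContractError("expected header snapshot_id,position,intensity")
        for row in reader:
            if not row:
                continue
            sid = row[0].strip()
            by_snapshot.setdefault(sid, []).append((float(row[1]), float(row[2])))
    return [
        StickSpectrum(axis_unit=axis_unit, lines=lines, snapshot_id=sid, observable=observable)
        for sid, lines in by_snapshot.items()
    ]


def write_stick_table(path, stick_sets):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["snapshot_id", "position", "intensity"])
        for sticks in stick_sets:
            for pos, inten in sticks.lines:
                w.writerow([sticks.snapshot_id, pos, inten])
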