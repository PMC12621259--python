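"""Partial Hessian vibrational analysis (PHVA) and harmonic stick intensities.

Vibrational modes of a solvated solute are computed from the Cartesian
second derivatives of the *active* atoms only, with the (frozen) solvent
entering solely through its effect on those derivatives.  The active-region
block is mass-weighted, optionally purged of the region's own rigid-body
translations/rotations by projection, and diagonalized; eigenvalues map to
wavenumbers via ν̃ = C·sign(λ)√|λ| with C the hartree/bohr²/amu → cm⁻¹
factor.  IR intensities follow |∂μ/∂Q|², Raman activities the Placzek
invariants 45a′² + 7γ′² with the (ν₀ − ν_k)⁴ factor of the declared
excitation; circular-intensity-difference (ROA) sticks are accepted as
externally supplied per-mode values only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .constants import EV_NM, EV_TO_WAVENUMBER, HESSIAN_EIGENVALUE_TO_CM
from .errors import ContractError, ConvergenceError
from .spectra import StickSpectrum

NEAR_ZERO_LABEL_CM = 5.0  # residual rigid-body modes are labeled, never deleted

__all__ = [
    "HessianBlock",
    "NormalModes",
    "DerivativeTables",
    "partial_hessian",
    "normal_modes",
    "mode_intensities",
    "partial_optimize",
]


@dataclass
class HessianBlock:
    """Active-region Cartesian Hessian (hartree/bohr²) with labels and masses (amu)."""

    labels: list
    masses: np.ndarray
    hessian: np.ndarray
    positions: np.ndarray | None = None  # Å; needed for rotational projection

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.hessian = np.asarray(self.hessian, dtype=float)
        n = len(self.labels)
        if self.masses.shape != (n,) or np.any(self.masses <= 0):
            raise ContractError("one positive mass per active atom required")
        if self.hessian.shape != (3 * n, 3 * n):
            raise ContractError("hessian must be 3N×3N for N active atoms")
        asym = np.max(np.abs(self.hessian - self.hessian.T))
        if asym > 1e-10:
            raise ContractError(f"hessian asymmetry {asym:.2e} exceeds 1e-10")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)


@dataclass
class NormalModes:
    """Frequencies (cm⁻¹, imaginary as negative) and mass-weighted eigenvectors."""

    frequencies: np.ndarray
    vectors: np.ndarray          # columns, orthonormal in mass-weighted space
    masses: np.ndarray
    projected: bool
    near_zero: np.ndarray = field(default=None)  # bool mask, |ν̃| < label threshold

    def __post_init__(self):
        if self.near_zero is None:
            self.near_zero = np.abs(self.frequencies) < NEAR_ZERO_LABEL_CM

    def cartesian_displacements(self):
        """Un-mass-weighted displacement vectors (columns), not normalized."""
        w = np.repeat(1.0 / np.sqrt(self.masses), 3)
        return self.vectors * w[:, None]


@dataclass
class DerivativeTables:
    """Cartesian dipole/polarizability derivatives for the active region.

    ``dipole``: (3, 3N) a.u.; ``polarizability``: (6, 3N) a.u. in the order
    xx, yy, zz, xy, xz, yz; ``roa_per_mode`` optionally carries externally
    computed per-mode circular intensity differences.
    """

    dipole: np.ndarray | None = None
    polarizability: np.ndarray | None = None
    roa_per_mode: np.ndarray | None = None

    def validate(self, n_atoms):
        if self.dipole is not None and np.asarray(self.dipole).shape != (3, 3 * n_atoms):
            raise ContractError("dipole derivatives must have shape (3, 3N)")
        if self.polarizability is not None and np.asarray(self.polarizability).shape != (6, 3 * n_atoms):
            raise ContractError("polarizability derivatives must have shape (6, 3N)")


def partial_hessian(full_hessian, active_indices):
    """Extract the active-by-active Cartesian sub-block of a full Hessian.

    Symmetrizes the extracted block as (H + Hᵀ)/2 and raises if the
    asymmetry norm exceeds 1e-6 (a data-quality failure, not a numerics
    issue).  Returns the raw 3n×3n array; wrap it in :class:`HessianBlock`
    with labels and masses for analysis.
    """
    full = np.asarray(full_hessian, dtype=float)
    idx = list(active_indices)
    if len(set(idx)) != len(idx):
        raise ContractError("active indices must be distinct")
    if idx and (min(idx) < 0 or 3 * (max(idx) + 1) > full.shape[0]):
        raise ContractError("active indices out of range for the full Hessian")
    cart = np.concatenate([[3 * i, 3 * i + 1, 3 * i + 2] for i in idx]).astype(int)
    block = full[np.ix_(cart, cart)]
    asym = np.max(np.abs(block - block.T)) if block.size else 0.0
    if asym > 1e-6:
        raise ContractError(f"extracted block asymmetry {asym:.2e} exceeds 1e-6")
    return 0.5 * (block + block.T)


def _rigid_body_basis(masses, positions_ang):
    """Orthonormal mass-weighted translation+rotation vectors of the region."""
    n = len(masses)
    sqm = np.sqrt(masses)
    vecs = []
    for k in range(3):
        v = np.zeros((n, 3))
        v[:, k] = sqm
        vecs.append(v.ravel())
    if positions_ang is not None:
        com = (masses[:, None] * positions_ang).sum(axis=0) / masses.sum()
        rel = positions_ang - com
        for axis in np.eye(3):
            v = np.cross(axis, rel) * sqm[:, None]
            vecs.append(v.ravel())
    B = np.array(vecs).T
    q, r = np.linalg.qr(B)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(r).max())
    return q[:, keep]


def normal_modes(block, project=True):
    """Diagonalize the mass-weighted Hessian of the active region.

    With ``project=True`` the region's own 3 translations (and up to 3
    rotations when positions are available; 2 for linear fragments) are
    projected out before diagonalization.  Residual near-zero modes are
    labeled via the ``near_zero`` mask rather than deleted.  Negative
    Hessian eigenvalues appear as negative wavenumbers.
    """
    invsqm = np.repeat(1.0 / np.sqrt(block.masses), 3)
    mw = block.hessian * invsqm[:, None] * invsqm[None, :]

    if project:
        basis = _rigid_body_basis(block.masses, block.positions)
        P = np.eye(mw.shape[0]) - basis @ basis.T
        mw = P @ mw @ P
    w, v = np.linalg.eigh(mw)
    if not np.all(np.isfinite(w)):
        raise ContractError("non-finite eigenvalues in mass-weighted Hessian")
    if project:
        # drop the exactly-projected rigid-body dimensions
        basis_dim = basis.shape[1]
        order = np.argsort(np.abs(w))
        drop = set(order[:basis_dim].tolist())
        keep = [i for i in range(len(w)) if i not in drop]
        w, v = w[keep], v[:, keep]
        order = np.argsort(w)
        w, v = w[order], v[:, order]
    freqs = np.sign(w) * np.sqrt(np.abs(w)) * HESSIAN_EIGENVALUE_TO_CM
    return NormalModes(frequencies=freqs, vectors=v, masses=block.masses,
                       projected=project)


def mode_intensities(modes, tables, excitation_nm=634.0):
    """Harmonic IR/Raman(/ROA pass-through) stick spectra for the modes.

    IR sticks carry |∂μ/∂Q_k|² (a.u.); Raman sticks the Placzek activity
    45a′² + 7γ′² scaled by (ν̃₀ − ν̃_k)⁴ at the declared excitation
    wavelength.  Returns a dict observable → StickSpectrum on a cm⁻¹ axis.
    """
    n = len(modes.masses)
    tables.validate(n)
    invsqm = np.repeat(1.0 / np.sqrt(modes.masses), 3)
    out = {}
    freqs = modes.frequencies

    if tables.dipole is not None:
        dmu_dq = np.asarray(tables.dipole) @ (modes.vectors * invsqm[:, None])
        ir = np.sum(dmu_dq**2, axis=0)
        out["ir"] = StickSpectrum(axis_unit="cm-1",
                                  lines=list(zip(freqs, ir)), observable="ir")

    if tables.polarizability is not None:
        da_dq = np.asarray(tables.polarizability) @ (modes.vectors * invsqm[:, None])
        axx, ayy, azz, axy, axz, ayz = da_dq
        a_iso = (axx + ayy + azz) / 3.0
        gamma2 = 0.5 * ((axx - ayy) ** 2 + (ayy - azz) ** 2 + (azz - axx) ** 2) \
            + 3.0 * (axy**2 + axz**2 + ayz**2)
        activity = 45.0 * a_iso**2 + 7.0 * gamma2
        nu0 = EV_TO_WAVENUMBER * EV_NM / excitation_nm  # excitation, cm^-1
        raman = activity * (nu0 - freqs) ** 4
        out["raman"] = StickSpectrum(axis_unit="cm-1",
                                     lines=list(zip(freqs, raman)), observable="raman")
        out["raman_activity"] = StickSpectrum(axis_unit="cm-1",
                                              lines=list(zip(freqs, activity)),
                                              observable="raman")

    if tables.roa_per_mode is not None:
        roa = np.asarray(tables.roa_per_mode, dtype=float)
        if roa.shape[0] != len(freqs):
            raise ContractError("one ROA value per mode required")
        out["roa"] = StickSpectrum(axis_unit="cm-1",
                                   lines=list(zip(freqs, roa)), observable="roa")
    if not out:
        raise ContractError("no derivative tables supplied for any observable")
    return out


def partial_optimize(geometry, energy_gradient, frozen_indices, tol=1e-6,
                     max_iter=500):
    """Relax active coordinates with frozen atoms held bit-identical.

    ``energy_gradient(positions) -> (E, grad)`` must cover the full system;
    a quasi-Newton (L-BFGS-B) minimization runs over the active coordinates
    only.  Exits when the active-coordinate gradient max-norm is ≤ ``tol``;
    raises :class:`ConvergenceError` (carrying the energy trace) otherwise.
    """
    geo = np.asarray(geometry, dtype=float).reshape(-1, 3)
    frozen = np.zeros(len(geo), dtype=bool)
    frozen[list(frozen_indices)] = True
    active = ~frozen
    if not active.any():
        raise ContractError("no active atoms to optimize")
    trace = []

    def fun(x_active):
        pos = geo.copy()
        pos[active] = x_active.reshape(-1, 3)
        e, g = energy_gradient(pos)
        trace.append(float(e))
        return float(e), np.asarray(g, dtype=float).reshape(-1, 3)[active].ravel()

    res = scipy.optimize.minimize(
        fun, geo[active].ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol * 1e-2, "ftol": 1e-15},
    )
    out = geo.copy()
    out[active] = res.x.reshape(-1, 3)
    _, grad = energy_gradient(out)
    gmax = np.max(np.abs(np.asarray(grad).reshape(-1, 3)[active]))
    if gmax > tol:
        raise ConvergenceError(
            f"active gradient max-norm {gmax:.2e} exceeds tol {tol:.2e}", trace=trace
        )
    return out
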