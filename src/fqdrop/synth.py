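"""Seeded synthetic-data generators for every pipeline input.

Each generator draws from its own named substream of the master seed, so
adding one generator never perturbs another, and a fixed configuration is
bit-reproducible.  Water droplets use the rigid three-site water geometry
of classical simulation (O–H 0.9572 Å, H–O–H 104.52°) with uniformly
random positions and orientations inside a ball; stick ensembles emulate
solvent-induced inhomogeneous broadening by normal draws of band positions
and intensities per snapshot; ball-and-spring systems provide analytic
Hessians for vibrational-analysis fixtures.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .droplets import TrajectoryFrame
from .errors import ContractError, PackingError
from .fq import AtomSite, SolventTopology
from .phva import DerivativeTables, HessianBlock
from .spectra import StickSpectrum

OH_BOND_ANGSTROM = 0.9572
HOH_ANGLE_DEG = 104.52

__all__ = [
    "substream",
    "gen_water_droplet",
    "Band",
    "gen_stick_ensemble",
    "gen_ballspring_system",
    "ballspring_energy_gradient",
    "gen_spin_system",
    "water_template",
]


def substream(seed, name):
    """Independent Generator for one named substream of the master seed."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, tag])


def water_template():
    """Rigid water geometry (Å): O at the origin, H's in the xy plane."""
    theta = math.radians(HOH_ANGLE_DEG)
    return np.array([
        [0.0, 0.0, 0.0],
        [OH_BOND_ANGSTROM, 0.0, 0.0],
        [OH_BOND_ANGSTROM * math.cos(theta), OH_BOND_ANGSTROM * math.sin(theta), 0.0],
    ])


def gen_water_droplet(n_waters, radius=18.0, min_separation=2.5, seed=0,
                      oxygen_type="OW", hydrogen_type="HW", molecule_charge=0.0):
    """Random rigid-water droplet: uniform positions/orientations in a ball.

    No two oxygens come closer than ``min_separation``; infeasible packings
    (checked by volume and by bounded rejection retries) raise
    :class:`PackingError`.  Returns ``(TrajectoryFrame, SolventTopology)``.
    """
    if n_waters < 1:
        raise ContractError("n_waters must be at least 1")
    ball = 4.0 / 3.0 * math.pi * radius**3
    occupied = n_waters * 4.0 / 3.0 * math.pi * (min_separation / 2.0) ** 3
    if occupied > 0.5 * ball:
        raise PackingError(
            f"{n_waters} waters with min O–O separation {min_separation} Å "
            f"cannot pack into a {radius} Å ball"
        )
    rng = substream(seed, "water_droplet")
    centers = np.empty((0, 3))
    attempts = 0
    max_attempts = 2000 * n_waters
    while len(centers) < n_waters:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed {len(centers)}/{n_waters} waters after {attempts} attempts"
            )
        attempts += 1
        p = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(p) > radius:
            continue
        if len(centers) and np.min(np.linalg.norm(centers - p, axis=1)) < min_separation:
            continue
        centers = np.vstack([centers, p])

    template = water_template()
    positions, elements, sites = [], [], []
    for mol, c in enumerate(centers):
        rot = Rotation.from_quat(_uniform_quaternion(rng)).as_matrix()
        geom = template @ rot.T + c
        for el, tkey, pos in zip(("O", "H", "H"),
                                 (oxygen_type, hydrogen_type, hydrogen_type), geom):
            positions.append(pos)
            elements.append(el)
            sites.append(AtomSite(element=el, position=tuple(pos),
                                  molecule_id=mol, type_key=tkey))
    frame = TrajectoryFrame(
        time=0.0, positions=np.array(positions), elements=elements,
        molecule_ids=np.repeat(np.arange(n_waters), 3),
    )
    topology = SolventTopology(
        sites=sites,
        molecule_charges={m: molecule_charge for m in range(n_waters)},
    )
    return frame, topology


def _uniform_quaternion(rng):
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


@dataclass(frozen=True)
class Band:
    """One inhomogeneously broadened band: normal draws per snapshot."""

    position: float
    position_sigma: float
    intensity: float
    intensity_sigma: float
    sign: float = 1.0

    def __post_init__(self):
        if self.position_sigma < 0 or self.intensity_sigma < 0:
            raise ContractError("band sigmas must be nonnegative")


def gen_stick_ensemble(n_snapshots, bands, seed=0, axis_unit="nm", observable="uv"):
    """Ensemble of per-snapshot stick spectra with normal band statistics.

    Each band contributes one stick per snapshot: position ~
    N(position, position_sigma), intensity = sign · N(intensity,
    intensity_sigma).  The sign is applied after the draw, so two
    ensembles generated with the same seed and sign-flipped bands share
    their underlying draws exactly (useful for signed-vs-unsigned
    convergence comparisons).
    """
    bands = [b if isinstance(b, Band) else Band(*b) for b in bands]
    rng = substream(seed, "stick_ensemble")
    out = []
    for snap in range(n_snapshots):
        lines = []
        for b in bands:
            pos = rng.normal(b.position, b.position_sigma) if b.position_sigma else b.position
            raw = rng.normal(b.intensity, b.intensity_sigma) if b.intensity_sigma else b.intensity
            lines.append((pos, b.sign * raw))
        out.append(StickSpectrum(axis_unit=axis_unit, lines=lines,
                                 snapshot_id=snap, observable=observable))
    return out


# ---------------------------------------------------------------------------
# ball-and-spring vibrational fixtures
# ---------------------------------------------------------------------------

def _connected(n_atoms, bonds):
    adj = {i: set() for i in range(n_atoms)}
    for i, j, *_ in bonds:
        adj[i].add(j)
        adj[j].add(i)
    seen, stack = {0}, [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == n_atoms


def ballspring_energy_gradient(positions, bonds):
    """Energy (hartree) and gradient for harmonic bond springs.

    ``bonds`` holds ``(i, j, k, r0)`` with k in hartree/bohr² interpreted on
    the Å-scaled coordinates as given (the fixtures are unit-consistent by
    construction)."""
    pos = np.asarray(positions, float).reshape(-1, 3)
    e = 0.0
    g = np.zeros_like(pos)
    for i, j, k, r0 in bonds:
        d = pos[i] - pos[j]
        r = np.linalg.norm(d)
        e += 0.5 * k * (r - r0) ** 2
        f = k * (r - r0) * d / r
        g[i] += f
        g[j] -= f
    return e, g


def ballspring_hessian(positions, bonds):
    """Analytic Cartesian Hessian of the harmonic-bond energy."""
    pos = np.asarray(positions, float).reshape(-1, 3)
    n = len(pos)
    H = np.zeros((3 * n, 3 * n))
    eye = np.eye(3)
    for i, j, k, r0 in bonds:
        d = pos[i] - pos[j]
        r = np.linalg.norm(d)
        rhat = d / r
        blk = k * (np.outer(rhat, rhat) + (1.0 - r0 / r) * (eye - np.outer(rhat, rhat)))
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[si, si] += blk
        H[sj, sj] += blk
        H[si, sj] -= blk
        H[sj, si] -= blk
    return H


def gen_ballspring_system(positions, bonds, masses=None, labels=None, seed=0,
                          derivative_scale=0.1, at_equilibrium=True):
    """Ball-and-spring fixture: geometry, analytic Hessian, derivative tables.

    ``bonds`` is ``(i, j, k)`` or ``(i, j, k, r0)``; with ``at_equilibrium``
    missing rest lengths default to the current distances, making the input
    geometry a minimum.  Dipole/polarizability derivatives are small random
    tables of the declared scale drawn from the ``ballspring`` substream.
    Raises when the spring graph is disconnected.
    """
    pos = np.asarray(positions, float).reshape(-1, 3)
    n = len(pos)
    full = []
    for b in bonds:
        if len(b) == 3:
            i, j, k = b
            r0 = float(np.linalg.norm(pos[i] - pos[j])) if at_equilibrium else 1.0
        else:
            i, j, k, r0 = b
        full.append((int(i), int(j), float(k), float(r0)))
    if not _connected(n, full):
        raise ContractError("spring graph is disconnected")
    if masses is None:
        masses = np.ones(n)
    if labels is None:
        labels = [f"X{i}" for i in range(n)]
    H = ballspring_hessian(pos, full)
    rng = substream(seed, "ballspring")
    tables = DerivativeTables(
        dipole=derivative_scale * rng.normal(size=(3, 3 * n)),
        polarizability=derivative_scale * rng.normal(size=(6, 3 * n)),
    )
    block = HessianBlock(labels=list(labels), masses=np.asarray(masses, float),
                         hessian=H, positions=pos)
    return pos, block, tables, full


def gen_spin_system(n_spins, seed=0, spectrometer_mhz=600.0,
                    shift_range=(0.5, 9.5), geminal_range=(17.0, 19.0),
                    vicinal_range=(4.0, 12.0), coupling_density=0.5):
    """Random coupled spin system spanning realistic proton J ranges.

    Couplings alternate between geminal-like (17–19 Hz) and vicinal-like
    (4–12 Hz) magnitudes with the given pair density.
    """
    from .nmr import SpinSystem

    rng = substream(seed, "spin_system")
    labels = [f"H{i + 1}" for i in range(n_spins)]
    shifts = {l: float(rng.uniform(*shift_range)) for l in labels}
    couplings = {}
    for a in range(n_spins):
        for b in range(a + 1, n_spins):
            if rng.uniform() < coupling_density:
                rng_range = geminal_range if rng.uniform() < 0.3 else vicinal_range
                couplings[(labels[a], labels[b])] = float(rng.uniform(*rng_range))
    return SpinSystem(shifts, couplings, spectrometer_mhz)
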