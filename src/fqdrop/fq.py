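"""Fluctuating-charge / fluctuating-dipole (FQ / FQFμ) polarizable force field.

Each classical solvent atom carries a charge that equilibrates according to
the electronegativity-equalization principle under a fixed total charge per
molecule, enforced through Lagrange multipliers.  In the FQFμ variant every
atom additionally carries an induced point dipole governed by an isotropic
atomic polarizability.  The charges, multipliers and dipoles solve a single
symmetric linear system obtained as the stationarity condition of the
quadratic energy functional

    E(q, λ, μ) = ½ q_λᵀ M q_λ + q_λᵀ C_Q + qᵀ V + qᵀ Tqμ μ + ½ μᵀ Tμμ μ − μᵀ E

where ``M`` borders the charge–charge kernel Tqq with one constraint
row/column per molecule, ``C_Q`` stacks the atomic electronegativities χ and
the (negated) molecular charge constraints Q, and V, E are the external
potential and field at the solvent sites (here produced by a classical
solute stand-in; see :class:`SoluteModel`).

All public interfaces take coordinates in Å; charges, dipoles, energies and
kernels are atomic units (e, e·bohr, hartree).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import yaml
from scipy.special import erf

from .constants import ANGSTROM_TO_BOHR
from .errors import (
    ConditioningError,
    ContractError,
    ConvergenceError,
    GeometryError,
    ParameterError,
)

COINCIDENCE_TOL_ANGSTROM = 1e-6

__all__ = [
    "AtomSite",
    "SolventTopology",
    "FQParameterSet",
    "KernelMatrices",
    "ExternalSources",
    "SoluteModel",
    "ResponseSolution",
    "build_kernels",
    "solute_sources",
    "solve_response",
    "total_energy",
    "interaction_energy",
    "embedding_potential",
    "embedding_field",
    "mutual_polarization_scf",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomSite:
    """One classical solvent atom.

    Parameters
    ----------
    element : str
        Chemical symbol.
    position : array-like of 3 floats
        Cartesian position, Å.
    molecule_id : int
        Nonnegative id of the molecule this site belongs to.
    type_key : str
        Lookup key into the active :class:`FQParameterSet`.
    """

    element: str
    position: tuple
    molecule_id: int
    type_key: str

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ContractError(f"site position must be a finite 3-vector, got {self.position!r}")
        if self.molecule_id < 0:
            raise ContractError("molecule_id must be nonnegative")
        object.__setattr__(self, "position", tuple(pos))


@dataclass
class SolventTopology:
    """Ordered solvent sites plus a total-charge constraint per molecule.

    Sites belonging to one molecule must occupy a contiguous index range;
    the constructor raises otherwise.  Molecule order is the order of first
    appearance in ``sites`` and is used canonically everywhere downstream.
    """

    sites: list
    molecule_charges: dict

    def __post_init__(self):
        seen, order = set(), []
        prev = None
        for s in self.sites:
            if s.molecule_id != prev:
                if s.molecule_id in seen:
                    raise ContractError(
                        f"molecule {s.molecule_id} is not a contiguous index range"
                    )
                seen.add(s.molecule_id)
                order.append(s.molecule_id)
                prev = s.molecule_id
        missing = seen - set(self.molecule_charges)
        if missing:
            raise ContractError(f"molecule_charges missing entries for molecules {sorted(missing)}")
        self.molecule_order = order

    @property
    def n_sites(self):
        return len(self.sites)

    @property
    def n_molecules(self):
        return len(self.molecule_order)

    @property
    def positions(self):
        """Site positions, Å, shape (n, 3)."""
        return np.array([s.position for s in self.sites], dtype=float)

    @property
    def positions_bohr(self):
        return self.positions * ANGSTROM_TO_BOHR

    def molecule_indicator(self):
        """Constraint matrix Λ, shape (n_molecules, n_sites), entries 0/1."""
        lam = np.zeros((self.n_molecules, self.n_sites))
        row = {m: a for a, m in enumerate(self.molecule_order)}
        for i, s in enumerate(self.sites):
            lam[row[s.molecule_id], i] = 1.0
        return lam

    def constraint_vector(self):
        """Molecular charges Q in canonical molecule order, e."""
        return np.array([self.molecule_charges[m] for m in self.molecule_order], dtype=float)


@dataclass(frozen=True)
class SiteParameters:
    chi: float     # electronegativity, hartree/e
    eta: float     # chemical hardness, hartree/e^2
    alpha: float | None = None  # isotropic polarizability, bohr^3

    def __post_init__(self):
        if self.eta <= 0:
            raise ContractError(f"chemical hardness must be positive, got eta={self.eta}")


@dataclass
class FQParameterSet:
    """Per-type FQ(Fμ) parameters plus the interaction-kernel dialect.

    ``kernel_dialect`` selects how off-diagonal interactions are damped:
    ``"bare_coulomb"`` uses 1/r (and its derivatives), ``"gaussian_smeared"``
    (default) replaces point multipoles by spherical Gaussians whose widths
    derive from η (charges) and α (dipoles), regularizing close contacts.
    """

    types: dict = field(default_factory=dict)  # type_key -> SiteParameters
    dipoles_enabled: bool = False
    kernel_dialect: str = "gaussian_smeared"

    def __post_init__(self):
        if self.kernel_dialect not in ("bare_coulomb", "gaussian_smeared"):
            raise ContractError(f"unknown kernel dialect {self.kernel_dialect!r}")
        if self.dipoles_enabled:
            for key, p in self.types.items():
                if p.alpha is None or p.alpha <= 0:
                    raise ContractError(
                        f"type {key!r}: alpha must be positive when dipoles are enabled"
                    )

    def lookup(self, type_key):
        try:
            return self.types[type_key]
        except KeyError:
            raise ParameterError(f"no parameters for type_key {type_key!r}") from None

    @classmethod
    def from_yaml(cls, path, dipoles_enabled=False, kernel_dialect="gaussian_smeared"):
        """Load a ``type_key: {chi, eta, alpha}`` mapping from YAML."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        types = {
            key: SiteParameters(
                chi=float(v["chi"]), eta=float(v["eta"]),
                alpha=float(v["alpha"]) if "alpha" in v and v["alpha"] is not None else None,
            )
            for key, v in raw.items()
        }
        return cls(types=types, dipoles_enabled=dipoles_enabled, kernel_dialect=kernel_dialect)


@dataclass
class KernelMatrices:
    """Assembled interaction kernels, atomic units.

    ``Tqq`` (n×n), ``Tqmu`` (n×3n), ``Tmumu`` (3n×3n) and the bordered
    matrix ``M`` ((n+m)×(n+m)) with one constraint row/column per molecule.
    """

    Tqq: np.ndarray
    Tqmu: np.ndarray
    Tmumu: np.ndarray
    M: np.ndarray


@dataclass
class ExternalSources:
    """External potential V (hartree/e) and field E (hartree/(e·bohr)) per site."""

    V: np.ndarray
    E: np.ndarray

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.E.shape != (self.V.shape[0], 3):
            raise ContractError("E must have shape (n_sites, 3) matching V")

    @classmethod
    def zeros(cls, n):
        return cls(np.zeros(n), np.zeros((n, 3)))


@dataclass
class SoluteModel:
    """Classical stand-in for the solute charge distribution.

    Positions in Å; charges in e, dipoles in e·bohr, polarizabilities in
    bohr³.  ``polarizable_sites`` may be empty (rigid solute).
    """

    point_charges: list = field(default_factory=list)     # (position, q)
    static_dipoles: list = field(default_factory=list)    # (position, 3-vector)
    polarizable_sites: list = field(default_factory=list)  # (position, alpha)

    def is_empty(self):
        return not (self.point_charges or self.static_dipoles or self.polarizable_sites)


@dataclass
class ResponseSolution:
    """Solved charges q (e), multipliers λ (hartree/e) and dipoles μ (e·bohr).

    ``mu`` has shape (n, 3) in FQFμ mode and (0, 3) when dipoles are
    disabled.  ``residual`` is the max-norm residual of the stationarity
    system at the returned solution.
    """

    q: np.ndarray
    lam: np.ndarray
    mu: np.ndarray
    residual: float = 0.0

    def to_dict(self):
        return {
            "charges_e": self.q.tolist(),
            "lagrange_multipliers": self.lam.tolist(),
            "dipoles_au": self.mu.tolist(),
            "residual": self.residual,
        }

    def to_json(self, **kwargs):
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# kernel assembly
# ---------------------------------------------------------------------------

def _pairwise(pos_bohr):
    """Displacements (n,n,3) and distances (n,n, diag=inf) in bohr."""
    d = pos_bohr[:, None, :] - pos_bohr[None, :, :]
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    return d, r


def _charge_exponent(eta):
    # Gaussian charge exponent a with self-Coulomb sqrt(2a/pi) = eta.
    return math.pi * eta * eta / 2.0

def _dipole_exponent(alpha):
    # Smearing length set by the polarizability radius alpha^(1/3).
    sigma = alpha ** (1.0 / 3.0)
    return 1.0 / (2.0 * sigma * sigma)

def _combine(a, b):
    return a * b / (a + b)


def _damping_g1(x):
    return erf(x) - 2.0 * x * np.exp(-x * x) / math.sqrt(math.pi)

def _damping_g2(x):
    return erf(x) - 2.0 * x * (1.0 + 2.0 * x * x / 3.0) * np.exp(-x * x) / math.sqrt(math.pi)


def build_kernels(topology, params):
    """Assemble Tqq, Tqμ, Tμμ and the bordered matrix M for a topology.

    Diagonal Tqq entries are the atomic hardnesses η; diagonal 3×3 blocks of
    Tμμ are (1/α)·I.  Off-diagonal interactions are either bare Coulomb or
    Gaussian-smeared depending on the parameter set's dialect.  Raises
    :class:`ParameterError` for unresolvable type keys and
    :class:`GeometryError` for coincident sites.
    """
    n = topology.n_sites
    p = [params.lookup(s.type_key) for s in topology.sites]
    eta = np.array([x.eta for x in p])
    pos = topology.positions_bohr
    disp, r = _pairwise(pos)

    min_r = r.min(initial=np.inf)
    if min_r < COINCIDENCE_TOL_ANGSTROM * ANGSTROM_TO_BOHR:
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise GeometryError(f"sites {i} and {j} are coincident (r = {min_r:.3e} bohr)")

    smeared = params.kernel_dialect == "gaussian_smeared"
    r_safe = np.where(np.isinf(r), 1.0, r)  # diagonal placeholder, overwritten below
    if smeared:
        a_q = np.array([_charge_exponent(x.eta) for x in p])
        beta_qq = np.sqrt(_combine(a_q[:, None], a_q[None, :]))
        Tqq = erf(beta_qq * r_safe) / r_safe
    else:
        Tqq = 1.0 / r_safe
    np.fill_diagonal(Tqq, eta)

    if params.dipoles_enabled:
        alpha = np.array([x.alpha for x in p])
        inv_r3 = np.where(np.isinf(r), 0.0, r_safe ** -3)
        if smeared:
            a_mu = _dipole_exponent(alpha)
            beta_qmu = np.sqrt(_combine(a_q[:, None], a_mu[None, :]))
            beta_mumu = np.sqrt(_combine(a_mu[:, None], a_mu[None, :]))
            g1_qmu = _damping_g1(beta_qmu * r_safe)
            g1_mm = _damping_g1(beta_mumu * r_safe)
            g2_mm = _damping_g2(beta_mumu * r_safe)
        else:
            g1_qmu = g1_mm = g2_mm = np.ones_like(r)

        # T^qmu_{i,(j,k)}: energy coupling q_i with dipole k-component at j,
        # bare form (r_i - r_j)_k / r^3.
        Tqmu = (disp * (g1_qmu * inv_r3)[:, :, None]).reshape(n, 3 * n)

        rhat = disp / r_safe[:, :, None]
        eye = np.eye(3)
        blocks = (g1_mm * inv_r3)[:, :, None, None] * eye \
            - (3.0 * g2_mm * inv_r3)[:, :, None, None] * (rhat[:, :, :, None] * rhat[:, :, None, :])
        for i in range(n):
            blocks[i, i] = eye / alpha[i]
        Tmumu = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    else:
        Tqmu = np.zeros((n, 0))
        Tmumu = np.zeros((0, 0))

    m = topology.n_molecules
    M = np.zeros((n + m, n + m))
    M[:n, :n] = Tqq
    lam = topology.molecule_indicator()
    M[n:, :n] = lam
    M[:n, n:] = lam.T
    return KernelMatrices(Tqq=Tqq, Tqmu=Tqmu, Tmumu=Tmumu, M=M)


# ---------------------------------------------------------------------------
# external sources from the classical solute stand-in
# ---------------------------------------------------------------------------

def _coulomb_vf(src_pos_bohr, q, dip, target_bohr):
    """Potential and field at targets from point charges and point dipoles."""
    nt = target_bohr.shape[0]
    V = np.zeros(nt)
    E = np.zeros((nt, 3))
    if len(src_pos_bohr):
        d = target_bohr[:, None, :] - src_pos_bohr[None, :, :]   # r - r_src
        s = np.linalg.norm(d, axis=-1)
        if s.min(initial=np.inf) < COINCIDENCE_TOL_ANGSTROM * ANGSTROM_TO_BOHR:
            raise GeometryError("a source site coincides with an evaluation point")
        inv_s3 = s ** -3
        if q is not None:
            V += (q[None, :] / s).sum(axis=1)
            E += np.einsum("ts,tsx->tx", q[None, :] * inv_s3, d)
        if dip is not None:
            # phi = mu.(r - r_d)/s^3 ; E = (3(mu.s^)s^ - mu)/s^3
            mudotd = np.einsum("sx,tsx->ts", dip, d)
            V += (mudotd * inv_s3).sum(axis=1)
            shat = d / s[:, :, None]
            mudots = np.einsum("sx,tsx->ts", dip, shat)
            E += np.einsum("ts,tsx->tx", 3.0 * mudots / s**3, shat) \
                - (dip[None, :, :] * inv_s3[:, :, None]).sum(axis=1)
    return V, E


def _solute_arrays(solute, extra_dipoles=None):
    """Split a SoluteModel into (positions_bohr, q) and (positions_bohr, mu)."""
    cpos = np.array([p for p, _ in solute.point_charges], dtype=float).reshape(-1, 3)
    cq = np.array([q for _, q in solute.point_charges], dtype=float)
    dpos = [np.asarray(p, dtype=float) for p, _ in solute.static_dipoles]
    dmu = [np.asarray(m, dtype=float) for _, m in solute.static_dipoles]
    if extra_dipoles is not None:
        for p, m in extra_dipoles:
            dpos.append(np.asarray(p, dtype=float))
            dmu.append(np.asarray(m, dtype=float))
    dpos = np.array(dpos, dtype=float).reshape(-1, 3)
    dmu = np.array(dmu, dtype=float).reshape(-1, 3)
    return cpos * ANGSTROM_TO_BOHR, cq, dpos * ANGSTROM_TO_BOHR, dmu


def solute_sources(solute, topology, induced_dipoles=None):
    """Coulomb potential and field of the solute at every solvent site.

    ``induced_dipoles`` optionally appends (position Å, μ a.u.) pairs to the
    solute's static dipoles (used by the mutual-polarization loop).
    """
    if solute.is_empty() and not induced_dipoles:
        raise ContractError("solute model is empty")
    cpos, cq, dpos, dmu = _solute_arrays(solute, induced_dipoles)
    targets = topology.positions_bohr
    V = np.zeros(topology.n_sites)
    E = np.zeros((topology.n_sites, 3))
    if len(cpos):
        v, e = _coulomb_vf(cpos, cq, None, targets)
        V += v
        E += e
    if len(dpos):
        v, e = _coulomb_vf(dpos, None, dmu, targets)
        V += v
        E += e
    return ExternalSources(V=V, E=E)


# ---------------------------------------------------------------------------
# linear response solve
# ---------------------------------------------------------------------------

def _assemble_system(kernels, params, topology, sources):
    n = topology.n_sites
    m = topology.n_molecules
    chi = np.array([params.lookup(s.type_key).chi for s in topology.sites])
    Q = topology.constraint_vector()
    if sources.V.shape[0] != n:
        raise ContractError("sources dimensioned differently from topology")

    if params.dipoles_enabled:
        dim = n + m + 3 * n
        A = np.zeros((dim, dim))
        A[: n + m, : n + m] = kernels.M
        A[:n, n + m:] = kernels.Tqmu
        A[n + m:, :n] = kernels.Tqmu.T
        A[n + m:, n + m:] = kernels.Tmumu
        rhs = np.concatenate([-chi - sources.V, Q, sources.E.ravel()])
    else:
        dim = n + m
        A = kernels.M.copy()
        rhs = np.concatenate([-chi - sources.V, Q])
    return A, rhs, n, m


def solve_response(kernels, params, topology, sources):
    """Solve the stationarity system of the FQ(Fμ) energy functional.

    The symmetric block system

        [[Tqq, Λᵀ, Tqμ], [Λ, 0, 0], [Tμq, 0, Tμμ]] · [q; λ; μ] = [−χ−V; Q; E]

    is factorized densely after scaling the constraint rows/columns to unit
    magnitude; iterative refinement is applied until the max-norm residual
    is ≤ 1e-10 (or a few refinement sweeps, whichever first).
    """
    A, rhs, n, m = _assemble_system(kernels, params, topology, sources)
    dim = A.shape[0]

    # scale constraint rows/columns by 1/sqrt(molecule size)
    scale = np.ones(dim)
    sizes = topology.molecule_indicator().sum(axis=1)
    scale[n:n + m] = 1.0 / np.sqrt(sizes)
    As = A * scale[:, None] * scale[None, :]
    bs = rhs * scale

    try:
        lu, piv = scipy.linalg.lu_factor(As)
    except scipy.linalg.LinAlgError as exc:
        raise ConditioningError(f"response system is singular: {exc}") from exc
    ys = scipy.linalg.lu_solve((lu, piv), bs)
    if not np.all(np.isfinite(ys)):
        raise ConditioningError(
            "response system is numerically singular",
            condition_estimate=np.linalg.cond(A),
        )
    x = ys * scale
    for _ in range(5):
        res = rhs - A @ x
        if np.max(np.abs(res)) <= 1e-10:
            break
        x += scale * scipy.linalg.lu_solve((lu, piv), res * scale)
    residual = float(np.max(np.abs(rhs - A @ x)))
    if residual > 1e-8 or not np.isfinite(residual):
        raise ConditioningError(
            f"response residual {residual:.2e} exceeds tolerance after refinement",
            condition_estimate=np.linalg.cond(A),
        )

    q = x[:n]
    lam = x[n:n + m]
    mu = x[n + m:].reshape(-1, 3) if params.dipoles_enabled else np.zeros((0, 3))
    return ResponseSolution(q=q, lam=lam, mu=mu, residual=residual)


# ---------------------------------------------------------------------------
# energies and the embedding operator
# ---------------------------------------------------------------------------

def total_energy(solution, kernels, params, topology, sources):
    """Evaluate the FQ(Fμ) energy functional at an arbitrary (q, λ, μ).

    Returns ½ q_λᵀMq_λ + q_λᵀC_Q + qᵀV + qᵀTqμμ + ½ μᵀTμμμ − μᵀE in
    hartree.  Accepts any state, not only the solved one (used by the
    variational tests and by direct-minimization cross-checks).
    """
    n = topology.n_sites
    m = topology.n_molecules
    q, lam = np.asarray(solution.q, float), np.asarray(solution.lam, float)
    mu = np.asarray(solution.mu, float).reshape(-1, 3)
    if q.shape[0] != n or lam.shape[0] != m:
        raise ContractError("solution dimensioned differently from topology")
    if sources.V.shape[0] != n:
        raise ContractError("sources dimensioned differently from topology")

    chi = np.array([params.lookup(s.type_key).chi for s in topology.sites])
    Q = topology.constraint_vector()
    qlam = np.concatenate([q, lam])
    cq = np.concatenate([chi, -Q])
    e = 0.5 * qlam @ kernels.M @ qlam + qlam @ cq + q @ sources.V
    if params.dipoles_enabled:
        if mu.shape[0] != n:
            raise ContractError("dipole vector dimensioned differently from topology")
        muf = mu.ravel()
        e += q @ kernels.Tqmu @ muf + 0.5 * muf @ kernels.Tmumu @ muf \
            - muf @ sources.E.ravel()
    elif mu.size:
        raise ContractError("dipoles supplied but dipoles_enabled is False")
    return float(e)


def interaction_energy(solution, sources):
    """Electrostatic solvent–solute interaction qᵀV − μᵀE, hartree."""
    q = np.asarray(solution.q, float)
    if q.shape[0] != sources.V.shape[0]:
        raise ContractError("solution and sources have mismatched site counts")
    e = float(q @ sources.V)
    mu = np.asarray(solution.mu, float).reshape(-1, 3)
    if mu.size:
        if mu.shape[0] != sources.E.shape[0]:
            raise ContractError("dipoles and field have mismatched site counts")
        e -= float(np.sum(mu * sources.E))
    return e


def _check_points(points_bohr, site_bohr):
    d = points_bohr[:, None, :] - site_bohr[None, :, :]
    s = np.linalg.norm(d, axis=-1)
    if s.min(initial=np.inf) < COINCIDENCE_TOL_ANGSTROM * ANGSTROM_TO_BOHR:
        raise GeometryError("an evaluation point coincides with a solvent site")
    return d, s


def embedding_potential(solution, topology, points):
    """Potential of the solved solvent multipoles at arbitrary points (Å).

    V(r) = Σ_i q_i/|r_i − r| − Σ_i μ_i·(r_i − r)/|r_i − r|³, hartree/e.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3) * ANGSTROM_TO_BOHR
    d, s = _check_points(pts, topology.positions_bohr)   # d = r - r_i
    V = (solution.q[None, :] / s).sum(axis=1)
    mu = np.asarray(solution.mu, float).reshape(-1, 3)
    if mu.size:
        # −μ·(r_i − r)/s³ = +μ·(r − r_i)/s³
        V += (np.einsum("ix,pix->pi", mu, d) * s ** -3).sum(axis=1)
    return V


def embedding_field(solution, topology, points):
    """Electric field −∇V of the solvent multipoles at points (Å), a.u."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3) * ANGSTROM_TO_BOHR
    d, s = _check_points(pts, topology.positions_bohr)
    inv_s3 = s ** -3
    E = np.einsum("pi,pix->px", solution.q[None, :] * inv_s3, d)
    mu = np.asarray(solution.mu, float).reshape(-1, 3)
    if mu.size:
        shat = d / s[:, :, None]
        mudots = np.einsum("ix,pix->pi", mu, shat)
        E += np.einsum("pi,pix->px", 3.0 * mudots * inv_s3, shat) \
            - np.einsum("ix,pi->px", mu, inv_s3)
    return E


# ---------------------------------------------------------------------------
# mutual polarization between a polarizable solute and the solvent
# ---------------------------------------------------------------------------

def _dipole_interaction_tensor(pos_bohr):
    """Bare dipole–dipole tensor between distinct points, (3k×3k), zero diag."""
    k = pos_bohr.shape[0]
    T = np.zeros((k, k, 3, 3))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            d = pos_bohr[i] - pos_bohr[j]
            s = np.linalg.norm(d)
            rhat = d / s
            T[i, j] = (np.eye(3) - 3.0 * np.outer(rhat, rhat)) / s**3
    return T.transpose(0, 2, 1, 3).reshape(3 * k, 3 * k)


def mutual_polarization_scf(solute, topology, params, tol=1e-10, max_iter=200,
                            mixing=0.5):
    """Self-consistent mutual polarization of a polarizable solute and the solvent.

    Alternates an exact solvent response solve (given the current solute
    induced dipoles) with a damped exact update of the solute induced
    dipoles (given the solvent multipoles), which is block coordinate
    descent on the jointly convex coupled energy; the energy trace is
    therefore monotone non-increasing after the first iteration.

    Returns ``(ResponseSolution, induced_dipoles (k×3, a.u.), trace)`` where
    ``trace`` is the per-iteration coupled energy.  With no polarizable
    solute sites this reduces to a single :func:`solve_response` call.
    """
    kernels = build_kernels(topology, params)
    k = len(solute.polarizable_sites)
    if k == 0:
        src = solute_sources(solute, topology)
        sol = solve_response(kernels, params, topology, src)
        return sol, np.zeros((0, 3)), [total_energy(sol, kernels, params, topology, src)]

    ppos = np.array([p for p, _ in solute.polarizable_sites], dtype=float).reshape(-1, 3)
    alphas = np.array([a for _, a in solute.polarizable_sites], dtype=float)
    if np.any(alphas < 0):
        raise ContractError("solute polarizabilities must be nonnegative")
    ppos_bohr = ppos * ANGSTROM_TO_BOHR

    # permanent-solute field at the polarizable sites (excluding them)
    cpos, cq, dpos, dmu = _solute_arrays(solute)
    E_perm = np.zeros((k, 3))
    if len(cpos):
        E_perm += _coulomb_vf(cpos, cq, None, ppos_bohr)[1]
    if len(dpos):
        E_perm += _coulomb_vf(dpos, None, dmu, ppos_bohr)[1]

    Tmm = _dipole_interaction_tensor(ppos_bohr)
    # conditional minimization matrix for the induced dipoles; sites with
    # alpha = 0 carry no dipole and are excluded from the solve
    active = np.repeat(alphas > 0, 3)
    inv_alpha = np.where(alphas > 0, 1.0 / np.where(alphas > 0, alphas, 1.0), 0.0)
    Amat = Tmm + np.kron(np.diag(inv_alpha), np.eye(3))

    def coupled_energy(sol, src, m_flat):
        e = total_energy(sol, kernels, params, topology, src)
        e += 0.5 * m_flat @ Tmm @ m_flat
        with np.errstate(divide="ignore", invalid="ignore"):
            self_term = np.where(alphas > 0, np.sum(m_flat.reshape(-1, 3)**2, axis=1) / (2 * alphas), 0.0)
        e += self_term.sum()
        e -= float(np.sum(m_flat.reshape(-1, 3) * E_perm))
        return e

    m = np.zeros(3 * k)
    trace = []
    for it in range(max_iter):
        induced = [(ppos[i], m.reshape(-1, 3)[i]) for i in range(k)]
        src = solute_sources(solute, topology, induced_dipoles=induced)
        sol = solve_response(kernels, params, topology, src)

        # energy at the consistent state (sol solved for this m)
        trace.append(coupled_energy(sol, src, m))
        if it > 0 and abs(trace[-1] - trace[-2]) <= tol:
            return sol, m.reshape(-1, 3), trace

        E_solv = embedding_field(sol, topology, ppos)
        e_tot = (E_perm + E_solv).ravel()
        m_star = np.zeros(3 * k)
        if active.any():
            m_star[active] = np.linalg.solve(Amat[np.ix_(active, active)], e_tot[active])
        m = m + mixing * (m_star - m)
    raise ConvergenceError(
        f"mutual polarization not converged in {max_iter} iterations", trace=trace
    )
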