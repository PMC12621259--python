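"""Unit and property tests for the FQ/FQFμ engine.

The independent oracle used throughout is a loop-based re-derivation of the
energy functional (pair sums over sites, no shared code with the kernel
assembly) minimized under the per-molecule charge constraints with scipy.
"""

import math

import numpy as np
import pytest
import scipy.optimize
from scipy.special import erf

from fqdrop.constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM
from fqdrop.errors import (
    ConditioningError,
    ContractError,
    GeometryError,
    ParameterError,
)
from fqdrop.fq import (
    AtomSite,
    ExternalSources,
    FQParameterSet,
    ResponseSolution,
    SiteParameters,
    SoluteModel,
    SolventTopology,
    build_kernels,
    embedding_field,
    embedding_potential,
    interaction_energy,
    mutual_polarization_scf,
    solute_sources,
    solve_response,
    total_energy,
)
from fqdrop.synth import gen_water_droplet

from conftest import two_site_topology, uniform_field_sources


# ---------------------------------------------------------------------------
# independent energy oracle (loops, no kernel code)
# ---------------------------------------------------------------------------

def oracle_energy(q, mu, topo, params, sources):
    """Pair-sum re-derivation of the energy functional, bare or smeared."""
    pos = topo.positions_bohr
    n = topo.n_sites
    p = [params.lookup(s.type_key) for s in topo.sites]
    smeared = params.kernel_dialect == "gaussian_smeared"
    a_q = [math.pi * x.eta**2 / 2.0 for x in p]
    e = 0.0
    for i in range(n):
        e += p[i].chi * q[i] + 0.5 * p[i].eta * q[i] ** 2 + q[i] * sources.V[i]
    for i in range(n):
        for j in range(i + 1, n):
            r = np.linalg.norm(pos[i] - pos[j])
            damp = erf(math.sqrt(a_q[i] * a_q[j] / (a_q[i] + a_q[j])) * r) if smeared else 1.0
            e += q[i] * q[j] * damp / r
    if params.dipoles_enabled:
        a_m = [1.0 / (2.0 * x.alpha ** (2.0 / 3.0)) for x in p]
        for i in range(n):
            e += float(mu[i] @ mu[i]) / (2.0 * p[i].alpha) - float(mu[i] @ sources.E[i])
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = pos[i] - pos[j]
                r = np.linalg.norm(d)
                if smeared:
                    x = math.sqrt(a_q[i] * a_m[j] / (a_q[i] + a_m[j])) * r
                    g1 = erf(x) - 2 * x * math.exp(-x * x) / math.sqrt(math.pi)
                else:
                    g1 = 1.0
                # charge i with dipole j
                e += q[i] * g1 * float(mu[j] @ d) / r**3
        for i in range(n):
            for j in range(i + 1, n):
                d = pos[i] - pos[j]
                r = np.linalg.norm(d)
                rhat = d / r
                if smeared:
                    x = math.sqrt(a_m[i] * a_m[j] / (a_m[i] + a_m[j])) * r
                    g1 = erf(x) - 2 * x * math.exp(-x * x) / math.sqrt(math.pi)
                    g2 = erf(x) - 2 * x * (1 + 2 * x * x / 3) * math.exp(-x * x) / math.sqrt(math.pi)
                else:
                    g1 = g2 = 1.0
                e += (g1 * float(mu[i] @ mu[j]) - 3.0 * g2 * float(mu[i] @ rhat) * float(mu[j] @ rhat)) / r**3
    return e


def oracle_minimize(topo, params, sources):
    """Constrained direct minimization of the oracle energy."""
    n = topo.n_sites
    lam = topo.molecule_indicator()
    Q = topo.constraint_vector()
    # particular solution + null-space parametrization of the constraints
    q0 = lam.T @ np.linalg.solve(lam @ lam.T, Q)
    _, _, vt = np.linalg.svd(lam)
    null = vt[lam.shape[0]:].T      # (n, n - m)
    ndip = 3 * n if params.dipoles_enabled else 0

    def fun(z):
        q = q0 + null @ z[: null.shape[1]]
        mu = z[null.shape[1]:].reshape(-1, 3) if ndip else np.zeros((n, 3))
        return oracle_energy(q, mu, topo, params, sources)

    z0 = np.zeros(null.shape[1] + ndip)
    res = scipy.optimize.minimize(fun, z0, method="BFGS",
                                  options={"gtol": 1e-12, "maxiter": 5000})
    return res.fun


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

class TestBuildKernels:
    def test_bare_two_site_kernel_matches_coulomb(self):
        params = FQParameterSet(types={"A": SiteParameters(chi=0.1, eta=0.5)},
                                kernel_dialect="bare_coulomb")
        topo = two_site_topology(2.0 * BOHR_TO_ANGSTROM)
        k = build_kernels(topo, params)
        np.testing.assert_allclose(k.Tqq, [[0.5, 0.5], [0.5, 0.5]], atol=1e-14)

    def test_dipole_self_block_is_inverse_polarizability(self):
        params = FQParameterSet(types={"A": SiteParameters(chi=0.0, eta=0.5, alpha=8.0)},
                                dipoles_enabled=True, kernel_dialect="bare_coulomb")
        topo = SolventTopology(sites=[AtomSite("X", (0, 0, 0), 0, "A")],
                               molecule_charges={0: 0.0})
        k = build_kernels(topo, params)
        np.testing.assert_allclose(k.Tmumu, np.eye(3) / 8.0, atol=1e-14)

    def test_smeared_offdiagonals_bounded_by_bare(self, fqmu_params, smeared_params):
        _, topo = gen_water_droplet(3, radius=5.0, seed=4)
        bare = build_kernels(topo, fqmu_params)
        smeared = build_kernels(topo, smeared_params)
        off = ~np.eye(topo.n_sites, dtype=bool)
        assert np.all(smeared.Tqq[off] <= bare.Tqq[off] + 1e-14)
        # large-separation equality
        topo_far = two_site_topology(40.0)
        params_far = FQParameterSet(types={"A": SiteParameters(chi=0.1, eta=0.6)},
                                    kernel_dialect="gaussian_smeared")
        bare_far = 1.0 / (40.0 * ANGSTROM_TO_BOHR)
        k_far = build_kernels(topo_far, params_far)
        np.testing.assert_allclose(k_far.Tqq[0, 1], bare_far, rtol=1e-12)

    def test_bordered_matrix_has_molecule_indicator_rows(self, fq_params, small_droplet):
        _, topo = small_droplet
        k = build_kernels(topo, fq_params)
        n, m = topo.n_sites, topo.n_molecules
        np.testing.assert_array_equal(k.M[n:, :n], topo.molecule_indicator())
        np.testing.assert_array_equal(k.M[n:, n:], np.zeros((m, m)))
        np.testing.assert_allclose(k.M, k.M.T, atol=0)

    def test_missing_parameter_names_the_type_key(self, fq_params):
        topo = two_site_topology(3.0, type_key="MISSING")
        with pytest.raises(ParameterError, match="MISSING"):
            build_kernels(topo, fq_params)

    def test_coincident_sites_rejected(self):
        params = FQParameterSet(types={"A": SiteParameters(chi=0.1, eta=0.5)})
        topo = two_site_topology(1e-9)
        with pytest.raises(GeometryError):
            build_kernels(topo, params)


# ---------------------------------------------------------------------------
# solute sources
# ---------------------------------------------------------------------------

class TestSoluteSources:
    def test_unit_charge_coulomb_law(self):
        topo = SolventTopology(
            sites=[AtomSite("X", (BOHR_TO_ANGSTROM, 0, 0), 0, "A")],
            molecule_charges={0: 0.0})
        solute = SoluteModel(point_charges=[((0.0, 0.0, 0.0), 1.0)])
        src = solute_sources(solute, topo)
        np.testing.assert_allclose(src.V, [1.0], atol=1e-14)
        np.testing.assert_allclose(src.E, [[1.0, 0.0, 0.0]], atol=1e-14)

    def test_static_dipole_matches_shrinking_charge_pair(self):
        target = (3.0, 1.0, -2.0)
        topo = SolventTopology(sites=[AtomSite("X", target, 0, "A")],
                               molecule_charges={0: 0.0})
        mu = np.array([0.2, -0.1, 0.3])  # a.u.
        exact = solute_sources(SoluteModel(static_dipoles=[((0.0, 0.0, 0.0), mu)]), topo)
        d_bohr = 1e-4
        d_ang = d_bohr * BOHR_TO_ANGSTROM
        qmag = np.linalg.norm(mu) / d_bohr
        unit = mu / np.linalg.norm(mu)
        plus = tuple(+0.5 * d_ang * unit)
        minus = tuple(-0.5 * d_ang * unit)
        approx = solute_sources(
            SoluteModel(point_charges=[(plus, qmag), (minus, -qmag)]), topo)
        np.testing.assert_allclose(approx.V, exact.V, rtol=1e-6)
        np.testing.assert_allclose(approx.E, exact.E, rtol=1e-6)

    def test_zero_magnitude_sources_vanish(self, small_droplet):
        _, topo = small_droplet
        src = solute_sources(SoluteModel(point_charges=[((0.0, 0.0, 0.0), 0.0)]), topo)
        np.testing.assert_array_equal(src.V, np.zeros(topo.n_sites))
        np.testing.assert_array_equal(src.E, np.zeros((topo.n_sites, 3)))

    def test_coincident_solute_site_rejected(self, small_droplet):
        _, topo = small_droplet
        clash = tuple(topo.positions[0])
        with pytest.raises(GeometryError):
            solute_sources(SoluteModel(point_charges=[(clash, 1.0)]), topo)


# ---------------------------------------------------------------------------
# response solve
# ---------------------------------------------------------------------------

class TestSolveResponse:
    def test_symmetric_water_charges(self, fq_params):
        _, topo = gen_water_droplet(1, radius=3.0, seed=7)
        k = build_kernels(topo, fq_params)
        sol = solve_response(k, fq_params, topo, ExternalSources.zeros(3))
        assert sol.q[1] == pytest.approx(sol.q[2], abs=1e-12)
        assert sol.q[0] == pytest.approx(-2.0 * sol.q[1], abs=1e-12)

    def test_two_identical_atoms_split_the_molecular_charge(self):
        params = FQParameterSet(types={"A": SiteParameters(chi=0.1, eta=0.5)},
                                kernel_dialect="bare_coulomb")
        topo = two_site_topology(2.0, charges={0: -1.0})
        k = build_kernels(topo, params)
        sol = solve_response(k, params, topo, ExternalSources.zeros(2))
        np.testing.assert_allclose(sol.q, [-0.5, -0.5], atol=1e-12)

    @pytest.mark.parametrize("dialect", ["bare_coulomb", "gaussian_smeared"])
    def test_solver_energy_matches_direct_minimization(self, dialect):
        types = {"OW": SiteParameters(chi=0.25, eta=0.7, alpha=1.5),
                 "HW": SiteParameters(chi=0.05, eta=0.9, alpha=0.4)}
        params = FQParameterSet(types=types, dipoles_enabled=True,
                                kernel_dialect=dialect)
        _, topo = gen_water_droplet(5, radius=6.0, seed=21)
        solute = SoluteModel(point_charges=[((0.3, -0.2, 0.1), 0.8)])
        src = solute_sources(solute, topo)
        k = build_kernels(topo, params)
        sol = solve_response(k, params, topo, src)
        e_solver = total_energy(sol, k, params, topo, src)
        e_oracle = oracle_minimize(topo, params, src)
        assert e_solver == pytest.approx(e_oracle, abs=1e-8)

    def test_charge_conservation_and_residual(self, fqmu_params):
        for seed in range(5):
            _, topo = gen_water_droplet(4, radius=5.5, seed=100 + seed)
            src = solute_sources(SoluteModel(point_charges=[((0.1, 0.0, 0.0), 1.0)]), topo)
            k = build_kernels(topo, fqmu_params)
            sol = solve_response(k, fqmu_params, topo, src)
            sums = topo.molecule_indicator() @ sol.q
            np.testing.assert_allclose(sums, topo.constraint_vector(), atol=1e-12)
            assert sol.residual <= 1e-10

    def test_singular_system_reports_conditioning(self):
        # with eta exactly equal to the off-diagonal 1/r the two site rows of
        # the bordered matrix coincide and the system is exactly singular
        params = FQParameterSet(types={"A": SiteParameters(chi=0.1, eta=0.5)},
                                kernel_dialect="bare_coulomb")
        topo = two_site_topology(2.0 * BOHR_TO_ANGSTROM)
        k = build_kernels(topo, params)
        with pytest.raises(ConditioningError):
            solve_response(k, params, topo, ExternalSources.zeros(2))


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

class TestEnergies:
    def test_zero_state_zero_sources_gives_zero(self, fqmu_params, small_droplet):
        _, topo = small_droplet
        k = build_kernels(topo, fqmu_params)
        zero = ResponseSolution(q=np.zeros(topo.n_sites),
                                lam=np.zeros(topo.n_molecules),
                                mu=np.zeros((topo.n_sites, 3)))
        assert total_energy(zero, k, fqmu_params, topo,
                            ExternalSources.zeros(topo.n_sites)) == 0.0

    def test_solution_is_variational_minimum(self, fqmu_params, small_droplet):
        _, topo = small_droplet
        src = solute_sources(SoluteModel(point_charges=[((0.2, 0.1, 0.0), 1.0)]), topo)
        k = build_kernels(topo, fqmu_params)
        sol = solve_response(k, fqmu_params, topo, src)
        e0 = total_energy(sol, k, fqmu_params, topo, src)
        rng = np.random.default_rng(42)
        lam = topo.molecule_indicator()
        proj = np.eye(topo.n_sites) - lam.T @ np.linalg.solve(lam @ lam.T, lam)
        for _ in range(100):
            dq = proj @ rng.normal(scale=0.05, size=topo.n_sites)
            dmu = rng.normal(scale=0.05, size=sol.mu.shape)
            pert = ResponseSolution(q=sol.q + dq, lam=sol.lam, mu=sol.mu + dmu)
            assert total_energy(pert, k, fqmu_params, topo, src) > e0

    def test_fq_limit_equals_dipole_free_evaluation(self, fq_params, fqmu_params,
                                                    small_droplet):
        _, topo = small_droplet
        src = solute_sources(SoluteModel(point_charges=[((0.2, 0.1, 0.0), 1.0)]), topo)
        k_fq = build_kernels(topo, fq_params)
        sol_fq = solve_response(k_fq, fq_params, topo, src)
        e_fq = total_energy(sol_fq, k_fq, fq_params, topo, src)
        # evaluate the FQFmu functional at the FQ charges with mu = 0
        k_mu = build_kernels(topo, fqmu_params)
        state = ResponseSolution(q=sol_fq.q, lam=sol_fq.lam,
                                 mu=np.zeros((topo.n_sites, 3)))
        e_mu_at_zero_dip = total_energy(state, k_mu, fqmu_params, topo, src)
        assert e_mu_at_zero_dip == pytest.approx(e_fq, abs=1e-13)

    def test_interaction_energy_products(self):
        sol = ResponseSolution(q=np.array([1.0]), lam=np.zeros(1),
                               mu=np.zeros((0, 3)))
        src = ExternalSources(V=np.array([0.25]), E=np.zeros((1, 3)))
        assert interaction_energy(sol, src) == pytest.approx(0.25)
        sol_mu = ResponseSolution(q=np.array([0.0]), lam=np.zeros(1),
                                  mu=np.array([[0.0, 0.0, 1.0]]))
        src_e = ExternalSources(V=np.zeros(1), E=np.array([[0.0, 0.0, 0.1]]))
        assert interaction_energy(sol_mu, src_e) == pytest.approx(-0.1)
        zero = ResponseSolution(q=np.zeros(1), lam=np.zeros(1), mu=np.zeros((0, 3)))
        assert interaction_energy(zero, src) == 0.0

    def test_frame_invariance_of_total_energy(self, fqmu_params):
        from scipy.spatial.transform import Rotation

        _, topo = gen_water_droplet(3, radius=5.0, seed=31)
        solute_pos = np.array([0.4, -0.3, 0.2])
        rot = Rotation.from_euler("zyx", [0.3, -1.1, 0.7]).as_matrix()
        shift = np.array([5.0, -2.0, 1.0])

        def solve_energy(positions, solute_xyz):
            sites = [AtomSite(s.element, tuple(p), s.molecule_id, s.type_key)
                     for s, p in zip(topo.sites, positions)]
            t = SolventTopology(sites=sites, molecule_charges=topo.molecule_charges)
            src = solute_sources(SoluteModel(point_charges=[(tuple(solute_xyz), 0.9)]), t)
            k = build_kernels(t, fqmu_params)
            sol = solve_response(k, fqmu_params, t, src)
            return total_energy(sol, k, fqmu_params, t, src)

        e1 = solve_energy(topo.positions, solute_pos)
        e2 = solve_energy(topo.positions @ rot.T + shift, rot @ solute_pos + shift)
        assert e2 == pytest.approx(e1, abs=1e-10)

    def test_linear_response_to_uniform_field(self, fqmu_params, small_droplet):
        _, topo = small_droplet
        k = build_kernels(topo, fqmu_params)
        pos = topo.positions_bohr

        def total_dipole(field):
            src = uniform_field_sources(topo, field)
            sol = solve_response(k, fqmu_params, topo, src)
            return pos.T @ sol.q + sol.mu.sum(axis=0)

        base = total_dipole(np.zeros(3))
        pol = np.zeros((3, 3))
        f0 = 1e-4
        for a in range(3):
            e = np.zeros(3)
            e[a] = f0
            pol[:, a] = (total_dipole(e) - base) / f0
        # linearity over a 10x field range
        for a in range(3):
            e = np.zeros(3)
            e[a] = 10 * f0
            strong = (total_dipole(e) - base) / (10 * f0)
            np.testing.assert_allclose(strong, pol[:, a], rtol=1e-2)
        np.testing.assert_allclose(pol, pol.T, atol=1e-8)
        assert np.all(np.linalg.eigvalsh(0.5 * (pol + pol.T)) > 0)


# ---------------------------------------------------------------------------
# embedding operator
# ---------------------------------------------------------------------------

class TestEmbeddingPotential:
    def test_point_charge_coulomb(self):
        topo = SolventTopology(sites=[AtomSite("X", (0, 0, 0), 0, "A")],
                               molecule_charges={0: 1.0})
        sol = ResponseSolution(q=np.array([1.0]), lam=np.zeros(1), mu=np.zeros((0, 3)))
        v = embedding_potential(sol, topo, [(BOHR_TO_ANGSTROM, 0.0, 0.0)])
        assert v[0] == pytest.approx(1.0, abs=1e-14)

    def test_pure_dipole_matches_shrinking_pair(self):
        mu = np.array([0.0, 0.0, 0.4])
        topo = SolventTopology(sites=[AtomSite("X", (0, 0, 0), 0, "A")],
                               molecule_charges={0: 0.0})
        sol = ResponseSolution(q=np.array([0.0]), lam=np.zeros(1), mu=mu[None, :])
        pt = [(1.0, 2.0, 1.5)]
        exact = embedding_potential(sol, topo, pt)[0]
        d_bohr = 1e-4
        qmag = np.linalg.norm(mu) / d_bohr
        half = 0.5 * d_bohr * BOHR_TO_ANGSTROM * mu / np.linalg.norm(mu)
        t2 = SolventTopology(
            sites=[AtomSite("X", tuple(half), 0, "A"),
                   AtomSite("X", tuple(-half), 0, "A")],
            molecule_charges={0: 0.0})
        s2 = ResponseSolution(q=np.array([qmag, -qmag]), lam=np.zeros(1),
                              mu=np.zeros((0, 3)))
        approx = embedding_potential(s2, t2, pt)[0]
        assert approx == pytest.approx(exact, rel=1e-6)

    def test_translation_invariance(self, fqmu_params, small_droplet):
        _, topo = small_droplet
        src = solute_sources(SoluteModel(point_charges=[((0.1, 0.2, 0.0), 1.0)]), topo)
        k = build_kernels(topo, fqmu_params)
        sol = solve_response(k, fqmu_params, topo, src)
        pts = np.array([[6.0, 0.0, 0.0], [0.0, 7.0, 1.0]])
        v1 = embedding_potential(sol, topo, pts)
        shift = np.array([3.0, -4.0, 5.0])
        shifted_sites = [AtomSite(s.element, tuple(np.array(s.position) + shift),
                                  s.molecule_id, s.type_key) for s in topo.sites]
        topo2 = SolventTopology(sites=shifted_sites,
                                molecule_charges=topo.molecule_charges)
        v2 = embedding_potential(sol, topo2, pts + shift)
        np.testing.assert_allclose(v2, v1, atol=1e-12)

    def test_point_on_site_rejected(self, small_droplet):
        _, topo = small_droplet
        sol = ResponseSolution(q=np.zeros(topo.n_sites),
                               lam=np.zeros(topo.n_molecules), mu=np.zeros((0, 3)))
        with pytest.raises(GeometryError):
            embedding_potential(sol, topo, [tuple(topo.positions[2])])


# ---------------------------------------------------------------------------
# mutual polarization
# ---------------------------------------------------------------------------

class TestMutualPolarization:
    def test_rigid_solute_reduces_to_single_solve(self, fqmu_params, small_droplet):
        _, topo = small_droplet
        solute = SoluteModel(point_charges=[((0.2, 0.0, 0.1), 1.0)])
        sol_scf, induced, trace = mutual_polarization_scf(solute, topo, fqmu_params)
        k = build_kernels(topo, fqmu_params)
        sol_direct = solve_response(k, fqmu_params, topo,
                                    solute_sources(solute, topo))
        assert induced.shape == (0, 3)
        np.testing.assert_allclose(sol_scf.q, sol_direct.q, atol=1e-14)
        np.testing.assert_allclose(sol_scf.mu, sol_direct.mu, atol=1e-14)

    def test_zero_polarizability_site_matches_one_shot(self, fqmu_params, small_droplet):
        _, topo = small_droplet
        base = SoluteModel(point_charges=[((0.2, 0.0, 0.1), 1.0)])
        withzero = SoluteModel(point_charges=[((0.2, 0.0, 0.1), 1.0)],
                               polarizable_sites=[((0.9, 0.4, -0.2), 0.0)])
        sol_a, _, _ = mutual_polarization_scf(base, topo, fqmu_params, tol=1e-13)
        sol_b, induced, _ = mutual_polarization_scf(withzero, topo, fqmu_params, tol=1e-13)
        np.testing.assert_allclose(induced, np.zeros((1, 3)), atol=1e-14)
        np.testing.assert_allclose(sol_b.q, sol_a.q, atol=1e-10)

    def test_two_polarizable_points_analytic(self):
        """One polarizable solute site + one dipole-only solvent site, driven
        by a distant point charge, against the closed-form coupled solve."""
        alpha_solute, alpha_solvent = 3.0, 2.0
        eta_huge = 1e6      # pins the solvent charge to ~0 under Q = 0
        params = FQParameterSet(
            types={"S": SiteParameters(chi=0.0, eta=eta_huge, alpha=alpha_solvent)},
            dipoles_enabled=True, kernel_dialect="bare_coulomb")
        solvent_xyz = np.array([4.0, 0.0, 0.0])
        topo = SolventTopology(sites=[AtomSite("X", tuple(solvent_xyz), 0, "S")],
                               molecule_charges={0: 0.0})
        solute_pol_xyz = np.array([0.0, 0.0, 0.0])
        charge_xyz = np.array([-6.0, 1.0, 0.0])
        qc = 1.5
        solute = SoluteModel(point_charges=[(tuple(charge_xyz), qc)],
                             polarizable_sites=[(tuple(solute_pol_xyz), alpha_solute)])
        sol, induced, trace = mutual_polarization_scf(solute, topo, params,
                                                      tol=1e-16, max_iter=5000)

        # closed form: solve the 6x6 coupled dipole system directly
        def field_of_charge(at):
            d = (at - charge_xyz) * ANGSTROM_TO_BOHR
            return qc * d / np.linalg.norm(d) ** 3

        def dip_tensor(a, b):
            d = (a - b) * ANGSTROM_TO_BOHR
            r = np.linalg.norm(d)
            rhat = d / r
            return (np.eye(3) - 3.0 * np.outer(rhat, rhat)) / r**3

        A = np.zeros((6, 6))
        A[:3, :3] = np.eye(3) / alpha_solute
        A[3:, 3:] = np.eye(3) / alpha_solvent
        T = dip_tensor(solute_pol_xyz, solvent_xyz)
        A[:3, 3:] = T
        A[3:, :3] = T
        rhs = np.concatenate([field_of_charge(solute_pol_xyz),
                              field_of_charge(solvent_xyz)])
        mu_pair = np.linalg.solve(A, rhs)
        np.testing.assert_allclose(induced[0], mu_pair[:3], atol=1e-8)
        np.testing.assert_allclose(sol.mu[0], mu_pair[3:], atol=1e-8)

    def test_energy_trace_monotone_after_first_iteration(self, fqmu_params):
        for seed in range(20):
            _, topo = gen_water_droplet(3, radius=5.0, seed=300 + seed)
            solute = SoluteModel(point_charges=[((0.2, -0.1, 0.0), 1.0)],
                                 polarizable_sites=[((0.8, 0.5, 0.1), 2.5)])
            _, _, trace = mutual_polarization_scf(solute, topo, fqmu_params,
                                                  tol=1e-12, max_iter=500)
            diffs = np.diff(trace[1:])
            assert np.all(diffs <= 1e-12), f"seed {seed}: trace not monotone"
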