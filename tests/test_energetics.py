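import numpy as np
import pytest

from gbscan import (
    COULOMB_CONSTANT,
    GBOptions,
    SASAOptions,
    decompose_per_residue,
    effective_binding_energy,
    inter_nonbonded,
)
from gbscan.energetics import (
    EnergyComponents,
    gb_energy,
    hct_obc_radii,
    pair_descreening_integral,
    shrake_rupley,
)
from gbscan.geometry import rotation_about_axis

from conftest import make_toy_system

NO_SALT = GBOptions(ionic_strength=0.0)


# ---------------------------------------------------------------------------
# Born radii
# ---------------------------------------------------------------------------

def test_isolated_atom_reduced_radius():
    """With no neighbours the descreening integral vanishes (tanh(0)=0)."""
    r = hct_obc_radii(np.zeros((1, 3)), np.array([1.5]), np.array([0.85]), NO_SALT)
    assert r[0] == pytest.approx(1.5 - 0.09, rel=1e-12)


def _quadrature_descreening(r, s, rho, n=400):
    """Numeric (1/4pi) integral of x^-4 over a sphere of radius s at
    distance r, excluding the ball of radius rho around the origin."""
    u = (np.arange(n) + 0.5) / n
    rr = u * s
    ct = -1 + 2 * (np.arange(n) + 0.5) / n
    RR, CT = np.meshgrid(rr, ct, indexing="ij")
    d2 = (r + RR * CT) ** 2 + (RR**2) * (1 - CT**2)
    integrand = np.where(d2 > rho**2, 1.0 / d2**2, 0.0)
    dV = (2 * np.pi) * (RR**2) * (s / n) * (2.0 / n)
    return float((integrand * dV).sum() / (4 * np.pi))


@pytest.mark.parametrize(
    "r,s,rho",
    [(3.0, 1.0, 1.4), (2.0, 1.0, 1.4), (1.6, 1.0, 1.4), (1.0, 1.2, 0.8), (0.5, 2.0, 0.3)],
)
def test_descreening_matches_quadrature(r, s, rho):
    analytic = float(pair_descreening_integral(r, s, rho))
    numeric = _quadrature_descreening(r, s, rho)
    assert analytic == pytest.approx(numeric, abs=2e-3, rel=1e-2)


def test_two_atom_born_radius_against_quadrature():
    rho = np.array([1.5, 1.2]) - 0.09
    screen = np.array([0.85, 0.85])
    coords = np.array([[0.0, 0, 0], [2.4, 0, 0]])
    radii = hct_obc_radii(coords, rho + 0.09, screen, NO_SALT)
    integral = _quadrature_descreening(2.4, screen[1] * rho[1], rho[0])
    psi = rho[0] * integral
    expected = 1.0 / (1.0 / rho[0] - np.tanh(psi - 0.8 * psi**2 + 4.85 * psi**3) / 1.5)
    assert radii[0] == pytest.approx(expected, rel=1e-3)


def test_burial_never_shrinks_born_radius():
    """Adding descreening neighbours monotonically increases the radius."""
    rng = np.random.default_rng(5)
    center = np.zeros((1, 3))
    neighbours = rng.normal(scale=2.5, size=(12, 3)) + np.array([3.0, 0, 0])
    previous = 0.0
    for k in range(len(neighbours) + 1):
        coords = np.vstack([center, neighbours[:k]])
        radii = hct_obc_radii(
            coords, np.full(k + 1, 1.7), np.full(k + 1, 0.72), NO_SALT
        )
        assert radii[0] >= previous - 1e-12
        previous = radii[0]


def test_nonpositive_radius_rejected():
    with pytest.raises(ValueError):
        hct_obc_radii(np.zeros((1, 3)), np.array([-1.0]), np.array([0.8]))


# ---------------------------------------------------------------------------
# GB polar energy
# ---------------------------------------------------------------------------

def test_born_ion_analytic_limit():
    e, per = gb_energy(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]), NO_SALT)
    expected = -COULOMB_CONSTANT / 2.0 * (1.0 - 1.0 / 80.0) / 2.0
    assert e == pytest.approx(expected, rel=1e-9)
    assert e == pytest.approx(-81.98, abs=5e-3)
    assert per[0] == pytest.approx(e, rel=1e-12)


def test_zero_charges_zero_energy():
    coords = np.random.default_rng(1).normal(size=(5, 3)) * 3
    e, per = gb_energy(coords, np.zeros(5), np.full(5, 1.5), NO_SALT)
    assert e == 0.0
    assert np.all(per == 0.0)


def test_per_atom_shares_conserve_total():
    rng = np.random.default_rng(2)
    coords = rng.normal(size=(8, 3)) * 4
    q = rng.normal(size=8)
    e, per = gb_energy(coords, q, np.full(8, 1.6), GBOptions())
    assert per.sum() == pytest.approx(e, rel=1e-9)


def test_salt_screens_cross_partner_polar_term():
    """The GB binding term of an ion pair grows with ionic strength.

    Salt screens the cross-partner electrostatics, so the (positive)
    polar-solvation penalty of bringing two opposite charges together
    never decreases when kappa rises; each ion's self-solvation, in
    contrast, becomes more favourable.
    """
    coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
    q = np.array([1.0, -1.0])
    R = np.array([2.0, 2.0])
    prev_cross, prev_self = -np.inf, np.inf
    for ionic in (0.0, 0.05, 0.1, 0.5):
        opts = GBOptions(ionic_strength=ionic)
        pair, _ = gb_energy(coords, q, R, opts)
        self_a, _ = gb_energy(coords[:1], q[:1], R[:1], opts)
        self_b, _ = gb_energy(coords[1:], q[1:], R[1:], opts)
        cross = pair - self_a - self_b
        assert cross >= prev_cross
        assert self_a <= prev_self
        prev_cross, prev_self = cross, self_a


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_isolated_sphere_analytic_area():
    areas = shrake_rupley(np.zeros((1, 3)), np.array([1.6]), SASAOptions())
    exact = 4.0 * np.pi * 3.0**2
    assert areas[0] == pytest.approx(exact, rel=0.01)
    assert exact == pytest.approx(113.10, abs=0.005)


def test_overlapping_identical_spheres_symmetric():
    coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    areas = shrake_rupley(coords, np.array([1.5, 1.5]))
    assert areas[0] == pytest.approx(areas[1], rel=1e-9)
    assert areas[0] < 4.0 * np.pi * 2.9**2


def _mc_sasa(coords, radii, probe, n=120000, seed=4):
    """Independent Monte-Carlo surface sampling oracle."""
    rng = np.random.default_rng(seed)
    R = radii + probe
    out = np.empty(len(coords))
    for i in range(len(coords)):
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        surface = coords[i] + R[i] * pts
        free = np.ones(n, bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= ((surface - coords[j]) ** 2).sum(1) >= R[j] ** 2
        out[i] = 4.0 * np.pi * R[i] ** 2 * free.mean()
    return out


def test_cluster_sasa_against_dense_oracle():
    rng = np.random.default_rng(9)
    coords = rng.normal(scale=1.5, size=(5, 3))
    radii = np.array([1.2, 1.5, 1.7, 1.4, 1.6])
    mine = shrake_rupley(coords, radii, SASAOptions(n_sphere_points=10000))
    oracle = _mc_sasa(coords, radii, 1.4)
    assert np.abs(mine - oracle).max() <= 0.5


def test_sasa_input_validation():
    with pytest.raises(ValueError):
        shrake_rupley(np.zeros((0, 3)), np.array([]))
    with pytest.raises(ValueError):
        shrake_rupley(np.zeros((1, 3)), np.array([-1.0]))


# ---------------------------------------------------------------------------
# inter-partner nonbonded
# ---------------------------------------------------------------------------

def _point_pair_system(d, q=(1.0, -1.0), rmin_half=(0.0, 0.0), eps=(0.0, 0.0)):
    return make_toy_system(
        coords=[[0.0, 0, 0], [d, 0, 0]],
        charges=list(q),
        rmin_half=list(rmin_half),
        eps=list(eps),
        gb_radius=[1.5, 1.5],
        side_a=[True, False],
    )


def test_coulomb_pair_at_ten_angstrom():
    system = _point_pair_system(10.0)
    e_elec, e_vdw, _ = inter_nonbonded(system, 0)
    assert e_elec == pytest.approx(-COULOMB_CONSTANT / 10.0, rel=1e-12)
    assert e_elec == pytest.approx(-33.206, abs=5e-4)
    assert e_vdw == 0.0


def test_lj_minimum_identity():
    system = _point_pair_system(3.8, q=(0.0, 0.0), rmin_half=(1.9, 1.9), eps=(0.25, 0.25))
    _, e_vdw, _ = inter_nonbonded(system, 0)
    assert e_vdw == pytest.approx(-0.25, rel=1e-12)


def test_distant_partners_negligible():
    system = _point_pair_system(500.0, rmin_half=(1.9, 1.9), eps=(0.1, 0.1))
    e_elec, e_vdw, _ = inter_nonbonded(system, 0)
    assert abs(e_elec) < 1e-3 or abs(e_elec) == pytest.approx(COULOMB_CONSTANT / 500, rel=1e-6)
    assert abs(e_vdw) < 1e-3


def test_zero_distance_rejected():
    system = _point_pair_system(0.0)
    with pytest.raises(ValueError, match="zero interatomic"):
        inter_nonbonded(system, 0)


# ---------------------------------------------------------------------------
# effective binding energy and decomposition
# ---------------------------------------------------------------------------

def _brute_force_effective_energy(system, frame, gb_options, sasa_options):
    """Naive re-enumeration: python loops over pairs and explicit
    complex/monomer evaluations via the array primitives."""
    x = system.coords(frame)
    n = system.n_atoms
    a_idx = np.flatnonzero(system.side_a_mask)
    b_idx = np.flatnonzero(~system.side_a_mask)
    e_elec = e_vdw = 0.0
    for i in a_idx:
        for j in b_idx:
            r = float(np.linalg.norm(x[i] - x[j]))
            e_elec += COULOMB_CONSTANT * system.charges[i] * system.charges[j] / r
            rmin = system.rmin_half[i] + system.rmin_half[j]
            eps = float(np.sqrt(system.eps[i] * system.eps[j]))
            sr6 = (rmin / r) ** 6
            e_vdw += eps * (sr6**2 - 2 * sr6)

    def gb_total(idx):
        radii = hct_obc_radii(x[idx], system.gb_radius[idx], system.gb_screen[idx], gb_options)
        total = 0.0
        kappa = gb_options.kappa
        for p, i in enumerate(idx):
            for s, j in enumerate(idx):
                r2 = float(((x[i] - x[j]) ** 2).sum())
                f = np.sqrt(r2 + radii[p] * radii[s] * np.exp(-r2 / (4 * radii[p] * radii[s])))
                tau = 1.0 / gb_options.eps_in - np.exp(-kappa * f) / gb_options.eps_out
                total += -0.5 * COULOMB_CONSTANT * tau * system.charges[i] * system.charges[j] / f
        return total

    def sasa_total(idx):
        return shrake_rupley(x[idx], system.gb_radius[idx], sasa_options).sum()

    every = np.arange(n)
    g_gb = gb_total(every) - gb_total(a_idx) - gb_total(b_idx)
    g_sa = sasa_options.surface_tension * (
        sasa_total(every) - sasa_total(a_idx) - sasa_total(b_idx)
    )
    return e_elec + e_vdw + g_gb + g_sa


def _toy_dimer_system():
    rng = np.random.default_rng(12)
    coords = np.array(
        [
            [0.0, 0.0, 0.0], [1.6, 0.0, 0.3], [0.4, 1.5, -0.2], [2.2, 1.4, 0.5],
            [5.2, 0.3, 0.0], [6.5, 0.2, -0.4], [5.5, 1.7, 0.4], [7.0, 1.5, 0.1],
        ]
    ) + rng.normal(scale=0.05, size=(8, 3))
    charges = np.array([0.35, -0.45, 0.25, -0.15, -0.30, 0.40, -0.20, 0.10])
    return make_toy_system(
        coords=coords,
        charges=charges,
        rmin_half=np.full(8, 1.8),
        eps=np.full(8, 0.12),
        gb_radius=np.full(8, 1.6),
        side_a=[True, True, True, True, False, False, False, False],
    )


def test_effective_energy_matches_brute_force_oracle():
    system = _toy_dimer_system()
    gb, sa = GBOptions(), SASAOptions()
    mine = effective_binding_energy(system, 0, gb, sa).total
    oracle = _brute_force_effective_energy(system, 0, gb, sa)
    assert mine == pytest.approx(oracle, abs=1e-6)


def test_noninteracting_limit(c2_system):
    """Partners 500 A apart bind with essentially zero effective energy."""
    import copy

    far = copy.deepcopy(c2_system)
    shift = np.where(far.side_a_mask[:, None], 0.0, 500.0) * np.array([1.0, 0, 0])
    far.ensemble.frames[0] = far.ensemble.frames[0] + shift
    components = effective_binding_energy(far, 0)
    assert abs(components.total) < 0.01


def test_components_total_invariant():
    with pytest.raises(ValueError):
        EnergyComponents(e_elec=1.0, e_vdw=1.0, g_gb=1.0, g_sa=1.0, total=5.0)
    ok = EnergyComponents(e_elec=1.0, e_vdw=1.0, g_gb=1.0, g_sa=1.0)
    assert ok.total == pytest.approx(4.0)


def test_decomposition_conserves_and_matches_ledger(c2_system):
    table = decompose_per_residue(c2_system)
    for col, frame_total in enumerate(table.frame_totals):
        components = effective_binding_energy(c2_system, col)
        assert table.components["total"][:, col].sum() == pytest.approx(
            components.total, abs=1e-6
        )
        # gas columns re-sum the pair ledger exactly
        _, _, ledger = inter_nonbonded(c2_system, col)
        gas = table.components["e_elec"][:, col] + table.components["e_vdw"][:, col]
        assert gas.sum() == pytest.approx(ledger.elec.sum() + ledger.vdw.sum(), abs=1e-9)


def test_c2_symmetric_profiles_identical(c2_system):
    table = decompose_per_residue(c2_system, frames=[0])
    profile = table.components["total"][:, 0]
    n = len(profile) // 2
    assert np.abs(profile[:n] - profile[n:]).max() <= 1e-6


def test_rigid_transform_invariance():
    system = _toy_dimer_system()
    reference = effective_binding_energy(system, 0)
    R = rotation_about_axis((0.3, 0.5, 0.9), 73.0)
    moved = _toy_dimer_system()
    moved.ensemble.frames[0] = system.coords(0) @ R.T + np.array([11.0, -3.0, 7.0])
    transformed = effective_binding_energy(moved, 0)
    for attr in ("e_elec", "e_vdw", "g_gb", "g_sa", "total"):
        assert getattr(transformed, attr) == pytest.approx(
            getattr(reference, attr), abs=1e-6
        )


def test_empty_frame_range_rejected(c2_system):
    with pytest.raises(ValueError, match="empty frame range"):
        decompose_per_residue(c2_system, frames=[])
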