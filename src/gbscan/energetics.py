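"""Effective (binding) energy of a dimer and its per-residue decomposition.

The effective energy is the MM-GB/SA end-point estimate: inter-partner
Coulomb and Lennard-Jones terms (no cutoff), a generalized Born polar
solvation term (HCT pairwise descreening with the OBC-II tanh rescaling,
mbondi2 intrinsic radii, salt screening via a Debye factor) and a nonpolar
term proportional to the solvent-accessible surface area.  Complex and
monomer terms are evaluated on identical coordinates (single-trajectory
scheme), so intramolecular gas-phase contributions cancel exactly and are
never computed.  Configurational entropy is not estimated.

Units: kcal/mol, Angstrom, elementary charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import sphere_points
from .forcefield import ParameterizedSystem

__all__ = [
    "COULOMB_CONSTANT",
    "GBOptions",
    "SASAOptions",
    "EnergyComponents",
    "PairLedger",
    "ResidueEnergyTable",
    "pair_descreening_integral",
    "hct_obc_radii",
    "gb_energy",
    "shrake_rupley",
    "compute_born_radii",
    "gb_polar_energy",
    "sasa",
    "inter_nonbonded",
    "effective_binding_energy",
    "decompose_per_residue",
]

#: electrostatic conversion constant, kcal A mol^-1 e^-2
COULOMB_CONSTANT = 332.0637


@dataclass(frozen=True)
class GBOptions:
    """Generalized Born settings (OBC-II defaults).

    ``kappa_scale`` multiplies the Debye screening parameter; 1.0 applies
    the unscaled kappa = sqrt(0.10806 * I) A^-1 at 298.15 K.
    """

    eps_in: float = 1.0
    eps_out: float = 80.0
    ionic_strength: float = 0.100  # mol/L
    offset: float = 0.09  # A, intrinsic-radius offset
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.85
    kappa_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.eps_out > self.eps_in >= 1.0):
            raise ValueError("require eps_out > eps_in >= 1")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")

    @property
    def kappa(self) -> float:
        """Debye screening parameter in A^-1."""
        return self.kappa_scale * np.sqrt(0.10806 * self.ionic_strength)


@dataclass(frozen=True)
class SASAOptions:
    """Shrake-Rupley settings; the point set is deterministic (no RNG)."""

    probe_radius: float = 1.4  # A
    n_sphere_points: int = 960
    surface_tension: float = 0.0072  # kcal mol^-1 A^-2

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.n_sphere_points < 60:
            raise ValueError("need at least 60 sphere points")


@dataclass(frozen=True)
class EnergyComponents:
    """Additive components of one effective-energy evaluation (kcal/mol)."""

    e_elec: float
    e_vdw: float
    g_gb: float
    g_sa: float
    total: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        s = self.e_elec + self.e_vdw + self.g_gb + self.g_sa
        if self.total is None:
            object.__setattr__(self, "total", s)
        elif abs(self.total - s) > 1e-9 * max(1.0, abs(s)):
            raise ValueError(f"total {self.total} does not equal component sum {s}")


@dataclass
class PairLedger:
    """Cross-partner pair energies of one frame.

    ``elec`` and ``vdw`` are (len(idx_a), len(idx_b)) matrices; entry (p, q)
    is the full pair energy between atoms ``idx_a[p]`` and ``idx_b[q]``.
    """

    idx_a: np.ndarray
    idx_b: np.ndarray
    elec: np.ndarray
    vdw: np.ndarray

    def per_atom_shares(self, n_atoms: int) -> np.ndarray:
        """Half/half split of every pair energy onto its two atoms."""
        shares = np.zeros(n_atoms)
        total = self.elec + self.vdw
        shares[self.idx_a] += 0.5 * total.sum(axis=1)
        shares[self.idx_b] += 0.5 * total.sum(axis=0)
        return shares


# ---------------------------------------------------------------------------
# array-level primitives
# ---------------------------------------------------------------------------

def pair_descreening_integral(r: np.ndarray, s: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """HCT pairwise descreening integral H(r, s; rho).

    The contribution of a descreening sphere of radius ``s`` at distance
    ``r`` to the Born integral of an atom with reduced intrinsic radius
    ``rho``: (1/4pi) * integral of x^-4 over the sphere volume outside the
    ball of radius rho.  Broadcasts over array inputs.
    """
    r = np.asarray(r, float)
    s, rho = np.broadcast_arrays(np.asarray(s, float), np.asarray(rho, float))
    r, s, rho = np.broadcast_arrays(r, s, rho)
    out = np.zeros_like(r)
    U = r + s
    # engulfed by atom i: no contribution
    active = U > rho
    inside = s > r + rho  # atom i fully inside the descreening sphere
    L = np.where(rho >= np.abs(r - s), rho, np.abs(r - s))
    L = np.where(inside, s - r, L)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = (
            1.0 / L
            - 1.0 / U
            + 0.25 * r * (1.0 / U**2 - 1.0 / L**2)
            + 0.5 / r * np.log(L / U)
            + 0.25 * s**2 / r * (1.0 / L**2 - 1.0 / U**2)
        )
        term = 0.5 * term
        term = np.where(inside, term + (1.0 / rho - 1.0 / L), term)
    out[active] = term[active]
    return out


def hct_obc_radii(
    coords: np.ndarray,
    gb_radius: np.ndarray,
    screen: np.ndarray,
    options: GBOptions = GBOptions(),
) -> np.ndarray:
    """Effective Born radii via HCT descreening with OBC-II rescaling.

    With reduced radii ``rho_i = gb_radius_i - offset`` and the summed
    descreening integral ``I_i``, psi = rho_i * I_i and

        1/R_i = 1/rho_i - tanh(alpha*psi - beta*psi^2 + gamma*psi^3) / gb_radius_i
    """
    coords = np.asarray(coords, float)
    gb_radius = np.asarray(gb_radius, float)
    if np.any(gb_radius <= 0):
        raise ValueError("non-positive intrinsic radius")
    rho = gb_radius - options.offset
    if np.any(rho <= 0):
        raise ValueError("radius offset leaves a non-positive reduced radius")
    n = len(coords)
    if n == 1:
        integral = np.zeros(1)
    else:
        diff = coords[:, None, :] - coords[None, :, :]
        r = np.sqrt((diff**2).sum(-1))
        s = (screen * rho)[None, :]  # scaled radius of the descreener j
        h = pair_descreening_integral(r, s, rho[:, None])
        np.fill_diagonal(h, 0.0)
        integral = h.sum(axis=1)
    psi = rho * integral
    a, b, g = options.obc_alpha, options.obc_beta, options.obc_gamma
    inv_r = 1.0 / rho - np.tanh(a * psi - b * psi**2 + g * psi**3) / gb_radius
    return 1.0 / inv_r


def gb_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    born_radii: np.ndarray,
    options: GBOptions = GBOptions(),
) -> tuple[float, np.ndarray]:
    """Still-style GB polar solvation energy and its per-atom decomposition.

    f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))), with the diagonal
    f = R_i; the dielectric factor is (1/eps_in - exp(-kappa f)/eps_out).
    The per-atom shares assign each self term to its atom and split every
    pairwise term half/half; they sum exactly to the total.
    """
    coords = np.asarray(coords, float)
    charges = np.asarray(charges, float)
    R = np.asarray(born_radii, float)
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = (diff**2).sum(-1)
    RiRj = R[:, None] * R[None, :]
    f = np.sqrt(r2 + RiRj * np.exp(-r2 / (4.0 * RiRj)))
    tau = 1.0 / options.eps_in - np.exp(-options.kappa * f) / options.eps_out
    e = -0.5 * COULOMB_CONSTANT * tau * (charges[:, None] * charges[None, :]) / f
    per_atom = e.sum(axis=1)
    return float(e.sum()), per_atom


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    options: SASAOptions = SASAOptions(),
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2) by sphere sampling.

    Each atom's accessible sphere has radius ``radii + probe``; surface
    points (deterministic spiral set) are accessible when inside no other
    atom's accessible sphere.  The point set is oriented in a local frame
    built from the atom's two nearest overlapping neighbours, so areas are
    exactly invariant under rigid transforms of the whole system (for a
    single neighbour the burial is axially symmetric and the azimuthal
    freedom is immaterial).
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if coords.ndim != 2 or len(coords) < 1:
        raise ValueError("need at least one atom")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    R = radii + options.probe_radius
    pts = sphere_points(options.n_sphere_points)
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = (diff**2).sum(-1)
    cut2 = (R[:, None] + R[None, :]) ** 2
    areas = np.empty(n)
    for i in range(n):
        nb = np.flatnonzero((d2[i] < cut2[i]) & (np.arange(n) != i))
        if len(nb) == 0:
            areas[i] = 4.0 * np.pi * R[i] ** 2
            continue
        order = nb[np.argsort(d2[i, nb], kind="stable")]
        e1 = coords[order[0]] - coords[i]
        e1 = e1 / np.linalg.norm(e1)
        e3 = None
        for j in order[1:]:
            v = coords[j] - coords[i]
            c = np.cross(e1, v)
            norm = np.linalg.norm(c)
            if norm > 1e-8 * np.linalg.norm(v):
                e3 = c / norm
                break
        if e3 is None:  # axially symmetric burial: azimuth is irrelevant
            helper = np.zeros(3)
            helper[int(np.argmin(np.abs(e1)))] = 1.0
            e3 = np.cross(e1, helper)
            e3 /= np.linalg.norm(e3)
        e2 = np.cross(e3, e1)
        frame = np.stack([e1, e2, e3], axis=1)
        surface = coords[i] + R[i] * (pts @ frame.T)
        d2_nb = ((surface[:, None, :] - coords[order][None, :, :]) ** 2).sum(-1)
        buried = (d2_nb < (R[order] ** 2)[None, :]).any(axis=1)
        areas[i] = 4.0 * np.pi * R[i] ** 2 * (1.0 - buried.mean())
    return areas


# ---------------------------------------------------------------------------
# system-level operations
# ---------------------------------------------------------------------------

def _subset(system: ParameterizedSystem, subset: np.ndarray | None) -> np.ndarray:
    if subset is None:
        return np.arange(system.n_atoms)
    return np.asarray(subset, dtype=int)


def compute_born_radii(
    system: ParameterizedSystem,
    frame_index: int,
    options: GBOptions = GBOptions(),
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Effective Born radii of (a subset of) the system on one frame."""
    idx = _subset(system, subset)
    return hct_obc_radii(
        system.coords(frame_index)[idx],
        system.gb_radius[idx],
        system.gb_screen[idx],
        options,
    )


def gb_polar_energy(
    system: ParameterizedSystem,
    frame_index: int,
    options: GBOptions = GBOptions(),
    subset: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """GB polar solvation energy of (a subset of) the system on one frame."""
    idx = _subset(system, subset)
    radii = compute_born_radii(system, frame_index, options, idx)
    return gb_energy(system.coords(frame_index)[idx], system.charges[idx], radii, options)


def sasa(
    system: ParameterizedSystem,
    frame_index: int,
    options: SASAOptions = SASAOptions(),
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom SASA of (a subset of) the system on one frame.

    Atom radii are the intrinsic GB radii; hydrogens are included.
    """
    idx = _subset(system, subset)
    return shrake_rupley(system.coords(frame_index)[idx], system.gb_radius[idx], options)


def inter_nonbonded(
    system: ParameterizedSystem,
    frame_index: int,
) -> tuple[float, float, PairLedger]:
    """Cross-partner Coulomb and Lennard-Jones energies, no cutoff.

    Lorentz-Berthelot combination: rmin = rmin_half_i + rmin_half_j,
    eps = sqrt(eps_i * eps_j).  Only inter-molecular pairs are evaluated,
    so no 1-4 scaling applies.
    """
    idx_a = np.flatnonzero(system.side_a_mask)
    idx_b = np.flatnonzero(~system.side_a_mask)
    x = system.coords(frame_index)
    diff = x[idx_a][:, None, :] - x[idx_b][None, :, :]
    r = np.sqrt((diff**2).sum(-1))
    if np.any(r < 1e-6):
        raise ValueError("zero interatomic distance between partners")
    qq = system.charges[idx_a][:, None] * system.charges[idx_b][None, :]
    elec = COULOMB_CONSTANT * qq / r
    rmin = system.rmin_half[idx_a][:, None] + system.rmin_half[idx_b][None, :]
    eps = np.sqrt(system.eps[idx_a][:, None] * system.eps[idx_b][None, :])
    sr6 = (rmin / r) ** 6
    vdw = eps * (sr6**2 - 2.0 * sr6)
    ledger = PairLedger(idx_a=idx_a, idx_b=idx_b, elec=elec, vdw=vdw)
    return float(elec.sum()), float(vdw.sum()), ledger


def effective_binding_energy(
    system: ParameterizedSystem,
    frame_index: int,
    gb_options: GBOptions = GBOptions(),
    sasa_options: SASAOptions = SASAOptions(),
) -> EnergyComponents:
    """Single-trajectory effective binding energy of one frame.

    dG_eff = E_elec(inter) + E_vdw(inter)
             + [G_GB(complex) - G_GB(A) - G_GB(B)]
             + gamma * [SASA(complex) - SASA(A) - SASA(B)],
    with monomer terms evaluated on the same frame coordinates.
    """
    e_elec, e_vdw, _ = inter_nonbonded(system, frame_index)
    idx_a = np.flatnonzero(system.side_a_mask)
    idx_b = np.flatnonzero(~system.side_a_mask)
    g_cx, _ = gb_polar_energy(system, frame_index, gb_options)
    g_a, _ = gb_polar_energy(system, frame_index, gb_options, idx_a)
    g_b, _ = gb_polar_energy(system, frame_index, gb_options, idx_b)
    sa_cx = sasa(system, frame_index, sasa_options).sum()
    sa_a = sasa(system, frame_index, sasa_options, idx_a).sum()
    sa_b = sasa(system, frame_index, sasa_options, idx_b).sum()
    gamma = sasa_options.surface_tension
    return EnergyComponents(
        e_elec=e_elec,
        e_vdw=e_vdw,
        g_gb=g_cx - g_a - g_b,
        g_sa=gamma * (sa_cx - sa_a - sa_b),
    )


@dataclass
class ResidueEnergyTable:
    """Per-residue effective-energy contributions over an ensemble.

    ``components[name]`` has shape (n_residues, n_frames); rows follow
    ``keys`` = (chain, residue number, residue name).  Per-frame column sums
    reproduce the corresponding frame totals exactly (conservation of the
    decomposition).
    """

    keys: list[tuple[str, int, str]]
    components: dict[str, np.ndarray]
    frame_totals: np.ndarray  # dG_eff per frame

    COLUMNS = ("e_elec", "e_vdw", "g_gb", "g_sa", "total")

    @property
    def n_frames(self) -> int:
        return self.components["total"].shape[1]

    def mean(self, component: str = "total") -> np.ndarray:
        return self.components[component].mean(axis=1)

    def sem(self, component: str = "total") -> np.ndarray:
        """Standard error of the mean over frames; NaN for a single frame."""
        x = self.components[component]
        if x.shape[1] < 2:
            return np.full(x.shape[0], np.nan)
        return x.std(axis=1, ddof=1) / np.sqrt(x.shape[1])

    def to_dataframe(self) -> pd.DataFrame:
        rows = {
            "chain": [k[0] for k in self.keys],
            "resnum": [k[1] for k in self.keys],
            "resname": [k[2] for k in self.keys],
        }
        for c in ("e_elec", "e_vdw", "g_gb", "g_sa", "total"):
            rows[c] = self.components[c].mean(axis=1)
        rows["sem"] = self.sem("total")
        rows["n_frames"] = self.n_frames
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")


def decompose_per_residue(
    system: ParameterizedSystem,
    frames: range | list[int] | None = None,
    gb_options: GBOptions = GBOptions(),
    sasa_options: SASAOptions = SASAOptions(),
) -> ResidueEnergyTable:
    """Per-residue decomposition of the effective binding energy.

    For residue r:  dG_r = 1/2 * (cross-partner elec+vdW pairs touching r)
    + [G_GB,r(complex) - G_GB,r(monomer)] + gamma * [SASA_r(complex) -
    SASA_r(monomer)], with GB per-atom shares = self term + half of every
    pairwise term (all pairs, because Born radii change upon binding).
    The residue sums reproduce dG_eff on every frame.
    """
    frame_list = list(frames) if frames is not None else list(range(system.n_frames))
    if not frame_list:
        raise ValueError("empty frame range")
    n_res = len(system.residue_keys)
    n_atoms = system.n_atoms
    idx_a = np.flatnonzero(system.side_a_mask)
    idx_b = np.flatnonzero(~system.side_a_mask)
    gamma = sasa_options.surface_tension
    comps = {c: np.zeros((n_res, len(frame_list))) for c in ResidueEnergyTable.COLUMNS}
    totals = np.zeros(len(frame_list))

    for col, k in enumerate(frame_list):
        e_elec, e_vdw, ledger = inter_nonbonded(system, k)
        elec_atom = np.zeros(n_atoms)
        vdw_atom = np.zeros(n_atoms)
        elec_atom[ledger.idx_a] += 0.5 * ledger.elec.sum(axis=1)
        elec_atom[ledger.idx_b] += 0.5 * ledger.elec.sum(axis=0)
        vdw_atom[ledger.idx_a] += 0.5 * ledger.vdw.sum(axis=1)
        vdw_atom[ledger.idx_b] += 0.5 * ledger.vdw.sum(axis=0)

        _, gb_cx_atom = gb_polar_energy(system, k, gb_options)
        gb_atom = gb_cx_atom.copy()
        for idx in (idx_a, idx_b):
            _, gb_mono = gb_polar_energy(system, k, gb_options, idx)
            gb_atom[idx] -= gb_mono

        sa_cx = sasa(system, k, sasa_options)
        sa_atom = sa_cx.copy()
        for idx in (idx_a, idx_b):
            sa_atom[idx] -= sasa(system, k, sasa_options, idx)
        sa_atom *= gamma

        for name, vec in (
            ("e_elec", elec_atom),
            ("e_vdw", vdw_atom),
            ("g_gb", gb_atom),
            ("g_sa", sa_atom),
        ):
            comps[name][:, col] = np.bincount(system.atom_residue, weights=vec, minlength=n_res)
        comps["total"][:, col] = (
            comps["e_elec"][:, col]
            + comps["e_vdw"][:, col]
            + comps["g_gb"][:, col]
            + comps["g_sa"][:, col]
        )
        totals[col] = comps["total"][:, col].sum()

    return ResidueEnergyTable(keys=list(system.residue_keys), components=comps, frame_totals=totals)
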