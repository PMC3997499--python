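"""Synthetic inputs at desk scale: ideal helical dimers, pseudo-ensembles,
melting curves and SEC standards.

The pseudo-ensembles are i.i.d. Gaussian coordinate jitter around one
conformation -- they emulate the *bookkeeping* of an MD snapshot set (frame
averaging, SEMs, conservation checks), not its physics.  The helical dimers
provide controllable interfaces, including an exactly C2-symmetric mode for
symmetry tests and a "sticky pair" preset with one salt-bridged contact
residue per chain that should dominate the interface energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure.info as struc_info

from .forcefield import build_hydrogens, ParameterSet, _ccd_geometry
from .geometry import kabsch, place_internal, rotation_about_axis
from .structure import Atom, DimerPartition, Ensemble, Residue, Structure, StructureError

__all__ = [
    "GeneratorConfig",
    "AA3",
    "build_ideal_helix",
    "build_helix_dimer",
    "sticky_helix_dimer",
    "jitter_ensemble",
    "synth_melting_curve",
    "synth_sec_standards",
    "SEC_STANDARD_MW",
]

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

#: molecular weights (Da) of the printed SEC calibration standards
SEC_STANDARD_MW = (14000.0, 29000.0, 66000.0, 150000.0, 200000.0, 443000.0)

# ideal backbone geometry (A, degrees)
_B = dict(n_ca=1.458, ca_c=1.525, c_n=1.329, c_o=1.231)
_A = dict(n_ca_c=111.0, ca_c_n=116.6, c_n_ca=121.7, ca_c_o=120.5)


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded defaults for the synthetic generators."""

    seed: int = 0
    helix_phi: float = -57.0  # deg
    helix_psi: float = -47.0  # deg
    separation: float = 9.5  # A between helix axes
    jitter_sigma: float = 0.15  # A per coordinate
    n_frames: int = 10
    melt_noise: float = 0.02  # fraction of amplitude
    sec_noise: float = 0.05  # mL


def _validate_sequence(sequence: str) -> list[str]:
    seq = sequence.strip().upper()
    bad = sorted(set(seq) - set(AA3))
    if bad:
        raise ValueError(f"invalid residue letters: {bad}")
    if len(seq) < 4:
        raise ValueError("need at least 4 residues for a helix")
    return [AA3[c] for c in seq]


def build_ideal_helix(
    sequence: str,
    start: np.ndarray | tuple = (0.0, 0.0, 0.0),
    axis: np.ndarray | tuple = (0.0, 0.0, 1.0),
    chain_id: str = "A",
    phi: float = -57.0,
    psi: float = -47.0,
    add_hydrogens: bool = True,
) -> Structure:
    """Build an ideal alpha helix with template-rotamer side chains.

    The backbone is chained at the given phi/psi (omega 180); side chains
    (and their hydrogens) are grafted from the ideal residue geometry by
    superposition on the local N/CA/C frame, i.e. one fixed rotamer per
    residue type.  The helix axis is aligned with ``axis`` and the first
    CA sits at ``start``.
    """
    resnames = _validate_sequence(sequence)
    n = len(resnames)
    # backbone trace via internal coordinates
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B["n_ca"], 0.0, 0.0)
    C[0] = place_internal(CA[0], N[0], N[0] + (0, 0, 1.0), _B["ca_c"], _A["n_ca_c"], 57.0)
    for i in range(1, n):
        N[i] = place_internal(C[i - 1], CA[i - 1], N[i - 1], _B["c_n"], _A["ca_c_n"], psi)
        CA[i] = place_internal(N[i], C[i - 1], CA[i - 1], _B["n_ca"], _A["c_n_ca"], 180.0)
        C[i] = place_internal(CA[i], N[i], C[i - 1], _B["ca_c"], _A["n_ca_c"], phi)
    O = np.zeros((n, 3))
    for i in range(n - 1):
        O[i] = place_internal(C[i], CA[i], N[i + 1], _B["c_o"], _A["ca_c_o"], 180.0)
    # last carbonyl keeps the helical psi; OXT completes the carboxylate
    O[n - 1] = place_internal(C[n - 1], CA[n - 1], N[n - 1], 1.25, 117.0, psi - 180.0)
    OXT = place_internal(C[n - 1], CA[n - 1], N[n - 1], 1.25, 117.0, psi)

    residues = []
    for i, resname in enumerate(resnames):
        res = Residue(name=resname, number=i + 1)
        res.atoms = [
            Atom(0, "N", "N", N[i]),
            Atom(0, "CA", "C", CA[i]),
            Atom(0, "C", "C", C[i]),
            Atom(0, "O", "O", O[i]),
        ]
        coords_t, _adj = _ccd_geometry(resname)
        # graft only atoms the polymer charge template knows (side chain + HA)
        allowed = set(ParameterSet.default().templates[resname].atom_order)
        anchors = ["N", "CA", "C"]
        R, t = kabsch(np.stack([coords_t[a] for a in anchors]), np.stack([N[i], CA[i], C[i]]))
        for name, xyz in coords_t.items():
            if name in ("N", "CA", "C", "O", "H") or name not in allowed:
                continue
            el = "H" if name.startswith("H") else name[0]
            res.atoms.append(Atom(0, name, el, R @ xyz + t))
        if i == n - 1:
            res.atoms.insert(4, Atom(0, "OXT", "O", OXT))
        residues.append(res)
    structure = Structure(chains=[(chain_id, residues)])

    # align helix axis (first->last CA direction) with the requested axis
    ca = structure.coords()
    v = CA[-1] - CA[0]
    v /= np.linalg.norm(v)
    target = np.asarray(axis, float)
    target /= np.linalg.norm(target)
    cross = np.cross(v, target)
    dot = float(np.clip(v @ target, -1.0, 1.0))
    if np.linalg.norm(cross) > 1e-12:
        R = rotation_about_axis(cross, np.degrees(np.arccos(dot)))
    else:
        R = np.eye(3) if dot > 0 else rotation_about_axis((1.0, 0.0, 0.0), 180.0)
    xyz = structure.coords() @ R.T
    xyz += np.asarray(start, float) - (R @ CA[0])
    structure.set_coords(xyz)
    if add_hydrogens:
        structure = build_hydrogens(structure)
    return structure


def _rotate_about_own_axis(structure: Structure, axis_point, axis_dir, angle: float) -> Structure:
    out = structure.copy()
    R = rotation_about_axis(axis_dir, angle)
    p = np.asarray(axis_point, float)
    out.set_coords((out.coords() - p) @ R.T + p)
    return out


def _min_heavy_distance(sa: Structure, sb: Structure) -> float:
    xa = np.stack([a.coords for _, _, a in sa.iter_atoms() if not a.is_hydrogen])
    xb = np.stack([a.coords for _, _, a in sb.iter_atoms() if not a.is_hydrogen])
    d = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(-1))
    return float(d.min())


def build_helix_dimer(
    seq_a: str,
    seq_b: str | None = None,
    separation: float = 9.5,
    antiparallel: bool = True,
    c2_symmetric: bool = True,
    rotation_a: float = 0.0,
    rotation_b: float = 0.0,
    relieve_clashes: bool = True,
) -> tuple[Structure, DimerPartition]:
    """Two helices with parallel axes at the given separation.

    With ``c2_symmetric`` (requires ``seq_b`` None or equal to ``seq_a``),
    chain B is the exact image of chain A under a 180-degree rotation about
    the symmetry axis, which also makes the pair antiparallel; downstream
    per-chain quantities are then equal by construction.  Otherwise chain B
    is built independently and translated.  If the closest inter-chain
    heavy-atom contact is tighter than 2.5 A, both helices are rotated
    about their own axes on a coarse 10-degree grid to relieve the clash;
    below 2.0 A after relief the build fails (steric collapse).
    """
    if c2_symmetric and seq_b is not None and seq_b != seq_a:
        raise ValueError("c2_symmetric requires identical sequences")
    seq_b = seq_b if seq_b is not None else seq_a

    def make_a(rot: float) -> Structure:
        h = build_ideal_helix(seq_a, start=(-separation / 2.0, 0.0, 0.0), axis=(0, 0, 1), chain_id="A")
        return _rotate_about_own_axis(h, (-separation / 2.0, 0.0, 0.0), (0, 0, 1), rot)

    def make_b(rot: float) -> Structure:
        h = build_ideal_helix(
            seq_b,
            start=(separation / 2.0, 0.0, 0.0),
            axis=(0, 0, -1 if antiparallel else 1),
            chain_id="B",
        )
        return _rotate_about_own_axis(h, (separation / 2.0, 0.0, 0.0), (0, 0, 1), rot)

    def ca_z(structure: Structure) -> np.ndarray:
        return np.array([r.atom("CA").coords[2] for r in structure.chains[0][1]])

    def assemble(rot_a: float, rot_b: float) -> tuple[Structure, Structure]:
        a = make_a(rot_a)
        if c2_symmetric:
            b = a.copy()
            # exact two-fold: 180 deg about a y-parallel axis through the
            # mid-plane of helix A maps its axis line onto the B position
            # with reversed direction, so the two spans coincide
            zc = float(ca_z(a).mean())
            p = np.array([0.0, 0.0, zc])
            b.set_coords((b.coords() - p) @ rotation_about_axis((0, 1, 0), 180.0).T + p)
            b.chains = [("B", b.chains[0][1])]
        else:
            b = make_b(rot_b)
            shift = float(ca_z(a).mean() - ca_z(b).mean())
            b.set_coords(b.coords() + np.array([0.0, 0.0, shift]))
        return a, b

    a, b = assemble(rotation_a, rotation_b)
    dmin = _min_heavy_distance(a, b)
    if relieve_clashes and dmin < 2.5:
        best = (dmin, rotation_a, rotation_b)
        grid = np.arange(0.0, 360.0, 10.0)
        for ra in grid:
            for rb in [0.0] if c2_symmetric else grid:
                aa, bb = assemble(ra, rb)
                d = _min_heavy_distance(aa, bb)
                if d > best[0]:
                    best = (d, ra, rb)
                if d >= 2.5:
                    break
            if best[0] >= 2.5:
                break
        dmin, rot_a, rot_b = best
        a, b = assemble(rot_a, rot_b)
    if dmin < 2.0:
        raise StructureError(f"steric collapse: closest inter-chain contact {dmin:.2f} A")
    structure = Structure(chains=[("A", a.chains[0][1]), ("B", b.chains[0][1])])
    return structure, DimerPartition(frozenset("A"), frozenset("B"))


def sticky_helix_dimer(
    n_res: int = 11,
    separation: float = 12.0,
    sticky: tuple[str, str] = ("W", "W"),
) -> tuple[Structure, DimerPartition, tuple[str, int]]:
    """Poly-alanine dimer with one engineered hydrophobic anchor contact.

    Chain A carries one bulky hydrophobic residue (default Trp) at its
    midpoint and chain B a matching partner; both helices are spun about
    their own axes on a deterministic 10-degree grid to the orientation
    with the lowest inter-chain gas-phase (Coulomb + Lennard-Jones)
    energy, which packs the two side chains against each other.  The
    anchor then dominates the interface the way the hot spots of a real
    dimerization interface do (large buried hydrophobic contact); an
    isolated solvent-exposed charge pair is not a usable anchor here
    because generalized Born desolvation cancels its Coulomb attraction
    almost exactly.  Returns the structure, the partition and the
    (chain, resnum) of the anchor residue on chain A -- the residue the
    hot-spot analysis should recover as rank 1.
    """
    from .forcefield import assign_parameters  # local import, keeps module load light
    from .energetics import COULOMB_CONSTANT

    mid = n_res // 2 + 1
    seq_a = "A" * (mid - 1) + sticky[0] + "A" * (n_res - mid)
    seq_b = "A" * (mid - 1) + sticky[1] + "A" * (n_res - mid)
    structure, partition = build_helix_dimer(
        seq_a, seq_b, separation=separation, antiparallel=True,
        c2_symmetric=False, relieve_clashes=False,
    )
    system = assign_parameters(Ensemble.from_structure(structure), partition=partition)
    x = structure.coords()
    ia = np.flatnonzero(system.side_a_mask)
    ib = np.flatnonzero(~system.side_a_mask)
    pa = np.array([-separation / 2.0, 0.0, 0.0])
    pb = np.array([separation / 2.0, 0.0, 0.0])
    qq = system.charges[ia][:, None] * system.charges[ib][None, :]
    rmin = system.rmin_half[ia][:, None] + system.rmin_half[ib][None, :]
    eps = np.sqrt(system.eps[ia][:, None] * system.eps[ib][None, :])
    best = None
    grid = np.arange(0.0, 360.0, 10.0)
    for ra in grid:
        ya = (x[ia] - pa) @ rotation_about_axis((0, 0, 1), ra).T + pa
        for rb in grid:
            yb = (x[ib] - pb) @ rotation_about_axis((0, 0, 1), rb).T + pb
            d = np.sqrt(((ya[:, None] - yb[None]) ** 2).sum(-1))
            sr6 = (rmin / d) ** 6
            e = (COULOMB_CONSTANT * qq / d).sum() + (eps * (sr6**2 - 2.0 * sr6)).sum()
            if best is None or e < best[0]:
                best = (e, ra, rb)
    _, ra, rb = best
    out = structure.copy()
    coords = out.coords()
    coords[ia] = (coords[ia] - pa) @ rotation_about_axis((0, 0, 1), ra).T + pa
    coords[ib] = (coords[ib] - pb) @ rotation_about_axis((0, 0, 1), rb).T + pb
    out.set_coords(coords)
    if _min_heavy_distance(*(Structure(chains=[c]) for c in out.chains)) < 2.0:
        raise StructureError("steric collapse in sticky dimer")
    return out, partition, ("A", mid)


def jitter_ensemble(
    structure: Structure, sigma: float, n_frames: int, seed: int = 0
) -> Ensemble:
    """Pseudo-ensemble: i.i.d. Gaussian displacement per atom and frame.

    Frame 0 is the unperturbed input.  Not dynamics -- a bookkeeping stand-in
    for an MD snapshot set.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    base = structure.coords()
    frames = [base.copy()]
    for _ in range(n_frames - 1):
        frames.append(base + rng.normal(0.0, sigma, size=base.shape))
    return Ensemble(topology=structure.copy(), frames=frames)


def synth_melting_curve(
    tm: float,
    slope: float = 2.0,
    f_min: float = 0.0,
    f_max: float = 1.0,
    noise_sigma: float = 0.0,
    t_range: tuple[float, float] = (25.0, 95.0),
    step: float = 0.5,
    seed: int = 0,
    aggregation_decay: float = 0.0,
):
    """Boltzmann unfolding sigmoid with additive Gaussian noise.

    F(T) = f_min + (f_max - f_min) / (1 + exp((tm - T)/slope)); an optional
    linear post-transition decay (fluorophore loss on aggregation) starts
    two transition widths above the midpoint.  Returns a
    :class:`gbscan.assays.MeltingCurve`.
    """
    from .assays import MeltingCurve

    if step <= 0:
        raise ValueError("step must be positive")
    if slope <= 0:
        raise ValueError("slope must be positive")
    if not (t_range[0] < tm < t_range[1]):
        raise ValueError(f"tm {tm} outside temperature range {t_range}")
    T = np.arange(t_range[0], t_range[1] + 0.5 * step, step)
    F = f_min + (f_max - f_min) / (1.0 + np.exp((tm - T) / slope))
    if aggregation_decay > 0.0:
        onset = tm + 2.0 * slope
        post = T > onset
        F[post] -= aggregation_decay * (f_max - f_min) * (T[post] - onset)
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, noise_sigma * (f_max - f_min), size=F.shape)
    return MeltingCurve(temperatures=T, fluorescence=F)


def synth_sec_standards(
    slope: float = -0.18,
    intercept: float = 7.2,
    noise_sigma: float = 0.0,
    mw_list: tuple[float, ...] = SEC_STANDARD_MW,
    seed: int = 0,
) -> pd.DataFrame:
    """Elution volumes for a log-linear SEC column: log10(MW) = a*Ve + b.

    The default molecular weights are the six printed calibration
    standards (lysozyme through apoferritin).
    """
    if slope >= 0:
        raise ValueError("SEC calibration slope must be negative (larger elutes earlier)")
    mw = np.asarray(mw_list, float)
    ve = (np.log10(mw) - intercept) / slope
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        ve = ve + rng.normal(0.0, noise_sigma, size=ve.shape)
    return pd.DataFrame({"mw": mw, "ve": ve})
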