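"""Per-atom force-field assignment, hydrogen building and alanine truncation.

The parameter tables (packaged as ``data/ff_params.tsv``) carry, for every
atom of the 20 standard residues, the fixed partial charge of the published
Amber protein charge set, Lennard-Jones ``rmin/2`` and ``eps`` by Amber vdW
type, the intrinsic Born radius (mbondi2 convention) and the pairwise
descreening scale factor.  Histidine is modelled as the neutral N-epsilon
tautomer, Asp/Glu deprotonated, Lys/Arg protonated and Cys reduced --
defaults for pH 7.5.

Terminal residues are detected from chain ends.  The N-terminus is modelled
protonated (H1/H2/H3); the C-terminus as carboxylate when an OXT atom is
present, otherwise the interior (neutral) charge set is kept.  Terminal
charges follow an exact-integer adjustment rule described in the methods
notes rather than a separately fitted terminal charge set.

Ideal hydrogen geometry comes from the chemical component dictionary bundled
with biotite; backbone amide hydrogens are constructed in the peptide plane
from the preceding carbonyl.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info

from .geometry import kabsch, place_internal
from .structure import (
    Atom,
    DimerPartition,
    Ensemble,
    Residue,
    Structure,
    StructureError,
)

__all__ = [
    "AtomParams",
    "ResidueTemplate",
    "ParameterSet",
    "ParameterizedSystem",
    "ParameterizationError",
    "assign_parameters",
    "build_hydrogens",
    "add_hydrogens",
    "mutate_to_alanine",
]

# charge placed on each added N-terminal proton (remainder absorbed by N)
_NTERM_H_CHARGE = 0.26
_NTERM_H_CHARGE_PRO = 0.30
# carboxylate oxygens of the C-terminus
_CTERM_O_CHARGE = -0.80

_H_LJ = (0.6000, 0.0157)  # amber type H (on nitrogen)
_O2_LJ = (1.6612, 0.2100)


class ParameterizationError(ValueError):
    """Unknown residue, missing atom, or inconsistent template."""


@dataclass(frozen=True)
class AtomParams:
    """Nonbonded parameters of a single atom."""

    charge: float  # elementary charges
    lj_rmin_half: float  # A
    lj_eps: float  # kcal/mol
    gb_radius: float  # intrinsic Born radius, A
    gb_screen: float  # HCT descreening scale
    element: str = "C"

    def __post_init__(self) -> None:
        if self.lj_eps < 0:
            raise ParameterizationError("lj_eps must be >= 0")
        if self.gb_radius <= 0:
            raise ParameterizationError("gb_radius must be > 0")


@dataclass
class ResidueTemplate:
    """Atom names, order and parameters of one residue variant."""

    name: str
    formal_charge: int
    atom_order: list[str]
    params: dict[str, AtomParams]

    @property
    def hydrogens(self) -> list[str]:
        return [a for a in self.atom_order if self.params[a].element == "H"]

    @property
    def heavy(self) -> list[str]:
        return [a for a in self.atom_order if self.params[a].element != "H"]

    def total_charge(self) -> float:
        return sum(p.charge for p in self.params.values())


class ParameterSet:
    """Residue templates plus derived terminal variants.

    Interior templates are read from the packaged TSV; each template's
    charges sum to the residue's formal integer charge (validated on load,
    tolerance 1e-3 e).
    """

    def __init__(self, templates: dict[str, ResidueTemplate]):
        self.templates = templates
        for tpl in templates.values():
            if abs(tpl.total_charge() - tpl.formal_charge) > 1e-3:
                raise ParameterizationError(
                    f"template {tpl.name}: charges sum to {tpl.total_charge():.4f}, "
                    f"expected {tpl.formal_charge}"
                )

    @classmethod
    @functools.lru_cache(maxsize=1)
    def default(cls) -> "ParameterSet":
        text = (resources.files("gbscan.data") / "ff_params.tsv").read_text()
        templates: dict[str, ResidueTemplate] = {}
        for line in text.splitlines():
            if not line or line.startswith("#") or line.startswith("residue\t"):
                continue
            res, atom, el, _typ, q, rmin, eps, gb, screen, formal = line.split("\t")
            tpl = templates.get(res)
            if tpl is None:
                tpl = ResidueTemplate(res, int(formal), [], {})
                templates[res] = tpl
            tpl.atom_order.append(atom)
            tpl.params[atom] = AtomParams(
                float(q), float(rmin), float(eps), float(gb), float(screen), el
            )
        return cls(templates)

    def knows(self, resname: str) -> bool:
        return resname in self.templates

    @functools.lru_cache(maxsize=256)
    def variant(self, resname: str, n_terminal: bool = False, c_terminal: bool = False) -> ResidueTemplate:
        """Template for a residue, with terminal modifications applied."""
        if resname not in self.templates:
            raise ParameterizationError(f"no template for {resname!r}")
        base = self.templates[resname]
        if not n_terminal and not c_terminal:
            return base
        order = list(base.atom_order)
        params = dict(base.params)
        if n_terminal:
            h_q = _NTERM_H_CHARGE_PRO if resname == "PRO" else _NTERM_H_CHARGE
            new_h = ["H2", "H3"] if resname == "PRO" else ["H1", "H2", "H3"]
            removed = 0.0
            if "H" in params:
                removed = params["H"].charge
                order.remove("H")
                del params["H"]
            for i, name in enumerate(new_h):
                order.insert(1 + i, name)
                params[name] = AtomParams(h_q, *_H_LJ, 1.30, 0.85, "H")
            n_par = params["N"]
            n_charge = n_par.charge + 1.0 - len(new_h) * h_q + removed
            params["N"] = AtomParams(
                n_charge, n_par.lj_rmin_half, n_par.lj_eps, n_par.gb_radius, n_par.gb_screen, "N"
            )
        if c_terminal:
            o_par = params["O"]
            c_par = params["C"]
            params["O"] = AtomParams(_CTERM_O_CHARGE, *_O2_LJ, o_par.gb_radius, o_par.gb_screen, "O")
            params["OXT"] = AtomParams(_CTERM_O_CHARGE, *_O2_LJ, o_par.gb_radius, o_par.gb_screen, "O")
            order.insert(order.index("O") + 1, "OXT")
            c_charge = c_par.charge - 1.0 - 2.0 * _CTERM_O_CHARGE + o_par.charge
            params["C"] = AtomParams(
                c_charge, c_par.lj_rmin_half, c_par.lj_eps, c_par.gb_radius, c_par.gb_screen, "C"
            )
        formal = base.formal_charge + (1 if n_terminal else 0) - (1 if c_terminal else 0)
        return ResidueTemplate(base.name, formal, order, params)


# ---------------------------------------------------------------------------
# ideal residue geometry (chemical component dictionary via biotite)
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=64)
def _ccd_geometry(resname: str) -> tuple[dict[str, np.ndarray], dict[str, list[str]]]:
    """Ideal coordinates and bond graph of the polymer form of a residue.

    Free-amino-acid extras (OXT/HXT, the second amine proton) are removed;
    for His the N-delta proton is removed to leave the N-epsilon tautomer.
    """
    comp = struc_info.residue(resname)
    if comp is None:
        raise ParameterizationError(f"no ideal geometry for {resname!r}")
    drop = {"OXT", "HXT", "H2"}
    if resname == "HIS":
        drop.add("HD1")
    if resname == "PRO":
        drop.add("H")
    keep = ~np.isin(comp.atom_name, list(drop))
    comp = comp[keep]
    coords = {str(n): np.array(c, float) for n, c in zip(comp.atom_name, comp.coord)}
    adjacency: dict[str, list[str]] = {str(n): [] for n in comp.atom_name}
    bonds, _ = comp.bonds.get_all_bonds()
    names = [str(n) for n in comp.atom_name]
    for i, partners in enumerate(bonds):
        for j in partners:
            if j >= 0:
                adjacency[names[i]].append(names[j])
    return coords, adjacency


def _heavy_anchors(parent: str, adjacency: dict[str, list[str]], elements) -> list[str]:
    """Parent plus nearby heavy atoms, enough to fix a local frame (>=3)."""
    heavy = lambda n: not n.startswith("H")
    anchors = [parent]
    shell = [n for n in adjacency[parent] if heavy(n)]
    anchors += shell
    if len(anchors) < 3:
        for s in shell:
            for n in adjacency[s]:
                if heavy(n) and n not in anchors:
                    anchors.append(n)
    if len(anchors) < 3:
        raise ParameterizationError(f"cannot build local frame around {parent}")
    return anchors


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_hydrogens(structure: Structure, pset: ParameterSet | None = None) -> Structure:
    """Add missing hydrogens at ideal template geometry.

    Existing hydrogens are preserved; added ones carry ``built=True``.
    Backbone amide hydrogens are placed in the peptide plane anti to the
    preceding carbonyl oxygen; N-terminal protons are staggered about the
    N-CA bond; all other hydrogens are grafted from the ideal residue
    geometry by local-frame superposition.
    """
    pset = pset or ParameterSet.default()
    out = structure.copy()
    for cid, residues in out.chains:
        for ri, res in enumerate(residues):
            if not pset.knows(res.name):
                raise ParameterizationError(f"no template for {res.name!r} ({cid} {res.number})")
            tpl = pset.variant(res.name, n_terminal=(ri == 0), c_terminal=(ri == len(residues) - 1))
            missing = [h for h in tpl.hydrogens if not res.has_atom(h)]
            if not missing:
                continue
            coords_t, adjacency = _ccd_geometry(res.name)
            for hname in missing:
                pos = _place_hydrogen(hname, res, residues, ri, coords_t, adjacency)
                res.atoms.append(
                    Atom(serial=0, name=hname, element="H", coords=pos, built=True)
                )
    return out


def _place_hydrogen(
    hname: str,
    res: Residue,
    residues: list[Residue],
    ri: int,
    coords_t: dict[str, np.ndarray],
    adjacency: dict[str, list[str]],
) -> np.ndarray:
    def xyz(name: str) -> np.ndarray:
        try:
            return res.atom(name).coords
        except KeyError as exc:
            raise ParameterizationError(
                f"residue {res.name} {res.number}: missing heavy anchor {name}"
            ) from exc

    if hname in ("H1", "H2", "H3") and hname not in coords_t:
        # N-terminal ammonium protons, staggered about N-CA relative to C
        offsets = {"H1": 60.0, "H2": 180.0, "H3": 300.0}
        return place_internal(xyz("N"), xyz("CA"), xyz("C"), 1.010, 109.5, offsets[hname])
    if hname == "H":
        # amide proton: in the peptide plane, anti to the preceding C=O
        if ri == 0:
            raise ParameterizationError("amide H requested for an N-terminal residue")
        prev = residues[ri - 1]
        c_prev = prev.atom("C").coords
        n = xyz("N")
        ca = xyz("CA")
        u1 = (c_prev - n) / np.linalg.norm(c_prev - n)
        u2 = (ca - n) / np.linalg.norm(ca - n)
        d = -(u1 + u2)
        return n + 1.010 * d / np.linalg.norm(d)
    if hname not in coords_t:
        raise ParameterizationError(f"no ideal geometry for hydrogen {hname} of {res.name}")
    parent = next(a for a in adjacency[hname] if not a.startswith("H"))
    anchors = _heavy_anchors(parent, adjacency, None)
    ref = np.stack([xyz(a) for a in anchors])
    mob = np.stack([coords_t[a] for a in anchors])
    R, t = kabsch(mob, ref)
    return R @ coords_t[hname] + t


def add_hydrogens(ensemble: Ensemble, pset: ParameterSet | None = None) -> Ensemble:
    """Hydrogenate every frame of an ensemble with a shared topology."""
    topo = build_hydrogens(ensemble.structure_for_frame(0), pset)
    frames = [topo.coords()]
    for k in range(1, ensemble.n_frames):
        s = build_hydrogens(ensemble.structure_for_frame(k), pset)
        frames.append(s.coords())
    return Ensemble(topology=topo, frames=frames)


_SIDECHAIN_KEEP = {"N", "CA", "C", "O", "CB", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}


def mutate_to_alanine(structure: Structure, chain: str, resnum: int) -> Structure:
    """Truncate one residue's side chain beyond C-beta and rename it ALA.

    Backbone atoms and the C-beta position are untouched; side-chain
    hydrogens are removed so that re-hydrogenation rebuilds the alanine
    methyl at ideal geometry.  Gly (no C-beta) and Pro (backbone ring)
    cannot be truncated.
    """
    out = structure.copy()
    target = None
    for res in out.chain(chain):
        if res.number == resnum:
            target = res
            break
    if target is None:
        raise ParameterizationError(f"no residue {resnum} in chain {chain}")
    if target.name == "GLY":
        raise ParameterizationError("cannot truncate glycine (no C-beta)")
    if target.name == "PRO":
        raise ParameterizationError("cannot truncate proline (backbone ring)")
    if target.name not in ParameterSet.default().templates:
        raise ParameterizationError(f"unknown residue {target.name!r}")
    if target.name == "ALA":
        return out
    target.atoms = [a for a in target.atoms if a.name in _SIDECHAIN_KEEP]
    target.name = "ALA"
    return out


@dataclass
class ParameterizedSystem:
    """An ensemble with per-atom parameters and a dimer partition.

    Array attributes are in canonical (topology) atom order.
    """

    ensemble: Ensemble
    partition: DimerPartition
    charges: np.ndarray
    rmin_half: np.ndarray
    eps: np.ndarray
    gb_radius: np.ndarray
    gb_screen: np.ndarray
    is_hydrogen: np.ndarray
    atom_names: list[str]
    atom_chain: list[str]
    residue_keys: list[tuple[str, int, str]]  # ordered (chain, resnum, resname)
    atom_residue: np.ndarray  # atom index -> index into residue_keys
    side_a_mask: np.ndarray  # True for atoms of partner A
    formal_charge: int

    @property
    def n_atoms(self) -> int:
        return len(self.charges)

    @property
    def n_frames(self) -> int:
        return self.ensemble.n_frames

    def coords(self, frame_index: int) -> np.ndarray:
        return self.ensemble.frames[frame_index]

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def residue_atom_indices(self, key: tuple[str, int, str] | tuple[str, int]) -> np.ndarray:
        if len(key) == 2:
            matches = [i for i, k in enumerate(self.residue_keys) if k[:2] == key]
            if not matches:
                raise KeyError(f"no residue {key}")
            r = matches[0]
        else:
            r = self.residue_keys.index(key)
        return np.flatnonzero(self.atom_residue == r)


def assign_parameters(
    ensemble: Ensemble, pset: ParameterSet | None = None, partition: DimerPartition | None = None
) -> ParameterizedSystem:
    """Assign per-atom parameters to every atom of the ensemble topology.

    Every residue must match its (terminal-aware) template exactly; missing
    or unknown atoms are reported with chain, residue and atom name.
    """
    pset = pset or ParameterSet.default()
    topo = ensemble.topology
    if partition is None:
        ids = topo.chain_ids
        if len(ids) < 2:
            raise ParameterizationError("partition required for single-chain systems")
        partition = DimerPartition(frozenset(ids[:1]), frozenset(ids[1:]))
    covered = partition.partner_a | partition.partner_b
    if set(topo.chain_ids) - covered:
        raise ParameterizationError(
            f"partition does not cover chains {sorted(set(topo.chain_ids) - covered)}"
        )

    per_atom: list[AtomParams] = []
    atom_names: list[str] = []
    atom_chain: list[str] = []
    residue_keys: list[tuple[str, int, str]] = []
    atom_residue: list[int] = []
    formal = 0
    for cid, residues in topo.chains:
        for ri, res in enumerate(residues):
            if not pset.knows(res.name):
                raise ParameterizationError(f"no template for {res.name!r} ({cid} {res.number})")
            c_term = ri == len(residues) - 1 and res.has_atom("OXT")
            tpl = pset.variant(res.name, n_terminal=(ri == 0), c_terminal=c_term)
            have = [a.name for a in res.atoms]
            missing = [n for n in tpl.atom_order if n not in have]
            if missing:
                raise ParameterizationError(
                    f"chain {cid} residue {res.name} {res.number}: missing atoms {missing} "
                    "(run build_hydrogens first if these are hydrogens)"
                )
            extra = [n for n in have if n not in tpl.params]
            if extra:
                raise ParameterizationError(
                    f"chain {cid} residue {res.name} {res.number}: no parameters for atoms {extra}"
                )
            rindex = len(residue_keys)
            residue_keys.append((cid, res.number, res.name))
            formal += tpl.formal_charge
            for a in res.atoms:
                per_atom.append(tpl.params[a.name])
                atom_names.append(a.name)
                atom_chain.append(cid)
                atom_residue.append(rindex)

    charges = np.array([p.charge for p in per_atom])
    system = ParameterizedSystem(
        ensemble=ensemble,
        partition=partition,
        charges=charges,
        rmin_half=np.array([p.lj_rmin_half for p in per_atom]),
        eps=np.array([p.lj_eps for p in per_atom]),
        gb_radius=np.array([p.gb_radius for p in per_atom]),
        gb_screen=np.array([p.gb_screen for p in per_atom]),
        is_hydrogen=np.array([p.element == "H" for p in per_atom]),
        atom_names=atom_names,
        atom_chain=atom_chain,
        residue_keys=residue_keys,
        atom_residue=np.array(atom_residue, dtype=int),
        side_a_mask=np.array([c in partition.partner_a for c in atom_chain]),
        formal_charge=formal,
    )
    if abs(system.total_charge - formal) > 1e-3 * max(1, len(residue_keys)):
        raise ParameterizationError(
            f"total charge {system.total_charge:.4f} deviates from formal {formal}"
        )
    return system
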