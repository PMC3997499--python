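import numpy as np
import pytest

from gbscan import (
    DimerPartition,
    Ensemble,
    assign_parameters,
    build_helix_dimer,
    jitter_ensemble,
    sticky_helix_dimer,
)
from gbscan.forcefield import ParameterizedSystem


@pytest.fixture(scope="session")
def c2_dimer():
    """Exactly C2-symmetric 10+10 residue helical dimer (mixed sequence)."""
    structure, partition = build_helix_dimer(
        "ALKAAELAYL", separation=9.5, c2_symmetric=True
    )
    return structure, partition


@pytest.fixture(scope="session")
def c2_system(c2_dimer):
    structure, partition = c2_dimer
    ensemble = jitter_ensemble(structure, 0.12, 3, seed=11)
    return assign_parameters(ensemble, partition=partition)


@pytest.fixture(scope="session")
def sticky_system():
    structure, partition, anchor = sticky_helix_dimer()
    ensemble = jitter_ensemble(structure, 0.15, 8, seed=7)
    return assign_parameters(ensemble, partition=partition), anchor


def make_toy_system(coords, charges, rmin_half, eps, gb_radius, side_a):
    """Assemble a bare ParameterizedSystem from arrays (one atom per residue).

    For oracle tests on hand-enumerable systems; atoms on side A belong to
    chain A, the rest to chain B, each atom its own residue.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    side_a = np.asarray(side_a, bool)
    from gbscan.structure import Atom, Residue, Structure

    chains_a, chains_b = [], []
    atom_chain, residue_keys, atom_residue = [], [], []
    for i in range(n):
        cid = "A" if side_a[i] else "B"
        res = Residue(name="ALA", number=i + 1)
        res.atoms = [Atom(i + 1, "CA", "C", coords[i])]
        (chains_a if side_a[i] else chains_b).append(res)
    chains = []
    if chains_a:
        chains.append(("A", chains_a))
    if chains_b:
        chains.append(("B", chains_b))
    structure = Structure(chains=chains)
    # canonical order regroups chain A first; build index arrays to match
    order = np.concatenate([np.flatnonzero(side_a), np.flatnonzero(~side_a)])
    for rank, i in enumerate(order):
        cid = "A" if side_a[i] else "B"
        atom_chain.append(cid)
        residue_keys.append((cid, int(i) + 1, "ALA"))
        atom_residue.append(rank)
    return ParameterizedSystem(
        ensemble=Ensemble.from_structure(structure),
        partition=DimerPartition(frozenset("A"), frozenset("B")),
        charges=np.asarray(charges, float)[order],
        rmin_half=np.asarray(rmin_half, float)[order],
        eps=np.asarray(eps, float)[order],
        gb_radius=np.asarray(gb_radius, float)[order],
        gb_screen=np.full(n, 0.85),
        is_hydrogen=np.zeros(n, bool),
        atom_names=["CA"] * n,
        atom_chain=atom_chain,
        residue_keys=residue_keys,
        atom_residue=np.asarray(atom_residue, int),
        side_a_mask=np.array([c == "A" for c in atom_chain]),
        formal_charge=int(round(float(np.sum(charges)))),
    )
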