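"""Shared fixtures: synthetic ensembles and hand-built miniature frames."""

from __future__ import annotations

import numpy as np
import pytest

import nucbreathe as nb
from nucbreathe.structure_io import ConformationFrame
from nucbreathe.topology import build_topology


@pytest.fixture(scope="session")
def closed_nucleosome():
    """Default closed 168-bp synthetic nucleosome (frame, topology, gt)."""
    return nb.build_ideal_nucleosome(nb.SyntheticParams(seed=0))


@pytest.fixture(scope="session")
def opening_ensemble():
    """20-frame noise-free trajectory with both arms opening linearly."""
    sched = {"5p": nb.make_linear_schedule(20, 30.0, 10.0),
             "3p": nb.make_linear_schedule(20, 40.0, 15.0)}
    return nb.generate_breathing_trajectory(
        nb.SyntheticParams(frames=20, schedule=sched, seed=2))


@pytest.fixture(scope="session")
def tf_bridging_nucleosome():
    return nb.build_ideal_nucleosome(
        nb.SyntheticParams(tf_mode="bridging", seed=4))


def make_point_frame(coords, chains=None, resids=None, names=None,
                     elements=None):
    """Minimal frame around raw coordinates for geometry/contact tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    chains = np.array(chains if chains is not None else ["X"] * n)
    names = np.array(names if names is not None else ["CA"] * n)
    elements = np.array(elements if elements is not None else ["C"] * n)
    masses = np.where(elements == "H", 1.008, 12.011)
    return ConformationFrame(
        names=names, elements=elements, masses=masses, chains=chains,
        resids=np.array(resids if resids is not None else range(1, n + 1),
                        dtype=int),
        resnames=np.array(["ALA"] * n), coords=coords,
        roles=np.array(["unassigned"] * n),
    )


def make_mini_dna_system(rng, n_bp=10, protein_res=6, atoms_per_nt=2,
                         atoms_per_res=3, spread=12.0):
    """Random miniature DNA + protein system with a real topology binding.

    Coordinates are uniform in a cube so that some pairs land within the
    4.5 Å contact cutoff; returns (frame, topology, protein_mask, dna_mask).
    """
    cfg = {
        "chains": {"I": "DNA_I", "J": "DNA_J", "E": "H3-A"},
        "species": "custom",
        "tails": {"H3": [1, protein_res]},
        "n_bp": n_bp,
        "dna_residues": {"I": list(range(1, n_bp + 1)),
                         "J": list(range(n_bp, 0, -1))},
        "regions": {"core_size": n_bp, "outer_gyre_size": n_bp // 3},
    }
    topo = build_topology(cfg)
    names, chains, resids, elements = [], [], [], []
    for chain in ("I", "J"):
        for res in range(1, n_bp + 1):
            for k in range(atoms_per_nt):
                names.append("P" if k == 0 else "N1")
                elements.append("P" if k == 0 else "N")
                chains.append(chain)
                resids.append(res)
    for res in range(1, protein_res + 1):
        for k in range(atoms_per_res):
            names.append("CA" if k == 0 else ("CB" if k == 1 else "HA"))
            elements.append("H" if k == 2 else "C")
            chains.append("E")
            resids.append(res)
    n = len(names)
    coords = rng.uniform(-spread / 2, spread / 2, size=(n, 3))
    elements = np.array(elements)
    frame = ConformationFrame(
        names=np.array(names), elements=elements,
        masses=np.where(elements == "H", 1.008, 14.0),
        chains=np.array(chains), resids=np.array(resids, dtype=int),
        resnames=np.where(np.isin(np.array(chains), ["I", "J"]), "DA", "ALA"),
        coords=coords,
        roles=np.array([{"I": "DNA_I", "J": "DNA_J",
                         "E": "H3-A"}[c] for c in chains]),
    )
    protein = frame.roles == "H3-A"
    dna = np.isin(frame.roles, ("DNA_I", "DNA_J"))
    return frame, topo, protein, dna


def brute_force_contacts(frame, mask_a, mask_b, cutoff=4.5,
                         granularity="atom_pair", topology=None):
    """O(N²) reference contact counter used as the test oracle."""
    from nucbreathe.selections import bp_index_of_atoms

    ia = np.nonzero(np.asarray(mask_a) & frame.heavy)[0]
    ib = np.nonzero(np.asarray(mask_b) & frame.heavy)[0]
    pairs = []
    for i in ia:
        for j in ib:
            d = np.linalg.norm(frame.coords[i] - frame.coords[j])
            if d < cutoff:
                pairs.append((i, j))
    if granularity == "atom_pair":
        return len(pairs)
    bp_of = bp_index_of_atoms(frame, topology)
    return len({
        (str(frame.chains[i]), int(frame.resids[i]), int(bp_of[j]))
        for i, j in pairs
    })
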