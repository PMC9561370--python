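"""Atom-group selections derived from a topology.

Every observable (Rg, breathing angles, contacts, collective variables)
consumes boolean atom masks produced here, so the mapping from scientific
group names ("H3 tail", "outer gyre backbone", "POU_HD Cα") to atom indices
lives in exactly one place.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .structure_io import ConformationFrame
from .topology import (
    NucleosomeTopology,
    classify_dna_regions,
    partition_dna_atoms,
    tail_residues,
)

__all__ = [
    "bp_index_of_atoms",
    "dna_mask",
    "histone_core_ca",
    "histone_core_heavy",
    "tail_mask",
    "tf_subdomain_mask",
    "resolve_group",
]


def bp_index_of_atoms(frame: ConformationFrame,
                      topology: NucleosomeTopology) -> np.ndarray:
    """Base-pair index (0-based) per atom; -1 for non-DNA atoms."""
    out = np.full(frame.n_atoms, -1, dtype=int)
    for strand, role in zip(topology.dna_strands, ("DNA_I", "DNA_J")):
        lookup = {res: i for i, res in enumerate(strand)}
        sel = frame.roles == role
        out[sel] = [lookup.get(int(r), -1) for r in frame.resids[sel]]
    return out


def dna_mask(frame: ConformationFrame, topology: NucleosomeTopology,
             bps: Iterable[int] | None = None, part: str = "all",
             heavy_only: bool = True,
             atom_names: Sequence[str] | None = None) -> np.ndarray:
    """Mask of DNA atoms, optionally restricted to base pairs / atom part.

    ``part`` is 'all', 'base' or 'backbone'; ``atom_names`` restricts to
    specific names (e.g. ["P"] for the phosphate trace).
    """
    mask = np.isin(frame.roles, ("DNA_I", "DNA_J"))
    if heavy_only:
        mask &= frame.heavy
    if bps is not None:
        bp_of = bp_index_of_atoms(frame, topology)
        mask &= np.isin(bp_of, np.fromiter(bps, dtype=int))
    if atom_names is not None:
        mask &= np.isin(frame.names, list(atom_names))
    if part != "all":
        idx = np.nonzero(mask)[0]
        keep = [i for i in idx
                if partition_dna_atoms(str(frame.names[i])) == part]
        mask = np.zeros(frame.n_atoms, dtype=bool)
        mask[keep] = True
    return mask


def _histone_mask(frame: ConformationFrame,
                  topology: NucleosomeTopology) -> np.ndarray:
    roles = list(topology.histone_chains)
    return np.isin(frame.roles, roles)


def tail_mask(frame: ConformationFrame, topology: NucleosomeTopology,
              roles: Sequence[str] | None = None,
              heavy_only: bool = True) -> np.ndarray:
    """Mask of histone-tail atoms, optionally for specific copies.

    ``roles`` names histone copies like ``["H3-A", "H2A-A"]``; H2A includes
    its C-terminal ("H2AC") tail range whenever the preset defines one.
    """
    tails = tail_residues(topology)
    wanted = list(tails) if roles is None else list(roles)
    mask = np.zeros(frame.n_atoms, dtype=bool)
    for role in wanted:
        res = tails.get(role, frozenset())
        if not res:
            continue
        sel = (frame.roles == role) & np.isin(
            frame.resids, np.fromiter(res, dtype=int))
        mask |= sel
    if heavy_only:
        mask &= frame.heavy
    return mask


def histone_core_heavy(frame: ConformationFrame,
                       topology: NucleosomeTopology) -> np.ndarray:
    """Heavy atoms of the globular (non-tail) histone core."""
    mask = _histone_mask(frame, topology) & frame.heavy
    mask &= ~tail_mask(frame, topology, heavy_only=False)
    return mask


def histone_core_ca(frame: ConformationFrame,
                    topology: NucleosomeTopology) -> np.ndarray:
    """Cα atoms of the non-tail histone core (the superposition selection)."""
    return histone_core_heavy(frame, topology) & (frame.names == "CA")


def tf_subdomain_mask(frame: ConformationFrame,
                      topology: NucleosomeTopology, name: str,
                      heavy_only: bool = True,
                      ca_only: bool = False) -> np.ndarray:
    """Mask of TF subdomain atoms (``POU_S`` | ``POU_HD`` | ``linker``)."""
    if name not in topology.tf_subdomains:
        raise KeyError(f"topology defines no TF subdomain {name!r}")
    lo, hi = topology.tf_subdomains[name]
    mask = (frame.roles == "TF") & (frame.resids >= lo) & (frame.resids <= hi)
    if heavy_only:
        mask &= frame.heavy
    if ca_only:
        mask &= frame.names == "CA"
    return mask


def resolve_group(frame: ConformationFrame, topology: NucleosomeTopology,
                  spec: str) -> np.ndarray:
    """Resolve a symbolic group name into an atom mask.

    Grammar (colon-separated qualifiers):

    - ``dna[:region][:part][:P]`` — region in {core, linker_5p, linker_3p,
      inner_gyre, outer_gyre_5p, outer_gyre_3p, outer_gyres, all};
      part in {base, backbone}; trailing ``P`` keeps the phosphate trace only.
    - ``tails:ROLE+ROLE`` — histone tail heavy atoms (``tails:all`` for every
      tail), ``:CA`` suffix for the Cα/bead trace.
    - ``tf:SUBDOMAIN[:CA]`` — TF subdomain heavy atoms.
    - ``histone_core[:CA]`` — globular histone atoms.
    """
    parts = spec.split(":")
    kind = parts[0]
    if kind == "dna":
        regions = classify_dna_regions(topology)
        region = parts[1] if len(parts) > 1 else "all"
        bps = None
        if region != "all":
            if region == "outer_gyres":
                bps = regions.outer_gyre_5p + regions.outer_gyre_3p
            else:
                bps = getattr(regions, region)
        part = "all"
        names = None
        for q in parts[2:]:
            if q in ("base", "backbone"):
                part = q
            elif q == "P":
                names = ["P"]
        return dna_mask(frame, topology, bps=bps, part=part, atom_names=names)
    if kind == "tails":
        roles = None if len(parts) < 2 or parts[1] == "all" \
            else parts[1].split("+")
        mask = tail_mask(frame, topology, roles=roles)
        if "CA" in parts[2:]:
            mask &= frame.names == "CA"
        return mask
    if kind == "tf":
        return tf_subdomain_mask(frame, topology, parts[1],
                                 ca_only="CA" in parts[2:])
    if kind == "histone_core":
        mask = histone_core_heavy(frame, topology)
        if "CA" in parts[1:]:
            mask &= frame.names == "CA"
        return mask
    raise ValueError(f"cannot resolve group spec {spec!r}")
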