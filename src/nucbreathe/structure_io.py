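"""Structure and trajectory I/O bound to a nucleosome topology.

Reading goes through MDAnalysis (PDB, mmCIF, DCD, XTC, multi-model PDB);
frames are materialized as :class:`ConformationFrame` objects holding plain
numpy arrays so that the geometry and contact code never touches a reader
API. PDB writing is a minimal fixed-format writer: synthetic fixtures must
be byte-identical across runs with the same seed, so the output contains
nothing but ATOM/MODEL records derived from the data.

Solvent and ions are dropped on load. Hydrogens are kept in memory but
carry a flag so contact and collective-variable groups can exclude them.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .topology import NucleosomeTopology, partition_dna_atoms

__all__ = [
    "ConformationFrame",
    "TrajectoryHandle",
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "write_multimodel_pdb",
    "write_table",
]

#: standard atomic masses (amu) keyed by element symbol
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.973762, "S": 32.06, "FE": 55.845, "ZN": 65.38,
}

_SOLVENT_RESNAMES = {
    "HOH", "WAT", "TIP3", "SPC", "SOL",
    "NA", "NA+", "CL", "CL-", "K", "K+", "MG", "CA2", "SOD", "CLA", "POT",
}


def guess_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name (fallback when no element column)."""
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    stripped = name.lstrip("0123456789")
    first = stripped[0].upper() if stripped else name[0].upper()
    if first in ("H", "C", "N", "O", "P", "S"):
        return first
    if name.upper() in ATOMIC_MASSES:
        return name.upper()
    raise ValueError(f"cannot infer element for atom name {atom_name!r}")


@dataclass
class ConformationFrame:
    """One set of labeled atomic coordinates.

    All arrays share length n_atoms. ``roles`` holds the topology role of
    each atom's chain ("DNA_I", "H3-A", "TF", or "unassigned").
    """

    names: np.ndarray          # str atom names
    elements: np.ndarray       # str element symbols
    masses: np.ndarray         # float amu
    chains: np.ndarray         # str chain IDs
    resids: np.ndarray         # int residue numbers
    resnames: np.ndarray       # str residue names
    coords: np.ndarray         # (n, 3) float Angstrom
    roles: np.ndarray          # str topology roles
    frame_index: int = 0
    time_ns: float | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise ValueError("non-positive atomic mass")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def heavy(self) -> np.ndarray:
        """Boolean mask of non-hydrogen atoms."""
        return self.elements != "H"

    def select(self, mask: np.ndarray) -> "ConformationFrame":
        """Sub-frame restricted to ``mask`` (boolean or index array)."""
        return ConformationFrame(
            names=self.names[mask], elements=self.elements[mask],
            masses=self.masses[mask], chains=self.chains[mask],
            resids=self.resids[mask], resnames=self.resnames[mask],
            coords=self.coords[mask], roles=self.roles[mask],
            frame_index=self.frame_index, time_ns=self.time_ns,
        )

    def with_coords(self, coords: np.ndarray, frame_index: int | None = None,
                    time_ns: float | None = None) -> "ConformationFrame":
        return replace(
            self, coords=np.asarray(coords, dtype=float),
            frame_index=self.frame_index if frame_index is None else frame_index,
            time_ns=self.time_ns if time_ns is None else time_ns,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": self.names, "element": self.elements, "mass": self.masses,
            "chain": self.chains, "resid": self.resids,
            "resname": self.resnames, "role": self.roles,
            "x": self.coords[:, 0], "y": self.coords[:, 1],
            "z": self.coords[:, 2],
        })


class TrajectoryHandle:
    """Ordered, lazily iterable frame source with a stable atom table."""

    def __init__(self, frames: Sequence[ConformationFrame] | None = None,
                 provenance: str = "in-memory"):
        self._frames = list(frames) if frames is not None else []
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self._frames)

    def __getitem__(self, i: int) -> ConformationFrame:
        return self._frames[i]

    def __iter__(self) -> Iterator[ConformationFrame]:
        return iter(self._frames)

    def iter_frames(self, start: int = 0, stop: int | None = None,
                    stride: int = 1) -> Iterator[ConformationFrame]:
        yield from self._frames[start:stop:stride]

    def sliced(self, start: int = 0, stop: int | None = None,
               stride: int = 1) -> "TrajectoryHandle":
        return TrajectoryHandle(self._frames[start:stop:stride],
                                provenance=self.provenance)

    @staticmethod
    def concatenate(*handles: "TrajectoryHandle") -> "TrajectoryHandle":
        """Join run segments (e.g. a run and its '-b' continuation) seamlessly."""
        frames: list[ConformationFrame] = []
        for h in handles:
            for f in h:
                frames.append(replace(f, frame_index=len(frames)))
        return TrajectoryHandle(
            frames, provenance="+".join(h.provenance for h in handles))


def _bind_roles(chains: np.ndarray, topology: NucleosomeTopology) -> np.ndarray:
    chain_map = dict(topology.chain_map)
    return np.array([chain_map.get(c, "unassigned") for c in chains])


def _frame_from_universe(u, topology: NucleosomeTopology,
                         frame_index: int = 0) -> ConformationFrame:
    ag = u.atoms
    names = ag.names.astype(str)
    chains = np.array([str(s) for s in ag.segids])
    # chainIDs are more reliable than segids for PDB input
    try:
        cid = np.array([str(c) for c in ag.chainIDs])
        if any(c.strip() for c in cid):
            chains = cid
    except Exception:
        pass
    resnames = ag.resnames.astype(str)
    keep = ~np.isin(np.char.upper(resnames), list(_SOLVENT_RESNAMES))
    names, chains, resnames = names[keep], chains[keep], resnames[keep]
    resids = ag.resids[keep].astype(int)
    coords = ag.positions[keep].astype(float)

    try:
        elements = np.array([str(e).upper() for e in ag.elements[keep]])
        if not all(e.strip() for e in elements):
            raise ValueError
    except Exception:
        elements = np.array([guess_element(n) for n in names])
    masses = np.array([ATOMIC_MASSES.get(e, 12.011) for e in elements])

    roles = _bind_roles(chains, topology)
    frame = ConformationFrame(
        names=names, elements=elements, masses=masses, chains=chains,
        resids=resids, resnames=resnames, coords=coords, roles=roles,
        frame_index=frame_index,
    )
    if not np.any(roles != "unassigned"):
        raise ValueError("zero atoms bound to topology roles")
    missing = [ch for ch in topology.chain_map
               if ch not in set(chains.tolist())]
    if missing:
        raise ValueError(f"structure is missing topology chains: {missing}")
    return frame


def read_structure(path, topology: NucleosomeTopology) -> ConformationFrame:
    """Read a PDB/mmCIF structure and bind atoms to topology roles."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    return _frame_from_universe(u, topology)


def read_trajectory(path, topology: NucleosomeTopology,
                    top_path=None, start: int = 0, stop: int | None = None,
                    stride: int = 1) -> TrajectoryHandle:
    """Read a trajectory (multi-model PDB, DCD or XTC) into a handle.

    Coordinate containers without an atom table (DCD/XTC) need ``top_path``
    pointing at a topology-bearing structure with matching atom count.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if top_path is not None:
            u = mda.Universe(str(top_path), str(path))
        else:
            u = mda.Universe(str(path))

    template = _frame_from_universe(u, topology)
    ag = u.atoms
    resnames = ag.resnames.astype(str)
    keep = ~np.isin(np.char.upper(resnames), list(_SOLVENT_RESNAMES))

    frames = []
    n_out = 0
    for i, ts in enumerate(u.trajectory):
        if i < start or (stop is not None and i >= stop):
            continue
        if (i - start) % stride:
            continue
        frames.append(template.with_coords(
            ag.positions[keep].astype(float), frame_index=n_out))
        n_out += 1
    return TrajectoryHandle(frames, provenance=str(path))


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resid: int, xyz: np.ndarray, element: str) -> str:
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial % 100000:5d} {nm:<4.4s} {resname:<4.4s}"
        f"{chain[:1]:1s}{resid % 10000:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2.2s}\n"
    )


def _write_frame_records(fh, frame: ConformationFrame) -> None:
    for i in range(frame.n_atoms):
        fh.write(_pdb_atom_line(
            i + 1, str(frame.names[i]), str(frame.resnames[i]),
            str(frame.chains[i]), int(frame.resids[i]),
            frame.coords[i], str(frame.elements[i])))


def write_pdb(frame: ConformationFrame, path) -> None:
    """Write one frame as a deterministic single-model PDB."""
    with open(path, "w", newline="\n") as fh:
        _write_frame_records(fh, frame)
        fh.write("END\n")


def write_multimodel_pdb(frames: Iterable[ConformationFrame], path) -> None:
    """Write frames as a deterministic multi-model PDB trajectory."""
    with open(path, "w", newline="\n") as fh:
        for m, frame in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            _write_frame_records(fh, frame)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_table(records, path, float_format: str = "%.6g") -> None:
    """Write tidy records as CSV with deterministic column order.

    ``records`` may be a DataFrame or an iterable of mappings; column order
    follows the first record (or the DataFrame's existing order). An empty
    record list with no columns yields an empty file; otherwise a
    header-only file.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        cols = list(records[0].keys()) if records else []
        df = pd.DataFrame(records, columns=cols)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format)


def dna_part_mask(frame: ConformationFrame, part: str) -> np.ndarray:
    """Mask of heavy DNA atoms in ``part`` ('base' | 'backbone' | 'all')."""
    is_dna = np.isin(frame.roles, ("DNA_I", "DNA_J"))
    mask = is_dna & frame.heavy
    if part == "all":
        return mask
    out = np.zeros(frame.n_atoms, dtype=bool)
    for i in np.nonzero(mask)[0]:
        if partition_dna_atoms(str(frame.names[i])) == part:
            out[i] = True
    return out
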