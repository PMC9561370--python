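"""Heavy-atom contact counting and persistence statistics.

A contact is two non-hydrogen atoms closer than a cutoff (4.5 Å by
default). Counts are reported either per atom pair or per
(residue, base-pair) pair; a residue–base-pair contact is *stable* when it
is present in strictly more than a threshold fraction (75% by default) of
the analyzed frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .selections import (
    bp_index_of_atoms,
    dna_mask,
    resolve_group,
    tf_subdomain_mask,
)
from .structure_io import ConformationFrame, TrajectoryHandle
from .topology import NucleosomeTopology, classify_dna_regions

__all__ = [
    "ContactSpec",
    "ContactSeries",
    "StableContactProfile",
    "count_contacts",
    "contact_pairs",
    "contact_series",
    "stable_contact_profile",
    "subdomain_gyre_contact_table",
]

DEFAULT_CUTOFF = 4.5       # Å, heavy-atom contact definition
DEFAULT_STABILITY = 0.75   # strict "more than 75% of the simulation"


@dataclass(frozen=True)
class ContactSpec:
    """Two heavy-atom groups, a cutoff, and a counting granularity."""

    group_a: np.ndarray
    group_b: np.ndarray
    cutoff: float = DEFAULT_CUTOFF
    granularity: str = "atom_pair"  # or "residue_bp"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.granularity not in ("atom_pair", "residue_bp"):
            raise ValueError(f"unknown granularity {self.granularity!r}")
        if np.any(np.asarray(self.group_a) & np.asarray(self.group_b)):
            raise ValueError("contact groups overlap")


@dataclass(frozen=True)
class ContactSeries:
    """Per-frame contact counts for one spec."""

    counts: np.ndarray
    cutoff: float
    granularity: str

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class StableContactProfile:
    """Occupancy and stability per (tail residue, base pair)."""

    residues: np.ndarray       # residue numbers, one per profile row
    bps: np.ndarray            # base-pair indices, one per profile column
    occupancy: np.ndarray      # (n_res, n_bp) fraction of frames in contact
    threshold: float
    n_frames: int

    @property
    def stable(self) -> np.ndarray:
        """Stability flags: occupancy strictly above the threshold."""
        return self.occupancy > self.threshold

    def stable_per_bp(self) -> np.ndarray:
        """Number of stably contacting residues per base pair."""
        return self.stable.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        res, bp = np.meshgrid(self.residues, self.bps, indexing="ij")
        return pd.DataFrame({
            "residue": res.ravel(),
            "bp": bp.ravel(),
            "occupancy": self.occupancy.ravel(),
            "stable": self.stable.ravel(),
        })


def _close_pairs(frame: ConformationFrame, ia: np.ndarray, ib: np.ndarray,
                 cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (into ia, ib) strictly closer than cutoff."""
    a = frame.coords[ia]
    b = frame.coords[ib]
    tree_b = cKDTree(b)
    pairs_a, pairs_b = [], []
    for k, neigh in enumerate(cKDTree(a).query_ball_tree(tree_b, cutoff)):
        for j in neigh:
            # query_ball_tree includes pairs at exactly the cutoff; the
            # contact definition is strict ("closer than").
            if np.dot(a[k] - b[j], a[k] - b[j]) < cutoff * cutoff:
                pairs_a.append(k)
                pairs_b.append(j)
    return np.asarray(pairs_a, dtype=int), np.asarray(pairs_b, dtype=int)


def _heavy_indices(frame: ConformationFrame, group: np.ndarray) -> np.ndarray:
    idx = np.nonzero(np.asarray(group) & frame.heavy)[0]
    if len(idx) == 0:
        raise ValueError("group empty after hydrogen exclusion")
    return idx


def count_contacts(frame: ConformationFrame, spec: ContactSpec,
                   topology: NucleosomeTopology | None = None) -> int:
    """Number of contacts between the two groups in one frame.

    Atom-pair granularity counts unordered heavy-atom pairs closer than
    the cutoff; residue-bp granularity counts (residue, base-pair) pairs
    with at least one such atom pair (requires ``topology``; group A
    residues are keyed (chain, resid), group B atoms by base pair).
    """
    ia = _heavy_indices(frame, spec.group_a)
    ib = _heavy_indices(frame, spec.group_b)
    ka, kb = _close_pairs(frame, ia, ib, spec.cutoff)
    if spec.granularity == "atom_pair":
        return len(ka)
    if topology is None:
        raise ValueError("residue_bp granularity requires a topology")
    bp_of = bp_index_of_atoms(frame, topology)
    pairs = {
        (str(frame.chains[ia[x]]), int(frame.resids[ia[x]]),
         int(bp_of[ib[y]]))
        for x, y in zip(ka, kb)
    }
    return len(pairs)


def contact_pairs(frame: ConformationFrame, spec: ContactSpec,
                  topology: NucleosomeTopology) -> set[tuple]:
    """The set of ((chain, residue), bp) pairs in contact in one frame."""
    ia = _heavy_indices(frame, spec.group_a)
    ib = _heavy_indices(frame, spec.group_b)
    ka, kb = _close_pairs(frame, ia, ib, spec.cutoff)
    bp_of = bp_index_of_atoms(frame, topology)
    return {
        ((str(frame.chains[ia[x]]), int(frame.resids[ia[x]])),
         int(bp_of[ib[y]]))
        for x, y in zip(ka, kb)
    }


def contact_series(trajectory: TrajectoryHandle, spec: ContactSpec,
                   topology: NucleosomeTopology | None = None,
                   stride: int = 1) -> ContactSeries:
    """Per-frame contact counts over a trajectory."""
    counts = []
    for fr in trajectory.iter_frames(stride=stride):
        try:
            counts.append(count_contacts(fr, spec, topology=topology))
        except ValueError as exc:
            raise ValueError(
                f"contact counting failed at frame {fr.frame_index}: {exc}"
            ) from exc
    return ContactSeries(counts=np.asarray(counts, dtype=int),
                         cutoff=spec.cutoff, granularity=spec.granularity)


def stable_contact_profile(trajectory: TrajectoryHandle,
                           tail_selection: np.ndarray,
                           dna_selection: np.ndarray,
                           topology: NucleosomeTopology,
                           cutoff: float = DEFAULT_CUTOFF,
                           threshold: float = DEFAULT_STABILITY,
                           granularity: str = "residue_bp",
                           ) -> StableContactProfile:
    """Residue–base-pair occupancy over the analyzed frames.

    Occupancy is the fraction of frames in which a (tail residue, base
    pair) pair has at least one heavy-atom contact; the stability flag is
    strict (``occupancy > threshold``). Frame windows/strides are applied
    by slicing the trajectory before calling. With
    ``granularity="atom_pair"`` the persistence rule is applied to
    individual heavy-atom pairs instead (rows/columns are then atom
    indices rather than residue numbers / base pairs).
    """
    if len(trajectory) == 0:
        raise ValueError("zero frames")
    if granularity == "atom_pair":
        return _stable_atom_pair_profile(trajectory, tail_selection,
                                         dna_selection, cutoff, threshold)
    if granularity != "residue_bp":
        raise ValueError(f"unknown granularity {granularity!r}")
    spec = ContactSpec(group_a=tail_selection, group_b=dna_selection,
                       cutoff=cutoff, granularity="residue_bp")
    first = trajectory[0]
    residues = sorted({
        (str(c), int(r))
        for c, r in zip(first.chains[np.asarray(tail_selection)],
                        first.resids[np.asarray(tail_selection)])
    })
    bp_of = bp_index_of_atoms(first, topology)
    bps = sorted({int(b) for b in bp_of[np.asarray(dna_selection)] if b >= 0})
    res_idx = {r: i for i, r in enumerate(residues)}
    bp_idx = {b: i for i, b in enumerate(bps)}

    hits = np.zeros((len(residues), len(bps)), dtype=int)
    for fr in trajectory:
        for res_key, bp in contact_pairs(fr, spec, topology):
            hits[res_idx[res_key], bp_idx[bp]] += 1

    return StableContactProfile(
        residues=np.array([r for _, r in residues]),
        bps=np.array(bps),
        occupancy=hits / len(trajectory),
        threshold=threshold,
        n_frames=len(trajectory),
    )


def _stable_atom_pair_profile(trajectory, group_a, group_b, cutoff,
                              threshold) -> StableContactProfile:
    first = trajectory[0]
    ia = _heavy_indices(first, group_a)
    ib = _heavy_indices(first, group_b)
    hits = np.zeros((len(ia), len(ib)), dtype=int)
    for fr in trajectory:
        ka, kb = _close_pairs(fr, ia, ib, cutoff)
        for x, y in zip(ka, kb):
            hits[x, y] += 1
    return StableContactProfile(
        residues=ia.astype(int), bps=ib.astype(int),
        occupancy=hits / len(trajectory), threshold=threshold,
        n_frames=len(trajectory))


def subdomain_gyre_contact_table(trajectory: TrajectoryHandle,
                                 topology: NucleosomeTopology,
                                 cutoff: float = DEFAULT_CUTOFF,
                                 ) -> pd.DataFrame:
    """Contact-count summaries for TF subdomains vs DNA parts and gyres.

    For each subdomain (POU_S, POU_HD) × DNA part (bases, backbone) × gyre
    (inner, outer, all), the per-frame atom-pair contact series is
    summarized as median and 5/95 percentiles, the reporting convention of
    the per-simulation tables.
    """
    from .report import summarize_series  # local import to avoid a cycle

    first = trajectory[0]
    regions = classify_dna_regions(topology)
    gyres = {
        "inner": list(regions.inner_gyre),
        "outer": list(regions.outer_gyre_5p + regions.outer_gyre_3p),
        "all": None,
    }
    rows = []
    for sub in ("POU_S", "POU_HD"):
        group_a = tf_subdomain_mask(first, topology, sub)
        if not group_a.any():
            raise ValueError(f"missing TF subdomain atoms for {sub}")
        for part in ("base", "backbone"):
            for gyre, bps in gyres.items():
                group_b = dna_mask(first, topology, bps=bps, part=part)
                series = contact_series(
                    trajectory,
                    ContactSpec(group_a=group_a, group_b=group_b,
                                cutoff=cutoff))
                s = summarize_series(series.counts)
                rows.append({
                    "subdomain": sub, "dna_part": part, "gyre": gyre,
                    "median": s.median, "p5": s.p5, "p95": s.p95,
                    "n_frames": s.n,
                })
    return pd.DataFrame(rows)
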