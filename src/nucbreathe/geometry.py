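"""Superposition, radius of gyration, the dyad frame, and breathing angles.

Nucleosome breathing is quantified in a coordinate system anchored on the
dyad of a reference structure: X points from the wrapped-DNA centroid to
the dyad, Z along the superhelical (winding) axis, Y completes the
right-handed triad. Each linker arm (L-DNA) defines an outward vector v;
its projection angles are

- gamma1: signed angle in the XZ plane from Z to the projection of v
  (positive sense = rotation about +Y, i.e. Z tilting toward X),
- gamma2: signed angle in the XY plane from Y to the projection of v
  (positive sense = rotation about +Z).

The frame is built once from the reference and reused for every frame;
trajectories are first rigid-body fitted to the reference over the
globular histone core, so the angles measure DNA motion relative to the
histones rather than global tumbling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .selections import bp_index_of_atoms, dna_mask, histone_core_ca
from .structure_io import ConformationFrame, TrajectoryHandle
from .topology import NucleosomeTopology, classify_dna_regions

__all__ = [
    "DyadFrame",
    "BreathingAngles",
    "superpose_to_reference",
    "radius_of_gyration",
    "build_dyad_frame",
    "linker_vector",
    "breathing_angles",
    "min_group_distance",
    "intergyre_min_distance",
    "analyze_trajectory",
]


@dataclass(frozen=True)
class DyadFrame:
    """Orthonormal right-handed frame (X, Y, Z) with origin on the dyad."""

    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        for a, b in ((self.X, self.Y), (self.X, self.Z), (self.Y, self.Z)):
            if abs(float(a @ b)) > 1e-8:
                raise ValueError("dyad frame axes are not orthogonal")
        if not np.allclose(np.cross(self.X, self.Y), self.Z, atol=1e-8):
            raise ValueError("dyad frame is not right-handed")


@dataclass(frozen=True)
class BreathingAngles:
    """Signed linker-arm angles (degrees) for the 5' and 3' arms.

    NaN marks a frame where a projection had near-zero norm (the arm vector
    was nearly perpendicular to the projection plane).
    """

    gamma1_5p: float
    gamma2_5p: float
    gamma1_3p: float
    gamma2_3p: float


def superpose_to_reference(
    frame: ConformationFrame,
    reference: ConformationFrame,
    selection: np.ndarray | None = None,
    topology: NucleosomeTopology | None = None,
) -> tuple[ConformationFrame, float]:
    """Least-squares rigid-body fit of ``frame`` onto ``reference``.

    The fit selection defaults to the Cα trace of the non-tail histone
    core (requires ``topology``). Returns the fitted frame (all atoms
    moved) and the post-fit RMSD (Å) over the selection.
    """
    if selection is None:
        if topology is None:
            raise ValueError("need a selection mask or a topology")
        selection = histone_core_ca(reference, topology)
    sel = np.asarray(selection)
    if sel.dtype == bool and (len(sel) != reference.n_atoms
                              or len(sel) != frame.n_atoms):
        raise ValueError("selection atom mismatch between frame and reference")
    a = reference.coords[sel]
    b = frame.coords[sel]
    if a.shape != b.shape or len(a) == 0:
        raise ValueError("selection atom mismatch between frame and reference")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(a - ca, b - cb)
    fitted = rot.apply(frame.coords - cb) + ca
    rmsd = float(rssd) / math.sqrt(len(a))
    return frame.with_coords(fitted), rmsd


def radius_of_gyration(frame: ConformationFrame,
                       selection: np.ndarray,
                       mass_weighted: bool = True) -> float:
    """Mass-weighted radius of gyration (Å) of the selected atoms."""
    xyz = frame.coords[selection]
    if len(xyz) == 0:
        raise ValueError("empty selection")
    w = frame.masses[selection] if mass_weighted else np.ones(len(xyz))
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total mass in selection")
    centroid = (w[:, None] * xyz).sum(axis=0) / total
    return float(np.sqrt((w * ((xyz - centroid) ** 2).sum(axis=1)).sum() / total))


def _bp_positions(frame: ConformationFrame, topology: NucleosomeTopology,
                  bps) -> np.ndarray:
    """Per-base-pair reference point: mean of the pair's phosphate atoms
    (all heavy atoms of the pair when a terminal residue lacks P)."""
    bp_of = bp_index_of_atoms(frame, topology)
    is_p = frame.names == "P"
    heavy = frame.heavy
    out = np.empty((len(bps), 3))
    for k, bp in enumerate(bps):
        sel = (bp_of == bp) & is_p
        if not sel.any():
            sel = (bp_of == bp) & heavy
        out[k] = frame.coords[sel].mean(axis=0)
    return out


def _winding_normal(path: np.ndarray) -> np.ndarray:
    """Axis of an ordered, roughly circular path: the polygon normal
    sum_i (p_i - c) x (p_{i+1} - c). Exact for planar circles and a close
    estimate of the superhelical axis for the wrapped DNA path."""
    centered = path - path.mean(axis=0)
    n = np.cross(centered[:-1], centered[1:]).sum(axis=0)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise ValueError("degenerate DNA path (collinear points)")
    return n / norm


def build_dyad_frame(reference: ConformationFrame,
                     topology: NucleosomeTopology,
                     normal_method: str = "winding") -> DyadFrame:
    """Construct the dyad-anchored XYZ frame from a reference structure.

    Origin: midpoint of the two central core base pairs. X: unit vector
    from the core-DNA centroid to the origin. Z: the core-DNA winding
    normal (5'->3' right-hand rule), orthogonalized against X. Y = Z × X.
    ``normal_method`` may be ``"winding"`` (default) or ``"plane_fit"``
    (normal of the least-squares plane through the core path).
    """
    regions = classify_dna_regions(topology)
    core = list(regions.core)
    path = _bp_positions(reference, topology, core)

    mid = len(core) // 2
    if len(core) % 2 == 0:
        origin = 0.5 * (path[mid - 1] + path[mid])
    else:
        origin = path[mid].copy()

    centroid = path.mean(axis=0)
    x = origin - centroid
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError("dyad coincides with the core centroid")
    x = x / nx

    if normal_method == "winding":
        n = _winding_normal(path)
    elif normal_method == "plane_fit":
        centered = path - centroid
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        n = vt[2]
        if n @ _winding_normal(path) < 0:  # fix the SVD sign ambiguity
            n = -n
    else:
        raise ValueError(f"unknown normal_method {normal_method!r}")

    z = n - (n @ x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ValueError("winding axis parallel to dyad direction")
    z = z / nz
    y = np.cross(z, x)
    return DyadFrame(origin=origin, X=x, Y=y, Z=z)


def linker_vector(frame: ConformationFrame, topology: NucleosomeTopology,
                  side: str, method: str = "line_fit") -> np.ndarray:
    """Unit vector along one linker arm, oriented core -> terminus.

    ``method="line_fit"`` (default) takes the principal axis of the arm's
    phosphate positions; ``"endpoints"`` the vector between the
    core-proximal and terminal base-pair positions.
    """
    regions = classify_dna_regions(topology)
    bps = {"5p": list(regions.linker_5p), "3p": list(regions.linker_3p)}[side]
    if len(bps) < 3:
        raise ValueError(f"linker {side} too short for a stable fit "
                         f"({len(bps)} bp)")
    # order from core-proximal to terminal
    if side == "5p":
        bps = bps[::-1]
    path = _bp_positions(frame, topology, bps)
    outward = path[-1] - path[0]

    if method == "endpoints":
        v = outward
    elif method == "line_fit":
        # all heavy atoms of the arm: maximal noise averaging, and the
        # asymmetric helical cross-section enters the axis the same way
        # for every frame
        mask = dna_mask(frame, topology, bps=bps)
        pts = frame.coords[mask]
        if len(pts) < 3:
            pts = path
        centered = pts - pts.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[0] < 1e-9:
            raise ValueError("degenerate linker (coincident points)")
        v = vt[0]
        if v @ outward < 0:
            v = -v
    else:
        raise ValueError(f"unknown linker method {method!r}")
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError("degenerate linker vector")
    return v / norm


def _project_angles(v: np.ndarray, dyad: DyadFrame,
                    min_norm: float = 1e-6) -> tuple[float, float]:
    vx, vy, vz = float(v @ dyad.X), float(v @ dyad.Y), float(v @ dyad.Z)
    g1 = math.degrees(math.atan2(vx, vz)) \
        if math.hypot(vx, vz) >= min_norm else math.nan
    g2 = math.degrees(math.atan2(-vx, vy)) \
        if math.hypot(vx, vy) >= min_norm else math.nan
    return g1, g2


def breathing_angles(frame: ConformationFrame, dyad: DyadFrame,
                     topology: NucleosomeTopology,
                     method: str = "line_fit",
                     gamma_sign: tuple[int, int] = (1, 1)) -> BreathingAngles:
    """Breathing angles of both linker arms in the dyad frame (degrees).

    ``gamma_sign`` flips the reported sign per angle, for matching an
    external convention.
    """
    s1, s2 = gamma_sign
    v5 = linker_vector(frame, topology, "5p", method=method)
    v3 = linker_vector(frame, topology, "3p", method=method)
    g1_5, g2_5 = _project_angles(v5, dyad)
    g1_3, g2_3 = _project_angles(v3, dyad)
    return BreathingAngles(
        gamma1_5p=s1 * g1_5, gamma2_5p=s2 * g2_5,
        gamma1_3p=s1 * g1_3, gamma2_3p=s2 * g2_3,
    )


def min_group_distance(frame: ConformationFrame, group_a: np.ndarray,
                       group_b: np.ndarray) -> float:
    """Exact minimal pairwise distance (Å) between two atom groups."""
    a = frame.coords[group_a]
    b = frame.coords[group_b]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    d, _ = cKDTree(b).query(a)
    return float(d.min())


def intergyre_min_distance(frame: ConformationFrame,
                           topology: NucleosomeTopology,
                           side: str = "3p",
                           junction_buffer: int = 10) -> float:
    """Minimal P–P distance between the inner gyre and one outer gyre.

    The two gyres are covalently contiguous, so ``junction_buffer`` base
    pairs are trimmed from each side of the junction before measuring;
    otherwise the minimum is always the backbone bond at the boundary.
    """
    regions = classify_dna_regions(topology)
    inner = list(regions.inner_gyre)
    outer = list(getattr(regions, f"outer_gyre_{side}"))
    if side == "3p":
        inner = inner[: len(inner) - junction_buffer]
        outer = outer[junction_buffer:]
    else:
        inner = inner[junction_buffer:]
        outer = outer[: len(outer) - junction_buffer]
    ga = dna_mask(frame, topology, bps=inner, atom_names=["P"])
    gb = dna_mask(frame, topology, bps=outer, atom_names=["P"])
    return min_group_distance(frame, ga, gb)


def analyze_trajectory(trajectory: TrajectoryHandle,
                       topology: NucleosomeTopology,
                       reference: ConformationFrame,
                       superpose: bool = True,
                       linker_method: str = "line_fit") -> pd.DataFrame:
    """Per-frame geometry series: Rg, breathing angles, inter-gyre distance.

    Returns a tidy DataFrame with columns frame, time_ns, rg_A,
    gamma1_5p_deg, gamma2_5p_deg, gamma1_3p_deg, gamma2_3p_deg,
    intergyre_min_A.
    """
    dyad = build_dyad_frame(reference, topology)
    dna = dna_mask(reference, topology)
    fit_sel = histone_core_ca(reference, topology)
    records = []
    for fr in trajectory:
        if superpose:
            fr, _ = superpose_to_reference(fr, reference, selection=fit_sel)
        ang = breathing_angles(fr, dyad, topology, method=linker_method)
        records.append({
            "frame": fr.frame_index,
            "time_ns": math.nan if fr.time_ns is None else fr.time_ns,
            "rg_A": radius_of_gyration(fr, dna),
            "gamma1_5p_deg": ang.gamma1_5p,
            "gamma2_5p_deg": ang.gamma2_5p,
            "gamma1_3p_deg": ang.gamma1_3p,
            "gamma2_3p_deg": ang.gamma2_3p,
            "intergyre_min_A": intergyre_min_distance(fr, topology),
        })
    return pd.DataFrame.from_records(records)
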