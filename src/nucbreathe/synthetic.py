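"""Idealized synthetic nucleosomes with known ground truth.

The generator builds a geometric stand-in for a 168-bp nucleosome: DNA as
two complementary pseudo-strands (P, C1' and an N1 base-proxy atom per
nucleotide) wound on a canonical superhelix (radius 41.9 Å, pitch 25.9 Å,
1.65 turns for the 146-bp core) with straight 11-bp linker arms; a
pseudo-histone core of Cα beads inside the wrap, with tail beads that can
be wrapped onto an outer DNA gyre or released; and an optional two-domain
pseudo-TF whose specific domain sits on the bases of a chosen site while
the second domain is free, on the inner gyre, or bridging both gyres.

Breathing trajectories rotate each linker arm rigidly about the dyad-frame
axes through its attachment point, following a per-frame opening schedule;
the exact per-frame arm angles, tail–DNA contact counts and TF contact
counts are emitted alongside as :class:`GroundTruth`, computed with the
generator's own direct O(N²) distance scans so that downstream analysis
can be validated against them.

All randomness flows from a single seed: identical parameters and seed
give byte-identical structures. The pseudo-atoms carry standard element
masses, so mass-weighted observables are exercised; the tails are
geometric walks, not physical polymers — their only contract is a
controllable contact pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .geometry import build_dyad_frame
from .structure_io import ConformationFrame, TrajectoryHandle
from .topology import NucleosomeTopology, build_topology, classify_dna_regions

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "SyntheticEnsemble",
    "build_ideal_nucleosome",
    "generate_breathing_trajectory",
    "place_pseudo_tf",
    "make_linear_schedule",
    "region_config_dict",
]

# pseudo-histone chain layout: role -> (chain ID, globular residue range)
_HISTONE_LAYOUT = {
    "H3-A": ("E", (46, 135)),
    "H4-A": ("F", (33, 102)),
    "H2A-A": ("G", (19, 118)),
    "H2B-A": ("H", (34, 125)),
}
_HUMAN_TAILS = {
    "H3-A": [(1, 45)],
    "H4-A": [(1, 32)],
    "H2A-A": [(1, 18), (119, 129)],
    "H2B-A": [(1, 33)],
}

_TF_SUBDOMAINS = {"POU_S": (1, 75), "linker": (76, 90), "POU_HD": (91, 150)}

#: rotation sense (about the dyad-frame Y and Z axes) that moves each arm
#: away from the wrapped core, i.e. that "opening" means for that arm
_OPEN_SIGN = {"5p": 1.0, "3p": -1.0}

# pseudo-nucleotide template: (atom name, duplex radius Å, phase offset deg).
# One full heavy-atom complement per nucleotide (phosphate + sugar backbone,
# six-membered base proxy) so that atom densities, base/backbone partitions
# and noise-averaged line fits behave like real B-DNA. P comes first: the
# tail/TF placement code keys on it.
_NUCLEOTIDE_ATOMS = (
    ("P", 8.9, 0.0), ("OP1", 9.9, 6.0), ("OP2", 9.4, -8.0),
    ("O5'", 8.3, 10.0), ("C5'", 7.8, 16.0), ("C4'", 7.2, 22.0),
    ("O4'", 6.5, 28.0), ("C3'", 7.0, 12.0), ("O3'", 7.6, 4.0),
    ("C2'", 6.3, 18.0), ("C1'", 5.9, 26.0),
    ("N1", 4.9, 32.0), ("C2", 4.1, 40.0), ("N3", 3.3, 48.0),
    ("C4", 2.6, 58.0), ("C5", 3.0, 70.0), ("C6", 3.9, 78.0),
)
_ATOMS_PER_NT = len(_NUCLEOTIDE_ATOMS)
_TWIST_DEG = 36.0           # helical twist per bp
_STRAND2_PHASE_DEG = 140.0  # angular offset of the complementary strand


@dataclass(frozen=True)
class SyntheticParams:
    """Generator parameters; defaults emulate a canonical 168-bp nucleosome."""

    n_bp: int = 168
    core_bp: int = 146
    superhelix_radius: float = 41.9
    pitch: float = 25.9
    wrap_turns: float = 1.65
    linker_rise: float = 3.4
    #: histone tail mode per role: "wrapped" (on an outer gyre) | "released"
    tail_modes: Mapping[str, str] = field(
        default_factory=lambda: {r: "wrapped" for r in _HISTONE_LAYOUT})
    #: outer gyre the H3/H2A tails wrap onto ("5p" | "3p")
    tail_side: str = "3p"
    #: frame at which wrapped tails switch to released (None = never)
    tail_release_frame: int | None = None
    #: pseudo-TF placement of the second domain:
    #: "none" | "free" | "inner" | "bridging" | "outer_backbone"
    tf_mode: str = "none"
    #: first bp (0-based) of the specific-binding site window
    tf_site_bp: int = 120
    tf_site_len: int = 8
    #: opening schedule per arm: arm -> (frames, 2) rotation angles in
    #: degrees about the dyad-frame Y (gamma1-like) and Z (gamma2-like)
    #: axes through the arm attachment point. Missing arm = closed.
    schedule: Mapping[str, np.ndarray] = field(default_factory=dict)
    frames: int = 1
    noise_sigma: float = 0.0
    apply_rigid_motion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_bp > self.n_bp:
            raise ValueError("core exceeds n_bp")
        for arr in self.schedule.values():
            if np.asarray(arr).shape != (self.frames, 2):
                raise ValueError("schedule length must equal frames")
        for role, mode in self.tail_modes.items():
            if mode not in ("wrapped", "released"):
                raise ValueError(f"unknown tail mode {mode!r} for {role}")
        if self.tf_mode not in ("none", "free", "inner", "bridging",
                                "outer_backbone"):
            raise ValueError(f"unknown tf_mode {self.tf_mode!r}")
        if self.tf_mode != "none" and not (
                0 <= self.tf_site_bp
                and self.tf_site_bp + self.tf_site_len <= self.n_bp):
            raise ValueError("TF site window outside n_bp")


@dataclass
class GroundTruth:
    """Exact per-frame state of a generated ensemble."""

    #: arm ("5p"/"3p") -> (frames, 2) true (gamma1, gamma2) in degrees
    gamma: dict[str, np.ndarray]
    #: per-frame heavy-atom-pair contact count, H3+H2A tails vs tail-side
    #: outer gyre, measured by the generator's direct distance scan
    tail_outer_counts: np.ndarray
    #: (subdomain, dna_part, gyre) -> atom-pair contact count on frame 0
    tf_counts: dict[tuple[str, str, str], int]
    #: named event frames (e.g. "tail_release")
    events: dict[str, int]
    #: superhelical axis direction used to build the wrap (lab coordinates)
    axis: np.ndarray
    #: arm -> closed-state outward unit vector (lab coordinates)
    arm_axes: dict[str, np.ndarray]


@dataclass
class SyntheticEnsemble:
    """A generated trajectory plus everything needed to analyze it."""

    trajectory: TrajectoryHandle
    topology: NucleosomeTopology
    reference: ConformationFrame
    ground_truth: GroundTruth
    params: SyntheticParams


def make_linear_schedule(frames: int, gamma1_end: float = 0.0,
                         gamma2_end: float = 0.0) -> np.ndarray:
    """Linear (frames, 2) ramp from 0 to the requested end angles (deg)."""
    t = np.linspace(0.0, 1.0, frames)
    return np.column_stack([t * gamma1_end, t * gamma2_end])


# ---------------------------------------------------------------------------
# geometry of the ideal wrap

def _core_path(params: SyntheticParams, j: np.ndarray):
    """Positions and local frames of core bp indices j (0..core_bp-1)."""
    n = params.core_bp
    center = (n - 1) / 2.0  # dyad: midpoint of the two central bp for even n
    theta = 2 * math.pi * params.wrap_turns * (j - center) / (n - 1)
    c = params.pitch / (2 * math.pi)  # rise per radian along the axis
    pos = np.column_stack([
        params.superhelix_radius * np.cos(theta),
        params.superhelix_radius * np.sin(theta),
        c * theta,
    ])
    tang = np.column_stack([
        -params.superhelix_radius * np.sin(theta),
        params.superhelix_radius * np.cos(theta),
        np.full_like(theta, c),
    ])
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    radial = np.column_stack([np.cos(theta), np.sin(theta),
                              np.zeros_like(theta)])
    binorm = np.cross(tang, radial)
    return pos, tang, radial, binorm


def _bp_frames(params: SyntheticParams):
    """Duplex-axis position and (normal, binormal) frame for every bp."""
    n, core = params.n_bp, params.core_bp
    n_link = n - core
    link3 = n_link // 2
    link5 = n_link - link3
    jcore = np.arange(core)
    pos_c, tang_c, rad_c, bin_c = _core_path(params, jcore)

    pos = np.empty((n, 3))
    normal = np.empty((n, 3))
    binorm = np.empty((n, 3))
    pos[link5:link5 + core] = pos_c
    normal[link5:link5 + core] = rad_c
    binorm[link5:link5 + core] = bin_c

    # straight arms continue along the terminal tangents
    u5 = -tang_c[0]
    for k in range(link5):
        bp = link5 - 1 - k
        pos[bp] = pos_c[0] + (k + 1) * params.linker_rise * u5
        normal[bp] = rad_c[0]
        binorm[bp] = bin_c[0]
    u3 = tang_c[-1]
    for k in range(link3):
        bp = link5 + core + k
        pos[bp] = pos_c[-1] + (k + 1) * params.linker_rise * u3
        normal[bp] = rad_c[-1]
        binorm[bp] = bin_c[-1]
    return pos, normal, binorm, u5, u3


def _dna_atoms(params: SyntheticParams):
    """Atom records for both strands: (names, chains, resids, resnames, xyz)."""
    pos, normal, binorm, _, _ = _bp_frames(params)
    n = params.n_bp
    names, chains, resids, resnames, xyz = [], [], [], [], []
    for strand, chain in ((0, "I"), (1, "J")):
        phase0 = 0.0 if strand == 0 else math.radians(_STRAND2_PHASE_DEG)
        order = range(n)
        for bp in order:
            phi0 = math.radians(_TWIST_DEG) * bp + phase0
            resid = bp + 1 if strand == 0 else n - bp
            resname = "DA" if strand == 0 else "DT"
            for name, radius, dphi in _NUCLEOTIDE_ATOMS:
                phi = phi0 + math.radians(dphi)
                u = math.cos(phi) * normal[bp] + math.sin(phi) * binorm[bp]
                names.append(name)
                chains.append(chain)
                resids.append(resid)
                resnames.append(resname)
                xyz.append(pos[bp] + radius * u)
    return names, chains, resids, resnames, np.array(xyz)


def _globular_beads(params: SyntheticParams):
    """Rigid pseudo-histone core: bead rings inside the superhelix."""
    names, chains, resids, resnames, xyz = [], [], [], [], []
    for idx, (role, (chain, (lo, hi))) in enumerate(_HISTONE_LAYOUT.items()):
        n_beads = hi - lo + 1
        z0 = (idx - 1.5) * 9.0
        for k in range(n_beads):
            ang = 2 * math.pi * k / n_beads + idx * 0.7
            r = 24.0 + 3.0 * math.cos(3 * ang + idx)
            names.append("CA")
            chains.append(chain)
            resids.append(lo + k)
            resnames.append("ALA")
            xyz.append([r * math.cos(ang), r * math.sin(ang),
                        z0 + 2.0 * math.sin(2 * ang)])
    return names, chains, resids, resnames, np.array(xyz)


def _tail_positions(params: SyntheticParams, role: str, ranges,
                    mode: str, dna_xyz_by_bp: dict[int, np.ndarray],
                    bp_pos: np.ndarray, outer_bps: list[int],
                    rng: np.random.Generator, slot: int) -> np.ndarray:
    """Bead positions for one tail: wrapped along the outer gyre backbone,
    or released along the superhelical axis, clear of all DNA."""
    n_beads = sum(hi - lo + 1 for lo, hi in ranges)
    if mode == "wrapped":
        pts = np.array(_backbone_shelf(outer_bps, dna_xyz_by_bp, bp_pos,
                                       n_beads, offset=3.8))
    else:
        z0 = 45.0 + 8.0 * slot
        t = np.arange(n_beads)
        pts = np.column_stack([
            10.0 * np.cos(0.6 * t + slot),
            10.0 * np.sin(0.6 * t + slot),
            z0 + 1.5 * t,
        ])
    pts = pts + rng.normal(0.0, 0.15, size=pts.shape)
    return pts


def _tail_atoms(params: SyntheticParams, mode_override: str | None,
                dna_xyz_by_bp, bp_pos, regions, rng):
    """All tail beads; ``mode_override`` forces every tail's mode."""
    outer = {
        "5p": list(regions.outer_gyre_5p),
        "3p": list(regions.outer_gyre_3p),
    }
    other = "5p" if params.tail_side == "3p" else "3p"
    side_of = {"H3-A": params.tail_side, "H2A-A": params.tail_side,
               "H4-A": other, "H2B-A": other}
    names, chains, resids, resnames, xyz = [], [], [], [], []
    for slot, (role, ranges) in enumerate(_HUMAN_TAILS.items()):
        chain = _HISTONE_LAYOUT[role][0]
        mode = mode_override or params.tail_modes.get(role, "wrapped")
        pts = _tail_positions(params, role, ranges, mode, dna_xyz_by_bp,
                              bp_pos, outer[side_of[role]], rng, slot)
        k = 0
        for lo, hi in ranges:
            for resid in range(lo, hi + 1):
                names.append("CA")
                chains.append(chain)
                resids.append(resid)
                resnames.append("ALA")
                xyz.append(pts[k])
                k += 1
    return names, chains, resids, resnames, np.array(xyz)


def _backbone_shelf(bps, dna_xyz_by_bp, bp_pos, n_pts,
                    offset: float = 3.9) -> list[np.ndarray]:
    """Points ``offset`` Å radially out of the duplex from phosphates that
    face away from the duplex axis — guaranteed backbone-proximal."""
    anchors = []
    for bp in bps:
        p = dna_xyz_by_bp[bp][0]        # strand-I phosphate
        d = p - bp_pos[bp]
        anchors.append(p + offset * d / np.linalg.norm(d))
    picks = np.linspace(0, len(anchors) - 1, n_pts).astype(int)
    return [anchors[i] for i in picks]


def _tf_atoms(params: SyntheticParams, dna_xyz_by_bp, bp_pos, regions, rng):
    """Two-domain pseudo-TF bead positions (chain T)."""
    names, chains, resids, resnames, xyz = [], [], [], [], []

    def add(resid_range, pts):
        lo, hi = resid_range
        for k, resid in enumerate(range(lo, hi + 1)):
            names.append("CA")
            chains.append("T")
            resids.append(resid)
            resnames.append("ALA")
            xyz.append(pts[k])

    site = list(range(params.tf_site_bp,
                      params.tf_site_bp + params.tf_site_len))
    n_s = _TF_SUBDOMAINS["POU_S"][1] - _TF_SUBDOMAINS["POU_S"][0] + 1
    if params.tf_mode == "outer_backbone":
        # specific domain touches backbone only: offset radially out of the
        # duplex from outward-facing phosphates, so the nearest DNA atoms
        # are always sugar-phosphate
        pts = _backbone_shelf(list(regions.outer_gyre_3p), dna_xyz_by_bp,
                              bp_pos, n_s, offset=3.9)
        s_pts = np.array(pts)
    else:
        # on the duplex axis of the site window: bases are the only atoms
        # within the 4.5 Å contact cutoff there
        picks = np.linspace(site[0], site[-1], n_s)
        lo_bp = np.floor(picks).astype(int)
        frac = (picks - lo_bp)[:, None]
        hi_bp = np.minimum(lo_bp + 1, site[-1])
        s_pts = (1 - frac) * bp_pos[lo_bp] + frac * bp_pos[hi_bp]
    add(_TF_SUBDOMAINS["POU_S"], s_pts)

    n_l = _TF_SUBDOMAINS["linker"][1] - _TF_SUBDOMAINS["linker"][0] + 1
    n_h = _TF_SUBDOMAINS["POU_HD"][1] - _TF_SUBDOMAINS["POU_HD"][0] + 1
    if params.tf_mode in ("free", "outer_backbone"):
        base = np.array([120.0, 0.0, 60.0])
        h_pts = base + np.column_stack([
            4.0 * np.cos(0.5 * np.arange(n_h)),
            4.0 * np.sin(0.5 * np.arange(n_h)),
            0.8 * np.arange(n_h)])
    elif params.tf_mode == "inner":
        inner = list(regions.inner_gyre)
        mid = inner[len(inner) // 2 - 15: len(inner) // 2 + 15]
        h_pts = np.array(_backbone_shelf(mid, dna_xyz_by_bp, bp_pos, n_h,
                                         offset=3.9))
    else:  # bridging: midway between the closest atoms of stacked gyres
        bp_per_turn = (params.core_bp - 1) / params.wrap_turns
        step = int(round(bp_per_turn))
        inner_set = set(regions.inner_gyre)
        outer_set = set(regions.outer_gyre_3p)
        pairs = [(j, j + step) for j in range(params.n_bp - step)
                 if j in inner_set and j + step in outer_set]
        mid0 = len(pairs) // 2
        window = pairs[max(0, mid0 - 4): mid0 + 4]
        mids = []
        for j_in, j_out in window:
            a = dna_xyz_by_bp[j_in]
            b = dna_xyz_by_bp[j_out]
            d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
            ia, ib = np.unravel_index(np.argmin(d2), d2.shape)
            mids.append(0.5 * (a[ia] + b[ib]))
        picks = np.linspace(0, len(mids) - 1, n_h).astype(int)
        h_pts = np.array([mids[i] for i in picks])
    # the interdomain linker dangles between the two domains
    t = np.linspace(0.1, 0.9, n_l)[:, None]
    l_pts = (1 - t) * s_pts[-1] + t * h_pts[0] + np.array([0, 0, 6.0])
    add(_TF_SUBDOMAINS["linker"], l_pts)
    add(_TF_SUBDOMAINS["POU_HD"], h_pts)
    xyz = np.array(xyz) + rng.normal(0.0, 0.1, size=(len(xyz), 3))
    return names, chains, resids, resnames, xyz


# ---------------------------------------------------------------------------
# generator-side brute-force contact oracle (independent of .contacts)

def _brute_count(xyz_a: np.ndarray, xyz_b: np.ndarray,
                 cutoff: float = 4.5) -> int:
    d2 = ((xyz_a[:, None, :] - xyz_b[None, :, :]) ** 2).sum(axis=2)
    return int((d2 < cutoff * cutoff).sum())


def region_config_dict(params: SyntheticParams) -> dict:
    """The region-configuration document matching a generated structure."""
    chains = {"I": "DNA_I", "J": "DNA_J"}
    for role, (chain, _) in _HISTONE_LAYOUT.items():
        chains[chain] = role
    if params.tf_mode != "none":
        chains["T"] = "TF"
    cfg = {
        "chains": chains,
        "species": "human",
        "n_bp": params.n_bp,
        "dna_residues": {
            "I": list(range(1, params.n_bp + 1)),
            # strand J stored in pairing order: J[i] pairs I[i]
            "J": list(range(params.n_bp, 0, -1)),
        },
        "regions": {
            "core_size": params.core_bp,
            "outer_gyre_size": 40,
        },
    }
    if params.tf_mode != "none":
        cfg["tf_subdomains"] = {
            name: list(rng) for name, rng in _TF_SUBDOMAINS.items()}
    return cfg


def build_ideal_nucleosome(params: SyntheticParams | None = None,
                           ) -> tuple[ConformationFrame, NucleosomeTopology,
                                      GroundTruth]:
    """Build the closed reference structure, its topology and ground truth."""
    params = params or SyntheticParams()
    rng = np.random.default_rng(params.seed)
    topology = build_topology(region_config_dict(params))
    regions = classify_dna_regions(topology)

    d_names, d_chains, d_resids, d_resnames, d_xyz = _dna_atoms(params)
    bp_pos, _, _, u5, u3 = _bp_frames(params)
    # strand-I atoms of bp i occupy one template block of the DNA arrays
    k = _ATOMS_PER_NT
    dna_by_bp = {bp: d_xyz[k * bp: k * (bp + 1)] for bp in range(params.n_bp)}

    g_names, g_chains, g_resids, g_resnames, g_xyz = _globular_beads(params)
    t_names, t_chains, t_resids, t_resnames, t_xyz = _tail_atoms(
        params, None, dna_by_bp, bp_pos, regions, rng)

    parts = [
        (d_names, d_chains, d_resids, d_resnames, d_xyz),
        (g_names, g_chains, g_resids, g_resnames, g_xyz),
        (t_names, t_chains, t_resids, t_resnames, t_xyz),
    ]
    tf_counts: dict[tuple[str, str, str], int] = {}
    if params.tf_mode != "none":
        parts.append(_tf_atoms(params, dna_by_bp, bp_pos, regions, rng))

    names = np.concatenate([np.array(p[0]) for p in parts])
    chains = np.concatenate([np.array(p[1]) for p in parts])
    resids = np.concatenate([np.array(p[2], dtype=int) for p in parts])
    resnames = np.concatenate([np.array(p[3]) for p in parts])
    coords = np.vstack([p[4] for p in parts])

    from .structure_io import ATOMIC_MASSES, guess_element
    elements = np.array([guess_element(n) for n in names])
    masses = np.array([ATOMIC_MASSES[e] for e in elements])
    chain_map = dict(topology.chain_map)
    roles = np.array([chain_map.get(c, "unassigned") for c in chains])

    frame = ConformationFrame(
        names=names, elements=elements, masses=masses, chains=chains,
        resids=resids, resnames=resnames, coords=coords, roles=roles)

    gt = GroundTruth(
        gamma={}, tail_outer_counts=np.zeros(0, dtype=int),
        tf_counts=tf_counts, events={},
        axis=np.array([0.0, 0.0, 1.0]),
        arm_axes={"5p": u5, "3p": u3},
    )
    if params.tf_mode != "none":
        gt.tf_counts = _measure_tf_counts(frame, topology, params)
    return frame, topology, gt


def _measure_tf_counts(frame: ConformationFrame,
                       topology: NucleosomeTopology,
                       params: SyntheticParams,
                       ) -> dict[tuple[str, str, str], int]:
    from .selections import dna_mask, tf_subdomain_mask
    regions = classify_dna_regions(topology)
    gyres = {
        "inner": list(regions.inner_gyre),
        "outer_5p": list(regions.outer_gyre_5p),
        "outer_3p": list(regions.outer_gyre_3p),
    }
    out: dict[tuple[str, str, str], int] = {}
    for sub in ("POU_S", "POU_HD"):
        a = frame.coords[tf_subdomain_mask(frame, topology, sub)]
        for part in ("base", "backbone"):
            for gyre, bps in gyres.items():
                b = frame.coords[dna_mask(frame, topology, bps=bps, part=part)]
                out[(sub, part, gyre)] = _brute_count(a, b)
    return out


def _rotation(axis: np.ndarray, deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.from_rotvec(np.asarray(axis) * math.radians(deg)
                                ).as_matrix()


def place_pseudo_tf(frame: ConformationFrame, params: SyntheticParams,
                    topology: NucleosomeTopology,
                    ) -> tuple[ConformationFrame,
                               dict[tuple[str, str, str], int]]:
    """Rebuild the structure with a pseudo-TF placed per ``params.tf_mode``.

    Returns the TF-bearing frame and the generator's own contact counts
    per (subdomain, DNA part, gyre). ``params.tf_mode`` must not be "none".
    """
    if params.tf_mode == "none":
        raise ValueError("params.tf_mode is 'none'")
    new_frame, new_topo, gt = build_ideal_nucleosome(params)
    # guard: the TF must not collide with the histone core cluster
    tf = new_frame.coords[new_frame.roles == "TF"]
    core = new_frame.coords[np.isin(new_frame.roles,
                                    list(_HISTONE_LAYOUT))]
    d2min = ((tf[:, None, :] - core[None, :, :]) ** 2).sum(axis=2).min()
    if d2min < 4.0:
        raise ValueError("pseudo-TF placement collides with the core cluster")
    return new_frame, gt.tf_counts


def generate_breathing_trajectory(params: SyntheticParams | None = None,
                                  ) -> SyntheticEnsemble:
    """Generate a breathing trajectory realizing the opening schedule.

    Each frame rotates the linker arms about the dyad-frame Y and Z axes
    (through each arm's attachment point) by the scheduled angles, applies
    the tail-release event if configured, and adds optional Gaussian
    coordinate noise. Ground truth holds the analytic per-frame arm angles
    in the reference dyad frame and the measured tail–outer-gyre contact
    counts.
    """
    params = params or SyntheticParams()
    reference, topology, gt = build_ideal_nucleosome(params)
    regions = classify_dna_regions(topology)
    dyad = build_dyad_frame(reference, topology)
    rng = np.random.default_rng(params.seed + 1)

    from .selections import bp_index_of_atoms, dna_mask, tail_mask
    bp_of = bp_index_of_atoms(reference, topology)
    arm_bps = {"5p": np.array(regions.linker_5p),
               "3p": np.array(regions.linker_3p)}
    # rotate the whole arm including any core-end overhang? no: linker only
    arm_atoms = {side: np.isin(bp_of, bps)
                 for side, bps in arm_bps.items()}
    # pivots: position of the core-proximal terminal core bp
    pivot = {
        "5p": reference.coords[bp_of == regions.core[0]].mean(axis=0),
        "3p": reference.coords[bp_of == regions.core[-1]].mean(axis=0),
    }

    outer_side = params.tail_side
    outer_mask = dna_mask(reference, topology,
                          bps=getattr(regions, f"outer_gyre_{outer_side}"))
    tails_hm = tail_mask(reference, topology, roles=["H3-A", "H2A-A"])

    # released-tail coordinates for the release event
    released_coords = None
    if params.tail_release_frame is not None:
        rel_frame, _, _ = build_ideal_nucleosome(
            replace(params,
                    tail_modes={r: "released" for r in _HISTONE_LAYOUT}))
        released_coords = rel_frame.coords

    all_tail = tail_mask(reference, topology, heavy_only=False)
    frames = []
    gamma = {side: np.zeros((params.frames, 2)) for side in ("5p", "3p")}
    tail_counts = np.zeros(params.frames, dtype=int)

    # closed-state arm direction: principal axis of the arm's heavy atoms,
    # oriented outward. This is the arm orientation an analysis can
    # actually observe; the idealized path tangent in gt.arm_axes sits
    # several degrees off it because of the partial helical winding.
    closed_axis = {}
    for side in ("5p", "3p"):
        pts = reference.coords[np.isin(bp_of, arm_bps[side])
                               & reference.heavy]
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        v0 = vt[0]
        if v0 @ gt.arm_axes[side] < 0:
            v0 = -v0
        closed_axis[side] = v0

    for f in range(params.frames):
        coords = reference.coords.copy()
        if (params.tail_release_frame is not None
                and f >= params.tail_release_frame):
            coords[all_tail] = released_coords[all_tail]
        for side in ("5p", "3p"):
            sched = params.schedule.get(side)
            a1, a2 = (0.0, 0.0) if sched is None else map(float, sched[f])
            s = _OPEN_SIGN[side]
            rot = _rotation(dyad.Z, s * a2) @ _rotation(dyad.Y, s * a1)
            sel = arm_atoms[side]
            coords[sel] = (coords[sel] - pivot[side]) @ rot.T + pivot[side]
            v = rot @ closed_axis[side]
            vx, vy, vz = v @ dyad.X, v @ dyad.Y, v @ dyad.Z
            gamma[side][f] = (math.degrees(math.atan2(vx, vz)),
                              math.degrees(math.atan2(-vx, vy)))
        if params.noise_sigma > 0:
            coords = coords + rng.normal(0.0, params.noise_sigma,
                                         size=coords.shape)
        if params.apply_rigid_motion:
            from scipy.spatial.transform import Rotation
            rmat = Rotation.random(rng=rng).as_matrix()
            shift = rng.uniform(-30, 30, size=3)
            coords = coords @ rmat.T + shift
        tail_counts[f] = _brute_count(coords[tails_hm], coords[outer_mask])
        frames.append(reference.with_coords(coords, frame_index=f))

    gt.gamma = gamma
    gt.tail_outer_counts = tail_counts
    if params.tail_release_frame is not None:
        gt.events["tail_release"] = params.tail_release_frame
    traj = TrajectoryHandle(frames, provenance=f"synthetic(seed={params.seed})")
    return SyntheticEnsemble(trajectory=traj, topology=topology,
                             reference=reference, ground_truth=gt,
                             params=params)
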