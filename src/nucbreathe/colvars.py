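"""Collective variables and declarative bias protocols.

Two scalar collective variables (CVs) over pairs of atom groups:

- ``distance_inv`` — the weighted mean distance

      d[n] = [ (1/(N1 N2)) * sum_ij ||d_ij||^-n ]^(-1/n),

  an even-exponent soft minimum that approaches the true minimal
  inter-group distance as n grows; n = 100 tracks the minimum closely
  while remaining smooth.

- ``coordination_number`` — the switching-function sum

      C = sum_ij (1 - r^n) / (1 - r^m),   r = ||x_i - x_j|| / d0,

  with d0 = 4.0 Å, n = 6, m = 12 by default; each pair contributes ~1 when
  much closer than d0 and ~0 when much farther, so C counts contacts
  smoothly. With m = 2n the ratio factorizes to 1/(1 + r^n), which is
  singularity-free and gives C = 1/2 at r = 1 exactly.

On top of the CVs sit one-sided harmonic walls, E = (k/2) Δ² for a bound
violation of depth Δ, and steered (moving-center) harmonic restraints whose
center ramps linearly between two values over a fixed duration. Protocol
presets cover two standard use cases: releasing the H3/H2A-C tails from
the outer DNA gyre, and steering the POU homeodomain in between the DNA
gyres. CV groups default to the Cα (protein) and P (DNA) traces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .selections import resolve_group
from .structure_io import ConformationFrame, TrajectoryHandle
from .topology import NucleosomeTopology

__all__ = [
    "DistanceInvSpec",
    "CoordinationSpec",
    "HarmonicWallSpec",
    "SteeredSpec",
    "BiasProtocol",
    "distance_inv",
    "coordination_number",
    "evaluate_cv",
    "wall_energy",
    "steered_center",
    "evaluate_protocol",
    "export_bias_config",
    "parse_bias_config",
    "tail_release_preset",
    "pou_hd_insertion_preset",
]

DEFAULT_FORCE_CONSTANT = 10.0  # kcal mol^-1 Å^-2

Group = Union[str, np.ndarray]


def _resolve(group: Group, frame: ConformationFrame,
             topology: NucleosomeTopology | None) -> np.ndarray:
    if isinstance(group, str):
        if topology is None:
            raise ValueError(f"symbolic group {group!r} needs a topology")
        mask = resolve_group(frame, topology, group)
    else:
        mask = np.asarray(group)
    if not mask.any():
        raise ValueError(f"group {group!r} resolves to no atoms")
    return mask


@dataclass(frozen=True)
class DistanceInvSpec:
    """Weighted-minimum-distance CV between two backbone-trace groups."""

    group1: Group
    group2: Group
    n: int = 100

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2:
            raise ValueError("exponent n must be an even integer >= 2")


@dataclass(frozen=True)
class CoordinationSpec:
    """Smooth contact-count CV with a rational switching function."""

    group1: Group
    group2: Group
    d0: float = 4.0
    n: int = 6
    m: int = 12

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if not (self.m > self.n > 0):
            raise ValueError("exponents must satisfy m > n > 0")


CVSpec = Union[DistanceInvSpec, CoordinationSpec]


@dataclass(frozen=True)
class HarmonicWallSpec:
    """One-sided harmonic restraint(s) on a CV: E = (k/2) Δ² outside bounds."""

    variable: CVSpec
    lower: float | None = None
    upper: float | None = None
    k: float = DEFAULT_FORCE_CONSTANT

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ValueError("wall needs at least one bound")
        if self.k <= 0:
            raise ValueError("force constant must be positive")


@dataclass(frozen=True)
class SteeredSpec:
    """Moving harmonic center ramped linearly start -> end over a duration."""

    variable: CVSpec
    start: float
    end: float
    duration: float
    duration_unit: str = "ns"   # or "frames"
    k: float = DEFAULT_FORCE_CONSTANT

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.duration_unit not in ("ns", "frames"):
            raise ValueError("duration unit must be 'ns' or 'frames'")


@dataclass(frozen=True)
class BiasProtocol:
    """A named, ordered set of wall and steered bias terms."""

    name: str
    terms: tuple[tuple[str, Union[HarmonicWallSpec, SteeredSpec]], ...]

    def __len__(self) -> int:
        return len(self.terms)


def distance_inv(frame: ConformationFrame, spec: DistanceInvSpec,
                 topology: NucleosomeTopology | None = None) -> float:
    """Evaluate the weighted-minimum-distance CV (Å), overflow-safely.

    The sum of ||d_ij||^-n is evaluated in the log domain so that n = 100
    never overflows; coincident atoms across the groups make the CV 0 in
    the limit (warned).
    """
    g1 = _resolve(spec.group1, frame, topology)
    g2 = _resolve(spec.group2, frame, topology)
    a = frame.coords[g1]
    b = frame.coords[g2]
    diff = a[:, None, :] - b[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    if np.any(d2 <= 0):
        warnings.warn("coincident atoms across CV groups; distance_inv -> 0")
        return 0.0
    log_d = 0.5 * np.log(d2)
    log_sum = logsumexp(-spec.n * log_d.ravel())
    log_mean = log_sum - math.log(a.shape[0] * b.shape[0])
    return float(math.exp(-log_mean / spec.n))


def _switching(r: np.ndarray, n: int, m: int) -> np.ndarray:
    """(1 - r^n)/(1 - r^m), continuous at r = 1 (limit n/m)."""
    if m == 2 * n:
        return 1.0 / (1.0 + r ** n)
    out = np.empty_like(r)
    near1 = np.abs(r - 1.0) < 1e-9
    out[near1] = n / m
    rr = r[~near1]
    out[~near1] = (1.0 - rr ** n) / (1.0 - rr ** m)
    return out


def coordination_number(frame: ConformationFrame, spec: CoordinationSpec,
                        topology: NucleosomeTopology | None = None) -> float:
    """Evaluate the coordination-number CV (dimensionless)."""
    g1 = _resolve(spec.group1, frame, topology)
    g2 = _resolve(spec.group2, frame, topology)
    a = frame.coords[g1]
    b = frame.coords[g2]
    diff = a[:, None, :] - b[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff)) / spec.d0
    return float(_switching(r.ravel(), spec.n, spec.m).sum())


def evaluate_cv(frame: ConformationFrame, spec: CVSpec,
                topology: NucleosomeTopology | None = None) -> float:
    if isinstance(spec, DistanceInvSpec):
        return distance_inv(frame, spec, topology)
    return coordination_number(frame, spec, topology)


def wall_energy(value: float, spec: HarmonicWallSpec) -> float:
    """Harmonic-wall energy (kcal/mol): zero inside the allowed region."""
    delta = 0.0
    if spec.lower is not None and value < spec.lower:
        delta = spec.lower - value
    elif spec.upper is not None and value > spec.upper:
        delta = value - spec.upper
    return 0.5 * spec.k * delta * delta


def steered_center(t: float, spec: SteeredSpec) -> float:
    """Restraint-center position at time ``t`` (linear ramp, clamped)."""
    if t < 0:
        raise ValueError("negative time")
    frac = min(t / spec.duration, 1.0)
    return spec.start + frac * (spec.end - spec.start)


ACTIVE_ENERGY_TOL = 1e-6  # kcal/mol; a smooth C is never exactly zero


def evaluate_protocol(trajectory: TrajectoryHandle, protocol: BiasProtocol,
                      topology: NucleosomeTopology | None = None,
                      active_tol: float = ACTIVE_ENERGY_TOL,
                      ) -> pd.DataFrame:
    """Evaluate every bias term of a protocol over a trajectory.

    One row per frame per term: the CV value, the wall bound or steered
    target, the restraint energy, and whether the term is effectively
    active (energy above ``active_tol`` — a rational switching function
    never reaches exactly zero, so "C equal to 0" walls always carry a
    vanishing residual). Steered ramps use the frame time stamp (ns) when
    present, otherwise the frame index against a duration in frames.
    """
    rows = []
    for fr in trajectory:
        for term_name, term in protocol.terms:
            value = evaluate_cv(fr, term.variable, topology)
            if isinstance(term, HarmonicWallSpec):
                energy = wall_energy(value, term)
                target = term.lower if term.lower is not None else term.upper
                kind = "wall"
            else:
                if term.duration_unit == "ns" and fr.time_ns is not None:
                    t = fr.time_ns
                else:
                    t = float(fr.frame_index)
                target = steered_center(t, term)
                energy = 0.5 * term.k * (value - target) ** 2
                kind = "steered"
            rows.append({
                "frame": fr.frame_index, "term": term_name, "kind": kind,
                "cv_value": value, "target": target,
                "energy_kcal_mol": energy, "active": energy > active_tol,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Presets

def _tail_groups(side: str) -> tuple[str, str]:
    return ("tails:H3-A+H2A-A:CA", f"dna:outer_gyre_{side}:P")


def tail_release_preset(side: str = "3p",
                        k: float = DEFAULT_FORCE_CONSTANT) -> BiasProtocol:
    """Keep the H3/H2A-C tails off the outer DNA gyre.

    Harmonic walls hold the tail–outer-gyre minimum distance above 12 Å
    and the corresponding coordination number at 0.
    """
    t, g = _tail_groups(side)
    return BiasProtocol(name="tail_release", terms=(
        ("tails_outer_dmin_wall",
         HarmonicWallSpec(DistanceInvSpec(t, g), lower=12.0, k=k)),
        ("tails_outer_coord_wall",
         HarmonicWallSpec(CoordinationSpec(t, g), upper=0.0, k=k)),
    ))


def pou_hd_insertion_preset(side: str = "3p",
                            duration_ns: float = 250.0,
                            k: float = DEFAULT_FORCE_CONSTANT) -> BiasProtocol:
    """Steer the POU homeodomain in between the two DNA gyres.

    Three constant-velocity ramps over 250 ns move the homeodomain's
    minimum distance to the inner gyre from 5 to 15 Å, to the outer gyre
    from 32 to 12 Å, and to the 3' L-DNA from 58 to 28 Å; guard walls keep
    the tails off the outer gyre (δ_min > 30 Å, C = 0) and the two gyres
    apart (δ_min > 20 Å).
    """
    t, g = _tail_groups(side)
    hd = "tf:POU_HD:CA"
    return BiasProtocol(name="pou_hd_insertion", terms=(
        ("hd_inner_ramp",
         SteeredSpec(DistanceInvSpec(hd, "dna:inner_gyre:P"),
                     start=5.0, end=15.0, duration=duration_ns, k=k)),
        ("hd_outer_ramp",
         SteeredSpec(DistanceInvSpec(hd, f"dna:outer_gyre_{side}:P"),
                     start=32.0, end=12.0, duration=duration_ns, k=k)),
        ("hd_ldna_ramp",
         SteeredSpec(DistanceInvSpec(hd, f"dna:linker_{side}:P"),
                     start=58.0, end=28.0, duration=duration_ns, k=k)),
        ("tails_outer_dmin_wall",
         HarmonicWallSpec(DistanceInvSpec(t, g), lower=30.0, k=k)),
        ("tails_outer_coord_wall",
         HarmonicWallSpec(CoordinationSpec(t, g), upper=0.0, k=k)),
        ("intergyre_dmin_wall",
         HarmonicWallSpec(
             DistanceInvSpec("dna:inner_gyre:P", f"dna:outer_gyre_{side}:P"),
             lower=20.0, k=k)),
    ))


# ---------------------------------------------------------------------------
# Configuration text export / parse (Colvars-style dialect)

def _group_token(group: Group) -> str:
    if isinstance(group, str):
        return group
    return "indices " + ",".join(str(i) for i in np.nonzero(group)[0])


def _emit_variable(name: str, spec: CVSpec, lines: list[str]) -> None:
    lines.append("colvar {")
    lines.append(f"    name {name}")
    if isinstance(spec, DistanceInvSpec):
        lines.append("    distanceInv {")
        lines.append(f"        exponent {spec.n}")
    else:
        lines.append("    coordNum {")
        lines.append(f"        cutoff {spec.d0:g}")
        lines.append(f"        expNumer {spec.n}")
        lines.append(f"        expDenom {spec.m}")
    lines.append(f"        group1 {{ {_group_token(spec.group1)} }}")
    lines.append(f"        group2 {{ {_group_token(spec.group2)} }}")
    lines.append("    }")
    lines.append("}")


def export_bias_config(protocol: BiasProtocol) -> str:
    """Serialize a protocol as deterministic Colvars-style configuration text."""
    lines = [f"# bias protocol: {protocol.name}"]
    for term_name, term in protocol.terms:
        cv_name = f"{term_name}_cv"
        _emit_variable(cv_name, term.variable, lines)
        if isinstance(term, HarmonicWallSpec):
            lines.append("harmonicWalls {")
            lines.append(f"    name {term_name}")
            lines.append(f"    colvars {cv_name}")
            if term.lower is not None:
                lines.append(f"    lowerWalls {term.lower:g}")
            if term.upper is not None:
                lines.append(f"    upperWalls {term.upper:g}")
            lines.append(f"    forceConstant {term.k:g}")
            lines.append("}")
        else:
            lines.append("harmonic {")
            lines.append(f"    name {term_name}")
            lines.append(f"    colvars {cv_name}")
            lines.append(f"    forceConstant {term.k:g}")
            lines.append(f"    centers {term.start:g}")
            lines.append(f"    targetCenters {term.end:g}")
            lines.append(
                f"    targetDuration {term.duration:g} {term.duration_unit}")
            lines.append("}")
    return "\n".join(lines) + "\n"


def _parse_blocks(text: str):
    """Yield (kind, dict-of-fields) for each top-level block."""
    tokens = text.splitlines()
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        kind = line.split("{")[0].strip()
        fields: dict[str, str] = {}
        depth = line.count("{") - line.count("}")
        stack = [fields]
        while depth > 0 and i < len(tokens):
            ln = tokens[i].strip()
            i += 1
            opens, closes = ln.count("{"), ln.count("}")
            if opens and opens == closes:     # inline sub-block: group spec
                key, rest = ln.split("{", 1)
                stack[-1][key.strip()] = rest.rsplit("}", 1)[0].strip()
            elif opens:
                key = ln.split("{")[0].strip()
                sub: dict[str, str] = {"__kind__": key}
                stack[-1][key] = sub  # type: ignore[assignment]
                stack.append(sub)
            elif closes:
                if len(stack) > 1:
                    stack.pop()
            elif ln:
                key, _, val = ln.partition(" ")
                stack[-1][key] = val.strip()
            depth += opens - closes
        yield kind, fields


def parse_bias_config(text: str) -> BiasProtocol:
    """Parse configuration text produced by :func:`export_bias_config`."""
    header = text.splitlines()[0]
    name = header.split(":", 1)[1].strip() if ":" in header else "protocol"
    variables: dict[str, CVSpec] = {}
    terms: list[tuple[str, Union[HarmonicWallSpec, SteeredSpec]]] = []
    for kind, fields in _parse_blocks(text):
        if kind == "colvar":
            if "distanceInv" in fields:
                sub = fields["distanceInv"]
                spec: CVSpec = DistanceInvSpec(
                    sub["group1"], sub["group2"], n=int(sub["exponent"]))
            else:
                sub = fields["coordNum"]
                spec = CoordinationSpec(
                    sub["group1"], sub["group2"], d0=float(sub["cutoff"]),
                    n=int(sub["expNumer"]), m=int(sub["expDenom"]))
            variables[fields["name"]] = spec
        elif kind == "harmonicWalls":
            terms.append((fields["name"], HarmonicWallSpec(
                variables[fields["colvars"]],
                lower=float(fields["lowerWalls"])
                if "lowerWalls" in fields else None,
                upper=float(fields["upperWalls"])
                if "upperWalls" in fields else None,
                k=float(fields["forceConstant"]))))
        elif kind == "harmonic":
            dur, unit = fields["targetDuration"].split()
            terms.append((fields["name"], SteeredSpec(
                variables[fields["colvars"]],
                start=float(fields["centers"]),
                end=float(fields["targetCenters"]),
                duration=float(dur), duration_unit=unit,
                k=float(fields["forceConstant"]))))
    return BiasProtocol(name=name, terms=tuple(terms))
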