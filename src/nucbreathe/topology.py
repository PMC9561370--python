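"""Nucleosome topology: chains, DNA regions, histone tails, TF subdomains.

The topology is the single source of truth for every atom-group definition
used downstream: which base pairs belong to the wrapped core versus the
linker arms (L-DNA), which belong to the inner gyre versus the two outer
gyres, which histone residues are disordered tails, and where the two
DNA-binding subdomains of a pioneer transcription factor (POU-specific
domain and POU homeodomain for Oct4) sit on their chain.

Conventions
-----------
Base pairs are indexed 0-based half-open internally; user-facing
configuration and reports use 1-based inclusive ranges, matching the
residue-numbering convention of structural biology. Base pair ``i`` on the
reference strand pairs with residue ``n_bp - 1 - i`` on the complementary
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "NucleosomeTopology",
    "RegionMap",
    "TAIL_PRESETS",
    "build_topology",
    "load_topology",
    "classify_dna_regions",
    "tail_residues",
    "partition_dna_atoms",
]

# Histone-tail residue ranges (1-based inclusive) per species preset.
# H2A carries both an N-terminal and a C-terminal ("H2AC") tail.
TAIL_PRESETS: dict[str, dict[str, tuple[tuple[int, int], ...]]] = {
    "human": {
        "H3": ((1, 45),),
        "H4": ((1, 32),),
        "H2A": ((1, 18), (119, 129)),
        "H2B": ((1, 33),),
    },
    "drosophila": {
        "H3": ((1, 45),),
        "H4": ((1, 32),),
        "H2A": ((1, 17), (116, 124)),
        "H2B": ((1, 31),),
    },
}

HISTONE_TYPES = ("H3", "H4", "H2A", "H2B")
TF_SUBDOMAIN_NAMES = ("POU_S", "POU_HD", "linker")

# Heavy-atom backbone names for standard nucleotides: the phosphate group
# plus the full (deoxy)ribose, including C1'. Glycosidic nitrogens and all
# remaining heavy atoms belong to the base.
_BACKBONE_ATOMS = {
    "P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
    # PDB v2 primed-as-star aliases
    "O5*", "C5*", "C4*", "O4*", "C3*", "O3*", "C2*", "O2*", "C1*",
}

_BASE_ATOMS = {
    "N1", "C2", "N2", "O2", "N3", "C4", "N4", "O4", "C5", "C5M", "C6",
    "N6", "O6", "N7", "C8", "N9",
}


class TopologyError(ValueError):
    """Raised when a region configuration is inconsistent."""


@dataclass(frozen=True)
class RegionMap:
    """Two exact partitions of the base pairs plus tail/globular labels.

    ``core``/``linker_5p``/``linker_3p`` partition all base pairs into the
    wrapped core and the two linker arms; ``inner_gyre``/``outer_gyre_5p``/
    ``outer_gyre_3p`` independently partition them into the central gyre and
    the two terminal gyres. All members are 0-based base-pair indices.
    """

    core: tuple[int, ...]
    linker_5p: tuple[int, ...]
    linker_3p: tuple[int, ...]
    inner_gyre: tuple[int, ...]
    outer_gyre_5p: tuple[int, ...]
    outer_gyre_3p: tuple[int, ...]

    def region_of(self, bp: int) -> str:
        if bp in self._core_set:
            return "core"
        return "linker_5p" if bp in set(self.linker_5p) else "linker_3p"

    @property
    def _core_set(self) -> frozenset[int]:
        return frozenset(self.core)


@dataclass(frozen=True)
class NucleosomeTopology:
    """Chain/residue role map for one nucleosome (optionally TF-bound)."""

    n_bp: int
    #: chain ID -> role; DNA roles are "DNA_I" (reference strand, 5'->3')
    #: and "DNA_J"; histone roles carry a copy index, e.g. "H3-A".
    chain_map: Mapping[str, str]
    #: per-strand ordered residue numbers; strand I runs 5'->3' on the
    #: reference strand, strand J is stored in pairing order (J[i] pairs I[i]).
    dna_strands: tuple[tuple[int, ...], tuple[int, ...]]
    species: str = "human"
    #: histone type ("H3") -> tail ranges, 1-based inclusive.
    tail_ranges: Mapping[str, tuple[tuple[int, int], ...]] = field(
        default_factory=dict
    )
    #: TF subdomain name -> (first, last) residue, 1-based inclusive.
    tf_subdomains: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    core_size: int = 146
    #: outer-gyre size per DNA end (bp).
    outer_gyre_size: int = 40

    def __post_init__(self) -> None:
        s1, s2 = self.dna_strands
        if len(s1) != len(s2):
            raise TopologyError(
                f"DNA strands have mismatched lengths {len(s1)} vs {len(s2)}"
            )
        if self.n_bp != len(s1):
            raise TopologyError(
                f"n_bp={self.n_bp} does not match strand length {len(s1)}"
            )

    @property
    def dna_chains(self) -> tuple[str, str]:
        """(strand I chain, strand J chain)."""
        inv = {role: ch for ch, role in self.chain_map.items()}
        return inv["DNA_I"], inv["DNA_J"]

    @property
    def histone_chains(self) -> dict[str, str]:
        """role (e.g. 'H3-A') -> chain ID for every histone chain."""
        return {
            role: ch
            for ch, role in self.chain_map.items()
            if role.split("-")[0] in HISTONE_TYPES
        }

    @property
    def tf_chain(self) -> str | None:
        for ch, role in self.chain_map.items():
            if role == "TF":
                return ch
        return None

    def paired_residues(self, bp: int) -> tuple[int, int]:
        """Residue numbers (strand I, strand J) forming base pair ``bp``."""
        return self.dna_strands[0][bp], self.dna_strands[1][bp]


def _as_range_list(value) -> tuple[tuple[int, int], ...]:
    """Normalize '1-45' / [1, 45] / [[1,18],[119,129]] into range tuples."""
    if isinstance(value, str):
        parts = value.replace("–", "-").split(",")
        return tuple(
            tuple(int(x) for x in p.strip().split("-"))  # type: ignore[misc]
            for p in parts
        )
    value = list(value)
    if value and isinstance(value[0], int):
        return ((value[0], value[1]),)
    return tuple((int(a), int(b)) for a, b in value)


def build_topology(config: Mapping) -> NucleosomeTopology:
    """Build and validate a :class:`NucleosomeTopology` from a config mapping.

    The configuration document has keys ``chains`` (chain ID -> role),
    ``species`` (``human`` | ``drosophila`` | ``custom``), optional
    ``tails`` (required for ``custom``), optional ``regions``
    (``core_size``, ``outer_gyre_size``) and optional ``tf_subdomains``.
    DNA strand residue numbering may be given per chain under
    ``dna_residues``; by default residues are numbered 1..n_bp per strand.
    """
    chains = dict(config["chains"])
    species = str(config.get("species", "human"))
    if species not in ("human", "drosophila", "custom"):
        raise TopologyError(f"unknown species preset {species!r}")

    roles = list(chains.values())
    for role in roles:
        base = role.split("-")[0]
        if base not in HISTONE_TYPES and role not in ("DNA_I", "DNA_J", "TF"):
            raise TopologyError(f"unknown chain role {role!r}")
    dup = {r for r in roles if roles.count(r) > 1}
    if dup:
        raise TopologyError(f"duplicate chain roles: {sorted(dup)}")
    for strand_role in ("DNA_I", "DNA_J"):
        if strand_role not in roles:
            raise TopologyError(f"missing DNA strand role {strand_role}")

    n_bp = int(config.get("n_bp", 168))
    dna_res = config.get("dna_residues", {})
    inv = {role: ch for ch, role in chains.items()}
    strands = []
    for strand_role in ("DNA_I", "DNA_J"):
        ch = inv[strand_role]
        if ch in dna_res:
            strands.append(tuple(int(r) for r in dna_res[ch]))
        else:
            strands.append(tuple(range(1, n_bp + 1)))
    if len(strands[0]) != len(strands[1]):
        raise TopologyError(
            "DNA strands have mismatched lengths "
            f"{len(strands[0])} vs {len(strands[1])}"
        )
    n_bp = len(strands[0])

    if species == "custom":
        if "tails" not in config:
            raise TopologyError("species=custom requires explicit 'tails'")
        tails = {
            h: _as_range_list(v) for h, v in dict(config["tails"]).items()
        }
    else:
        tails = dict(TAIL_PRESETS[species])
        for h, v in dict(config.get("tails", {})).items():
            tails[h] = _as_range_list(v)

    tf_sub = {}
    for name, rng in dict(config.get("tf_subdomains", {})).items():
        if name not in TF_SUBDOMAIN_NAMES:
            raise TopologyError(f"unknown TF subdomain {name!r}")
        (lo, hi), = _as_range_list(rng)
        tf_sub[name] = (lo, hi)

    regions = dict(config.get("regions", {}))
    topo = NucleosomeTopology(
        n_bp=n_bp,
        chain_map=chains,
        dna_strands=(strands[0], strands[1]),
        species=species,
        tail_ranges=tails,
        tf_subdomains=tf_sub,
        core_size=int(regions.get("core_size", 146)),
        outer_gyre_size=int(regions.get("outer_gyre_size", 40)),
    )
    # validate region arithmetic eagerly
    classify_dna_regions(topo)
    return topo


def load_topology(path) -> NucleosomeTopology:
    """Read a YAML region-configuration file and build the topology."""
    with open(path) as fh:
        return build_topology(yaml.safe_load(fh))


def classify_dna_regions(
    topology: NucleosomeTopology,
    core_size: int | None = None,
    outer_gyre_size: int | None = None,
) -> RegionMap:
    """Partition base pairs into core/linkers and inner/outer gyres.

    The core is centered on the dyad (for even sizes, split equally around
    the midpoint between the two central base pairs); the remaining base
    pairs at the 5' and 3' ends are the linker arms. Independently, the
    terminal ``outer_gyre_size`` base pairs at each end form the outer
    gyres and the central remainder the inner gyre. Any odd leftover base
    pair goes to the 5' side.
    """
    n = topology.n_bp
    core = core_size if core_size is not None else topology.core_size
    outer = (
        outer_gyre_size
        if outer_gyre_size is not None
        else topology.outer_gyre_size
    )
    if core > n:
        raise TopologyError(f"core size {core} exceeds n_bp={n}")
    if 2 * outer > n:
        raise TopologyError(f"outer gyres 2x{outer} exceed n_bp={n}")

    n_link = n - core
    link_3p = n_link // 2
    link_5p = n_link - link_3p  # odd leftover to the 5' side
    idx = range(n)
    return RegionMap(
        linker_5p=tuple(idx[:link_5p]),
        core=tuple(idx[link_5p : link_5p + core]),
        linker_3p=tuple(idx[link_5p + core :]),
        outer_gyre_5p=tuple(idx[:outer]),
        inner_gyre=tuple(idx[outer : n - outer]),
        outer_gyre_3p=tuple(idx[n - outer :]),
    )


def tail_residues(topology: NucleosomeTopology) -> dict[str, frozenset[int]]:
    """Tail residue sets per histone role (e.g. ``{"H3-A": {1..45}, ...}``).

    Residue numbers are 1-based; an empty mapping of tail ranges yields a
    tail-less ("TL") nucleosome in which every histone residue is globular.
    """
    out: dict[str, frozenset[int]] = {}
    for role in topology.histone_chains:
        htype = role.split("-")[0]
        residues: set[int] = set()
        for lo, hi in topology.tail_ranges.get(htype, ()):
            if hi < lo:
                raise TopologyError(f"invalid tail range {lo}-{hi} for {htype}")
            residues.update(range(lo, hi + 1))
        out[role] = frozenset(residues)
    return out


def partition_dna_atoms(atom_name: str, strict: bool = False) -> str:
    """Classify a heavy nucleotide atom name as ``"base"`` or ``"backbone"``.

    Phosphate and sugar atoms (including C1') are backbone; nucleobase
    atoms, including the glycosidic nitrogen, are base. Hydrogens are
    rejected — contact groups exclude them before calling this.
    Unrecognized names fall back to ``"backbone"`` unless ``strict``.
    """
    name = atom_name.strip().upper()
    if not name:
        raise ValueError("empty atom name")
    if name.startswith("H") or (name[0].isdigit() and "H" in name):
        raise ValueError(f"hydrogen atom {atom_name!r} has no base/backbone class")
    if name in _BACKBONE_ATOMS:
        return "backbone"
    if name in _BASE_ATOMS or name == "C7":  # C7 = thymine methyl (PDB v3)
        return "base"
    if strict:
        raise ValueError(f"unrecognized DNA atom name {atom_name!r}")
    return "backbone"
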