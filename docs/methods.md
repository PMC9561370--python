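# Methods

`nucbreathe` quantifies nucleosome breathing and pioneer-factor–nucleosome
interactions the way atomistic MD studies of Oct4-bound nucleosomes do,
but on any topology-labelled ensemble of conformations, including the
package's own synthetic nucleosomes with exact ground truth. This note
records the models, the conventions where several were defensible, the
numerical choices, and what the synthetic benchmark does and does not
demonstrate about real trajectories.

## Topology and region model

A nucleosome construct of `n_bp` base pairs (default 168) is described by
a chain→role map: two DNA strands (the reference strand stored 5'→3',
base pair *i* pairing residue *n_bp − 1 − i* of the complement), eight
histone chains carrying a copy index (`H3-A`, `H3-B`, …), and optionally
one transcription-factor chain with named subdomains (`POU_S`, `POU_HD`,
and their interdomain linker).

Two independent base-pair partitions drive every observable:

- **core / linkers** — 146 bp centered on the dyad are the wrapped core;
  the remaining 11 bp at each end are the linker arms (L-DNA). For an
  even core the dyad is the midpoint between the two central base pairs
  and the core splits 73/73 around it; a single odd leftover base pair is
  assigned to the 5' side.
- **gyres** — the terminal 40 bp at each end are the outer gyres, the
  central 88 bp the inner gyre.

Histone-tail presets (1-based inclusive ranges): human H3 1–45, H4 1–32,
H2A 1–18 and 119–129 (the C-terminal "H2AC" tail), H2B 1–33; *Drosophila*
H3 1–45, H4 1–32, H2A 1–17 and 116–124, H2B 1–31. A `custom` preset takes
explicit ranges; an empty range set yields a tail-less (TL) construct.

DNA heavy atoms partition into **backbone** (phosphate plus the full
sugar, including C1') and **base** (everything else, including the
glycosidic nitrogen). Sugar atoms are conventionally part of the
phosphodiester backbone; placing C1' there keeps the partition an exact
tiling of every standard nucleotide template. Hydrogens are excluded from
all contact and CV groups.

## Geometry

Frames are rigid-body fitted (Kabsch, via `scipy`'s rotation alignment)
to a reference over the Cα trace of the globular (non-tail) histone core,
so downstream angles measure DNA motion relative to the histones.

The **dyad frame** is built once from the reference: origin at the
central core base-pair midpoint; X the unit vector from the core-DNA
centroid to the origin; Z the core winding axis orthogonalized against X;
Y = Z × X. The winding axis is estimated as the polygon normal of the
ordered per-base-pair path, Σᵢ (pᵢ−c) × (pᵢ₊₁−c) — exact for planar
circles and aligned with the superhelical axis to a few degrees on ideal
1.65-turn geometry. A least-squares plane normal is available as an
option (`normal_method="plane_fit"`) but sits several degrees further
from the axis, because the axial rise of a fractional-turn helix tilts
the best-fit plane; the polygon normal is therefore the default.

Each linker arm defines an outward unit vector **v**: by default the
principal axis of all heavy atoms of the arm (total least squares),
oriented from the core-proximal toward the terminal base pair; an
endpoint-difference variant exists. Using all heavy atoms rather than the
phosphate trace matters under coordinate noise — the direction error of
the fit scales with the transverse atom spread over √N, and the full atom
complement roughly halves it.

Breathing angles, in degrees:

- γ₁ = signed angle in the XZ plane from Z to the projection of **v**
  (positive = rotation about +Y);
- γ₂ = signed angle in the XY plane from Y to the projection of **v**
  (positive = rotation about +Z).

The positive senses are this package's convention (sign conventions for
signed breathing angles are not standardized); `gamma_sign` flips either
axis for matching external data. A projection with norm below 10⁻⁶ is
reported NaN for that frame.

DNA compactness is the mass-weighted radius of gyration
Rg = √(Σmᵢ‖rᵢ−r̄‖²/Σmᵢ) over DNA heavy atoms. The inter-gyre separation
is the minimal P–P distance between the inner gyre and one outer gyre
after trimming 10 bp on each side of their covalent junction — without
the trim the minimum is always the backbone bond at the region boundary.

Periodic images are assumed resolved before analysis (whole-molecule
coordinates); the package performs no wrapping.

## Contacts

A contact is two non-hydrogen atoms strictly closer than 4.5 Å. Counts
are reported per unordered atom pair or per (residue, base pair); a
residue–base-pair contact is **stable** when present in strictly more
than 75% of the analyzed frames (0.750 is not stable, 0.751 is). The
frame window and stride are explicit arguments — no implicit
equilibration trimming. Neighbor search uses a k-d tree with an explicit
strict-inequality filter, so counts are bit-identical to a brute-force
O(N²) scan (asserted in the tests). Per-simulation tables summarize TF
subdomain × DNA-part (bases vs backbone) × gyre contact series as the
median with 5th–95th percentiles.

## Collective variables and bias protocols

Two CVs over Cα (protein) / P (DNA) trace groups by default:

- **distanceInv**: d⁽ⁿ⁾ = [ (1/N₁N₂) Σᵢⱼ ‖dᵢⱼ‖⁻ⁿ ]^(−1/n), an even-n
  soft minimum, evaluated in the log domain (via `logsumexp`) so n = 100
  cannot overflow. Coincident atoms across groups give 0 with a warning.
  Note an exact consequence of the normalization: d⁽ⁿ⁾ ≥ d_min, with
  d⁽ⁿ⁾ = d_min·(N₁N₂/k_eff)^(1/n) where k_eff counts near-minimal pairs.
  At n = 100 and 50×50 groups this is an ≈8% systematic excess above the
  true minimum — the CV tracks the minimum's *motion* faithfully but
  carries a size-dependent offset, which is worth remembering when
  placing wall positions.
- **coordination number**: C = Σᵢⱼ (1−rⁿ)/(1−rᵐ) with r = ‖xᵢ−xⱼ‖/d₀,
  d₀ = 4.0 Å, n = 6, m = 12. With m = 2n the ratio is evaluated as the
  singularity-free 1/(1+rⁿ), continuous with C-per-pair = ½ at r = 1.

Restraints: harmonic walls E = (k/2)Δ² with Δ the bound-violation depth
(the ½ prefactor is this package's stated convention; k = 10
kcal·mol⁻¹·Å⁻² by default), and steered restraints whose center moves
linearly from start to end over a fixed duration (250 ns default),
clamping afterwards. A "C equal to 0" wall is an upper wall at 0; since a
rational switching function never reaches exactly zero, a wall is flagged
"effectively active" only above 10⁻⁶ kcal/mol.

Two presets cover the standard protocols: `tail_release` (walls keeping the
H3/H2AC-tail–outer-gyre δ_min > 12 Å and the matching C at 0) and
`pou_hd_insertion` (three 250-ns ramps moving the homeodomain's δ_min to
the inner gyre 5→15 Å, to the outer gyre 32→12 Å, and to the 3' L-DNA
58→28 Å, guarded by walls: tails–outer-gyre δ_min > 30 Å, C = 0, and
inter-gyre δ_min > 20 Å). Protocols export as deterministic Colvars-style
text with symbolic group names and re-import losslessly.

## Synthetic nucleosomes and ground truth

The generator emulates the study systems geometrically: DNA as two
complementary pseudo-strands with a full 17-heavy-atom nucleotide
template (phosphate + sugar + six-atom base proxy at B-DNA-like radii,
36°/bp twist) wound on a canonical superhelix — radius 41.9 Å, pitch
25.9 Å, 1.65 turns across the 146-bp core — with straight 11-bp arms; a
rigid pseudo-histone core of Cα beads with human-preset tail beads that
are either wrapped onto an outer gyre (guaranteed backbone-proximal
placement) or released far from all DNA; and an optional two-domain
pseudo-TF (specific domain on the bases of its site window; second
domain free, on the inner gyre, or bridging the stacked gyres at the
midpoint of their closest backbone atoms).

Trajectories realize an opening schedule by rotating each arm rigidly
about the dyad-frame Y and Z axes through its attachment point; the
rotation sense that geometrically opens each arm (moves it away from the
wrap, monotonically increasing DNA Rg over the 0–40° range used) is +Y/+Z
for the 5' arm and −Y/−Z for the 3' arm. Ground truth records, per frame:
the analytic arm angles (the closed arm's observable axis — the principal
axis of its heavy atoms — propagated through the exact schedule
rotations), tail–outer-gyre contact counts from the generator's own
direct distance scans (independent of the k-d-tree path), TF contact
counts per subdomain/part/gyre, and event frames. Optional Gaussian
coordinate noise and random rigid motions exercise the noise and
superposition paths; all randomness derives from one seed and equal seeds
give byte-identical structures.

Benchmark sizes were chosen to keep the full suite fast while leaving no
statistical ambiguity: 500-frame trajectories for recovery (γ exact to
machine precision noise-free; worst-case per-frame error ≈1.5–1.8° at
σ = 1 Å), 100 seeded configurations for each oracle-equality property.

**What the synthetic benchmark does not show.** The generator has no
energetics: DNA is rigid between scheduled rotations, tails are geometric
bead walks, the TF does not move, and noise is isotropic and
uncorrelated. Passing tests therefore demonstrate that the measurement
pipeline recovers imposed geometry and counts exactly — not that the
observables are statistically converged or force-field-faithful on real
trajectories. Real MD adds correlated fluctuations, partial unwrapping
not describable by two rigid arm rotations, and conformational
heterogeneity in the fit selection; the superposition and line-fit
estimators degrade gracefully under such conditions but their errors must
be judged against controls like the σ = 1 Å benchmark here.

## Numerical choices

- Percentiles: linear interpolation (type 7), stated because reporting
  conventions differ at small n.
- Histograms: 1° bins over (−180°, 180°]², contour levels {1, 100}
  counts; per-ensemble grids are kept separate for overlays and pooled
  only on request; arms are binned separately by default.
- Contact cutoff comparisons are strict (`<`), stability strict (`>`),
  making the 0.750/0.751 edge well defined.
- distanceInv log-domain evaluation; coordination factorized at m = 2n.
- RMSD from scipy's `align_vectors` residual; degenerate inputs
  (collinear DNA paths, coincident linker points, zero-mass selections)
  raise rather than warn.

## Known limitations

- The dyad-frame origin uses phosphate midpoints of the central base
  pairs; a different origin choice shifts γ₂ by fractions of a degree on
  ideal geometry.
- `distanceInv` carries the (N₁N₂)^(1/n) normalization offset discussed
  above.
- DCD/XTC reading requires a separate topology-bearing structure with
  matching atom count; PSF/prmtop topologies are not parsed.
- The stable-contact rule is evaluated per residue–base-pair by default;
  per-atom-pair stability exists behind a flag but the two are not
  interchangeable on sparse contacts.
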