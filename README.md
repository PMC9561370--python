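# nucbreathe

Quantitative analysis of nucleosome breathing and pioneer
transcription-factor–nucleosome interactions from molecular-dynamics
ensembles — for structural bioinformaticians who need the standard
observables of Oct4–nucleosome-style MD studies as tested, reusable
code rather than one-off trajectory scripts.

A nucleosome wraps ~146 bp of DNA around a histone octamer; the flanking
linker DNA (L-DNA) spontaneously detaches and re-attaches ("breathing"),
and pioneer factors such as Oct4 bind their motifs on the wrapped DNA and
modulate that motion. The package measures this with the field's standard
toolkit:

- **Breathing angles** γ₁/γ₂: each linker arm's outward vector **v** is
  projected in a dyad-anchored orthonormal frame (X toward the dyad,
  Z along the superhelical axis, Y = Z × X);
  γ₁ = ∠(proj_XZ **v**, Z) captures out-of-plane opening and
  γ₂ = ∠(proj_XY **v**, Y) in-plane opening, both signed, per arm.
- **Compactness**: mass-weighted DNA radius of gyration
  Rg = √(Σmᵢ‖rᵢ−r̄‖²/Σmᵢ), after rigid-body fitting each frame to a
  reference over the globular histone core.
- **Contacts**: heavy-atom pairs closer than 4.5 Å, per atom pair or per
  (residue, base pair); a residue–base-pair contact is *stable* if
  present in more than 75% of frames. Tables per TF subdomain
  (POU-specific vs POU-homeodomain) × DNA bases/backbone × inner/outer
  gyre, reported as median (5th–95th percentile).
- **Collective variables & bias protocols**: the weighted-minimum
  distance d⁽ⁿ⁾ = [(1/N₁N₂)Σ‖dᵢⱼ‖⁻ⁿ]^(−1/n) (n = 100) and the
  coordination number C = Σ(1−r⁶)/(1−r¹²), r = d/4.0 Å, with harmonic
  walls E = (k/2)Δ² and constant-velocity steered ramps, including the
  tail-release and homeodomain-insertion protocol presets, exportable as
  Colvars-style configuration text.
- **Synthetic nucleosomes**: a generator producing idealized 168-bp
  nucleosomes (146-bp core on a canonical 41.9 Å/25.9 Å/1.65-turn
  superhelix, 11-bp arms, pseudo-histone core, tails, optional two-domain
  pseudo-TF) and breathing trajectories with exact per-frame ground
  truth, standing in for microsecond MD deposits.

Standard formats are read through MDAnalysis (PDB, mmCIF, multi-model
PDB, DCD, XTC); outputs are tidy CSV.

## Worked example

Generate a noisy opening trajectory, recover its geometry, and summarize:

```python
import nucbreathe as nb

sched = {"3p": nb.make_linear_schedule(300, 40.0, 15.0),
         "5p": nb.make_linear_schedule(300, 30.0, 10.0)}
ens = nb.generate_breathing_trajectory(
    nb.SyntheticParams(frames=300, schedule=sched, noise_sigma=0.5,
                       seed=2027))
series = nb.analyze_trajectory(ens.trajectory, ens.topology, ens.reference)
s = nb.summarize_series(series["rg_A"])
print("Rg:", nb.format_summary(s))
```

The same pipeline is scripted in `analysis/` (numbered drivers writing
tables to `results/`). `analysis/02_breathing_geometry.py` prints, for a
closed (thermal noise only) versus an opening ensemble:

```
closed   rg_A             45.6 (45.6–45.6)
closed   gamma1_3p_deg    76.8 (76.5–77.3)
opening  rg_A             46.1 (45.6–46.4)
opening  gamma1_3p_deg    58.7 (43.4–75.1)
opening  gamma1_3p recovery max error: 0.69°
```

Reading: the closed 3' arm sits at γ₁ ≈ 77° in this frame convention with
a 45.6 Å DNA Rg (inside the 45–55 Å envelope of free-nucleosome
simulations); driving the arm open by 40° widens the γ₁ distribution to a
43–75° span and raises Rg, and the measured per-frame angles track the
generator's ground truth to under a degree at 0.5 Å coordinate noise.
The "median (p5–p95)" cells follow the reporting convention of
per-simulation MD tables.

A command-line interface covers the same steps
(`nucbreathe fixture | analyze | contacts | colvar | report`), each run
writing a JSON manifest of its parameters:

```sh
nucbreathe fixture --seed 7 --frames 50 --open-gamma1 25 --out-dir fx
nucbreathe analyze --topology-config fx/topology.yaml \
    --reference fx/reference.pdb --trajectory fx/trajectory.pdb \
    --out-dir out
nucbreathe report --series out/geometry_series.csv --column rg_A
```

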