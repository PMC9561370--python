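#!/usr/bin/env python
"""Histone tail–DNA contact persistence with and without a release event.

Counts per-frame heavy-atom contacts between the H3/H2A-C tails and the
3' outer DNA gyre, and computes the residue–base-pair stable-contact
profile (stable = present in more than 75% of frames) for a stably
wrapped ensemble and for one whose tails release mid-run.

Writes results/tail_contact_series.csv and
results/tail_stable_profile_{wrapped,releasing}.csv.
"""

from pathlib import Path

import nucbreathe as nb
from nucbreathe.contacts import ContactSpec, contact_series, \
    stable_contact_profile
from nucbreathe.selections import dna_mask, tail_mask
from nucbreathe.structure_io import write_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2026
FRAMES = 200


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ensembles = {
        "wrapped": nb.generate_breathing_trajectory(nb.SyntheticParams(
            frames=FRAMES, noise_sigma=0.3, seed=SEED)),
        "releasing": nb.generate_breathing_trajectory(nb.SyntheticParams(
            frames=FRAMES, noise_sigma=0.3, tail_release_frame=60,
            seed=SEED)),
    }
    rows = []
    for name, ens in ensembles.items():
        topo = ens.topology
        rm = nb.classify_dna_regions(topo)
        tails = tail_mask(ens.reference, topo, roles=["H3-A", "H2A-A"])
        outer = dna_mask(ens.reference, topo, bps=rm.outer_gyre_3p)
        series = contact_series(ens.trajectory,
                                ContactSpec(tails, outer))
        rows += [{"ensemble": name, "frame": i, "contacts": int(c)}
                 for i, c in enumerate(series.counts)]
        prof = stable_contact_profile(ens.trajectory, tails, outer, topo)
        long = prof.to_dataframe()
        write_table(long[long.occupancy > 0],
                    OUT / f"tail_stable_profile_{name}.csv")
        n_stable = int(prof.stable.sum())
        print(f"{name:10s} first/last frame contacts: "
              f"{series.counts[0]}/{series.counts[-1]}; "
              f"stable residue–bp pairs: {n_stable} "
              f"(occupancy max {prof.occupancy.max():.2f})")
    write_table(rows, OUT / "tail_contact_series.csv")
    print(f"\nwrote {OUT / 'tail_contact_series.csv'}")


if __name__ == "__main__":
    main()
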