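#!/usr/bin/env python
"""SASA contact analysis and NIMS detection on constructed configurations.

Builds a clustered configuration with known components (sizes 4, 3, 2 and
two singletons, one cluster containing protein-flagged molecules), runs the
excluded-SASA contact series, the strict 0.48 Ų contact-time statistics,
and the contact-graph component tracking, and writes the per-molecule
contact table and the NIMS track summary under results/.
"""

from pathlib import Path

import numpy as np

from cytosolkit.model import Trajectory
from cytosolkit.nims import components_and_tracks, tracks_summary
from cytosolkit.sasa_contact import (
    contact_area_series,
    contact_stats,
    contact_summary,
    total_sasa_trace,
)
from cytosolkit.synthetic import gen_cluster_config, gen_contact_timeline

OUT = Path(__file__).parent.parent / "results"
SEED = 2026


def main():
    OUT.mkdir(exist_ok=True)
    topo, coords, clusters = gen_cluster_config(
        [4, 3, 2, 1, 1], separation=22.0, spacing=3.0,
        protein_clusters=(1,),
    )
    n_frames = 6
    rng = np.random.default_rng(SEED)
    # small thermal jitter that never breaks or makes contacts
    frames = coords[None] + rng.normal(0.0, 0.05, (n_frames, len(coords), 3))
    from cytosolkit.model import SimulationCell
    cell = SimulationCell.cubic(120.0)
    traj = Trajectory(np.arange(n_frames) * 4.0, frames, cell)

    series = contact_area_series(traj, topo)
    summary = contact_summary(series)
    summary["species"] = [topo.molecules[m].species
                          for m in series.molecule_ids]
    summary.to_csv(OUT / "contact_summary.tsv", sep="\t", index=False)

    tracks, sizes = components_and_tracks(traj, topo, mode="distance")
    tsum = tracks_summary(tracks, traj.dt)
    tsum.to_csv(OUT / "nims_tracks.tsv", sep="\t", index=False)

    trace = total_sasa_trace(traj, topo, window_ps=8.0)

    stats = contact_stats(gen_contact_timeline([0.5, 0.5, 0.4, 0.6], dt=4.0))

    print("Ground-truth clusters:", [len(c) for c in clusters])
    print("NIMS tracks detected:")
    print(tsum.to_string(index=False))
    print(f"\nClustered molecules in contact "
          f"{summary.percent_contact_time[summary.percent_contact_time > 0].mean():.0f}% "
          "of frames; singletons 0%.")
    print(f"Total non-water SASA (flat jittered config): "
          f"{trace.total.mean():.0f} ± {trace.total.std():.0f} Ų, "
          f"running-average loss {trace.percent_loss:.2f}%")
    print(f"Hand timeline [0.5, 0.5, 0.4, 0.6] Ų at the 0.48 Ų threshold: "
          f"{stats.percent_in_contact:.0f}% in contact, events "
          f"{[l for _, l in stats.contact_events]} frames, "
          f"mean {stats.mean_contact_ps:.0f} ps, max {stats.max_contact_ps:.0f} ps")


if __name__ == "__main__":
    main()
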