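#!/usr/bin/env python
"""Diffusion-coefficient recovery on Brownian ensembles with known D.

Generates ideal Brownian species spanning the diffusivity range of small
metabolites (0.1–1.0 Å²/ps ≈ 1–10 × 10⁻⁵ cm²/s), runs the full pipeline
(wrapped coordinates → unwrapping → replica-averaged MSD → Einstein-relation
fit, 100–2000 ps window, 50 ps origin stride) and writes the per-species
table with copy-based standard errors and lateral (2-D) variants.
"""

from pathlib import Path

from cytosolkit.diffusion import species_report
from cytosolkit.model import SimulationCell
from cytosolkit.synthetic import BrownianSpec, gen_brownian

OUT = Path(__file__).parent.parent / "results"
SEED = 2026


def main():
    OUT.mkdir(exist_ok=True)
    spec = BrownianSpec(
        counts={"fast": 20, "medium": 20, "slow": 20, "solo": 1},
        diffusion={"fast": 1.0, "medium": 0.5, "slow": 0.1, "solo": 0.3},
        cell=SimulationCell.cubic(100.0),
        dt=4.0, n_frames=10_000, seed=SEED,
    )
    sys = gen_brownian(spec)
    rep = species_report(sys.trajectory, sys.topology,
                         window=(100.0, 2000.0), max_lag=2500.0)
    truth = {"fast": 1.0, "medium": 0.5, "slow": 0.1, "solo": 0.3}
    rep["D_true"] = rep.species.map(truth)
    rep["rel_err_pct"] = 100 * (rep.D_A2_per_ps - rep.D_true).abs() / rep.D_true
    rep.to_csv(OUT / "diffusion_species.tsv", sep="\t", index=False)
    print("Einstein-relation diffusion recovery (40 ps-frame Brownian "
          "ensembles, 10⁴ frames):")
    cols = ["species", "n_copies", "D_true", "D_A2_per_ps", "D_se",
            "D_lateral_mean", "rel_err_pct"]
    print(rep[cols].to_string(index=False))
    print("\nSingle-copy species report no SE (no copies to spread over); "
          "lateral values are 2-D plane fits averaged over xy/xz/yz.")


if __name__ == "__main__":
    main()
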