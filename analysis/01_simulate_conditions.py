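#!/usr/bin/env python
"""Simulate Slimfield acquisitions for the three osmotic-stress conditions.

One synthetic movie per condition (control NaPi buffer, 1 M NaCl, 1.5 M
sorbitol), with per-aggregate molecule counts and diffusion coefficients set
to the published condition means. Movies and masks (binary TIFF) go to
scratch/sim/; ground-truth tables to results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from slimquant.config import SimulationConfig
from slimquant.io import write_stack, write_table
from slimquant.reference import DIFFUSION_MEAN, STOICHIOMETRY_MEAN
from slimquant.simulate import simulate_slimfield_movie

ROOT = Path(__file__).resolve().parents[1]
N_AGGREGATES = 12
N_FRAMES = 1000
SEED = {"NaPi": 101, "NaCl": 102, "sorbitol": 103}


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for cond in ("NaPi", "NaCl", "sorbitol"):
        n_mol = int(round(STOICHIOMETRY_MEAN[cond]))
        d = DIFFUSION_MEAN[cond]
        cfg = SimulationConfig(n_frames=N_FRAMES, rng_seed=SEED[cond])
        stack = simulate_slimfield_movie(cfg, [n_mol] * N_AGGREGATES, d_coeff=d)
        outdir = ROOT / "scratch" / "sim" / cond
        write_stack(stack.movie, outdir / "movie_C1.tif")
        write_stack(stack.cell_mask[None], outdir / "cell_mask.tif")
        rows = [{"aggregate_id": tr.aggregate_id, "cell_label": tr.cell_label,
                 "true_n_molecules": tr.true_n_molecules,
                 "diffusion_coeff": tr.diffusion_coeff,
                 "n_dark": int(tr.dark_flags.sum())}
                for tr in stack.truths]
        write_table(pd.DataFrame(rows), results / f"sim_truth_{cond}.csv")
        print(f"{cond}: {N_AGGREGATES} aggregates of {n_mol} molecules, "
              f"D={d} um2/s -> {outdir}")


if __name__ == "__main__":
    sys.exit(main())
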