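#!/usr/bin/env python
"""Quantify the simulated conditions: molecule counts and mobility.

Runs the full detection -> localization -> linking -> in-situ brightness
calibration -> counting pipeline on each condition's movie from
analysis/01, plus per-track MSD diffusion estimation. Writes per-condition
stoichiometry/diffusion tables and the brightness calibration report to
results/.
"""

import sys
from pathlib import Path

import pandas as pd

from slimquant.config import PipelineConfig, SimulationConfig, StoichiometryConfig
from slimquant.io import read_stack, write_table
from slimquant.pipeline import analyze_stack

ROOT = Path(__file__).resolve().parents[1]
N_FRAMES = 1000
SEED = {"NaPi": 101, "NaCl": 102, "sorbitol": 103}


def main() -> None:
    results = ROOT / "results"
    stoich_all, diff_all, calib = [], [], []
    for cond in ("NaPi", "NaCl", "sorbitol"):
        simdir = ROOT / "scratch" / "sim" / cond
        if not simdir.exists():
            print(f"missing {simdir}; run analysis/01_simulate_conditions.py first")
            return 1
        acq = SimulationConfig(n_frames=N_FRAMES, rng_seed=SEED[cond])
        movie = read_stack(simdir / "movie_C1.tif")
        mask = read_stack(simdir / "cell_mask.tif")[0]
        cfg = PipelineConfig(
            acquisition=SimulationConfig(**{**acq.__dict__,
                                            "image_shape": movie.shape[1:]}),
            stoichiometry=StoichiometryConfig(dark_fraction=acq.dark_fraction))
        res = analyze_stack(movie, mask, cfg)
        s = res.stoichiometries.assign(condition=cond)
        d = res.diffusion.assign(condition=cond)
        stoich_all.append(s)
        diff_all.append(d)
        calib.append({"condition": cond, "I_single": res.calibration.value,
                      "ci_low": res.calibration.ci[0],
                      "ci_high": res.calibration.ci[1],
                      "n_steps_used": res.calibration.n_steps_used})
        print(f"{cond}: mean S = {res.mean_stoichiometry:.1f} molecules "
              f"({len(s)} aggregates), mean D = {res.mean_diffusion:.3f} um2/s, "
              f"I_single = {res.calibration.value:.1f} A.U.")
    write_table(pd.concat(stoich_all), results / "stoichiometry.csv")
    write_table(pd.concat(diff_all), results / "diffusion.csv")
    write_table(pd.DataFrame(calib), results / "calibration.csv")


if __name__ == "__main__":
    sys.exit(main())
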