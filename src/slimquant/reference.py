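"""Published condition summaries used as inputs to fold-change arithmetic.

Published reference values (means ± sd as printed): aggregate
stoichiometries and diffusion coefficients under hyperosmotic stress, and
aggregate-positive cell percentages across heat stress. They are *inputs*
for reproducing the ratio/percentage arithmetic between conditions, not
outputs of this package.
"""

from __future__ import annotations

from .population import fold_changes

#: mean molecules per aggregate (± sd of the mean as printed)
STOICHIOMETRY_MEAN = {
    "NaPi": 157.0,        # 50 mM NaPi control
    "NaCl": 290.0,        # 1 M NaCl hyperosmotic stress
    "sorbitol": 217.0,    # 1.5 M sorbitol hyperosmotic stress
}
STOICHIOMETRY_SD = {"NaPi": 25.0, "NaCl": 28.0, "sorbitol": 17.0}

#: mean diffusion coefficient, µm²/s
DIFFUSION_MEAN = {"NaPi": 0.99, "NaCl": 0.47, "sorbitol": 0.36}
DIFFUSION_SD = {"NaPi": 0.15, "NaCl": 0.04, "sorbitol": 0.06}

#: percent aggregate-positive cells by growth temperature
PCT_POSITIVE_MEAN = {"30C": 19.0, "37C": 47.0, "42C": 59.0}
PCT_POSITIVE_SD = {"30C": 5.8, "37C": 9.4, "42C": 14.3}


def printed_arithmetic() -> dict[str, float]:
    """Recompute the published ratio/percentage arithmetic from the printed
    condition means: stoichiometry increases under NaCl and sorbitol,
    aggregate-positive fold changes at 37/42 °C, and the sorbitol diffusion
    level expressed as a percentage of control."""
    s_nacl = fold_changes(STOICHIOMETRY_MEAN["NaPi"], STOICHIOMETRY_MEAN["NaCl"])
    s_sorb = fold_changes(STOICHIOMETRY_MEAN["NaPi"], STOICHIOMETRY_MEAN["sorbitol"])
    p_37 = fold_changes(PCT_POSITIVE_MEAN["30C"], PCT_POSITIVE_MEAN["37C"])
    p_42 = fold_changes(PCT_POSITIVE_MEAN["30C"], PCT_POSITIVE_MEAN["42C"])
    d_sorb = fold_changes(DIFFUSION_MEAN["NaPi"], DIFFUSION_MEAN["sorbitol"])
    return {
        "stoich_increase_nacl_pct": s_nacl["percent_increase"],
        "stoich_increase_sorbitol_pct": s_sorb["percent_increase"],
        "positive_fold_37C": p_37["factor"],
        "positive_fold_42C": p_42["factor"],
        "diffusion_sorbitol_remaining_pct": d_sorb["remaining_percent"],
        "diffusion_sorbitol_decrease_pct": d_sorb["percent_decrease"],
        "diffusion_nacl_remaining_pct": fold_changes(
            DIFFUSION_MEAN["NaPi"], DIFFUSION_MEAN["NaCl"])["remaining_percent"],
    }
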