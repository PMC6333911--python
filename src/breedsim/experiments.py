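"""Canned comparison experiments over the shipped breeding plans.

``compare_plans`` reruns the three wheat plans (phenotypic selection, genomic
selection, speed breeding + GS) as paired replicates (shared seeds, so plans
share founder populations and the whole pre-burn-in trajectory) and reports
post-burn-in rates of genetic gain and the genetic variance left at the
horizon.  Variance is measured on the F4 cohort of the final time step — the
last selection-candidate cohort in which many families segregate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import load_builtin
from .reporting import genetic_gain_rate
from .scheduler import run_experiment

PLAN_STEMS = {"PS": "plan_a", "GS": "plan_b", "SPB": "plan_c"}


@dataclass
class PlanComparison:
    trait: str
    window: tuple[int, int]
    n_replicates: int
    gain: dict[str, float]              # mean OLS slope per plan label
    gain_sd: dict[str, float]
    variance_at_horizon: dict[str, float]
    slopes: dict[str, list[float]]

    def ratio(self, num: str, den: str) -> float:
        return self.gain[num] / self.gain[den]


def compare_plans(
    base_seed: int = 1,
    n_replicates: int = 10,
    window: tuple[int, int] = (11, 25),
    trait: str = "YA",
    scale: str = "small",
    plans: dict[str, str] = PLAN_STEMS,
) -> PlanComparison:
    gain, gain_sd, var, slopes = {}, {}, {}, {}
    for label, stem in plans.items():
        name = f"{stem}_small" if scale == "small" else stem
        scenario = load_builtin(name)
        result = run_experiment(scenario, n_replicates=n_replicates,
                                base_seed=base_seed)
        s = [genetic_gain_rate(rep.records, trait, window).slope
             for rep in result.replicates]
        slopes[label] = s
        gain[label] = float(np.mean(s))
        gain_sd[label] = float(np.std(s, ddof=1))
        df = result.records
        last = df["time_step"].max()
        var[label] = float(df[(df["generation"] == 4) & (df["time_step"] == last)]
                           .groupby("replicate")[f"var_{trait}"].mean().mean())
    return PlanComparison(trait=trait, window=window, n_replicates=n_replicates,
                          gain=gain, gain_sd=gain_sd, variance_at_horizon=var,
                          slopes=slopes)
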