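"""Per-time-step summaries, genetic-gain rates, replicate aggregation and
tabular output writers.

The rate of genetic gain over a window of time steps is operationalized as
the ordinary-least-squares slope of the final-generation mean TBV on the
time step (more robust to single-endpoint noise than an endpoint
difference).  Variances use the n-1 denominator throughout; the
within/between-family decomposition is exact (they sum to the total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genome import export_phased_genomes
from .scheduler import ExperimentResult, SimulationOutput, SimulationState

log = logging.getLogger(__name__)


@dataclass
class GainEstimate:
    """OLS regression of mean TBV on time step over a window."""

    trait: str
    window: tuple[int, int]
    slope: float
    intercept: float
    n_points: int


def summarize_time_step(state: SimulationState) -> pd.DataFrame:
    """Records already emitted for the state's current time step (one per
    active (cycle, generation) whose stage ran this step)."""
    df = pd.DataFrame(state.records)
    return df[df["time_step"] == state.clock].reset_index(drop=True)


def genetic_gain_rate(
    records: pd.DataFrame,
    trait: str,
    window: tuple[int, int],
    generation: int | None = None,
) -> GainEstimate:
    """Rate of genetic gain: OLS slope of the (replicate-averaged)
    final-generation mean TBV on time step over ``window`` (inclusive)."""
    col = f"mean_tbv_{trait}"
    if col not in records.columns:
        raise ConfigError(f"no records for trait {trait!r}")
    gen = records["generation"].max() if generation is None else generation
    sub = records[(records["generation"] == gen)
                  & records["time_step"].between(*window)]
    series = sub.groupby("time_step")[col].mean()
    if len(series) < 2:
        raise ConfigError(f"need >= 2 time steps in window {window}; got {len(series)}")
    slope, intercept = np.polyfit(series.index.to_numpy(dtype=float),
                                  series.to_numpy(), 1)
    return GainEstimate(trait=trait, window=window, slope=float(slope),
                        intercept=float(intercept), n_points=len(series))


def aggregate_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of every numeric record variable per
    (time step, generation) across replicates."""
    if "replicate" not in records.columns:
        records = records.assign(replicate=0)
    value_cols = [c for c in records.columns
                  if c not in ("replicate", "time_step", "cycle", "generation")
                  and pd.api.types.is_numeric_dtype(records[c])]
    g = records.groupby(["time_step", "generation"])[value_cols]
    mean = g.mean().add_suffix("_mean")
    sd = g.std(ddof=1).add_suffix("_sd").fillna(0.0)
    return mean.join(sd).reset_index()


def write_outputs(
    result: ExperimentResult | SimulationOutput,
    out_dir: str | Path,
    pedigree: bool = True,
    genotypes: bool = False,
    state: SimulationState | None = None,
) -> list[Path]:
    """Write TSV outputs: per-replicate records, the aggregate summary with
    means and SDs, the stage-count log, optionally the pedigree and (given a
    final state) the phased genotypes of the founder pool in the
    re-importable dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    reps = result.replicates if isinstance(result, ExperimentResult) else [result]
    records = (result.records if isinstance(result, ExperimentResult)
               else result.records.assign(replicate=0))

    for i, rep in enumerate(reps):
        p = out / f"records_rep{i}.tsv"
        rep.records.to_csv(p, sep="\t", index=False)
        written.append(p)
        p = out / f"stage_log_rep{i}.tsv"
        rep.counts.to_csv(p, sep="\t", index=False)
        written.append(p)

    p = out / "timestep_summary.tsv"
    aggregate_replicates(records).to_csv(p, sep="\t", index=False)
    written.append(p)

    if pedigree:
        for i, rep in enumerate(reps):
            p = out / f"pedigree_rep{i}.tsv"
            rep.pedigree.to_frame().to_csv(p, sep="\t", index=False)
            written.append(p)

    if genotypes:
        if state is None:
            raise ConfigError("genotype export needs the final simulation state")
        m, g = out / "founder_map.tsv", out / "founder_genotypes.tsv"
        export_phased_genomes(state.pool, m, g)
        written.extend([m, g])
        p = out / "allele_frequencies.tsv"
        pd.DataFrame({
            "position_morgans": state.gmap.positions,
            "role": np.where(state.gmap.roles == 1, "QTL", "MARKER"),
            "base_frequency": state.base_freqs,
        }).to_csv(p, sep="\t", index=False)
        written.append(p)

    log.info("wrote %d files to %s", len(written), out)
    return written
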