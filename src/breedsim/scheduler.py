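"""The breeding-program engine: overlapping cycles, calendars, speed
breeding, germplasm recycling, burn-in switching and replicate orchestration.

A breeding plan is an ordered set of per-generation stages (phenotyping ->
EBV estimation -> selection -> germplasm storage -> propagation) plus a
calendar mapping each generation to a time-step offset within its cycle.  A
new cycle starts at every time step, so cycles overlap; speed breeding is
expressed purely through the calendar (several early generations sharing one
offset).  The first ``founder_cycles`` cycles draw their parents from the
founder pool; later cycles draw them from germplasm stored by earlier cycles.
An optional burn-in switch runs alternative (baseline) selection criteria
before a given time step, after which genomic selection stages activate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, SimulationError, StandardizationError
from .genome import (FounderConfig, FounderPool, GenomeMap, build_genome_map,
                     simulate_founder_population)
from .population import (NO_FAMILY, Cohort, GermplasmEntry, GermplasmStore,
                         Pedigree, assign_ibd_alleles, ibd_inbreeding,
                         sample_base_population)
from .reproduction import (PropagationRule, enumerate_crosses,
                           make_doubled_haploids, mate_batch)
from .selection import (UNIT_ENTIRE_FAMILY,
                        ReferencePopulation, SelectionRule, estimate_ebv_blup,
                        estimate_ebv_gblup, selection_accuracy,
                        threshold_select, truncation_select)
from .traits import (TraitArchitecture, calibrate_residual_variance,
                     compute_tbv, realize_phenotypes,
                     residual_variance_from_h2, sample_qtl_effects,
                     sample_qtl_effects_multitrait)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# plan / scenario configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    n_chromosomes: int = 1
    chrom_length: float = 1.0
    n_loci: int = 500
    qtl_every_n: int | None = None
    n_qtl_random: int | None = None
    n_ibd: int = 20


@dataclass
class TraitNoise:
    """Per-trait residual-variance specification: exactly one of h2 (plant
    heritability), h2_plot (plot heritability, with the plot size Ns and
    expected homozygosity H of the calibrated generation) or sigma_e2."""

    h2: float | None = None
    h2_plot: float | None = None
    sigma_e2: float | None = None
    ns: int = 1
    homozygosity: float = 1.0

    def __post_init__(self) -> None:
        if sum(v is not None for v in (self.h2, self.h2_plot, self.sigma_e2)) != 1:
            raise ConfigError("specify exactly one of h2, h2_plot, sigma_e2 per trait")

    def resolve(self, sigma_g2: float) -> float:
        if self.sigma_e2 is not None:
            return float(self.sigma_e2)
        if self.h2 is not None:
            return residual_variance_from_h2(sigma_g2, self.h2)
        return calibrate_residual_variance(sigma_g2, self.h2_plot, self.ns,
                                           self.homozygosity)


@dataclass
class TraitsConfig:
    names: list[str]
    sigma_g2: list[float]
    correlations: list[list[float]]
    noise: dict[str, TraitNoise]
    p_negative_effect: float = 0.9
    economic_values: list[float] | None = None

    def covariance(self) -> np.ndarray:
        s = np.sqrt(np.asarray(self.sigma_g2, dtype=float))
        R = np.asarray(self.correlations, dtype=float)
        return R * np.outer(s, s)


@dataclass
class PhenotypingSpec:
    trait: str
    level: str = "plant"       # "plant" | "family"
    family: str = "f1"         # partition when level == "family"
    n_plots: int = 1


@dataclass
class StageSpec:
    generation: int
    phenotyping: list[PhenotypingSpec] = field(default_factory=list)
    selection: SelectionRule | None = None
    propagation: PropagationRule | None = None
    store_germplasm: bool = False
    genotype: bool = False
    start_lines: bool = False


@dataclass
class CrossingSpec:
    n_crosses: int
    max_uses: int
    n_seeds_per_cross: int = 1


@dataclass
class ParentSourceSpec:
    n_parents: int
    founder_cycles: int
    store_generations: list[int] = field(default_factory=list)
    policy: str = "uniform"    # "uniform" | "truncation"
    base_inbred: bool = True


@dataclass
class BreedingPlan:
    name: str
    last_generation: int
    crossing: CrossingSpec
    stages: dict[int, StageSpec]
    calendar: dict[int, int]           # generation -> time-step offset
    parent_source: ParentSourceSpec
    horizon: int
    burn_in_switch: int | None = None

    def __post_init__(self) -> None:
        gens = sorted(self.calendar)
        if gens != list(range(1, self.last_generation + 1)):
            raise ConfigError("calendar must cover generations 1..last_generation")
        offs = [self.calendar[g] for g in gens]
        if any(b < a for a, b in zip(offs, offs[1:])):
            raise ConfigError("calendar offsets must be non-decreasing")
        if self.calendar[1] != 0:
            raise ConfigError("F1 must be created at cycle age 0")
        if self.burn_in_switch is not None and self.burn_in_switch > self.horizon + 1:
            raise ConfigError("burn-in switch beyond the simulation horizon")

    @property
    def cycle_duration(self) -> int:
        return len(set(self.calendar.values()))


@dataclass
class Scenario:
    name: str
    genome: GenomeConfig
    founder: FounderConfig
    traits: TraitsConfig
    plan: BreedingPlan
    n_replicates: int = 1


# ---------------------------------------------------------------------------
# runtime state
# ---------------------------------------------------------------------------

@dataclass
class CycleState:
    index: int
    start_step: int
    cohorts: dict[int, Cohort] = field(default_factory=dict)
    line_dosage: dict[int, np.ndarray] = field(default_factory=dict)
    complete: bool = False


@dataclass
class SimulationState:
    scenario: Scenario
    gmap: GenomeMap
    pool: FounderPool
    arch: TraitArchitecture
    base_freqs: np.ndarray
    rng: np.random.Generator
    pedigree: Pedigree = field(default_factory=Pedigree)
    germplasm: GermplasmStore = field(default_factory=GermplasmStore)
    reference: ReferencePopulation = field(default_factory=ReferencePopulation)
    clock: int = 0
    cycles: list[CycleState] = field(default_factory=list)
    records: list[dict] = field(default_factory=list)
    counts: list[dict] = field(default_factory=list)
    next_ibd_label: int = 0

    @property
    def active_cycles(self) -> list[CycleState]:
        return [c for c in self.cycles if not c.complete]


@dataclass
class SimulationOutput:
    """One replicate: per-stage records, stage count log, pedigree, seed."""

    scenario_name: str
    seed: int
    records: pd.DataFrame
    counts: pd.DataFrame
    pedigree: Pedigree
    reference_size: int


# ---------------------------------------------------------------------------
# replicate setup
# ---------------------------------------------------------------------------

def _build_architecture(scenario: Scenario, gmap: GenomeMap, pool: FounderPool,
                        rng: np.random.Generator) -> tuple[TraitArchitecture, np.ndarray]:
    tc = scenario.traits
    t = len(tc.names)
    if t == 1:
        raw = sample_qtl_effects(gmap.n_qtl, tc.p_negative_effect, rng)[None, :]
    else:
        raw = sample_qtl_effects_multitrait(gmap.n_qtl, tc.covariance(), rng)

    # standardize against the pool's exact haplotype variance: a non-inbred
    # (HWE-scale) base cohort then has expected TBV variance sigma_g2, and a
    # fully inbred one 2*sigma_g2, without the sampling noise a small
    # standardization cohort would add
    hap_tbv = pool.haplotypes[:, gmap.qtl_indices].astype(float) @ raw.T
    var_hap = hap_tbv.var(axis=0, ddof=1)
    if np.any(var_hap <= 0):
        raise StandardizationError("founder pool carries no QTL variance")
    effects = raw * np.sqrt(np.asarray(tc.sigma_g2) / (2.0 * var_hap))[:, None]
    freqs = pool.allele_frequencies()

    sigma_e2 = np.array([tc.noise[name].resolve(tc.sigma_g2[i])
                         for i, name in enumerate(tc.names)])
    arch = TraitArchitecture(
        names=list(tc.names), effects=effects,
        sigma_g2=np.asarray(tc.sigma_g2, dtype=float),
        genetic_covariance=tc.covariance(), sigma_e2=sigma_e2,
    )
    return arch, freqs


def initialize_state(scenario: Scenario, seed: int,
                     pool: FounderPool | None = None) -> SimulationState:
    rng = np.random.default_rng(seed)
    gc = scenario.genome
    if pool is None:
        gmap = build_genome_map(
            gc.n_chromosomes, gc.chrom_length, gc.n_loci,
            qtl_every_n=gc.qtl_every_n, n_qtl_random=gc.n_qtl_random,
            n_ibd=gc.n_ibd, rng=rng,
        )
        # founder fitness: mean effect across traits (selection acts on TBV)
        tc = scenario.traits
        if len(tc.names) == 1:
            fit = sample_qtl_effects(gmap.n_qtl, tc.p_negative_effect, rng)
        else:
            fit = sample_qtl_effects_multitrait(gmap.n_qtl, tc.covariance(), rng).mean(axis=0)
        pool = simulate_founder_population(scenario.founder, gmap, fit, rng)
    else:
        gmap = pool.gmap
    arch, freqs = _build_architecture(scenario, gmap, pool, rng)
    return SimulationState(scenario=scenario, gmap=gmap, pool=pool, arch=arch,
                           base_freqs=freqs, rng=rng)


# ---------------------------------------------------------------------------
# parents
# ---------------------------------------------------------------------------

def source_parents(state: SimulationState, cycle_index: int) -> Cohort:
    """Parents for a new cycle: founder base plants for the first
    ``founder_cycles`` cycles, stored germplasm afterwards."""
    plan = state.scenario.plan
    ps = plan.parent_source
    n = ps.n_parents
    gmap = state.gmap
    if cycle_index <= ps.founder_cycles:
        alleles = sample_base_population(state.pool, n, ps.base_inbred, state.rng)
        ibd, state.next_ibd_label = assign_ibd_alleles(
            n, gmap.n_ibd, ps.base_inbred, state.next_ibd_label)
        ids = np.array([state.pedigree.add_base(ps.base_inbred, 0, cycle_index,
                                                state.clock) for _ in range(n)])
        tbv = compute_tbv(alleles[:, :, gmap.qtl_indices].sum(axis=1), state.arch.effects)
        return Cohort(ids=ids, alleles=alleles, ibd=ibd, tbv=np.atleast_2d(tbv),
                      f1_family=np.full(n, NO_FAMILY), line=np.full(n, NO_FAMILY),
                      generation=0, cycle=cycle_index, time_step_created=state.clock,
                      inbred=ps.base_inbred)

    # germplasm path: most recent storage steps first until n parents available
    entries = list(state.germplasm.all_entries())
    entries = [e for e in entries if e.generation in ps.store_generations]
    if not entries:
        raise SimulationError(
            f"cycle {cycle_index}: no germplasm stored for generations "
            f"{ps.store_generations}")
    by_step: dict[int, list[GermplasmEntry]] = {}
    for e in entries:
        by_step.setdefault(e.time_step, []).append(e)
    chosen: list[GermplasmEntry] = []
    for step in sorted(by_step, reverse=True):
        chosen.extend(by_step[step])
        if len(chosen) >= n:
            break
    if len(chosen) < n:
        raise SimulationError(
            f"cycle {cycle_index}: only {len(chosen)} germplasm entries for "
            f"{n} requested parents")
    if ps.policy == "uniform":
        pick = state.rng.choice(len(chosen), size=n, replace=False)
    elif ps.policy == "truncation":
        crit = np.array([e.criterion for e in chosen])
        pick = np.lexsort((np.arange(len(chosen)), -crit))[:n]
    else:
        raise ConfigError(f"unknown parent sampling policy {ps.policy!r}")
    picked = [chosen[i] for i in pick]
    alleles = np.stack([e.alleles for e in picked])
    ibd = np.stack([e.ibd for e in picked]) if picked[0].ibd is not None else None
    return Cohort(
        ids=np.array([e.plant_id for e in picked]),
        alleles=alleles, ibd=ibd,
        tbv=np.stack([e.tbv for e in picked]),
        f1_family=np.full(n, NO_FAMILY), line=np.full(n, NO_FAMILY),
        generation=0, cycle=cycle_index, time_step_created=state.clock,
    )


# ---------------------------------------------------------------------------
# stage execution
# ---------------------------------------------------------------------------

def _variance_partition(x: np.ndarray, fams: np.ndarray) -> tuple[float, float, float]:
    n = x.size
    if n < 2:
        return 0.0, 0.0, 0.0
    total = float(np.var(x, ddof=1))
    if np.all(fams == NO_FAMILY):
        return total, total, 0.0
    _, inv = np.unique(fams, return_inverse=True)
    counts = np.bincount(inv)
    means = np.bincount(inv, weights=x) / counts
    grand = x.mean()
    between = float(np.sum(counts * (means - grand) ** 2) / (n - 1))
    within = float(np.sum((x - means[inv]) ** 2) / (n - 1))
    return total, within, between


def _partition_tags(cohort: Cohort) -> np.ndarray:
    if np.any(cohort.line != NO_FAMILY):
        return cohort.line
    return cohort.f1_family


def _record_cohort(state: SimulationState, cohort: Cohort,
                   accuracy: float | None, n_selected: int | None) -> None:
    arch = state.arch
    fams = _partition_tags(cohort)
    row: dict = {
        "time_step": state.clock,
        "cycle": cohort.cycle,
        "generation": cohort.generation,
        "size": cohort.size,
        "n_families": int(np.unique(fams[fams != NO_FAMILY]).size)
        if np.any(fams != NO_FAMILY) else 0,
        "n_selected": n_selected,
        "accuracy": accuracy,
    }
    f_ped = np.asarray(state.pedigree.f, dtype=float)[cohort.ids]
    row["f_pedigree"] = float(f_ped.mean())
    row["f_ibd"] = (float(ibd_inbreeding(cohort.ibd).mean())
                    if cohort.ibd is not None and cohort.ibd.shape[-1] else np.nan)
    for t, name in enumerate(arch.names):
        x = cohort.tbv[:, t]
        total, within, between = _variance_partition(x, fams)
        row[f"mean_tbv_{name}"] = float(x.mean())
        row[f"var_{name}"] = total
        row[f"var_within_{name}"] = within
        row[f"var_between_{name}"] = between
        y = cohort.phenotypes.get(name)
        row[f"mean_pheno_{name}"] = float(np.mean(y)) if y is not None else np.nan
    state.records.append(row)


def _make_f1(state: SimulationState, cycle: CycleState, parents: Cohort) -> Cohort:
    plan = state.scenario.plan
    cs = plan.crossing
    crosses = enumerate_crosses(parents.ids, cs.n_crosses, cs.max_uses, state.rng)
    n_cand = parents.size * (parents.size - 1) // 2
    row_of = {int(pid): k for k, pid in enumerate(parents.ids)}
    sires = np.array([row_of[s] for s, _ in crosses for _ in range(cs.n_seeds_per_cross)])
    dams = np.array([row_of[d] for _, d in crosses for _ in range(cs.n_seeds_per_cross)])
    alleles, ibd = mate_batch(parents.alleles[sires], None if parents.ibd is None
                              else parents.ibd[sires], parents.alleles[dams],
                              None if parents.ibd is None else parents.ibd[dams],
                              state.gmap, state.rng)
    ids = np.array([state.pedigree.add_cross(int(parents.ids[s]), int(parents.ids[d]),
                                             1, cycle.index, state.clock)
                    for s, d in zip(sires, dams)])
    tbv = np.atleast_2d(compute_tbv(alleles[:, :, state.gmap.qtl_indices].sum(axis=1),
                                    state.arch.effects))
    cohort = Cohort(ids=ids, alleles=alleles, ibd=ibd, tbv=tbv,
                    f1_family=ids.copy(), line=np.full(ids.size, NO_FAMILY),
                    generation=1, cycle=cycle.index, time_step_created=state.clock)
    state.counts.append({"time_step": state.clock, "cycle": cycle.index,
                         "generation": 1, "event": "crossing",
                         "n_cross_candidates": n_cand, "n_crosses": len(crosses),
                         "n_created": cohort.size})
    return cohort


def _phenotype_stage(state: SimulationState, cohort: Cohort, stage: StageSpec) -> None:
    arch = state.arch
    for spec in stage.phenotyping:
        t = arch.trait_index(spec.trait)
        y = realize_phenotypes(cohort.tbv[:, t], arch.sigma_e2[t], state.rng)
        cohort.phenotypes[spec.trait] = y
        if spec.level == "family":
            fams = cohort.f1_family if spec.family == "f1" else cohort.line
            plot = np.zeros(cohort.size, dtype=np.int64)
            for fam in np.unique(fams):
                pos = np.flatnonzero(fams == fam)
                plot[pos] = np.arange(pos.size) * spec.n_plots // max(pos.size, 1)
            cohort.plot_of[spec.trait] = plot


def _family_tags(cohort: Cohort, family: str) -> np.ndarray:
    return cohort.f1_family if family == "f1" else cohort.line


def _gs_active(state: SimulationState) -> bool:
    sw = state.scenario.plan.burn_in_switch
    return sw is None or state.clock >= sw


def _gblup_line_gebv(state: SimulationState, cycle: CycleState, cohort: Cohort,
                     rule: SelectionRule) -> tuple[np.ndarray, np.ndarray]:
    """GEBVs of the cohort's lines from the accumulated reference population.

    The stage's own line-mean records (``rule.trait``) are appended to the
    reference, then a multi-trait GBLUP over every recorded trait predicts
    the index trait (the breeding-goal trait) for the candidate lines, so
    that e.g. records of an early yield trait inform selection on the
    correlated goal trait through the genetic covariance.
    """
    arch = state.arch
    t = arch.trait_index(rule.trait)
    fams = _family_tags(cohort, rule.family)
    lines = np.unique(fams)
    ref = state.reference
    y = cohort.phenotypes.get(rule.trait)
    if y is None:
        raise SimulationError(f"gblup stage needs {rule.trait} phenotypes")
    for ln in lines:
        dosage = cycle.line_dosage.get(int(ln))
        if dosage is None:
            raise SimulationError(f"line {ln} has no stored genotype for GBLUP")
        ref.add_genotype(int(ln), dosage)
        members = np.flatnonzero(fams == ln)
        ref.add_record(rule.trait, int(ln), float(y[members].mean()),
                       float(arch.sigma_e2[t] / members.size))

    index_trait = rule.index_trait or rule.trait
    traits = sorted(set(ref.records) | {index_trait}, key=arch.trait_index)
    local = {name: k for k, name in enumerate(traits)}
    yy, rows, tloc, rvar = [], [], [], []
    for name in traits:
        for pid, val, rv in ref.records.get(name, []):
            yy.append(val)
            rows.append(ref.row(pid))
            tloc.append(local[name])
            rvar.append(rv)
    gidx = [arch.trait_index(name) for name in traits]
    Sg = arch.genetic_covariance[np.ix_(gidx, gidx)]
    dosage = ref.dosage_matrix()
    u, _ = estimate_ebv_gblup(dosage, state.base_freqs[state.gmap.marker_indices],
                              np.asarray(yy), np.asarray(rows), Sg,
                              np.asarray(rvar), rec_trait=np.asarray(tloc))
    col = local[index_trait]
    gebv = np.array([u[ref.row(int(ln)), col] for ln in lines])
    return lines, gebv


def _blup_values(state: SimulationState, cohort: Cohort,
                 rule: SelectionRule) -> np.ndarray:
    arch = state.arch
    t = arch.trait_index(rule.trait)
    y = cohort.phenotypes.get(rule.trait)
    if y is None:
        raise SimulationError(f"blup stage needs {rule.trait} phenotypes")
    u, _ = estimate_ebv_blup(y, cohort.ids, state.pedigree, cohort.ids,
                             arch.sigma_g2[t],
                             np.full(y.size, arch.sigma_e2[t]))
    return u[:, 0]


def _select(state: SimulationState, cycle: CycleState, cohort: Cohort,
            stage: StageSpec) -> tuple[np.ndarray, float | None]:
    """Run the stage's selection; returns (selected positions, accuracy)."""
    rule = stage.selection
    criterion = rule.criterion
    if rule.burn_in_criterion is not None and not _gs_active(state):
        criterion = rule.burn_in_criterion
    arch = state.arch
    t = arch.trait_index(rule.trait)
    fams = (_family_tags(cohort, rule.family)
            if rule.unit != "population" else None)

    if criterion == "gblup":
        lines, gebv = _gblup_line_gebv(state, cycle, cohort, rule)
        top = lines[np.lexsort((lines, -gebv))[: rule.n_selected]]
        selected = np.flatnonzero(np.isin(fams, top))
        ti = arch.trait_index(rule.index_trait or rule.trait)
        line_tbv = np.array([cohort.tbv[fams == ln, ti].mean() for ln in lines])
        acc = selection_accuracy(gebv, line_tbv) if lines.size >= 3 else np.nan
        return selected, acc

    if criterion == "phenotype":
        values = cohort.phenotypes.get(rule.trait)
        if values is None:
            raise SimulationError(f"selection on unrecorded phenotype {rule.trait}")
    elif criterion == "tbv":
        values = cohort.tbv[:, t]
    elif criterion == "blup":
        values = _blup_values(state, cohort, rule)
    elif criterion == "threshold":
        values = cohort.phenotypes.get(rule.trait)
        selected = threshold_select(values, rule.threshold)
        return selected, None
    else:
        raise ConfigError(f"unsupported in-plan selection criterion {criterion!r}")

    selected = truncation_select(values, rule.n_selected, rule.unit,
                                 families=fams, ids=cohort.ids)
    acc = None
    try:
        acc = selection_accuracy(values, cohort.tbv[:, t],
                                 families=fams if rule.unit == UNIT_ENTIRE_FAMILY
                                 else None)
    except ConfigError:
        acc = np.nan
    return selected, acc


def _store_germplasm(state: SimulationState, cycle: CycleState, cohort: Cohort,
                     stage: StageSpec, selected: np.ndarray) -> None:
    """Store one representative per selected family (or each selected plant
    when selection is not family-based)."""
    rule = stage.selection
    entries: list[GermplasmEntry] = []
    if rule is not None and rule.unit == UNIT_ENTIRE_FAMILY:
        fams = _family_tags(cohort, rule.family)[selected]
        values = cohort.phenotypes.get(rule.trait)
        for fam in np.unique(fams):
            members = selected[fams == fam]
            rep = int(members[state.rng.integers(members.size)])
            crit = float(values[members].sum()) if values is not None else np.nan
            entries.append(_entry_from(cohort, rep, crit, state.clock))
    else:
        for rep in selected:
            entries.append(_entry_from(cohort, int(rep), np.nan, state.clock))
    state.germplasm.store((cycle.index, cohort.generation), entries)


def _entry_from(cohort: Cohort, idx: int, criterion: float, step: int) -> GermplasmEntry:
    return GermplasmEntry(
        plant_id=int(cohort.ids[idx]),
        alleles=cohort.alleles[idx].copy(),
        ibd=None if cohort.ibd is None else cohort.ibd[idx].copy(),
        tbv=cohort.tbv[idx].copy(),
        line=int(cohort.line[idx]),
        criterion=criterion,
        cycle=cohort.cycle,
        generation=cohort.generation,
        time_step=step,
    )


def _propagate(state: SimulationState, cycle: CycleState, cohort: Cohort,
               stage: StageSpec, selected: np.ndarray) -> Cohort:
    rule = stage.propagation
    rng = state.rng
    gmap = state.gmap
    ped = state.pedigree
    gen = cohort.generation + 1

    if rule.per == "family":
        fam_def = stage.selection.family if stage.selection is not None else "f1"
        fams = _family_tags(cohort, fam_def)[selected]
        parent_pos = []
        for fam in np.unique(fams):
            members = selected[fams == fam]
            parent_pos.append(members[rng.integers(members.size, size=rule.n_seeds)])
        parent_pos = np.concatenate(parent_pos)
    else:
        parent_pos = np.repeat(selected, rule.n_seeds)

    if rule.type == "selfing":
        alleles, ibd = mate_batch(cohort.alleles[parent_pos],
                                  None if cohort.ibd is None else cohort.ibd[parent_pos],
                                  cohort.alleles[parent_pos],
                                  None if cohort.ibd is None else cohort.ibd[parent_pos],
                                  gmap, rng)
        parent_ids = cohort.ids[parent_pos]
        f_par = np.asarray(ped.f, dtype=float)[parent_ids]
        start = len(ped)
        ped.sire.extend(int(i) for i in parent_ids)
        ped.dam.extend(int(i) for i in parent_ids)
        ped.origin.extend(["self"] * parent_ids.size)
        ped.f.extend((0.5 * (1.0 + f_par)).tolist())
        ped.generation.extend([gen] * parent_ids.size)
        ped.cycle.extend([cycle.index] * parent_ids.size)
        ped.time_step.extend([state.clock] * parent_ids.size)
        ids = np.arange(start, len(ped))
    elif rule.type == "dh":
        alleles, ibd = make_doubled_haploids(
            cohort.alleles[parent_pos],
            None if cohort.ibd is None else cohort.ibd[parent_pos], gmap, rng)
        ids = np.array([ped.add_dh(int(cohort.ids[p]), gen, cycle.index, state.clock)
                        for p in parent_pos])
    elif rule.type == "cloning":
        alleles = cohort.alleles[parent_pos].copy()
        ibd = None if cohort.ibd is None else cohort.ibd[parent_pos].copy()
        ids = np.array([ped.add_clone(int(cohort.ids[p]), gen, cycle.index, state.clock)
                        for p in parent_pos])
    elif rule.type == "crossing":
        others = selected[rng.integers(selected.size, size=parent_pos.size)]
        clash = others == parent_pos
        while np.any(clash):
            others[clash] = selected[rng.integers(selected.size, size=int(clash.sum()))]
            clash = others == parent_pos
        alleles, ibd = mate_batch(cohort.alleles[parent_pos],
                                  None if cohort.ibd is None else cohort.ibd[parent_pos],
                                  cohort.alleles[others],
                                  None if cohort.ibd is None else cohort.ibd[others],
                                  gmap, rng)
        ids = np.array([ped.add_cross(int(cohort.ids[p]), int(cohort.ids[o]),
                                      gen, cycle.index, state.clock)
                        for p, o in zip(parent_pos, others)])
    else:  # pragma: no cover - guarded by PropagationRule
        raise ConfigError(f"unknown propagation type {rule.type!r}")

    tbv = np.atleast_2d(compute_tbv(alleles[:, :, gmap.qtl_indices].sum(axis=1),
                                    state.arch.effects))
    line = cohort.line[parent_pos].copy()
    if stage.start_lines:
        line = cohort.ids[parent_pos].copy()
    return Cohort(ids=ids, alleles=alleles, ibd=ibd, tbv=tbv,
                  f1_family=cohort.f1_family[parent_pos].copy(), line=line,
                  generation=gen, cycle=cycle.index, time_step_created=state.clock)


def _execute_stage(state: SimulationState, cycle: CycleState, gen: int) -> None:
    plan = state.scenario.plan
    cohort = cycle.cohorts.get(gen)
    if cohort is None:
        raise SimulationError(
            f"time step {state.clock}: cycle {cycle.index} has no generation-{gen} cohort")
    stage = plan.stages.get(gen, StageSpec(generation=gen))

    _phenotype_stage(state, cohort, stage)

    selected = np.arange(cohort.size)
    accuracy = None
    n_sel: int | None = None
    if stage.selection is not None:
        selected, accuracy = _select(state, cycle, cohort, stage)
        n_sel = int(selected.size)

    if stage.start_lines:
        # selected plants found single-seed-descent lines; keep their marker
        # dosage for genomic prediction in later stages of this cycle
        markers = state.gmap.marker_indices
        dos = cohort.alleles[selected][:, :, markers].sum(axis=1, dtype=np.int16)
        for k, pos in enumerate(selected):
            cycle.line_dosage[int(cohort.ids[pos])] = dos[k]

    if stage.store_germplasm:
        _store_germplasm(state, cycle, cohort, stage, selected)

    _record_cohort(state, cohort, accuracy, n_sel)

    count_row = {"time_step": state.clock, "cycle": cycle.index, "generation": gen,
                 "event": "stage", "n_candidates": cohort.size,
                 "n_selected": n_sel}
    if stage.selection is not None and stage.selection.unit == UNIT_ENTIRE_FAMILY:
        fams = _family_tags(cohort, stage.selection.family)[selected]
        count_row["n_selected_families"] = int(np.unique(fams).size)

    if stage.propagation is not None:
        offspring = _propagate(state, cycle, cohort, stage, selected)
        cycle.cohorts[offspring.generation] = offspring
        count_row["n_seeds_produced"] = offspring.size
    state.counts.append(count_row)

    if gen == plan.last_generation:
        fams = _partition_tags(cohort)
        state.counts.append({"time_step": state.clock, "cycle": cycle.index,
                             "generation": gen, "event": "release",
                             "released_lines": int(np.unique(fams[fams != NO_FAMILY]).size)
                             if np.any(fams != NO_FAMILY) else cohort.size})
        cycle.complete = True
        cycle.line_dosage.clear()
    del cycle.cohorts[gen]


def advance_time_step(state: SimulationState) -> SimulationState:
    """Advance the engine one time step: start a new cycle, then execute every
    stage whose calendar offset matches its cycle's age (oldest cycle first,
    generations in order)."""
    state.clock += 1
    plan = state.scenario.plan
    new_cycle = CycleState(index=state.clock, start_step=state.clock)
    parents = source_parents(state, new_cycle.index)
    new_cycle.cohorts[0] = parents
    state.cycles.append(new_cycle)

    for cycle in state.active_cycles:
        age = state.clock - cycle.start_step
        for gen in range(1, plan.last_generation + 1):
            if plan.calendar[gen] != age:
                continue
            if gen == 1:
                cycle.cohorts[1] = _make_f1(state, cycle, cycle.cohorts.pop(0))
            _execute_stage(state, cycle, gen)
            if cycle.complete:
                break
    return state


# ---------------------------------------------------------------------------
# replicates and experiments
# ---------------------------------------------------------------------------

def run_replicate(scenario: Scenario, seed: int,
                  pool: FounderPool | None = None) -> SimulationOutput:
    """Run one fully reproducible replicate of a breeding plan."""
    state = initialize_state(scenario, seed, pool=pool)
    for _ in range(scenario.plan.horizon):
        advance_time_step(state)
    records = pd.DataFrame(state.records)
    counts = pd.DataFrame(state.counts)
    log.info("%s seed=%d: %d plants, %d records", scenario.name, seed,
             len(state.pedigree), len(records))
    return SimulationOutput(scenario_name=scenario.name, seed=seed,
                            records=records, counts=counts,
                            pedigree=state.pedigree,
                            reference_size=state.reference.n_genotyped)


@dataclass
class ExperimentResult:
    scenario_name: str
    base_seed: int
    replicates: list[SimulationOutput]
    records: pd.DataFrame               # all replicates, "replicate" column
    failures: list[tuple[int, str]]

    @property
    def complete(self) -> bool:
        return not self.failures


def run_experiment(scenario: Scenario, n_replicates: int | None = None,
                   base_seed: int = 0, shared_founder: bool = False) -> ExperimentResult:
    """Run ``n_replicates`` replicates on seeds base_seed + i and pool their
    records.  By default each replicate simulates its own founder population;
    ``shared_founder`` reuses the first replicate's pool."""
    n_reps = scenario.n_replicates if n_replicates is None else n_replicates
    if n_reps < 1:
        raise ConfigError("n_replicates must be >= 1")
    outputs: list[SimulationOutput] = []
    failures: list[tuple[int, str]] = []
    pool = None
    for i in range(n_reps):
        seed = base_seed + i
        try:
            if shared_founder and pool is None and i == 0:
                state = initialize_state(scenario, seed)
                pool = state.pool
            out = run_replicate(scenario, seed, pool=pool if shared_founder else None)
            outputs.append(out)
        except Exception as exc:  # keep going; summary flags the failure
            log.error("replicate %d failed: %s", i, exc)
            failures.append((i, str(exc)))
    frames = []
    for i, out in enumerate(outputs):
        df = out.records.copy()
        df.insert(0, "replicate", out.seed - base_seed)
        frames.append(df)
    records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return ExperimentResult(scenario_name=scenario.name, base_seed=base_seed,
                            replicates=outputs, records=records, failures=failures)
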