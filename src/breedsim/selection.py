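"""Selection criteria and units: phenotype/threshold truncation, pedigree
BLUP, genomic GBLUP, optimum-contribution selection, and accuracy reporting.

Breeding values are predicted from the mixed model y = Xb + Zu + e with
u ~ N(0, K (x) Sigma_g) where K is either the pedigree numerator relationship
matrix A (BLUP) or the VanRaden genomic relationship matrix G (GBLUP).  The
breeder is handed the simulation's true variance components (no REML); fixed
effects are an overall mean per trait.  OCS maximizes genetic merit of parent
contributions penalized by the rate of relationship gain,
U(c) = c'a - (omega / L^2) (c + Pv)' A (c + Pv), over the simplex c >= 0,
1'c = 1 (hermaphroditic, single parent pool).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .errors import ConfigError, InfeasibleError, SimulationError
from .population import Pedigree, genomic_relationship

log = logging.getLogger(__name__)

UNIT_POPULATION = "population"
UNIT_WITHIN_FAMILY = "within_family"
UNIT_ENTIRE_FAMILY = "entire_family"


@dataclass
class SelectionRule:
    """Declarative selection stage: how many to keep, at what unit, by what
    criterion (phenotype | threshold | blup | gblup | ocs | tbv)."""

    unit: str = UNIT_POPULATION
    criterion: str = "phenotype"
    trait: str | None = None
    index_trait: str | None = None     # trait whose GEBV ranks candidates (gblup)
    n_selected: int | None = None
    threshold: float | None = None
    family: str | None = None          # "f1" or "line"
    burn_in_criterion: str | None = None
    ocs_omega: float = 0.0
    ocs_l: float = 1.0

    def __post_init__(self) -> None:
        if self.unit not in (UNIT_POPULATION, UNIT_WITHIN_FAMILY, UNIT_ENTIRE_FAMILY):
            raise ConfigError(f"unknown selection unit {self.unit!r}")
        if self.unit != UNIT_POPULATION and self.family is None:
            raise ConfigError("family-based selection units require a family definition")


@dataclass
class ReferencePopulation:
    """Append-only store of genotyped plants and their trait records, grown
    across cycles for genomic prediction."""

    plant_ids: list[int] = field(default_factory=list)
    dosages: list[np.ndarray] = field(default_factory=list)
    records: dict[str, list[tuple[int, float, float]]] = field(default_factory=dict)
    _row_of: dict[int, int] = field(default_factory=dict)

    def add_genotype(self, plant_id: int, dosage: np.ndarray) -> None:
        if plant_id in self._row_of:
            return
        self._row_of[plant_id] = len(self.plant_ids)
        self.plant_ids.append(plant_id)
        self.dosages.append(np.asarray(dosage, dtype=np.int16))

    def add_record(self, trait: str, plant_id: int, value: float, resid_var: float) -> None:
        if plant_id not in self._row_of:
            raise SimulationError(f"phenotype record for ungenotyped plant {plant_id}")
        self.records.setdefault(trait, []).append((plant_id, float(value), float(resid_var)))

    def row(self, plant_id: int) -> int:
        return self._row_of[plant_id]

    @property
    def n_genotyped(self) -> int:
        return len(self.plant_ids)

    def dosage_matrix(self) -> np.ndarray:
        return np.stack(self.dosages).astype(float)


# ---------------------------------------------------------------------------
# truncation / threshold
# ---------------------------------------------------------------------------

def _ranked(values: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Indices sorted by descending value, ties broken by ascending id."""
    order = np.lexsort((ids, -np.asarray(values, dtype=float)))
    return order


def truncation_select(
    values: np.ndarray,
    n_selected: int,
    unit: str = UNIT_POPULATION,
    families: np.ndarray | None = None,
    ids: np.ndarray | None = None,
) -> np.ndarray:
    """Top-n truncation at the requested unit.

    * population: top ``n_selected`` plants overall;
    * within_family: top ``n_selected`` plants per family;
    * entire_family: top ``n_selected`` families by summed criterion, all
      members of the winning families returned.

    Returns positions into ``values``.  Missing criterion values (NaN) raise.
    """
    values = np.asarray(values, dtype=float)
    if np.any(np.isnan(values)):
        missing = np.flatnonzero(np.isnan(values))
        raise SimulationError(f"criterion missing for candidates at positions {missing[:10]}")
    ids = np.arange(values.size) if ids is None else np.asarray(ids)
    if unit == UNIT_POPULATION:
        if n_selected > values.size:
            raise ConfigError("n_selected exceeds candidate count")
        return np.sort(_ranked(values, ids)[:n_selected])
    if families is None:
        raise ConfigError(f"{unit} selection requires family tags")
    families = np.asarray(families)
    if unit == UNIT_WITHIN_FAMILY:
        picked = []
        for fam in np.unique(families):
            pos = np.flatnonzero(families == fam)
            if n_selected > pos.size:
                raise ConfigError(f"n_selected {n_selected} exceeds family {fam} size {pos.size}")
            picked.append(pos[_ranked(values[pos], ids[pos])[:n_selected]])
        return np.sort(np.concatenate(picked))
    # entire family: rank families on summed criterion
    fams, inv = np.unique(families, return_inverse=True)
    sums = np.bincount(inv, weights=values)
    if n_selected > fams.size:
        raise ConfigError("n_selected exceeds number of families")
    top = _ranked(sums, fams)[:n_selected]
    keep = np.isin(inv, top)
    return np.flatnonzero(keep)


def threshold_select(values: np.ndarray, threshold: float) -> np.ndarray:
    """All candidates whose phenotype meets the threshold (may be empty)."""
    values = np.asarray(values, dtype=float)
    sel = np.flatnonzero(values >= threshold)
    if sel.size == 0:
        warnings.warn("threshold selection returned no candidates", stacklevel=2)
    return sel


def selection_accuracy(
    criterion: np.ndarray,
    tbv: np.ndarray,
    families: np.ndarray | None = None,
) -> float:
    """Pearson correlation between the selection criterion and TBV, at the
    plant level or (when ``families`` is given) between family sums."""
    x = np.asarray(criterion, dtype=float)
    g = np.asarray(tbv, dtype=float)
    if families is not None:
        fams, inv = np.unique(np.asarray(families), return_inverse=True)
        x = np.bincount(inv, weights=x)
        g = np.bincount(inv, weights=g)
    if x.size < 3:
        raise ConfigError("accuracy needs at least 3 candidates (or families)")
    if x.std() == 0 or g.std() == 0:
        warnings.warn("zero variance; selection accuracy undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, g)[0, 1])


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------

def solve_mme(
    y: np.ndarray,
    rec_plant: np.ndarray,
    rec_trait: np.ndarray,
    K: np.ndarray,
    sigma_g: np.ndarray,
    resid_var: np.ndarray,
    fit_mean: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve Henderson's mixed-model equations.

    ``y`` (R,) records on plants ``rec_plant`` (indices into the K rows) and
    traits ``rec_trait``; u ~ N(0, Sigma_g (x) K) with ``sigma_g`` the t x t
    genetic covariance; ``resid_var`` per-record residual variances (repeated
    plot records of a line enter as independent observations).  Returns
    (u (n, t), b (t,)); with ``fit_mean=False`` the means are fixed at 0.
    """
    y = np.asarray(y, dtype=float)
    rec_plant = np.asarray(rec_plant, dtype=np.int64)
    rec_trait = np.asarray(rec_trait, dtype=np.int64)
    r = np.asarray(resid_var, dtype=float)
    Sg = np.atleast_2d(np.asarray(sigma_g, dtype=float))
    n = K.shape[0]
    t = Sg.shape[0]
    if np.any(r <= 0):
        raise ConfigError("residual variances must be positive")

    try:
        c, lower = scipy.linalg.cho_factor(K)
        Kinv = scipy.linalg.cho_solve((c, lower), np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise SimulationError("relationship matrix singular; regularize (e.g. blend with I)") from exc
    Sginv = np.linalg.inv(Sg) if t > 1 else np.array([[1.0 / Sg[0, 0]]])

    nt = n * t
    C = np.kron(Sginv, Kinv)            # (Sigma_g (x) K)^{-1}
    idx = rec_trait * n + rec_plant
    w = 1.0 / r
    np.add.at(C, (idx, idx), w)
    rhs_u = np.zeros(nt)
    np.add.at(rhs_u, idx, w * y)

    if fit_mean:
        # one mean per trait, but only for traits that actually have records
        # (an all-zero mean equation would make the system singular)
        obs = np.unique(rec_trait)
        to = t_obs = obs.size
        col = np.searchsorted(obs, rec_trait)
        Xt = np.zeros((to, to))
        np.add.at(Xt, (col, col), w)
        XtZ = np.zeros((to, nt))
        np.add.at(XtZ, (col, idx), w)
        rhs_b = np.zeros(to)
        np.add.at(rhs_b, col, w * y)
        M = np.block([[Xt, XtZ], [XtZ.T, C]])
        rhs = np.concatenate([rhs_b, rhs_u])
        sol = scipy.linalg.solve(M, rhs, assume_a="sym")
        b = np.zeros(t)
        b[obs] = sol[:t_obs]
        u = sol[t_obs:]
    else:
        b = np.zeros(t)
        u = scipy.linalg.solve(C, rhs_u, assume_a="sym")
    return u.reshape(t, n).T, b


def estimate_ebv_blup(
    y: np.ndarray,
    rec_plant_ids: np.ndarray,
    pedigree: Pedigree,
    ids: np.ndarray,
    sigma_g: np.ndarray | float,
    resid_var: np.ndarray,
    rec_trait: np.ndarray | None = None,
    fit_mean: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Pedigree BLUP: EBVs for all plants in ``ids`` (phenotyped or not) from
    records on ``rec_plant_ids`` via A from the pedigree."""
    ids = np.asarray(ids, dtype=np.int64)
    pos = {int(i): k for k, i in enumerate(ids)}
    try:
        rec_plant = np.array([pos[int(i)] for i in rec_plant_ids], dtype=np.int64)
    except KeyError as exc:
        raise ConfigError(f"record references plant {exc} outside the prediction set") from exc
    A = pedigree.relationship_matrix(ids)
    rec_trait = np.zeros(len(y), dtype=np.int64) if rec_trait is None else rec_trait
    return solve_mme(y, rec_plant, rec_trait, A, np.atleast_2d(sigma_g), resid_var, fit_mean)


def estimate_ebv_gblup(
    dosage: np.ndarray,
    base_frequencies: np.ndarray,
    y: np.ndarray,
    rec_plant: np.ndarray,
    sigma_g: np.ndarray | float,
    resid_var: np.ndarray,
    rec_trait: np.ndarray | None = None,
    fit_mean: bool = True,
    G: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Genomic BLUP: G (VanRaden 1 on marker dosages against frozen base
    frequencies) replaces A in the MME.  A singular G is blended as
    0.99 G + 0.01 I (logged) before solving.  Returns GEBVs for every row of
    ``dosage`` (reference and candidates alike)."""
    if G is None:
        G = genomic_relationship(dosage, base_frequencies)
    rec_trait = np.zeros(len(y), dtype=np.int64) if rec_trait is None else rec_trait
    try:
        return solve_mme(y, rec_plant, rec_trait, G, np.atleast_2d(sigma_g), resid_var, fit_mean)
    except SimulationError:
        log.info("G singular; blending G* = 0.99 G + 0.01 I")
        Gb = 0.99 * G + 0.01 * np.eye(G.shape[0])
        return solve_mme(y, rec_plant, rec_trait, Gb, np.atleast_2d(sigma_g), resid_var, fit_mean)


# ---------------------------------------------------------------------------
# optimum-contribution selection
# ---------------------------------------------------------------------------

def ocs_select(
    ebv: np.ndarray,
    A: np.ndarray,
    omega: float,
    L: float = 1.0,
    P: np.ndarray | None = None,
    v: np.ndarray | None = None,
    n_matings: int | None = None,
    max_contribution: float | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Optimum-contribution selection on a single hermaphroditic parent pool.

    Maximizes U(c) = c'ebv - (omega / L^2) (c + Pv)' A (c + Pv) subject to
    c >= 0, 1'c = 1 and optionally c_i <= max_contribution.  ``P`` and ``v``
    carry fixed contributions of existing age classes (default none).
    Returns (c, mating counts by largest-remainder apportionment of
    ``n_matings`` or None).
    """
    a = np.asarray(ebv, dtype=float)
    A = np.asarray(A, dtype=float)
    n = a.size
    if n < 2:
        raise ConfigError("OCS needs at least 2 candidates")
    if omega < 0:
        raise ConfigError("omega must be non-negative")
    if L <= 0:
        raise ConfigError("generation interval L must be positive")
    cap = 1.0 if max_contribution is None else float(max_contribution)
    if cap * n < 1.0:
        raise InfeasibleError(f"max_contribution {cap} infeasible for {n} candidates")
    pv = np.zeros(n) if (P is None or v is None) else np.asarray(P) @ np.asarray(v)
    lam = omega / L**2

    if lam == 0.0:
        # linear objective: fill greedily from the top EBV under the cap
        c = np.zeros(n)
        remaining = 1.0
        for i in _greedy_order(a):
            take = min(cap, remaining)
            c[i] = take
            remaining -= take
            if remaining <= 1e-15:
                break
    else:
        def neg_u(c):
            s = c + pv
            return -(c @ a) + lam * (s @ A @ s)

        def grad(c):
            return -a + 2.0 * lam * (A @ (c + pv))

        res = scipy.optimize.minimize(
            neg_u, np.full(n, 1.0 / n), jac=grad, method="SLSQP",
            bounds=[(0.0, cap)] * n,
            constraints=[{"type": "eq", "fun": lambda c: c.sum() - 1.0,
                          "jac": lambda c: np.ones(n)}],
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if not res.success:
            raise SimulationError(f"OCS optimizer failed: {res.message}")
        c = np.clip(res.x, 0.0, cap)
        c /= c.sum()

    matings = None
    if n_matings is not None:
        matings = largest_remainder_apportionment(c, n_matings)
    return c, matings


def _greedy_order(values: np.ndarray) -> np.ndarray:
    return np.lexsort((np.arange(values.size), -values))


def largest_remainder_apportionment(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` proportional to ``fractions``."""
    f = np.asarray(fractions, dtype=float)
    f = f / f.sum()
    raw = f * total
    counts = np.floor(raw).astype(np.int64)
    short = total - counts.sum()
    if short:
        rema = raw - counts
        order = np.lexsort((np.arange(f.size), -rema))
        counts[order[:short]] += 1
    return counts
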