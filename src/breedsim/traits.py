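"""Trait architecture: QTL effects, breeding values, phenotypes, calibration.

A trait is additive over QTLs: the true breeding value (TBV) of plant *i* is
``g_i = sum_j x_ij a_j`` with ``x_ij`` in {0, 1, 2} the mutant-allele dosage.
Effects are drawn either from an exponential magnitude distribution with a
default 90% negative sign (single trait), or from a multivariate normal with
a user-specified genetic covariance (correlated traits), and are then
standardized so a non-inbred (Hardy-Weinberg-scale) base cohort realizes the
target additive genetic variance sigma_g2 exactly.  A cohort of fully inbred
lines derived from the same pool consequently realizes ~2*sigma_g2
between-line variance, which is what the plot-heritability calibration below
assumes.

Plot heritability h2_plot is the squared correlation between plot sums of
TBVs and plot sums of phenotypes.  Under Hardy-Weinberg proportions with
homozygosity frequency H and Ns plants per plot, the residual variance that
realizes a target h2_plot is

    sigma_e2 = 2 * Ns * H * sigma_g2 * (1 - h2_plot) / h2_plot - (1 - H) * sigma_g2

(the between-line genetic variance 2*H*sigma_g2 is signal; the within-line
genetic variance (1 - H)*sigma_g2 joins the residual).  At H = 1 this reduces
to the fully-inbred form 2*Ns*sigma_g2*(1 - h2)/h2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InfeasibleError, StandardizationError


@dataclass
class PlotSpec:
    """Field-plot layout: Ns plants per plot, n_plots observations per family."""

    n_plants_per_plot: int = 1
    n_plots: int = 1

    def __post_init__(self) -> None:
        if self.n_plants_per_plot < 1 or self.n_plots < 1:
            raise ConfigError("plot spec counts must be >= 1")


@dataclass
class TraitArchitecture:
    """Effects and variance components for one or more correlated traits."""

    names: list[str]
    effects: np.ndarray                 # (n_traits, n_qtl)
    sigma_g2: np.ndarray                # (n_traits,)
    genetic_covariance: np.ndarray      # (n_traits, n_traits)
    sigma_e2: np.ndarray                # (n_traits,)
    economic_values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = len(self.names)
        self.effects = np.atleast_2d(np.asarray(self.effects, dtype=float))
        self.sigma_g2 = np.asarray(self.sigma_g2, dtype=float).reshape(t)
        self.sigma_e2 = np.asarray(self.sigma_e2, dtype=float).reshape(t)
        C = np.asarray(self.genetic_covariance, dtype=float).reshape(t, t)
        if not np.allclose(C, C.T):
            raise ConfigError("genetic covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(C) < -1e-9):
            raise ConfigError("genetic covariance must be positive semi-definite")
        if not np.allclose(np.diag(C), self.sigma_g2):
            raise ConfigError("sigma_g2 must equal the genetic-covariance diagonal")
        if np.any(self.sigma_e2 < 0):
            raise ConfigError("sigma_e2 must be non-negative")
        self.genetic_covariance = C

    @property
    def n_traits(self) -> int:
        return len(self.names)

    def trait_index(self, name: str) -> int:
        return self.names.index(name)


# ---------------------------------------------------------------------------
# effect sampling
# ---------------------------------------------------------------------------

def sample_qtl_effects(
    n_qtl: int,
    p_negative: float = 0.9,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single-trait mutant-allele effects: Exponential(1) magnitudes with a
    negative sign at probability ``p_negative`` (mutations are deleterious on
    average); wild-type effects are zero by convention."""
    if n_qtl < 1:
        raise ConfigError("n_qtl must be >= 1")
    if not 0 <= p_negative <= 1:
        raise ConfigError("p_negative must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    mag = rng.exponential(1.0, size=n_qtl)
    sign = np.where(rng.random(n_qtl) < p_negative, -1.0, 1.0)
    return mag * sign


def sample_qtl_effects_multitrait(
    n_qtl: int,
    genetic_covariance: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Correlated traits share the QTL set: each QTL's effect vector is an
    i.i.d. draw from N(0, genetic_covariance).  Returns (n_traits, n_qtl);
    standardize per trait afterwards."""
    C = np.atleast_2d(np.asarray(genetic_covariance, dtype=float))
    if not np.allclose(C, C.T) or np.any(np.linalg.eigvalsh(C) < -1e-9):
        raise ConfigError("genetic covariance must be symmetric positive semi-definite")
    return rng.multivariate_normal(np.zeros(C.shape[0]), C, size=n_qtl,
                                   method="svd").T


def standardize_effects(
    effects: np.ndarray,
    base_qtl_dosage: np.ndarray,
    target_sigma_g2: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Scale each trait's effects by one scalar so the realized variance of
    base-cohort TBVs equals the target exactly.

    ``base_qtl_dosage``: (n_plants, n_qtl) mutant-allele counts of the
    reference base cohort.  Returns (scaled effects, per-trait scalars).
    """
    eff = np.atleast_2d(np.asarray(effects, dtype=float))
    X = np.asarray(base_qtl_dosage, dtype=float)
    if X.shape[0] < 2:
        raise StandardizationError("base cohort must hold at least 2 plants")
    target = np.broadcast_to(np.asarray(target_sigma_g2, dtype=float), (eff.shape[0],))
    g = X @ eff.T                      # (n, t)
    v = g.var(axis=0, ddof=1)
    if np.any(v <= 0):
        bad = [i for i, vi in enumerate(v) if vi <= 0]
        raise StandardizationError(f"no segregating QTL variance for trait index(es) {bad}")
    scale = np.sqrt(target / v)
    return eff * scale[:, None], scale


def compute_tbv(qtl_dosage: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """TBV g_i = sum_j x_ij a_j.  ``qtl_dosage`` (n, n_qtl) or (n_qtl,);
    ``effects`` (n_traits, n_qtl) or (n_qtl,).  Returns (n, n_traits) or
    matching lower-dimensional shapes."""
    X = np.asarray(qtl_dosage, dtype=float)
    a = np.asarray(effects, dtype=float)
    return X @ a.T if a.ndim == 2 else X @ a


# ---------------------------------------------------------------------------
# residual-variance calibration and phenotypes
# ---------------------------------------------------------------------------

def calibrate_residual_variance(
    sigma_g2: float,
    h2_plot: float,
    ns: int,
    homozygosity: float,
) -> float:
    """Closed-form residual variance for a target plot heritability (see
    module docstring for the decomposition).  Raises if the target is
    infeasible (negative residual variance)."""
    if not 0 < h2_plot <= 1:
        raise ConfigError("h2_plot must be in (0, 1]")
    if ns < 1:
        raise ConfigError("ns (plants per plot) must be >= 1")
    if not 0 <= homozygosity <= 1:
        raise ConfigError("homozygosity must be in [0, 1]")
    se2 = (2.0 * ns * homozygosity * sigma_g2 * (1.0 - h2_plot) / h2_plot
           - (1.0 - homozygosity) * sigma_g2)
    if se2 < 0:
        bound = 2.0 * ns * homozygosity / (2.0 * ns * homozygosity + (1.0 - homozygosity))
        raise InfeasibleError(
            f"h2_plot={h2_plot} infeasible at H={homozygosity}, Ns={ns}: "
            f"maximum attainable h2_plot is {bound:.6g}"
        )
    return float(se2)


def residual_variance_from_h2(sigma_g2: float, h2: float) -> float:
    """Individual-plant heritability: sigma_e2 = sigma_g2 (1 - h2) / h2."""
    if not 0 < h2 <= 1:
        raise ConfigError("h2 must be in (0, 1]")
    return float(sigma_g2 * (1.0 - h2) / h2)


def realized_homozygosity(alleles: np.ndarray) -> float:
    """Mean homozygosity over selectable loci of a cohort, alleles (n, 2, L)."""
    return float((alleles[:, 0, :] == alleles[:, 1, :]).mean())


def expected_selfing_homozygosity(n_selfings: int) -> float:
    """Expected homozygosity 1 - (1/2)^t after t selfings of a fully
    heterozygous plant (the usual override for generation F(t+1))."""
    if n_selfings < 0:
        raise ConfigError("n_selfings must be >= 0")
    return 1.0 - 0.5 ** n_selfings


def realize_phenotypes(
    tbv: np.ndarray,
    sigma_e2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """y = g + e with e ~ N(0, sigma_e2), i.i.d. across plants/observations."""
    tbv = np.asarray(tbv, dtype=float)
    if sigma_e2 < 0:
        raise ConfigError("sigma_e2 must be non-negative")
    return tbv + rng.normal(0.0, np.sqrt(sigma_e2), size=tbv.shape)


def plot_phenotype(member_phenotypes: np.ndarray,
                   member_tbv: np.ndarray | None = None) -> tuple[float, float | None]:
    """Plot value = SUM of member phenotypes (companion TBV sum for
    diagnostics); empty plots are an error."""
    y = np.asarray(member_phenotypes, dtype=float)
    if y.size == 0:
        raise ConfigError("plot must contain at least one plant")
    tsum = None if member_tbv is None else float(np.sum(member_tbv))
    return float(y.sum()), tsum


def aggregate_breeding_value(tbv: np.ndarray, economic_values: np.ndarray) -> np.ndarray:
    """True aggregate breeding value: TBVs weighted by economic values,
    summed over traits.  ``tbv`` (n, t) or (t,)."""
    g = np.asarray(tbv, dtype=float)
    v = np.asarray(economic_values, dtype=float)
    if g.shape[-1] != v.size:
        raise ConfigError("economic value length does not match trait count")
    return g @ v


def infinitesimal_offspring_tbv(
    sire_tbv: np.ndarray | float,
    dam_tbv: np.ndarray | float,
    sire_f: np.ndarray | float,
    dam_f: np.ndarray | float,
    sigma_g2: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray | float:
    """Polygenic alternative to the locus-level model: offspring TBV is the
    midparent plus a Mendelian sampling deviation
    m ~ N(0, 0.5 * sigma_g2 * (1 - (F_s + F_d) / 2))."""
    fs = np.asarray(sire_f, dtype=float)
    fd = np.asarray(dam_f, dtype=float)
    if np.any(fs < 0) or np.any(fs > 1) or np.any(fd < 0) or np.any(fd > 1):
        raise ConfigError("inbreeding coefficients must be in [0, 1]")
    mid = (np.asarray(sire_tbv, dtype=float) + np.asarray(dam_tbv, dtype=float)) / 2.0
    var = 0.5 * sigma_g2 * (1.0 - (fs + fd) / 2.0)
    shape = (size,) if size is not None else np.broadcast(mid, var).shape
    m = rng.normal(0.0, 1.0, size=shape) * np.sqrt(var)
    return mid + m
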