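"""Seed propagation: cross enumeration under usage caps, crossing, selfing,
cloning and doubled haploids.

Crosses are unordered parent pairs without selfing and without reciprocals
(no maternal effects are modeled).  A requested cross set is drawn by
rejection sampling from the full pair set under the per-parent usage cap,
with a seeded usage-balanced greedy fallback when rejection keeps failing
(e.g. when the cap is exactly tight).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InfeasibleError
from .genome import GenomeMap, sample_gametes

log = logging.getLogger(__name__)

MAX_REJECTION_ATTEMPTS = 1000


@dataclass
class PropagationRule:
    """How a selected stage multiplies: selfing | crossing | cloning | dh,
    with seed counts resolved per plant or per family by the stage's
    selection unit."""

    type: str = "selfing"
    n_seeds: int = 1
    per: str = "plant"                 # "plant" | "family"
    scope: str = "population"          # crossing scope
    max_uses: int = 1
    n_crosses: int | None = None

    def __post_init__(self) -> None:
        if self.type not in ("selfing", "crossing", "cloning", "dh"):
            raise ConfigError(f"unknown propagation type {self.type!r}")
        if self.n_seeds < 1:
            raise ConfigError("n_seeds must be >= 1")
        if self.type == "crossing" and self.max_uses < 1:
            raise ConfigError("max_uses must be >= 1 for crossing")


def enumerate_crosses(
    parent_ids: np.ndarray | list[int],
    n_crosses: int,
    max_uses: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Pick ``n_crosses`` unordered parent pairs, no parent in more than
    ``max_uses`` pairs.

    Rejection sampling over the C(n, 2) candidate set; after
    ``MAX_REJECTION_ATTEMPTS`` failures a seeded usage-balanced greedy fill
    takes over (logged).  Infeasible requests
    (n_crosses > max_uses * n_parents / 2 or > C(n, 2)) raise with the bound.
    """
    parents = list(parent_ids)
    n = len(parents)
    if n < 2:
        raise ConfigError("crossing needs at least 2 parents")
    pairs = list(itertools.combinations(range(n), 2))
    cap_bound = max_uses * n // 2
    if n_crosses > len(pairs):
        raise InfeasibleError(f"n_crosses {n_crosses} exceeds C({n},2) = {len(pairs)}")
    if n_crosses > cap_bound:
        raise InfeasibleError(
            f"n_crosses {n_crosses} exceeds max_uses*n_parents/2 = {cap_bound}"
        )

    for _ in range(MAX_REJECTION_ATTEMPTS):
        pick = rng.choice(len(pairs), size=n_crosses, replace=False)
        usage = np.zeros(n, dtype=np.int64)
        for k in pick:
            i, j = pairs[k]
            usage[i] += 1
            usage[j] += 1
        if usage.max() <= max_uses:
            return [(parents[pairs[k][0]], parents[pairs[k][1]]) for k in sorted(pick)]

    log.info("cross enumeration: rejection failed %d times; greedy usage-balanced fill",
             MAX_REJECTION_ATTEMPTS)
    return _greedy_cross_fill(parents, n_crosses, max_uses, rng)


def _greedy_cross_fill(parents: list[int], n_crosses: int, max_uses: int,
                       rng: np.random.Generator) -> list[tuple[int, int]]:
    n = len(parents)
    for _ in range(200):
        usage = np.zeros(n, dtype=np.int64)
        used_pairs: set[tuple[int, int]] = set()
        out: list[tuple[int, int]] = []
        ok = True
        for _ in range(n_crosses):
            # least-used parents first, random tie-break
            elig = np.flatnonzero(usage < max_uses)
            order = elig[np.lexsort((rng.random(elig.size), usage[elig]))]
            found = False
            for a_i in range(order.size):
                for b_i in range(a_i + 1, order.size):
                    key = (min(order[a_i], order[b_i]), max(order[a_i], order[b_i]))
                    if key not in used_pairs:
                        used_pairs.add(key)
                        usage[key[0]] += 1
                        usage[key[1]] += 1
                        out.append(key)
                        found = True
                        break
                if found:
                    break
            if not found:
                ok = False
                break
        if ok:
            return [(parents[i], parents[j]) for i, j in out]
    raise InfeasibleError("could not realize the requested cross set under the usage cap")


# ---------------------------------------------------------------------------
# offspring generation (batched over parents)
# ---------------------------------------------------------------------------

def mate_batch(
    sire_alleles: np.ndarray,
    sire_ibd: np.ndarray | None,
    dam_alleles: np.ndarray,
    dam_ibd: np.ndarray | None,
    gmap: GenomeMap,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
) -> tuple[np.ndarray, np.ndarray | None]:
    """One offspring per (sire, dam) genotype row: two independent gametes."""
    g1, i1 = sample_gametes(sire_alleles, sire_ibd, gmap, rng, mutation_rate)
    g2, i2 = sample_gametes(dam_alleles, dam_ibd, gmap, rng, mutation_rate)
    alleles = np.stack([g1, g2], axis=1)
    ibd = None if i1 is None else np.stack([i1, i2], axis=1)
    return alleles, ibd


def cross_offspring(sire_geno, dam_geno, n_seeds: int, gmap: GenomeMap,
                    rng: np.random.Generator):
    """``n_seeds`` offspring of one sire x dam cross (single-plant API)."""
    sa = np.repeat(sire_geno[0][None, ...], n_seeds, axis=0)
    da = np.repeat(dam_geno[0][None, ...], n_seeds, axis=0)
    si = None if sire_geno[1] is None else np.repeat(sire_geno[1][None, ...], n_seeds, axis=0)
    di = None if dam_geno[1] is None else np.repeat(dam_geno[1][None, ...], n_seeds, axis=0)
    return mate_batch(sa, si, da, di, gmap, rng)


def self_progeny(geno, n_seeds: int, gmap: GenomeMap, rng: np.random.Generator):
    """``n_seeds`` self-pollinated offspring: two independent gametes of the
    same plant per seed."""
    return cross_offspring(geno, geno, n_seeds, gmap, rng)


def clone_progeny(geno, n: int):
    """``n`` exact genotype copies (new identities, clonal origin)."""
    alleles, ibd = geno
    if n == 0:
        empty_ibd = None if ibd is None else np.empty((0,) + ibd.shape, dtype=ibd.dtype)
        return np.empty((0,) + alleles.shape, dtype=alleles.dtype), empty_ibd
    out_a = np.repeat(alleles[None, ...], n, axis=0).copy()
    out_i = None if ibd is None else np.repeat(ibd[None, ...], n, axis=0).copy()
    return out_a, out_i


def make_doubled_haploids(
    alleles: np.ndarray,
    ibd: np.ndarray | None,
    gmap: GenomeMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """One doubled haploid per parent genotype row: a recombinant gamete is
    sampled and duplicated into both haplotypes (fully homozygous, F = 1)."""
    g, i = sample_gametes(alleles, ibd, gmap, rng)
    out_a = np.repeat(g[:, None, :], 2, axis=1)
    out_i = None if i is None else np.repeat(i[:, None, :], 2, axis=1)
    return out_a, out_i
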