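"""Plants, cohorts, pedigree, inbreeding and relationship matrices.

The engine works on cohorts (structure-of-arrays over plants created by the
same stage); :class:`Plant` is a per-plant view for inspection.  Pedigree
inbreeding F is maintained incrementally at plant creation: Wright's
F_i = 0.5 * a(sire, dam) with the additive relationship a() evaluated by a
memoized tabular recursion; doubled haploids are set to F = 1.  Realized
inbreeding is measured independently as the fraction of neutral IBD loci at
which a plant's two haplotypes carry the same founder label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import ConfigError, SimulationError
from .genome import FounderPool, GenomeMap, Haplotype

ORIGIN_BASE = "base"
ORIGIN_CROSS = "cross"
ORIGIN_SELF = "self"
ORIGIN_CLONE = "clone"
ORIGIN_DH = "dh"

NO_FAMILY = -1


@dataclass
class Plant:
    """Per-plant view extracted from a cohort."""

    id: int
    sire_id: int | None
    dam_id: int | None
    origin: str
    cycle: int
    generation: int
    time_step_created: int
    genotype: tuple[Haplotype, Haplotype] | None
    tbv: np.ndarray
    f1_family: int
    line: int
    inbred: bool


class Pedigree:
    """id -> (sire, dam, origin, F) over all created plants.

    Base plants use sire = dam = -1; clones and DH record their single
    progenitor as both parents.  Creation order is topological (parents
    precede offspring), which the tabular recursion relies on.
    """

    def __init__(self) -> None:
        self.sire: list[int] = []
        self.dam: list[int] = []
        self.origin: list[str] = []
        self.f: list[float] = []
        self.generation: list[int] = []
        self.cycle: list[int] = []
        self.time_step: list[int] = []
        self._kin: dict[tuple[int, int], float] = {}

    def __len__(self) -> int:
        return len(self.sire)

    # -- creation -------------------------------------------------------
    def _append(self, sire: int, dam: int, origin: str, f: float,
                generation: int, cycle: int, time_step: int) -> int:
        if sire >= len(self) or dam >= len(self):
            raise ConfigError("parents must precede offspring in the pedigree")
        self.sire.append(sire)
        self.dam.append(dam)
        self.origin.append(origin)
        self.f.append(f)
        self.generation.append(generation)
        self.cycle.append(cycle)
        self.time_step.append(time_step)
        return len(self) - 1

    def add_base(self, inbred: bool, generation: int = 0, cycle: int = 0,
                 time_step: int = 0) -> int:
        return self._append(-1, -1, ORIGIN_BASE, 1.0 if inbred else 0.0,
                            generation, cycle, time_step)

    def add_cross(self, sire: int, dam: int, generation: int, cycle: int,
                  time_step: int) -> int:
        if not (0 <= sire < len(self) and 0 <= dam < len(self)):
            raise ConfigError("parents must precede offspring in the pedigree")
        f = 0.5 * self.kinship(sire, dam)
        return self._append(sire, dam, ORIGIN_CROSS, f, generation, cycle, time_step)

    def add_self(self, parent: int, generation: int, cycle: int, time_step: int) -> int:
        f = 0.5 * (1.0 + self.f[parent])
        return self._append(parent, parent, ORIGIN_SELF, f, generation, cycle, time_step)

    def add_clone(self, parent: int, generation: int, cycle: int, time_step: int) -> int:
        return self._append(parent, parent, ORIGIN_CLONE, self.f[parent],
                            generation, cycle, time_step)

    def add_dh(self, parent: int, generation: int, cycle: int, time_step: int) -> int:
        return self._append(parent, parent, ORIGIN_DH, 1.0, generation, cycle, time_step)

    # -- relationships --------------------------------------------------
    def kinship(self, i: int, j: int) -> float:
        """Additive relationship a(i, j); a(i, i) = 1 + F_i."""
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return 1.0 + self.f[i]
        key = (i, j) if i < j else (j, i)
        memo = self._kin
        if key in memo:
            return memo[key]
        # iterative post-order over the (pair) recursion to avoid deep stacks
        stack = [key]
        while stack:
            a, b = stack[-1]
            if (a, b) in memo:
                stack.pop()
                continue
            lo, hi = (a, b) if a < b else (b, a)
            if self.origin[hi] in (ORIGIN_CLONE, ORIGIN_DH):
                # clone/DH carry their progenitor's gametic contribution
                p = self.sire[hi]
                sub = self._pair_key(lo, p)
                if p < 0 or sub in memo or lo == p:
                    memo[(a, b)] = self._resolve_clone_dh(lo, hi)
                    stack.pop()
                else:
                    stack.append(sub)
                continue
            if self.origin[hi] == ORIGIN_BASE:
                memo[(a, b)] = 0.0
                stack.pop()
                continue
            s, d = self.sire[hi], self.dam[hi]
            need = []
            for p in (s, d):
                if p >= 0 and lo != p:
                    sub = self._pair_key(lo, p)
                    if sub not in memo:
                        need.append(sub)
            if need:
                stack.extend(need)
                continue
            memo[(a, b)] = 0.5 * (self._lookup(lo, s) + self._lookup(lo, d))
            stack.pop()
        return memo[key]

    def _pair_key(self, i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def _lookup(self, i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return 1.0 + self.f[i]
        return self._kin[self._pair_key(i, j)]

    def _resolve_clone_dh(self, lo: int, hi: int) -> float:
        p = self.sire[hi]
        base = self._lookup(lo, p) if (p < 0 or lo == p or self._pair_key(lo, p) in self._kin) \
            else self.kinship(lo, p)
        if self.origin[hi] == ORIGIN_CLONE:
            return base
        return base  # DH: both gametes copy one sampled gamete of p; E[a] = a(lo, p)

    def inbreeding(self) -> np.ndarray:
        """Wright's F for every plant (computed incrementally at creation)."""
        return np.asarray(self.f, dtype=float)

    def relationship_matrix(self, ids: np.ndarray | list[int]) -> np.ndarray:
        """Numerator relationship matrix A restricted to ``ids`` (tabular
        method over the ancestor closure); diagonal is 1 + F."""
        ids = np.asarray(ids, dtype=np.int64)
        if ids.size and (ids.min() < 0 or ids.max() >= len(self)):
            raise ConfigError("unknown plant id in relationship_matrix request")
        n = ids.size
        A = np.empty((n, n))
        for r, i in enumerate(ids):
            for c in range(r, n):
                A[r, c] = A[c, r] = self.kinship(int(i), int(ids[c]))
        return A

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "id": np.arange(len(self)),
            "sire": self.sire,
            "dam": self.dam,
            "origin": self.origin,
            "generation": self.generation,
            "cycle": self.cycle,
            "time_step": self.time_step,
            "f_pedigree": self.f,
        })


def pedigree_inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Module-level accessor for Wright's F per plant."""
    return pedigree.inbreeding()


def relationship_matrix_pedigree(pedigree: Pedigree, ids) -> np.ndarray:
    return pedigree.relationship_matrix(ids)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Plants created by one (cycle, generation) stage, stored columnar."""

    ids: np.ndarray                         # (n,) pedigree ids
    alleles: np.ndarray | None              # (n, 2, L) int8
    ibd: np.ndarray | None                  # (n, 2, K) int32
    tbv: np.ndarray                         # (n, n_traits)
    f1_family: np.ndarray                   # (n,) F1-family id or NO_FAMILY
    line: np.ndarray                        # (n,) F4-line id or NO_FAMILY
    generation: int
    cycle: int
    time_step_created: int
    inbred: bool = False
    phenotypes: dict[str, np.ndarray] = field(default_factory=dict)
    plot_of: dict[str, np.ndarray] = field(default_factory=dict)
    ebv: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return int(self.ids.size)

    def qtl_dosage(self, gmap: GenomeMap) -> np.ndarray:
        return self.alleles[:, :, gmap.qtl_indices].sum(axis=1)

    def marker_dosage(self, gmap: GenomeMap) -> np.ndarray:
        return self.alleles[:, :, gmap.marker_indices].sum(axis=1)

    def plant(self, idx: int, pedigree: Pedigree | None = None) -> Plant:
        geno = None
        if self.alleles is not None:
            geno = (
                Haplotype(self.alleles[idx, 0].copy(),
                          None if self.ibd is None else self.ibd[idx, 0].copy()),
                Haplotype(self.alleles[idx, 1].copy(),
                          None if self.ibd is None else self.ibd[idx, 1].copy()),
            )
        pid = int(self.ids[idx])
        sire = dam = None
        origin = ORIGIN_BASE
        if pedigree is not None:
            sire, dam = pedigree.sire[pid], pedigree.dam[pid]
            origin = pedigree.origin[pid]
        return Plant(
            id=pid, sire_id=sire, dam_id=dam, origin=origin,
            cycle=self.cycle, generation=self.generation,
            time_step_created=self.time_step_created, genotype=geno,
            tbv=self.tbv[idx].copy(), f1_family=int(self.f1_family[idx]),
            line=int(self.line[idx]), inbred=self.inbred,
        )


def sample_base_population(
    pool: FounderPool,
    n_plants: int,
    inbred: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample base-plant genotypes from the founder pool.

    Per plant, per chromosome: two haplotypes drawn without replacement, the
    pool replaced before the next plant.  If ``inbred``, the second haplotype
    is set identical to the first (fully homozygous self-pollinated lines).
    Returns alleles (n_plants, 2, L).
    """
    if pool.n_haplotypes < 2:
        raise ConfigError("founder pool needs at least 2 haplotypes")
    gmap = pool.gmap
    out = np.empty((n_plants, 2, gmap.n_loci), dtype=np.int8)
    for c in range(gmap.n_chrom):
        sl = gmap.chrom_slice(c)
        for i in range(n_plants):
            pick = rng.choice(pool.n_haplotypes, size=2, replace=False)
            out[i, 0, sl] = pool.haplotypes[pick[0], sl]
            out[i, 1, sl] = pool.haplotypes[pick[1] if not inbred else pick[0], sl]
    return out


def assign_ibd_alleles(
    n_plants: int,
    n_ibd: int,
    inbred: bool,
    start_label: int,
) -> tuple[np.ndarray, int]:
    """Unique founder labels at every IBD locus: one label per haplotype for
    non-inbred base plants, one shared label per plant when inbred.  Returns
    (labels (n, 2, K), next free label)."""
    ibd = np.empty((n_plants, 2, n_ibd), dtype=np.int32)
    label = start_label
    for i in range(n_plants):
        if inbred:
            ibd[i, :, :] = label
            label += 1
        else:
            ibd[i, 0, :] = label
            ibd[i, 1, :] = label + 1
            label += 2
    return ibd, label


def ibd_inbreeding(ibd: np.ndarray) -> np.ndarray:
    """Realized inbreeding: fraction of IBD loci with identical founder
    labels on the two haplotypes.  ``ibd`` (n, 2, K) or (2, K)."""
    arr = np.asarray(ibd)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return (arr[:, 0, :] == arr[:, 1, :]).mean(axis=1)


def genomic_relationship(
    dosage: np.ndarray,
    base_frequencies: np.ndarray,
) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    ``dosage`` (n, m) allele counts at marker loci; ``base_frequencies`` the
    frozen base-population allele frequencies.  Monomorphic loci (frequency 0
    or 1 in the base) are excluded; all-monomorphic input is an error.
    """
    Z = np.asarray(dosage, dtype=float)
    p = np.asarray(base_frequencies, dtype=float)
    if Z.shape[0] < 2:
        raise ConfigError("genomic relationship needs at least 2 plants")
    keep = (p > 0) & (p < 1)
    if not np.any(keep):
        raise ConfigError("all loci monomorphic; genomic relationship undefined")
    Zc = Z[:, keep] - 2.0 * p[keep]
    denom = 2.0 * np.sum(p[keep] * (1.0 - p[keep]))
    return (Zc @ Zc.T) / denom


# ---------------------------------------------------------------------------
# germplasm
# ---------------------------------------------------------------------------

@dataclass
class GermplasmEntry:
    """Immutable genotype snapshot of a stored (selected) plant."""

    plant_id: int
    alleles: np.ndarray
    ibd: np.ndarray | None
    tbv: np.ndarray
    line: int
    criterion: float
    cycle: int
    generation: int
    time_step: int


class GermplasmStore:
    """Stored germplasm keyed by (cycle, generation)."""

    def __init__(self) -> None:
        self._entries: dict[tuple[int, int], list[GermplasmEntry]] = {}

    def store(self, key: tuple[int, int], entries: list[GermplasmEntry]) -> None:
        self._entries.setdefault(key, []).extend(entries)

    def fetch(self, key: tuple[int, int]) -> list[GermplasmEntry]:
        if key not in self._entries:
            raise SimulationError(f"no germplasm stored for (cycle, generation) = {key}")
        return list(self._entries[key])

    def keys(self) -> list[tuple[int, int]]:
        return sorted(self._entries)

    def all_entries(self) -> Iterator[GermplasmEntry]:
        for key in self.keys():
            yield from self._entries[key]

    def __len__(self) -> int:
        return sum(len(v) for v in self._entries.values())


def store_germplasm(store: GermplasmStore, key: tuple[int, int],
                    entries: list[GermplasmEntry]) -> None:
    store.store(key, entries)


def fetch_germplasm(store: GermplasmStore, key: tuple[int, int]) -> list[GermplasmEntry]:
    return store.fetch(key)
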