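"""Genome layout, founder-population simulation, meiosis and genotype I/O.

The genome is a set of chromosomes measured in Morgans.  Selectable loci
(bi-allelic QTLs and markers, allele codes 0 = wild type / 1 = mutant) sit at
evenly spaced positions; a separate set of equidistant neutral IBD loci
carries integer founder labels used to measure realized inbreeding.  Founder
linkage disequilibrium is generated by a Fisher-Wright process with mutation,
drift and truncation selection on fitness (true breeding value).

Meiosis follows a no-interference crossover model: the number of crossovers
per chromosome is Poisson with mean equal to the map length in Morgans, and
breakpoints fall uniformly along the chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError

ROLE_MARKER = 0
ROLE_QTL = 1
ROLE_NAMES = {ROLE_MARKER: "MARKER", ROLE_QTL: "QTL"}


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome/locus layout.

    Selectable loci (QTLs + markers) and IBD loci are stored flattened across
    chromosomes; per-chromosome views are obtained through ``chrom_slice`` and
    ``ibd_slice``.
    """

    chrom_lengths: np.ndarray          # (C,) Morgans
    n_loci_per_chrom: np.ndarray       # (C,) selectable loci
    positions: np.ndarray              # (L,) Morgans, flattened
    roles: np.ndarray                  # (L,) ROLE_QTL / ROLE_MARKER
    n_ibd_per_chrom: np.ndarray        # (C,)
    ibd_positions: np.ndarray          # (K,) Morgans, flattened
    qtl_every_n: int | None = None

    def __post_init__(self) -> None:
        for c in range(self.n_chrom):
            pos = self.positions[self.chrom_slice(c)]
            if pos.size and not np.all(np.diff(pos) > 0):
                raise ConfigError(f"locus positions not strictly increasing on chromosome {c + 1}")
            if pos.size and (pos[0] < 0 or pos[-1] > self.chrom_lengths[c]):
                raise ConfigError(f"locus positions outside [0, length] on chromosome {c + 1}")

    # -- derived layout -------------------------------------------------
    @property
    def n_chrom(self) -> int:
        return int(self.chrom_lengths.size)

    @property
    def n_loci(self) -> int:
        return int(self.positions.size)

    @property
    def n_ibd(self) -> int:
        return int(self.ibd_positions.size)

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_QTL)

    @property
    def marker_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_MARKER)

    @property
    def n_qtl(self) -> int:
        return int(np.count_nonzero(self.roles == ROLE_QTL))

    def _offsets(self, counts: np.ndarray) -> np.ndarray:
        return np.concatenate(([0], np.cumsum(counts)))

    def chrom_slice(self, c: int) -> slice:
        off = self._offsets(self.n_loci_per_chrom)
        return slice(int(off[c]), int(off[c + 1]))

    def ibd_slice(self, c: int) -> slice:
        off = self._offsets(self.n_ibd_per_chrom)
        return slice(int(off[c]), int(off[c + 1]))


@dataclass
class Haplotype:
    """One haploid genome: selectable-locus alleles plus IBD founder labels."""

    alleles: np.ndarray                # (L,) int8 in {0, 1}
    ibd_alleles: np.ndarray | None = None   # (K,) int32 founder labels


@dataclass
class FounderConfig:
    """Fisher-Wright founder-population settings.

    ``culling_fraction`` of each generation's offspring (lowest TBV) are
    culled and replaced by freshly resampled matings, introducing selection.
    ``size_schedule`` optionally sets per-generation offspring counts to
    create long/short-range LD via expansion and contraction.
    """

    n_pat: int = 50
    n_mat: int = 50
    ng_founder: int = 100
    mutation_rate: float = 2.5e-3
    culling_fraction: float = 0.05
    p_negative_effect: float = 0.9
    size_schedule: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if self.n_pat < 1 or self.n_mat < 1:
            raise ConfigError("need at least one paternal and one maternal founder")
        if not 0 <= self.culling_fraction < 1:
            raise ConfigError("culling_fraction must be in [0, 1)")
        if not 0 <= self.mutation_rate < 1:
            raise ConfigError("mutation_rate must be in [0, 1)")
        if self.size_schedule is not None and len(self.size_schedule) > self.ng_founder:
            raise ConfigError("size_schedule longer than ng_founder")


@dataclass
class FounderPool:
    """Pooled haplotypes of the final founder generation.

    ``haplotypes`` has shape (H, L) over selectable loci; base-population
    sampling draws chromosome segments from it independently per chromosome.
    """

    haplotypes: np.ndarray
    gmap: GenomeMap
    provenance: str = "simulated"
    cull_counts: list[int] | None = None   # per founder generation diagnostics

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] % 2:
            raise ConfigError("founder pool must hold an even number of haplotypes")
        if self.haplotypes.shape[1] != self.gmap.n_loci:
            raise ConfigError("founder pool locus count does not match the genome map")

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes.shape[0])

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


# ---------------------------------------------------------------------------
# map construction
# ---------------------------------------------------------------------------

def build_genome_map(
    n_chrom: int,
    chrom_length: float | Sequence[float],
    n_loci: int,
    qtl_every_n: int | None = None,
    qtl_indices: Sequence[int] | None = None,
    n_qtl_random: int | None = None,
    n_ibd: int = 0,
    rng: np.random.Generator | None = None,
) -> GenomeMap:
    """Lay out ``n_loci`` selectable loci evenly across ``n_chrom`` chromosomes.

    QTL designation modes (exactly one):

    * ``qtl_every_n`` -- every N-th selectable locus (1-based within its
      chromosome) is a QTL;
    * ``qtl_indices`` -- explicit flattened 0-based locus indices;
    * ``n_qtl_random`` -- that many loci drawn uniformly without replacement
      (requires ``rng``), mirroring a random QTL designation among real
      markers.

    ``n_ibd`` equidistant neutral IBD loci are added per chromosome.  If
    ``n_loci`` is not divisible by ``n_chrom`` the remainder is spread over
    the first chromosomes.
    """
    if n_chrom < 1 or n_loci < 1:
        raise ConfigError("n_chrom and n_loci must be positive")
    if n_ibd < 0:
        raise ConfigError("n_ibd must be non-negative")
    modes = [qtl_every_n is not None, qtl_indices is not None, n_qtl_random is not None]
    if sum(modes) != 1:
        raise ConfigError("specify exactly one of qtl_every_n, qtl_indices, n_qtl_random")
    if qtl_every_n is not None and qtl_every_n < 1:
        raise ConfigError("qtl_every_n must be >= 1")

    lengths = np.broadcast_to(np.asarray(chrom_length, dtype=float), (n_chrom,)).copy()
    if np.any(lengths <= 0):
        raise ConfigError("chromosome lengths must be positive")

    per = np.full(n_chrom, n_loci // n_chrom, dtype=np.int64)
    per[: n_loci % n_chrom] += 1
    positions = np.concatenate(
        [(np.arange(m) + 0.5) * (lengths[c] / m) for c, m in enumerate(per)]
    )
    roles = np.full(n_loci, ROLE_MARKER, dtype=np.int8)
    if qtl_every_n is not None:
        off = 0
        for m in per:
            within = np.arange(1, m + 1)
            roles[off : off + m][within % qtl_every_n == 0] = ROLE_QTL
            off += int(m)
    elif qtl_indices is not None:
        idx = np.asarray(qtl_indices, dtype=np.int64)
        if idx.size == 0 or idx.min() < 0 or idx.max() >= n_loci or np.unique(idx).size != idx.size:
            raise ConfigError("qtl_indices must be unique indices in [0, n_loci)")
        roles[idx] = ROLE_QTL
    else:
        if rng is None:
            raise ConfigError("n_qtl_random requires a seeded rng")
        if not 1 <= n_qtl_random <= n_loci:
            raise ConfigError("n_qtl_random out of range")
        roles[rng.choice(n_loci, size=n_qtl_random, replace=False)] = ROLE_QTL

    n_ibd_per = np.full(n_chrom, n_ibd, dtype=np.int64)
    ibd_positions = np.concatenate(
        [(np.arange(n_ibd) + 0.5) * (lengths[c] / max(n_ibd, 1)) for c in range(n_chrom)]
    ) if n_ibd else np.empty(0)

    return GenomeMap(
        chrom_lengths=lengths,
        n_loci_per_chrom=per,
        positions=positions,
        roles=roles,
        n_ibd_per_chrom=n_ibd_per,
        ibd_positions=np.asarray(ibd_positions, dtype=float),
        qtl_every_n=qtl_every_n,
    )


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def sample_gametes(
    alleles: np.ndarray,
    ibd: np.ndarray | None,
    gmap: GenomeMap,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw one gamete per parent genotype, vectorized over parents.

    ``alleles`` has shape (n, 2, L); ``ibd`` (n, 2, K) or None.  Per
    chromosome, crossover counts are Poisson(length in Morgans), breakpoints
    uniform, starting strand uniform; alleles are copied switching strand at
    each breakpoint (a breakpoint exactly on a locus, a measure-zero event,
    leaves the locus with the left segment).  IBD labels are inherited through
    the identical breakpoint process.  Mutation (allele toggle) is applied per
    selectable locus afterwards.
    """
    n = alleles.shape[0]
    out = np.empty((n, gmap.n_loci), dtype=alleles.dtype)
    out_ibd = np.empty((n, gmap.n_ibd), dtype=ibd.dtype) if ibd is not None else None

    for c in range(gmap.n_chrom):
        length = float(gmap.chrom_lengths[c])
        sl = gmap.chrom_slice(c)
        isl = gmap.ibd_slice(c)
        pos = gmap.positions[sl]
        ipos = gmap.ibd_positions[isl]

        k = rng.poisson(length, size=n)
        kmax = int(k.max(initial=0))
        if kmax:
            bp = rng.uniform(0.0, length, size=(n, kmax))
            bp[np.arange(kmax)[None, :] >= k[:, None]] = length + 1.0  # pad inert
        s0 = rng.integers(0, 2, size=n)

        for lo in range(0, n, 8192):
            hi = min(lo + 8192, n)
            if kmax:
                cnt = (bp[lo:hi, :, None] < pos[None, None, :]).sum(axis=1)
                strand = (s0[lo:hi, None] + cnt) & 1
            else:
                strand = np.broadcast_to(s0[lo:hi, None], (hi - lo, pos.size))
            a = alleles[lo:hi, :, sl]
            out[lo:hi, sl] = np.where(strand == 0, a[:, 0, :], a[:, 1, :])
            if out_ibd is not None and ipos.size:
                if kmax:
                    icnt = (bp[lo:hi, :, None] < ipos[None, None, :]).sum(axis=1)
                    istrand = (s0[lo:hi, None] + icnt) & 1
                else:
                    istrand = np.broadcast_to(s0[lo:hi, None], (hi - lo, ipos.size))
                b = ibd[lo:hi, :, isl]
                out_ibd[lo:hi, isl] = np.where(istrand == 0, b[:, 0, :], b[:, 1, :])

    if mutation_rate > 0:
        flips = rng.random((n, gmap.n_loci)) < mutation_rate
        out ^= flips.astype(out.dtype)
    return out, out_ibd


def sample_gamete(
    genotype: tuple[Haplotype, Haplotype],
    gmap: GenomeMap,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
) -> Haplotype:
    """Single-plant convenience wrapper around :func:`sample_gametes`."""
    h1, h2 = genotype
    alleles = np.stack([h1.alleles, h2.alleles])[None, :, :]
    ibd = None
    if h1.ibd_alleles is not None and h2.ibd_alleles is not None:
        ibd = np.stack([h1.ibd_alleles, h2.ibd_alleles])[None, :, :]
    a, b = sample_gametes(alleles, ibd, gmap, rng, mutation_rate)
    return Haplotype(alleles=a[0], ibd_alleles=None if b is None else b[0])


# ---------------------------------------------------------------------------
# founder simulation
# ---------------------------------------------------------------------------

def simulate_founder_population(
    cfg: FounderConfig,
    gmap: GenomeMap,
    effects: np.ndarray,
    rng: np.random.Generator,
    initial: np.ndarray | None = None,
) -> FounderPool:
    """Fisher-Wright founder process building mutation-drift-selection LD.

    Starts from an all-wild-type population of ``n_pat + n_mat`` plants and
    runs ``ng_founder`` discrete generations of random mating without selfing
    (disjoint paternal/maternal pools).  Each transmitted gamete mutates per
    locus at ``mutation_rate``; each generation the ``culling_fraction`` of
    offspring with lowest TBV (fitness) are culled and replaced by resampled
    matings.  Returns the pooled haplotypes of the final generation.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.size != gmap.n_qtl:
        raise ConfigError(f"effects length {effects.size} != number of QTLs {gmap.n_qtl}")
    if cfg.n_pat + cfg.n_mat < 2:
        raise ConfigError("founder population needs at least 2 plants")

    qtl = gmap.qtl_indices
    n0 = cfg.n_pat + cfg.n_mat
    if initial is None:
        alleles = np.zeros((n0, 2, gmap.n_loci), dtype=np.int8)
    else:
        alleles = np.asarray(initial, dtype=np.int8)
        if alleles.shape != (n0, 2, gmap.n_loci):
            raise ConfigError("initial genotypes must have shape (n_pat+n_mat, 2, n_loci)")
    pat = np.arange(cfg.n_pat)
    mat = np.arange(cfg.n_pat, n0)

    def _offspring(n_off: int) -> np.ndarray:
        sires = rng.choice(pat, size=n_off, replace=True)
        dams = rng.choice(mat, size=n_off, replace=True)
        g1, _ = sample_gametes(alleles[sires], None, gmap, rng, cfg.mutation_rate)
        g2, _ = sample_gametes(alleles[dams], None, gmap, rng, cfg.mutation_rate)
        return np.stack([g1, g2], axis=1)

    cull_counts: list[int] = []
    for g in range(cfg.ng_founder):
        n_off = n0
        if cfg.size_schedule is not None and g < len(cfg.size_schedule):
            n_off = int(cfg.size_schedule[g])
            if n_off < 2:
                raise ConfigError("size_schedule entries must be >= 2")
        off = _offspring(n_off)
        n_cull = int(np.floor(cfg.culling_fraction * n_off))
        cull_counts.append(n_cull)
        if n_cull:
            tbv = off[:, :, qtl].sum(axis=1).astype(float) @ effects
            worst = np.argsort(tbv, kind="stable")[:n_cull]
            off[worst] = _offspring(n_cull)
        alleles = off
        perm = rng.permutation(n_off)
        pat = perm[: n_off // 2]
        mat = perm[n_off // 2 :]
        if pat.size < 1 or mat.size < 1:
            raise ConfigError("founder population collapsed below 2 plants")

    pool = alleles.reshape(-1, gmap.n_loci).copy()
    freq = pool.mean(axis=0)
    if np.all((freq == 0) | (freq == 1)):
        warnings.warn("founder pool is monomorphic at every locus", stacklevel=2)
    return FounderPool(haplotypes=pool, gmap=gmap, provenance="simulated",
                       cull_counts=cull_counts)


# ---------------------------------------------------------------------------
# phased-genotype I/O (tabular dialect)
# ---------------------------------------------------------------------------

MAP_COLUMNS = ["chromosome", "locus_id", "position_morgans", "role"]


def export_phased_genomes(pool: FounderPool, map_file, genotype_file) -> None:
    """Write a founder pool in the tabular dialect read by
    :func:`import_phased_genomes` (haplotype pairs become individuals)."""
    gmap = pool.gmap
    rows = []
    i = 0
    for c in range(gmap.n_chrom):
        for p, r in zip(gmap.positions[gmap.chrom_slice(c)], gmap.roles[gmap.chrom_slice(c)]):
            rows.append((c + 1, f"L{i}", p, ROLE_NAMES[int(r)]))
            i += 1
        for p in gmap.ibd_positions[gmap.ibd_slice(c)]:
            rows.append((c + 1, f"I{i}", p, "IBD"))
            i += 1
    pd.DataFrame(rows, columns=MAP_COLUMNS).to_csv(map_file, sep="\t", index=False)

    haps = pool.haplotypes
    with open(genotype_file, "w") as fh:
        for ind in range(haps.shape[0] // 2):
            for h in (0, 1):
                codes = "\t".join(str(int(a)) for a in haps[2 * ind + h])
                fh.write(f"IND{ind + 1}\t{h + 1}\t{codes}\n")


def import_phased_genomes(map_file, genotype_file) -> tuple[GenomeMap, FounderPool]:
    """Read externally supplied phased genotypes.

    Map file: TSV with columns chromosome, locus_id, position_morgans, role
    (QTL / MARKER / IBD).  Genotype file: TSV rows individual_id,
    haplotype_index in {1, 2}, then one allele code in {0, 1} per
    selectable locus in map order.
    """
    try:
        mp = pd.read_csv(map_file, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{map_file}: cannot parse map file ({exc})") from exc
    if list(mp.columns) != MAP_COLUMNS:
        raise ParseError(f"{map_file}: expected columns {MAP_COLUMNS}, got {list(mp.columns)}")
    chroms = mp["chromosome"].to_numpy()
    if np.any(np.diff(chroms) < 0):
        raise ParseError(f"{map_file}: chromosomes out of order")

    sel = mp[mp["role"].isin(["QTL", "MARKER"])]
    ibd = mp[mp["role"] == "IBD"]
    bad = mp[~mp["role"].isin(["QTL", "MARKER", "IBD"])]
    if len(bad):
        raise ParseError(f"{map_file}: unknown role at line {int(bad.index[0]) + 2}")

    chrom_ids = np.unique(chroms)
    lengths, per, ibd_per, positions, roles, ipositions = [], [], [], [], [], []
    for cid in chrom_ids:
        s = sel[sel["chromosome"] == cid]
        i = ibd[ibd["chromosome"] == cid]
        pos = s["position_morgans"].to_numpy(dtype=float)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ParseError(f"{map_file}: unsorted positions on chromosome {cid}")
        positions.append(pos)
        ipositions.append(i["position_morgans"].to_numpy(dtype=float))
        roles.append(np.where(s["role"].to_numpy() == "QTL", ROLE_QTL, ROLE_MARKER))
        per.append(pos.size)
        ibd_per.append(len(i))
        hi = max(pos.max(initial=0.0), i["position_morgans"].max() if len(i) else 0.0)
        lengths.append(hi * (1 + 1e-9) if hi > 0 else 1.0)

    gmap = GenomeMap(
        chrom_lengths=np.asarray(lengths, dtype=float),
        n_loci_per_chrom=np.asarray(per, dtype=np.int64),
        positions=np.concatenate(positions) if positions else np.empty(0),
        roles=np.concatenate(roles).astype(np.int8),
        n_ibd_per_chrom=np.asarray(ibd_per, dtype=np.int64),
        ibd_positions=np.concatenate(ipositions) if ipositions else np.empty(0),
    )

    haps: list[np.ndarray] = []
    with open(genotype_file) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 + gmap.n_loci:
                raise ParseError(
                    f"{genotype_file}: line {ln} has {len(parts) - 2} allele codes, "
                    f"expected {gmap.n_loci}"
                )
            if parts[1] not in ("1", "2"):
                raise ParseError(f"{genotype_file}: line {ln}: haplotype_index must be 1 or 2")
            codes = np.array(parts[2:], dtype=np.int64)
            if np.any((codes != 0) & (codes != 1)):
                raise ParseError(f"{genotype_file}: line {ln}: allele codes must be 0 or 1")
            haps.append(codes.astype(np.int8))
    if not haps or len(haps) % 2:
        raise ParseError(f"{genotype_file}: expected an even, positive number of haplotype rows")
    pool = FounderPool(haplotypes=np.stack(haps), gmap=gmap, provenance="imported")
    return gmap, pool


def import_phased_vcf(vcf_file, morgans_per_bp: float = 1e-8) -> tuple[GenomeMap, FounderPool]:
    """Optional phased-VCF founder import (bi-allelic, fully phased GT only).

    Physical coordinates are converted to map positions at a constant
    ``morgans_per_bp`` (default 1 cM/Mb).  All loci are imported as markers;
    re-designate QTLs afterwards if needed.
    """
    from cyvcf2 import VCF  # deferred: optional dependency path

    chrom_order: list[str] = []
    per_chrom: dict[str, list[tuple[float, np.ndarray]]] = {}
    for var in VCF(str(vcf_file)):
        if len(var.ALT) != 1:
            raise ParseError(f"{vcf_file}: {var.CHROM}:{var.POS}: only bi-allelic records accepted")
        gts = np.asarray(var.genotype.array())
        if np.any(gts[:, 2] != 1):
            raise ParseError(f"{vcf_file}: {var.CHROM}:{var.POS}: genotypes must be phased")
        if var.CHROM not in per_chrom:
            per_chrom[var.CHROM] = []
            chrom_order.append(var.CHROM)
        per_chrom[var.CHROM].append((var.POS * morgans_per_bp, gts[:, :2].T.reshape(-1)))

    lengths, per, positions, cols = [], [], [], []
    for ch in chrom_order:
        entries = per_chrom[ch]
        pos = np.array([e[0] for e in entries])
        if np.any(np.diff(pos) <= 0):
            raise ParseError(f"{vcf_file}: unsorted positions on {ch}")
        positions.append(pos)
        per.append(pos.size)
        lengths.append(pos.max() * (1 + 1e-9))
        cols.extend(e[1] for e in entries)
    haps = np.stack(cols, axis=1).astype(np.int8)
    gmap = GenomeMap(
        chrom_lengths=np.asarray(lengths, dtype=float),
        n_loci_per_chrom=np.asarray(per, dtype=np.int64),
        positions=np.concatenate(positions),
        roles=np.full(sum(per), ROLE_MARKER, dtype=np.int8),
        n_ibd_per_chrom=np.zeros(len(per), dtype=np.int64),
        ibd_positions=np.empty(0),
    )
    return gmap, FounderPool(haplotypes=haps, gmap=gmap, provenance="imported")
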