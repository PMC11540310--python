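"""Phased genomes, linkage maps, meiosis, crossing and single-seed descent.

Individuals are diploid and fully phased: a population stores two
haplotype matrices (individuals x markers, alleles coded 0/1).  The
marker score is ``hap0 + hap1 - 1`` in {-1, 0, 1}.  Meiosis follows a
no-interference model: the gamete starts on a uniformly chosen parental
haplotype on each chromosome and switches haplotype independently at
each marker interval with the interval's recombination fraction
(equivalent, at marker resolution, to Haldane/Poisson crossovers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


def haldane(d: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance ``d`` in Morgans,
    r = (1 - exp(-2d)) / 2 (no crossover interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d, dtype=float)))


def inverse_haldane(r: np.ndarray | float) -> np.ndarray | float:
    """Map distance in Morgans for a recombination fraction ``r`` < 0.5."""
    return -0.5 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


@dataclass(frozen=True)
class LinkageMap:
    """Marker positions in Morgans plus per-interval recombination fractions.

    ``interval_r`` has length ``L - 1``; the entry between the last marker
    of one chromosome and the first marker of the next is fixed at 0.5,
    which makes chromosome starts independent uniform draws when meiosis
    is implemented as a single switch chain over all markers.
    """

    chrom: np.ndarray
    pos_morgans: np.ndarray
    interval_r: np.ndarray = field(init=False)

    def __post_init__(self):
        chrom = np.asarray(self.chrom)
        pos = np.asarray(self.pos_morgans, dtype=float)
        if chrom.shape != pos.shape or chrom.ndim != 1:
            raise ValueError("chrom and pos_morgans must be 1-D arrays of equal length")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos_morgans", pos)
        if len(pos) > 1:
            same = chrom[1:] == chrom[:-1]
            d = np.diff(pos)
            if np.any(d[same] <= 0):
                raise ValueError("marker positions must be strictly increasing within a chromosome")
            r = np.where(same, haldane(np.abs(d)), 0.5)
        else:
            r = np.empty(0)
        object.__setattr__(self, "interval_r", r)

    @property
    def n_markers(self) -> int:
        return len(self.pos_morgans)

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        _, idx = np.unique(self.chrom, return_index=True)
        return list(self.chrom[np.sort(idx)])

    def chromosome_slices(self):
        """Yield ``(label, slice)`` per chromosome (markers are contiguous)."""
        chrom = self.chrom
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                yield chrom[start], slice(start, i)
                start = i

    def pair_r(self, l: int, m: int) -> float:
        """Recombination fraction between two markers on the same chromosome."""
        if self.chrom[l] != self.chrom[m]:
            raise ValueError("markers are on different chromosomes")
        return float(haldane(abs(self.pos_morgans[m] - self.pos_morgans[l])))


def build_linkage_map(chrom, pos_bp, chrom_length_morgans: float = 1.0) -> LinkageMap:
    """Build a map by scaling physical positions linearly onto each chromosome.

    Each chromosome spans exactly ``chrom_length_morgans`` (default 1 M):
    ``pos = length * (bp - bp_min) / (bp_max - bp_min)``.  A chromosome
    with a single marker is placed at position 0.  Unsorted or duplicate
    physical positions within a chromosome are rejected.
    """
    chrom = np.asarray(chrom)
    pos_bp = np.asarray(pos_bp, dtype=float)
    if chrom.shape != pos_bp.shape:
        raise ValueError("chrom and pos_bp must have the same length")
    pos_m = np.empty(len(pos_bp))
    start = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            bp = pos_bp[start:i]
            if len(bp) > 1:
                d = np.diff(bp)
                if np.any(d < 0):
                    raise ValueError(
                        f"physical positions not sorted on chromosome {chrom[start]!r}"
                    )
                if np.any(d == 0):
                    raise ValueError(
                        f"duplicate physical positions on chromosome {chrom[start]!r}"
                    )
                pos_m[start:i] = chrom_length_morgans * (bp - bp[0]) / (bp[-1] - bp[0])
            else:
                pos_m[start:i] = 0.0
            start = i
    return LinkageMap(chrom=chrom, pos_morgans=pos_m)


def uniform_linkage_map(n_chrom: int, per_chrom: int, chrom_length_morgans: float = 1.0) -> LinkageMap:
    """Evenly spaced markers when no physical positions are available."""
    chrom = np.repeat(np.arange(n_chrom), per_chrom)
    if per_chrom > 1:
        pos = np.tile(np.linspace(0.0, chrom_length_morgans, per_chrom), n_chrom)
    else:
        pos = np.zeros(n_chrom)
    return LinkageMap(chrom=chrom, pos_morgans=pos)


@dataclass
class PhasedPopulation:
    """A set of phased diploid individuals over a common marker panel."""

    hap0: np.ndarray
    hap1: np.ndarray
    ids: list[str]
    generation: str = ""

    def __post_init__(self):
        self.hap0 = np.asarray(self.hap0, dtype=np.int8)
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)
        if self.hap0.shape != self.hap1.shape or self.hap0.ndim != 2:
            raise ValueError("hap0 and hap1 must be 2-D arrays of identical shape")
        if len(self.ids) != self.hap0.shape[0]:
            raise ValueError("number of ids must match number of individuals")

    @property
    def n_individuals(self) -> int:
        return self.hap0.shape[0]

    @property
    def n_markers(self) -> int:
        return self.hap0.shape[1]

    @property
    def score(self) -> np.ndarray:
        """Marker scores in {-1, 0, 1} (float matrix, individuals x L)."""
        return (self.hap0 + self.hap1 - 1).astype(float)

    def take(self, indices) -> "PhasedPopulation":
        indices = np.asarray(indices)
        return PhasedPopulation(
            hap0=self.hap0[indices].copy(),
            hap1=self.hap1[indices].copy(),
            ids=[self.ids[i] for i in indices],
            generation=self.generation,
        )


def _gamete_batch(hap0: np.ndarray, hap1: np.ndarray, gmap: LinkageMap,
                  rng: np.random.Generator) -> np.ndarray:
    """One gamete per row of ``hap0``/``hap1`` (vectorized meiosis).

    The haplotype-of-origin state is a XOR chain: uniform at the first
    marker, flipped at interval k with probability ``interval_r[k]``
    (0.5 across chromosome boundaries, i.e. a fresh uniform start).
    """
    n, L = hap0.shape
    state = np.empty((n, L), dtype=np.uint8)
    state[:, 0] = rng.integers(0, 2, n, dtype=np.uint8)
    if L > 1:
        switches = (rng.random((n, L - 1)) < gmap.interval_r).astype(np.uint8)
        state[:, 1:] = switches
        np.bitwise_xor.accumulate(state, axis=1, out=state)
    return np.where(state == 0, hap0, hap1)


def meiosis_gamete(hap0: np.ndarray, hap1: np.ndarray, gmap: LinkageMap,
                   rng: np.random.Generator) -> np.ndarray:
    """A single gamete from one individual's diplotype."""
    return _gamete_batch(np.atleast_2d(hap0), np.atleast_2d(hap1), gmap, rng)[0]


def cross(parent_a: PhasedPopulation, parent_b: PhasedPopulation, gmap: LinkageMap,
          n_progeny: int = 15, rng: np.random.Generator | None = None,
          generation: str = "F1") -> PhasedPopulation:
    """Cross two single individuals, producing ``n_progeny`` full sibs."""
    if parent_a.n_individuals != 1 or parent_b.n_individuals != 1:
        raise ValueError("parents must be single-individual populations")
    if parent_a.n_markers != parent_b.n_markers:
        raise ValueError("parents must share the same marker panel")
    rng = np.random.default_rng() if rng is None else rng
    a0 = np.repeat(parent_a.hap0, n_progeny, axis=0)
    a1 = np.repeat(parent_a.hap1, n_progeny, axis=0)
    b0 = np.repeat(parent_b.hap0, n_progeny, axis=0)
    b1 = np.repeat(parent_b.hap1, n_progeny, axis=0)
    h0 = _gamete_batch(a0, a1, gmap, rng)
    h1 = _gamete_batch(b0, b1, gmap, rng)
    ids = [f"{parent_a.ids[0]}x{parent_b.ids[0]}_{k}" for k in range(n_progeny)]
    return PhasedPopulation(hap0=h0, hap1=h1, ids=ids, generation=generation)


def make_crosses(pop: PhasedPopulation, pairs, gmap: LinkageMap, n_progeny: int,
                 rng: np.random.Generator, generation: str = "") -> PhasedPopulation:
    """Produce ``n_progeny`` progeny for every (i, j) pair in one batch."""
    ia = np.repeat([p[0] for p in pairs], n_progeny)
    ib = np.repeat([p[1] for p in pairs], n_progeny)
    h0 = _gamete_batch(pop.hap0[ia], pop.hap1[ia], gmap, rng)
    h1 = _gamete_batch(pop.hap0[ib], pop.hap1[ib], gmap, rng)
    # compact ids: lineage-embedding names grow without bound over cycles
    ids = [f"{generation}c{c}p{k}" for c in range(len(pairs)) for k in range(n_progeny)]
    return PhasedPopulation(hap0=h0, hap1=h1, ids=ids, generation=generation)


def self_ssd(individual: PhasedPopulation, gmap: LinkageMap, n_self: int = 7,
             n_first: int = 50, rng: np.random.Generator | None = None) -> PhasedPopulation:
    """Advance one individual to ``n_first`` inbred lines by single-seed descent.

    The first round of selfing yields ``n_first`` independent S1 progeny;
    each lineage is then advanced by ``n_self - 1`` further selfings with
    a single random seed per generation.
    """
    if individual.n_individuals != 1:
        raise ValueError("self_ssd expects a single individual")
    rng = np.random.default_rng() if rng is None else rng
    if n_self == 0:
        warnings.warn("n_self=0: returning unselfed copies of the input individual")
        return PhasedPopulation(
            hap0=np.repeat(individual.hap0, n_first, axis=0),
            hap1=np.repeat(individual.hap1, n_first, axis=0),
            ids=[f"{individual.ids[0]}_S0_{k}" for k in range(n_first)],
            generation="S0",
        )
    h0 = np.repeat(individual.hap0, n_first, axis=0)
    h1 = np.repeat(individual.hap1, n_first, axis=0)
    for _ in range(n_self):
        g0 = _gamete_batch(h0, h1, gmap, rng)
        g1 = _gamete_batch(h0, h1, gmap, rng)
        h0, h1 = g0, g1
    ids = [f"{individual.ids[0]}_S{n_self}_{k}" for k in range(n_first)]
    return PhasedPopulation(hap0=h0, hap1=h1, ids=ids, generation=f"S{n_self}")


def heterozygosity(pop: PhasedPopulation) -> tuple[np.ndarray, float]:
    """Per-individual fraction of heterozygous loci, and its mean."""
    per_ind = np.mean(pop.hap0 != pop.hap1, axis=1)
    return per_ind, float(per_ind.mean())
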