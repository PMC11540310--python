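"""Founder panels: synthetic generation, marker filtering, and the 4-way
initial population.

The synthetic generator stands in for a resequenced diversity panel: each
founder is an inbred mosaic of a small set of ancestral haplotypes with
geometric segment lengths, and founders are grouped into subpopulations
that favour different "home" ancestors, producing block LD and cluster
structure that k-means can recover.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import KMeans

from .genome import LinkageMap, PhasedPopulation, build_linkage_map, cross

_MAF_RETRIES = 500
_HOME_PROB = 0.6


@dataclass
class FounderPanel:
    """A phased accession panel plus marker metadata."""

    population: PhasedPopulation
    chrom: np.ndarray
    pos_bp: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp)
        if len(self.chrom) != self.population.n_markers or len(self.pos_bp) != len(self.chrom):
            raise ValueError("marker metadata length must match the genotype matrix")

    @property
    def n_accessions(self) -> int:
        return self.population.n_individuals

    @property
    def n_markers(self) -> int:
        return self.population.n_markers

    @property
    def score(self) -> np.ndarray:
        return self.population.score

    def linkage_map(self, chrom_length_morgans: float = 1.0) -> LinkageMap:
        return build_linkage_map(self.chrom, self.pos_bp, chrom_length_morgans)

    def take_markers(self, marker_idx) -> "FounderPanel":
        marker_idx = np.asarray(marker_idx)
        pop = PhasedPopulation(
            hap0=self.population.hap0[:, marker_idx],
            hap1=self.population.hap1[:, marker_idx],
            ids=list(self.population.ids),
            generation=self.population.generation,
        )
        return FounderPanel(population=pop, chrom=self.chrom[marker_idx],
                            pos_bp=self.pos_bp[marker_idx], provenance=self.provenance)


def _minor_allele_freq(alleles: np.ndarray) -> np.ndarray:
    p = alleles.mean(axis=0)
    return np.minimum(p, 1.0 - p)


def generate_founders(n_accessions: int = 198, n_chrom: int = 20, snp_per_chrom: int = 200,
                      n_ancestral_haplotypes: int = 8, segment_length_morgans: float = 0.1,
                      maf_min: float = 0.1, seed: int = 0) -> FounderPanel:
    """Simulate an inbred founder panel with block LD and subpopulations.

    Accessions are fully homozygous (both haplotypes identical), as
    expected of an inbred-crop diversity panel.  Markers failing the MAF
    floor have their ancestral alleles redrawn until the whole panel
    passes, with a bounded number of retries.
    """
    if n_ancestral_haplotypes < 4:
        raise ValueError("need at least 4 ancestral haplotypes")
    rng = np.random.default_rng(seed)
    L = n_chrom * snp_per_chrom
    chrom = np.repeat(np.arange(n_chrom), snp_per_chrom)

    # physical positions: sorted uniform draws per chromosome, deduplicated
    pos_bp = np.empty(L, dtype=np.int64)
    for c in range(n_chrom):
        raw = np.sort(rng.random(snp_per_chrom)) * 1e8
        raw = raw.astype(np.int64) + np.arange(snp_per_chrom)  # enforce strict increase
        pos_bp[c * snp_per_chrom:(c + 1) * snp_per_chrom] = raw

    # morgan distances between adjacent markers drive mosaic segment breaks
    gmap = build_linkage_map(chrom, pos_bp)
    d = np.abs(np.diff(gmap.pos_morgans))
    boundary = chrom[1:] != chrom[:-1]
    p_switch = np.where(boundary, 1.0, 1.0 - np.exp(-d / segment_length_morgans))

    n_subpop = 4
    home = np.arange(n_accessions) * n_subpop // n_accessions % n_ancestral_haplotypes

    switch = np.empty((n_accessions, L), dtype=bool)
    switch[:, 0] = True
    switch[:, 1:] = rng.random((n_accessions, L - 1)) < p_switch
    pick_home = rng.random((n_accessions, L)) < _HOME_PROB
    candidates = np.where(pick_home, home[:, None],
                          rng.integers(0, n_ancestral_haplotypes, (n_accessions, L)))
    seg_start = np.where(switch, np.arange(L), 0)
    seg_start = np.maximum.accumulate(seg_start, axis=1)
    ancestors = np.take_along_axis(candidates, seg_start, axis=1)

    anc_alleles = rng.integers(0, 2, (n_ancestral_haplotypes, L), dtype=np.int8)
    alleles = anc_alleles[ancestors, np.arange(L)]
    for _ in range(_MAF_RETRIES):
        bad = np.flatnonzero(_minor_allele_freq(alleles) < maf_min)
        if len(bad) == 0:
            break
        anc_alleles[:, bad] = rng.integers(0, 2, (n_ancestral_haplotypes, len(bad)),
                                           dtype=np.int8)
        alleles[:, bad] = anc_alleles[ancestors[:, bad], bad]
    else:
        raise RuntimeError(f"could not reach MAF >= {maf_min} after {_MAF_RETRIES} retries")

    pop = PhasedPopulation(hap0=alleles, hap1=alleles.copy(),
                           ids=[f"ACC{i:03d}" for i in range(n_accessions)],
                           generation="founder")
    return FounderPanel(population=pop, chrom=chrom, pos_bp=pos_bp, provenance="synthetic")


def filter_markers(panel: FounderPanel, maf_min: float = 0.1, ld_r2_max: float = 0.6,
                   window: int = 50) -> FounderPanel:
    """Greedy left-to-right LD pruning within a window, then a MAF floor.

    Within each chromosome a marker is dropped when its squared Pearson
    correlation with any retained marker among the previous ``window``
    retained markers reaches ``ld_r2_max``.  Marker order is preserved.
    """
    X = panel.score
    keep = np.zeros(panel.n_markers, dtype=bool)
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    for _, sl in panel.linkage_map().chromosome_slices():
        kept: list[int] = []
        for j in range(sl.start, sl.stop):
            if norms[j] == 0:
                keep[j] = True  # monomorphic; left for the MAF filter
                continue
            recent = [k for k in kept[-window:] if norms[k] > 0]
            drop = False
            for k in recent:
                rho = (Xc[:, j] @ Xc[:, k]) / (norms[j] * norms[k])
                if rho * rho >= ld_r2_max:
                    drop = True
                    break
            if not drop:
                keep[j] = True
                kept.append(j)
    idx = np.flatnonzero(keep)
    maf = _minor_allele_freq((panel.population.hap0[:, idx] + panel.population.hap1[:, idx]) / 2.0)
    idx = idx[maf >= maf_min]
    if len(idx) == 0:
        raise ValueError("no markers survive filtering")
    return panel.take_markers(idx)


def subsample_markers(panel: FounderPanel, per_chrom: int,
                      rng: np.random.Generator | int = 0) -> FounderPanel:
    """Uniform without-replacement subsample of markers per chromosome,
    preserving marker order."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    chosen = []
    for _, sl in panel.linkage_map().chromosome_slices():
        n = sl.stop - sl.start
        if per_chrom > n:
            raise ValueError(f"per_chrom={per_chrom} exceeds chromosome size {n}")
        chosen.append(np.sort(rng.choice(np.arange(sl.start, sl.stop), per_chrom,
                                         replace=False)))
    return panel.take_markers(np.concatenate(chosen))


def select_founder_parents(panel: FounderPanel, u: np.ndarray, k: int = 4,
                           seed: int = 0, n_restarts: int = 10) -> list[int]:
    """k-means the panel on raw marker scores; return, per cluster, the
    accession with the highest true genotypic value (ties: lowest index)."""
    u = np.asarray(u, dtype=float)
    if len(u) != panel.n_accessions:
        raise ValueError("u must have one value per accession")
    X = panel.score
    for attempt in range(5):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed + attempt)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) == k:
            break
    else:
        raise RuntimeError("k-means produced an empty cluster in every retry")
    picks = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        best = members[np.lexsort((members, -u[members]))[0]]
        picks.append(int(best))
    return picks


def make_initial_population(parents: list[PhasedPopulation], gmap: LinkageMap,
                            n: int = 150, rng: np.random.Generator | int = 0
                            ) -> PhasedPopulation:
    """4-way cross: (P1 x P2) and (P3 x P4) F1s crossed to give ``n``
    individuals carrying up to four founder alleles per locus."""
    if len(parents) != 4:
        raise ValueError("exactly 4 parents are required")
    ids = [p.ids[0] for p in parents]
    if len(set(ids)) != 4:
        raise ValueError(f"duplicate parent ids: {ids}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    f1a = cross(parents[0], parents[1], gmap, n_progeny=1, rng=rng, generation="F1")
    f1b = cross(parents[2], parents[3], gmap, n_progeny=1, rng=rng, generation="F1")
    pop = cross(f1a, f1b, gmap, n_progeny=n, rng=rng, generation="PIC0")
    pop.ids = [f"IND{i:03d}" for i in range(n)]
    return pop
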