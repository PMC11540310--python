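"""Exact moments of inbred progeny and the usefulness criterion.

For a pair of linked loci the diplotype of a selfed lineage is a Markov
chain on at most 16 states (ordered pairs of two-locus haplotypes).  The
founding distribution is either the product of two parental gamete
distributions (a cross, followed by ``n_self`` selfings) or a point mass
at an individual's own diplotype (selfing only).  One selfing step maps
the current diplotype to two independent gametes drawn from it, which is
exact for single-seed descent.  All per-pair expectations reduce to
quadratic forms in a 4x4 matrix ``V_r`` that depends only on the
recombination fraction and the number of selfings, so a whole
population's cross variances collapse to a handful of matrix products.

Variances are on the marker-score scale (x in {-1, 0, 1}), matching the
score-scale marker effects used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm, skew

from .genome import LinkageMap, PhasedPopulation, _gamete_batch, cross

# haplotype states over a locus pair: h = 2*a_l + a_m
_BIT_L = np.array([0, 0, 1, 1])
_BIT_M = np.array([0, 1, 0, 1])


def selection_intensity(pool_size: int, mode: str = "quantile") -> float:
    """Standardized multiplier for taking the single best line from a pool.

    ``quantile`` (default) returns the standard-normal quantile at
    1 - 1/pool_size, which reproduces the constants 3.004 (pool 750) and
    2.054 (pool 50).  ``truncation`` returns the classical truncation
    intensity phi(z)/p for the same tail probability.
    """
    if pool_size < 2:
        raise ValueError("pool_size must be at least 2")
    p = 1.0 / pool_size
    z = float(norm.ppf(1.0 - p))
    if mode == "quantile":
        return z
    if mode == "truncation":
        return float(norm.pdf(z) / p)
    raise ValueError(f"unknown intensity mode: {mode!r}")


@dataclass(frozen=True)
class UsefulnessScore:
    uc: float
    mu: float
    sigma: float
    intensity: float
    h: float = 1.0


@dataclass(frozen=True)
class CrossMoments:
    """Mean and inbred-progeny variance of a cross (or a selfing)."""

    mu: float
    sigma2: float

    @property
    def sigma(self) -> float:
        return float(np.sqrt(max(self.sigma2, 0.0)))


def uc_cross(mu: float, sigma: float, pool_size: int = 750, h: float = 1.0,
             mode: str = "quantile") -> UsefulnessScore:
    """Cross-level usefulness: expected best inbred line out of ``pool_size``."""
    i = selection_intensity(pool_size, mode)
    return UsefulnessScore(uc=mu + i * h * sigma, mu=mu, sigma=sigma, intensity=i, h=h)


def uc_self(g: float, sigma: float, pool_size: int = 50,
            mode: str = "quantile") -> UsefulnessScore:
    """Individual-level usefulness for advancement by selfing (h fixed at 1)."""
    i = selection_intensity(pool_size, mode)
    return UsefulnessScore(uc=g + i * sigma, mu=g, sigma=sigma, intensity=i, h=1.0)


@lru_cache(maxsize=1)
def _transition_components() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Constant 16x16 matrices A, B, C with T(r) = (1-r)^2 A + r(1-r) B + r^2 C.

    T is column-stochastic: p' = T p maps the diplotype distribution
    through one round of selfing.  The gamete distribution of diplotype
    (ha, hb) is (1-r) * (e_ha + e_hb)/2 + r * (e_rec1 + e_rec2)/2, where
    the recombinants swap the second-locus alleles.
    """
    A = np.zeros((16, 16))
    B = np.zeros((16, 16))
    C = np.zeros((16, 16))
    eye = np.eye(4)
    for ha in range(4):
        for hb in range(4):
            col = 4 * ha + hb
            u = 0.5 * (eye[ha] + eye[hb])
            rec1 = 2 * _BIT_L[ha] + _BIT_M[hb]
            rec2 = 2 * _BIT_L[hb] + _BIT_M[ha]
            v = 0.5 * (eye[rec1] + eye[rec2])
            A[:, col] = np.kron(u, u)
            B[:, col] = np.kron(u, v) + np.kron(v, u)
            C[:, col] = np.kron(v, v)
    return A, B, C


def _t_matrix(r: float) -> np.ndarray:
    A, B, C = _transition_components()
    return (1 - r) ** 2 * A + r * (1 - r) * B + r**2 * C


def _gamete_dist(h0: tuple[int, int], h1: tuple[int, int], r: float) -> np.ndarray:
    """4-vector gamete distribution of one individual at a locus pair."""
    g = np.zeros(4)
    g[2 * h0[0] + h0[1]] += (1 - r) / 2
    g[2 * h1[0] + h1[1]] += (1 - r) / 2
    g[2 * h0[0] + h1[1]] += r / 2
    g[2 * h1[0] + h0[1]] += r / 2
    return g


def pair_inbred_moments(hap_a0, hap_a1, hap_b0=None, hap_b1=None, *, r: float,
                        n_self: int, initial_cross: bool = True
                        ) -> tuple[float, float, float]:
    """Exact (E[x_l], E[x_m], cov(x_l, x_m)) of inbred progeny at two loci.

    With ``initial_cross`` the founding diplotype is (gamete from A) x
    (gamete from B) — parents may themselves be heterozygous, which makes
    the cross a 4-way cross of the four parental haplotypes — followed by
    ``n_self`` selfing transitions.  Without it, the founding state is
    A's own diplotype (pure selfing).  Reference implementation by direct
    chain iteration; the vectorized engine below is the production path.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")
    if n_self < 0:
        raise ValueError("n_self must be non-negative")
    hap_a0 = tuple(int(a) for a in hap_a0)
    hap_a1 = tuple(int(a) for a in hap_a1)
    if initial_cross:
        if hap_b0 is None or hap_b1 is None:
            raise ValueError("initial_cross=True requires both parents")
        ga = _gamete_dist(hap_a0, hap_a1, r)
        gb = _gamete_dist(tuple(int(a) for a in hap_b0), tuple(int(a) for a in hap_b1), r)
        p = np.kron(ga, gb)
    else:
        p = np.zeros(16)
        p[4 * (2 * hap_a0[0] + hap_a0[1]) + (2 * hap_a1[0] + hap_a1[1])] = 1.0
    T = _t_matrix(r)
    for _ in range(n_self):
        p = T @ p
    ha, hb = np.divmod(np.arange(16), 4)
    x_l = _BIT_L[ha] + _BIT_L[hb] - 1.0
    x_m = _BIT_M[ha] + _BIT_M[hb] - 1.0
    e_l = float(p @ x_l)
    e_m = float(p @ x_m)
    cov = float(p @ (x_l * x_m)) - e_l * e_m
    return e_l, e_m, cov


class InbredMomentEngine:
    """Vectorized exact inbred-progeny variances for a fixed map and n_self.

    Precomputes, for every within-chromosome marker pair, the 4x4 matrix
    ``V`` such that E[x_l x_m] after the selfing chain equals
    ``g_A^T V g_B`` for a cross with parental gamete distributions
    ``g_A, g_B`` (or ``V[h0, h1]`` for pure selfing of a diplotype).
    Between-chromosome pairs contribute exactly zero covariance and are
    skipped by construction.
    """

    def __init__(self, gmap: LinkageMap, n_self: int = 7, pair_chunk: int = 50_000):
        self.gmap = gmap
        self.n_self = int(n_self)
        self.pair_chunk = int(pair_chunk)
        self.half_n = 0.5**self.n_self

        l_idx, m_idx = [], []
        for _, sl in gmap.chromosome_slices():
            idx = np.arange(sl.start, sl.stop)
            if len(idx) < 2:
                continue
            li, mi = np.triu_indices(len(idx), k=1)
            l_idx.append(idx[li])
            m_idx.append(idx[mi])
        if l_idx:
            self.l_idx = np.concatenate(l_idx)
            self.m_idx = np.concatenate(m_idx)
        else:
            self.l_idx = np.empty(0, dtype=int)
            self.m_idx = np.empty(0, dtype=int)
        d = np.abs(gmap.pos_morgans[self.m_idx] - gmap.pos_morgans[self.l_idx])
        self.r = 0.5 * (1.0 - np.exp(-2.0 * d))

        A, B, C = _transition_components()
        r = self.r
        coeff = np.stack([(1 - r) ** 2, r * (1 - r), r**2], axis=1)
        T = np.einsum("pc,cij->pij", coeff, np.stack([A, B, C]))
        ha, hb = np.divmod(np.arange(16), 4)
        w = (_BIT_L[ha] + _BIT_L[hb] - 1.0) * (_BIT_M[ha] + _BIT_M[hb] - 1.0)
        # v = (T^n)^T w, built by n_self backward applications of T^T
        v = np.broadcast_to(w, (len(r), 16)).copy()
        for _ in range(self.n_self):
            v = np.einsum("pij,pi->pj", T, v)
        self.V = v.reshape(-1, 4, 4)

    @property
    def n_pairs(self) -> int:
        return len(self.l_idx)

    def self_sigma2(self, pop: PhasedPopulation, beta_hat: np.ndarray) -> np.ndarray:
        """Inbred-progeny variance of selfing each individual (length N)."""
        beta = self._check_beta(pop, beta_hat)
        h0, h1 = pop.hap0, pop.hap1
        x = pop.score
        b2 = beta**2
        diag = ((h0 != h1) @ b2) * (1.0 - self.half_n)
        if self.n_pairs == 0:
            return diag
        l, m = self.l_idx, self.m_idx
        h0i = 2 * h0[:, l] + h0[:, m]
        h1i = 2 * h1[:, l] + h1[:, m]
        e_lm = self.V[np.arange(self.n_pairs)[None, :], h0i, h1i]
        w_p = 2.0 * beta[l] * beta[m]
        pair_term = (e_lm - x[:, l] * x[:, m]) @ w_p
        return np.maximum(diag + pair_term, 0.0)

    def cross_sigma2_matrix(self, pop: PhasedPopulation, beta_hat: np.ndarray) -> np.ndarray:
        """N x N symmetric matrix of inbred-progeny variances for all crosses.

        Entry (i, j) is the GEBV variance of the inbred lines derived from
        the cross i x j by ``n_self`` rounds of selfing after the F1.
        """
        beta = self._check_beta(pop, beta_hat)
        x = pop.score
        N = pop.n_individuals
        f = (x + 1.0) / 2.0  # reference-allele dosage per individual in {0, .5, 1}
        b2 = beta**2
        n2 = self.half_n

        # single-locus variance terms, expanded into rank-one pieces
        s = f @ b2
        q = (f**2) @ b2
        F = (f * b2) @ f.T
        D = (2.0 - n2) * (s[:, None] + s[None, :]) - (q[:, None] + q[None, :]) \
            + (2.0 * n2 - 2.0) * F

        # product-of-means term: sum_p 2 b_l b_m E[x_l] E[x_m]
        R = (x * b2) @ x.T
        chrom_t = np.stack([x[:, sl] @ beta[sl] for _, sl in self.gmap.chromosome_slices()],
                           axis=1)
        u2 = np.sum(chrom_t**2, axis=1)
        TT = chrom_t @ chrom_t.T
        rdiag = np.diag(R)
        M2 = 0.25 * (u2[:, None] + u2[None, :] + 2.0 * TT
                     - rdiag[:, None] - rdiag[None, :] - 2.0 * R)

        # joint-expectation term, chunked over pairs to bound memory
        M1 = np.zeros((N, N))
        h0, h1 = pop.hap0, pop.hap1
        rows = np.arange(N)[:, None]
        for start in range(0, self.n_pairs, self.pair_chunk):
            sl = slice(start, min(start + self.pair_chunk, self.n_pairs))
            l, m, r = self.l_idx[sl], self.m_idx[sl], self.r[sl]
            P = len(l)
            cols = np.arange(P)[None, :]
            G = np.zeros((N, P, 4))
            for idx, wt in (
                (2 * h0[:, l] + h0[:, m], (1.0 - r) / 2.0),
                (2 * h1[:, l] + h1[:, m], (1.0 - r) / 2.0),
                (2 * h0[:, l] + h1[:, m], r / 2.0),
                (2 * h1[:, l] + h0[:, m], r / 2.0),
            ):
                G[rows, cols, idx] += wt
            W = np.einsum("npa,pab->npb", G, self.V[sl])
            Gw = G * (2.0 * beta[l] * beta[m])[None, :, None]
            M1 += W.reshape(N, -1) @ Gw.reshape(N, -1).T

        return np.maximum(D + M1 - M2, 0.0)

    def cross_sigma2(self, pop: PhasedPopulation, beta_hat: np.ndarray, pairs) -> np.ndarray:
        """Variances for an explicit list of (i, j) pairs."""
        mat = self.cross_sigma2_matrix(pop, beta_hat)
        return np.array([mat[i, j] for i, j in pairs])

    def _check_beta(self, pop: PhasedPopulation, beta_hat) -> np.ndarray:
        beta = np.asarray(beta_hat, dtype=float)
        if len(beta) != pop.n_markers or pop.n_markers != self.gmap.n_markers:
            raise ValueError("marker sets of population, map and effects do not match")
        return beta


def cross_inbred_sigma2(parent_a: PhasedPopulation, parent_b: PhasedPopulation,
                        gmap: LinkageMap, beta_hat: np.ndarray,
                        n_self: int = 7) -> CrossMoments:
    """Moments of the inbred progeny of one cross: mean is the parental GEBV
    midpoint, variance comes from the exact two-locus chain."""
    if parent_a.n_markers != parent_b.n_markers:
        raise ValueError("mismatched marker sets between parents")
    both = PhasedPopulation(
        hap0=np.vstack([parent_a.hap0, parent_b.hap0]),
        hap1=np.vstack([parent_a.hap1, parent_b.hap1]),
        ids=[parent_a.ids[0], parent_b.ids[0]],
    )
    engine = InbredMomentEngine(gmap, n_self=n_self)
    sigma2 = float(engine.cross_sigma2_matrix(both, beta_hat)[0, 1])
    g = both.score @ np.asarray(beta_hat, dtype=float)
    return CrossMoments(mu=float(g.mean()), sigma2=sigma2)


def self_inbred_sigma2(individual: PhasedPopulation, gmap: LinkageMap,
                       beta_hat: np.ndarray, n_self: int = 7) -> CrossMoments:
    """Moments of the inbred progeny of selfing one individual."""
    engine = InbredMomentEngine(gmap, n_self=n_self)
    sigma2 = float(engine.self_sigma2(individual, beta_hat)[0])
    g = float((individual.score @ np.asarray(beta_hat, dtype=float))[0])
    return CrossMoments(mu=g, sigma2=sigma2)


def sigma_matrix_for_cross(parent_a: PhasedPopulation, parent_b: PhasedPopulation,
                           gmap: LinkageMap, chrom_label, n_self: int = 7) -> np.ndarray:
    """Materialize the per-chromosome score covariance matrix of a cross.

    Diagonal entries are single-locus variances; off-diagonals the exact
    pair covariances.  Intended for inspection/diagnostics on small maps
    (scalar chain per pair).
    """
    sl = next(s for lab, s in gmap.chromosome_slices() if lab == chrom_label)
    idx = np.arange(sl.start, sl.stop)
    n = len(idx)
    C = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            # a == b uses the duplicated-locus encoding at r = 0, whose
            # "covariance" is the single-locus variance
            l, m = idx[a], idx[b]
            r = gmap.pair_r(l, m) if a != b else 0.0
            _, _, cov = pair_inbred_moments(
                (parent_a.hap0[0, l], parent_a.hap0[0, m]),
                (parent_a.hap1[0, l], parent_a.hap1[0, m]),
                (parent_b.hap0[0, l], parent_b.hap0[0, m]),
                (parent_b.hap1[0, l], parent_b.hap1[0, m]),
                r=r, n_self=n_self, initial_cross=True)
            C[a, b] = C[b, a] = cov
    return C


def simulate_inbred_progeny(parent_a: PhasedPopulation, parent_b: PhasedPopulation | None,
                            gmap: LinkageMap, beta_hat: np.ndarray, n_lines: int = 20_000,
                            n_self: int = 7, rng: np.random.Generator | int = 0) -> dict:
    """Monte-Carlo oracle: gamete-drop ``n_lines`` inbred lines and summarize.

    With ``parent_b`` the lines descend from independent F1s of the cross;
    without it, from selfing ``parent_a``.  Returns the GEBV sample and
    its mean/variance/skewness (a normality diagnostic for the UC).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if parent_b is not None:
        a0 = np.repeat(parent_a.hap0, n_lines, axis=0)
        a1 = np.repeat(parent_a.hap1, n_lines, axis=0)
        b0 = np.repeat(parent_b.hap0, n_lines, axis=0)
        b1 = np.repeat(parent_b.hap1, n_lines, axis=0)
        h0 = _gamete_batch(a0, a1, gmap, rng)
        h1 = _gamete_batch(b0, b1, gmap, rng)
    else:
        h0 = np.repeat(parent_a.hap0, n_lines, axis=0)
        h1 = np.repeat(parent_a.hap1, n_lines, axis=0)
    for _ in range(n_self):
        g0 = _gamete_batch(h0, h1, gmap, rng)
        g1 = _gamete_batch(h0, h1, gmap, rng)
        h0, h1 = g0, g1
    g = (h0 + h1 - 1.0) @ np.asarray(beta_hat, dtype=float)
    return {
        "gebv": g,
        "mean": float(g.mean()),
        "var": float(g.var(ddof=1)) if n_lines > 1 else 0.0,
        "skewness": float(skew(g)) if n_lines > 2 and g.std() > 0 else 0.0,
    }
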