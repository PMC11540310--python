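"""Cross-selection strategies: truncation GS with random pairing,
diversity-constrained OCS (evolutionary search), and exact usefulness-
criterion selection solved as an integer program, plus the shared
advancement (segregation/fixation) pick and diversity bookkeeping.

Every strategy returns a :class:`CrossPlan` that satisfies the common
constraints: exactly ``n_crosses`` distinct unordered pairs and no
individual used more than ``max_use`` times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

_DSEL_TOL = 1e-12


@dataclass
class CrossCandidateSet:
    """All unordered pairs (i < j) over N individuals with their scores."""

    n_individuals: int
    pair_i: np.ndarray = field(init=False)
    pair_j: np.ndarray = field(init=False)

    def __post_init__(self):
        i, j = np.triu_indices(self.n_individuals, k=1)
        self.pair_i = i
        self.pair_j = j

    @property
    def n_pairs(self) -> int:
        return len(self.pair_i)

    def mean_gebv(self, g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        return 0.5 * (g[self.pair_i] + g[self.pair_j])


@dataclass
class CrossPlan:
    pairs: list[tuple[int, int]]
    objective: float
    strategy: str
    feasible: bool = True
    mu: np.ndarray | None = None
    uc: np.ndarray | None = None

    def usage(self, n_individuals: int) -> np.ndarray:
        counts = np.zeros(n_individuals, dtype=int)
        for i, j in self.pairs:
            counts[i] += 1
            counts[j] += 1
        return counts

    def validate(self, n_individuals: int, n_crosses: int, max_use: int = 2) -> None:
        if len(self.pairs) != n_crosses:
            raise ValueError(f"plan has {len(self.pairs)} crosses, expected {n_crosses}")
        if len(set(map(tuple, self.pairs))) != n_crosses:
            raise ValueError("duplicate crosses in plan")
        if any(i == j for i, j in self.pairs):
            raise ValueError("self-cross in plan")
        if self.usage(n_individuals).max() > max_use:
            raise ValueError("an individual is used more than max_use times")


def ibs_matrix(X: np.ndarray) -> np.ndarray:
    """Identity-by-state similarity K = (X X^T / L + 1) / 2 on -1/0/1 scores."""
    X = np.asarray(X, dtype=float)
    return 0.5 * (X @ X.T / X.shape[1] + 1.0)


def initial_diversity(X: np.ndarray) -> float:
    """Mean expected heterozygosity (1/L) sum 2 p (1 - p) at reference-allele
    frequencies of the population."""
    X = np.asarray(X, dtype=float)
    p = ((X + 1.0) / 2.0).mean(axis=0)
    return float(np.mean(2.0 * p * (1.0 - p)))


def diversity_constraint_he(t: int, he0: float, t_star: int = 60, s: float = 1.0,
                            he_star: float | None = None) -> float:
    """Scheduled diversity floor: declines from He0 to He* by cycle t_star."""
    if he_star is None:
        he_star = 0.01 * he0
    if t <= t_star:
        return he0 + (t / t_star) ** s * (he_star - he0)
    return he_star


def dsel(pairs, K: np.ndarray) -> float:
    """Diversity of a plan, 1 - c^T K c with contributions c = Z a / (2 n_crosses)."""
    c = np.zeros(K.shape[0])
    for i, j in pairs:
        c[i] += 1.0
        c[j] += 1.0
    c /= c.sum()
    return float(1.0 - c @ K @ c)


def _random_two_regular(nodes: np.ndarray, rng: np.random.Generator,
                        max_tries: int = 10_000) -> list[tuple[int, int]]:
    """Uniform labeled 2-regular simple graph on ``nodes``.

    Configuration model with rejection: pair up two half-edges per node at
    random and reject self-loops and parallel edges.  Every simple
    2-regular graph corresponds to the same number (2^n) of pairings, so
    accepted draws are uniform.
    """
    half = np.repeat(nodes, 2)
    for _ in range(max_tries):
        perm = rng.permutation(half)
        edges = [tuple(sorted((int(perm[2 * k]), int(perm[2 * k + 1]))))
                 for k in range(len(nodes))]
        if any(a == b for a, b in edges) or len(set(edges)) != len(edges):
            continue
        return sorted(edges)
    raise RuntimeError("failed to sample a 2-regular pairing")


def gs_select(g: np.ndarray, rng: np.random.Generator, n_ind: int = 10) -> CrossPlan:
    """Truncation selection on GEBVs with random pairing.

    The top ``n_ind`` individuals (ties broken toward the lower index) are
    each used exactly twice in ``n_ind`` distinct random pairs.
    """
    g = np.asarray(g, dtype=float)
    if len(g) < n_ind:
        raise ValueError("population smaller than the number of selected individuals")
    order = np.lexsort((np.arange(len(g)), -g))
    selected = np.sort(order[:n_ind])
    pairs = _random_two_regular(selected, rng)
    mu = np.array([0.5 * (g[i] + g[j]) for i, j in pairs])
    return CrossPlan(pairs=pairs, objective=float(mu.sum()), strategy="gs", mu=mu)


def cps_select(uc: np.ndarray, n_individuals: int, n_crosses: int = 10,
               max_use: int = 2) -> CrossPlan:
    """Exact maximization of the summed usefulness criterion.

    Branch-and-bound integer program (HiGHS) over binary cross indicators
    with the budget and usage-cap constraints; equivalently a max-weight
    b-matching with edge budget ``n_crosses`` and degree cap ``max_use``.
    Ties are broken toward lexicographically smaller pair indices via an
    infinitesimal perturbation.
    """
    cand = CrossCandidateSet(n_individuals)
    uc = np.asarray(uc, dtype=float)
    if len(uc) != cand.n_pairs:
        raise ValueError(f"uc must have {cand.n_pairs} entries, got {len(uc)}")
    if not np.all(np.isfinite(uc)):
        raise ValueError("uc contains non-finite values")
    nc = cand.n_pairs
    scale = max(1.0, float(np.abs(uc).max()))
    eps = 1e-9 * scale / max(nc, 1)
    c = -(uc - eps * np.arange(nc))

    incidence = np.zeros((n_individuals, nc))
    incidence[cand.pair_i, np.arange(nc)] = 1.0
    incidence[cand.pair_j, np.arange(nc)] = 1.0
    constraints = [
        LinearConstraint(np.ones((1, nc)), n_crosses, n_crosses),
        LinearConstraint(incidence, 0, max_use),
    ]
    res = milp(c=c, constraints=constraints, integrality=np.ones(nc),
               bounds=Bounds(0.0, 1.0))
    if res.status != 0 or res.x is None:
        raise RuntimeError(f"integer program failed: {res.message}")
    chosen = np.flatnonzero(res.x > 0.5)
    pairs = [(int(cand.pair_i[k]), int(cand.pair_j[k])) for k in chosen]
    return CrossPlan(pairs=pairs, objective=float(uc[chosen].sum()), strategy="cps",
                     uc=uc[chosen])


def sfc_select(ucs: np.ndarray, n: int = 2) -> np.ndarray:
    """Top-n individuals by individual-level usefulness (ties: lower index).
    Selected individuals remain available as crossing parents."""
    ucs = np.asarray(ucs, dtype=float)
    order = np.lexsort((np.arange(len(ucs)), -ucs))
    return order[:n]


class _OcsSearch:
    """Evolutionary search over feasible plans for the OCS objective."""

    def __init__(self, g, K, he_t, rng, n_crosses, max_use, budget, pop_size=40,
                 n_elite=2):
        self.g = np.asarray(g, dtype=float)
        self.K = np.asarray(K, dtype=float)
        self.he_t = float(he_t)
        self.rng = rng
        self.N = len(self.g)
        self.n_crosses = n_crosses
        self.max_use = max_use
        self.budget = budget
        self.pop_size = pop_size
        self.n_elite = n_elite
        self.cand = CrossCandidateSet(self.N)
        self.mu = self.cand.mean_gebv(self.g)
        self.pair_index = -np.ones((self.N, self.N), dtype=int)
        self.pair_index[self.cand.pair_i, self.cand.pair_j] = np.arange(self.cand.n_pairs)
        self.evals = 0

    def pair_of(self, i: int, j: int) -> int:
        return int(self.pair_index[min(i, j), max(i, j)])

    def usage_of(self, plan: list[int]) -> np.ndarray:
        u = np.zeros(self.N, dtype=int)
        for k in plan:
            u[self.cand.pair_i[k]] += 1
            u[self.cand.pair_j[k]] += 1
        return u

    def random_plan(self) -> list[int]:
        for _ in range(200):
            order = self.rng.permutation(self.cand.n_pairs)
            plan: list[int] = []
            usage = np.zeros(self.N, dtype=int)
            for k in order:
                i, j = self.cand.pair_i[k], self.cand.pair_j[k]
                if usage[i] < self.max_use and usage[j] < self.max_use:
                    plan.append(int(k))
                    usage[i] += 1
                    usage[j] += 1
                    if len(plan) == self.n_crosses:
                        return plan
        raise RuntimeError("could not build a feasible random plan")

    def fitness(self, plan: list[int]) -> tuple[int, float, float]:
        self.evals += 1
        c = np.bincount(self.cand.pair_i[plan], minlength=self.N).astype(float)
        c += np.bincount(self.cand.pair_j[plan], minlength=self.N)
        c /= 2.0 * len(plan)
        ds = float(1.0 - c @ self.K @ c)
        obj = float(self.mu[plan].sum())
        feasible = ds > self.he_t + _DSEL_TOL
        # feasible plans rank by objective; infeasible ones by diversity
        return (1 if feasible else 0, obj if feasible else ds, ds)

    def mutate(self, plan: list[int]) -> list[int]:
        plan = list(plan)
        if self.rng.random() < 0.5:
            # replace one cross with a random feasible alternative
            slot = int(self.rng.integers(len(plan)))
            usage = self.usage_of(plan)
            k_old = plan[slot]
            usage[self.cand.pair_i[k_old]] -= 1
            usage[self.cand.pair_j[k_old]] -= 1
            ok = ((usage[self.cand.pair_i] < self.max_use)
                  & (usage[self.cand.pair_j] < self.max_use))
            ok[plan] = False
            choices = np.flatnonzero(ok)
            if len(choices):
                plan[slot] = int(self.rng.choice(choices))
        else:
            # swap one parent of one cross for another individual
            slot = int(self.rng.integers(len(plan)))
            k_old = plan[slot]
            i, j = int(self.cand.pair_i[k_old]), int(self.cand.pair_j[k_old])
            keep, drop = (i, j) if self.rng.random() < 0.5 else (j, i)
            usage = self.usage_of(plan)
            usage[drop] -= 1
            usage[keep] -= 1
            existing = set(plan) - {k_old}
            choices = [v for v in range(self.N)
                       if v != keep and usage[v] < self.max_use
                       and self.pair_of(keep, v) not in existing]
            if choices:
                new = choices[int(self.rng.integers(len(choices)))]
                plan[slot] = self.pair_of(keep, new)
        return plan

    def run(self) -> tuple[list[int] | None, list[int], tuple]:
        population = [self.random_plan() for _ in range(self.pop_size)]
        scored = [(self.fitness(p), p) for p in population]
        scored.sort(key=lambda t: t[0], reverse=True)
        best_feasible = None
        best_feasible_fit = None
        best_any = scored[0]
        for fit, p in scored:
            if fit[0] == 1 and (best_feasible_fit is None or fit > best_feasible_fit):
                best_feasible = p
                best_feasible_fit = fit
        while self.evals < self.budget:
            elites = [p for _, p in scored[: self.n_elite]]
            offspring = []
            for _ in range(self.pop_size - self.n_elite):
                a = scored[int(self.rng.integers(len(scored)))]
                b = scored[int(self.rng.integers(len(scored)))]
                parent = a[1] if a[0] >= b[0] else b[1]
                child = self.mutate(parent)
                if self.rng.random() < 0.3:
                    child = self.mutate(child)
                offspring.append(child)
            population = elites + offspring
            scored = [(self.fitness(p), p) for p in population]
            scored.sort(key=lambda t: t[0], reverse=True)
            if scored[0][0] > best_any[0]:
                best_any = scored[0]
            for fit, p in scored:
                if fit[0] == 1 and (best_feasible_fit is None or fit > best_feasible_fit):
                    best_feasible = p
                    best_feasible_fit = fit
        return best_feasible, best_any[1], best_any[0]


def ocs_select(g: np.ndarray, K: np.ndarray, he_t: float, rng: np.random.Generator,
               n_crosses: int = 10, max_use: int = 2, budget: int = 4000) -> CrossPlan:
    """Maximize summed mean GEBV subject to the diversity floor Dsel > He(t).

    The search is an evolutionary heuristic over feasible plans (replace-
    one-cross and swap-parent moves with repair).  If no plan satisfying
    the diversity constraint is found within the budget, the most diverse
    plan seen is returned flagged infeasible-relaxed.
    """
    search = _OcsSearch(g, K, he_t, rng, n_crosses, max_use, budget)
    best_feasible, best_any, _ = search.run()
    cand = search.cand
    if best_feasible is not None:
        pairs = sorted((int(cand.pair_i[k]), int(cand.pair_j[k])) for k in best_feasible)
        mu = np.array([0.5 * (g[i] + g[j]) for i, j in pairs])
        return CrossPlan(pairs=pairs, objective=float(mu.sum()), strategy="ocs", mu=mu)
    pairs = sorted((int(cand.pair_i[k]), int(cand.pair_j[k])) for k in best_any)
    mu = np.array([0.5 * (g[i] + g[j]) for i, j in pairs])
    return CrossPlan(pairs=pairs, objective=float(mu.sum()), strategy="ocs",
                     feasible=False, mu=mu)
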