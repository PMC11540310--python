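"""Two-part breeding-program orchestration and evaluation metrics.

One run: subsample markers from the founder panel, simulate the trait,
build the initial 4-way population, fit the prediction model once, then
iterate selection-and-crossing cycles.  Every even cycle (once per
simulated year) two individuals are advanced to inbred lines by
single-seed descent and their true genotypic values are logged for the
gain metric.  All stochastic stages draw from named substreams of the
run's master seed, and progeny generation uses streams independent of
the strategy so matched replicates differ only through selection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._rng import spawn_seed, substream
from .founders import FounderPanel, make_initial_population, select_founder_parents, subsample_markers
from .genome import PhasedPopulation, make_crosses, self_ssd
from .gp import fit_gblup, gebv
from .progeny import InbredMomentEngine, selection_intensity
from .selection import (CrossCandidateSet, cps_select, diversity_constraint_he, dsel,
                        gs_select, ibs_matrix, initial_diversity, ocs_select, sfc_select)
from .traits import assign_qtn, genotypic_value, sample_qtn_effects, simulate_phenotypes

STRATEGIES = ("gs", "ocs", "cps")


@dataclass
class ProgramConfig:
    """Parameters of one breeding-program run (defaults match the full-scale
    design: 60 cycles, 10 crosses of 15 progeny, usage cap 2, Inbred8)."""

    strategy: str = "cps"
    h2: float = 0.6
    n_cycles: int = 60
    crosses_per_cycle: int = 10
    progeny_per_cross: int = 15
    sfc_per_year: int = 2
    n_self: int = 7
    n_first_self: int = 50
    max_use: int = 2
    t_star: int = 60
    s: float = 1.0
    he_star_frac: float = 0.01
    n_chrom: int = 20
    snp_per_chrom: int = 200
    n_qtn: int = 1000
    qtn_var: float = 0.35
    ocs_budget: int = 4000
    intensity_mode: str = "quantile"
    denominator_mode: str = "variance"
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError(f"h2 must be in (0, 1], got {self.h2}")
        if self.denominator_mode not in ("variance", "sd"):
            raise ValueError("denominator_mode must be 'variance' or 'sd'")
        if self.n_qtn > self.n_chrom * self.snp_per_chrom:
            raise ValueError("n_qtn exceeds the number of markers")

    @property
    def pop_size(self) -> int:
        return self.crosses_per_cycle * self.progeny_per_cross

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationLog:
    """Per-cycle metrics and plan records of one run."""

    config: ProgramConfig
    gpic: list[float] = field(default_factory=list)
    sigma2: list[float] = field(default_factory=list)
    allele_rates: list[tuple[float, float, float]] = field(default_factory=list)
    plans: list[dict] = field(default_factory=list)
    gi8: dict[int, float] = field(default_factory=dict)
    inbred8_u: dict[int, np.ndarray] = field(default_factory=dict)
    sfc_ids: dict[int, list[int]] = field(default_factory=dict)
    baseline_u: float = 0.0
    sigma_g2_init: float = 0.0
    he0: float = 0.0


def gain_inbred8(u_batch: np.ndarray, baseline: float, sigma_g2: float,
                 denominator_mode: str = "variance") -> float:
    """Standardized gain of the best inbred line over the initial best."""
    den = sigma_g2 if denominator_mode == "variance" else float(np.sqrt(sigma_g2))
    return float((np.max(u_batch) - baseline) / den)


def gain_pic(u_pic: np.ndarray, baseline: float, sigma_g2: float,
             denominator_mode: str = "variance") -> float:
    """Standardized gain of the best current individual over the initial best."""
    den = sigma_g2 if denominator_mode == "variance" else float(np.sqrt(sigma_g2))
    return float((np.max(u_pic) - baseline) / den)


def variance_pic(u_pic: np.ndarray) -> float:
    """Population (denominator N) genetic variance of the current individuals."""
    return float(np.var(np.asarray(u_pic, dtype=float)))


def allele_state_rates(pop: PhasedPopulation, beta: np.ndarray,
                       qtn_indices: np.ndarray) -> tuple[float, float, float]:
    """Effect-weighted rates of (fixed favorable, fixed negative, non-fixed)
    causal loci.  A locus is fixed when every haplotype in the population
    carries the same allele; the fixed state is favorable when the fixed
    score times the true effect is positive.  The three rates sum to 1.
    """
    beta = np.asarray(beta, dtype=float)
    qtn = np.asarray(qtn_indices, dtype=int)
    h0 = pop.hap0[:, qtn]
    h1 = pop.hap1[:, qtn]
    all_one = np.all(h0 == 1, axis=0) & np.all(h1 == 1, axis=0)
    all_zero = np.all(h0 == 0, axis=0) & np.all(h1 == 0, axis=0)
    b = beta[qtn]
    w = np.abs(b)
    total = w.sum()
    if total == 0:
        return (0.0, 0.0, 1.0)
    fixed_score = np.where(all_one, 1.0, np.where(all_zero, -1.0, 0.0))
    fixed = all_one | all_zero
    favorable = fixed & (fixed_score * b > 0)
    negative = fixed & ~favorable
    return (float(w[favorable].sum() / total), float(w[negative].sum() / total),
            float(w[~fixed].sum() / total))


def _setup_replicate(config: ProgramConfig, panel: FounderPanel):
    """Marker subsample, trait draw, founder choice, initial population and
    the once-fitted prediction model."""
    seed = config.seed
    sub = subsample_markers(panel, config.snp_per_chrom, substream(seed, "markers"))
    gmap = sub.linkage_map()
    L = sub.n_markers
    qtn = assign_qtn(L, config.n_qtn, substream(seed, "qtn"))
    trait = sample_qtn_effects(qtn, L, config.qtn_var, substream(seed, "effects"))
    u_panel = genotypic_value(sub.score, trait.beta)
    parent_idx = select_founder_parents(sub, u_panel, k=4,
                                        seed=spawn_seed(seed, "kmeans") % 2**31)
    parents = [sub.population.take([i]) for i in parent_idx]
    pop = make_initial_population(parents, gmap, n=config.pop_size,
                                  rng=substream(seed, "init"))
    u0 = genotypic_value(pop.score, trait.beta)
    phen = simulate_phenotypes(u0, config.h2, substream(seed, "pheno"))
    model = fit_gblup(pop.score, phen.y)
    return sub, gmap, trait, pop, u0, phen, model


def run_program(config: ProgramConfig, panel: FounderPanel) -> SimulationLog:
    """Run the full two-part program for one strategy and one seed."""
    sub, gmap, trait, pop, u0, phen, model = _setup_replicate(config, panel)
    seed = config.seed
    beta_hat = model.beta_hat
    engine = InbredMomentEngine(gmap, n_self=config.n_self)
    he0 = initial_diversity(pop.score)
    i_cross = selection_intensity(config.progeny_per_cross * config.n_first_self,
                                  config.intensity_mode)
    i_self = selection_intensity(config.n_first_self, config.intensity_mode)
    cand = CrossCandidateSet(config.pop_size)

    log = SimulationLog(config=config, baseline_u=float(np.max(u0)),
                        sigma_g2_init=float(np.var(u0)), he0=he0)
    log.gpic.append(0.0)
    log.sigma2.append(variance_pic(u0))
    log.allele_rates.append(allele_state_rates(pop, trait.beta, trait.qtn_indices))

    for t in range(1, config.n_cycles + 1):
        g = gebv(pop.score, beta_hat)
        sel_rng = substream(seed, "select", config.strategy, t)
        record: dict = {"cycle": t, "strategy": config.strategy}
        if config.strategy == "gs":
            plan = gs_select(g, sel_rng, n_ind=config.crosses_per_cycle)
        elif config.strategy == "ocs":
            K = ibs_matrix(pop.score)
            he_t = diversity_constraint_he(t, he0, config.t_star, config.s,
                                           config.he_star_frac * he0)
            plan = ocs_select(g, K, he_t, sel_rng, n_crosses=config.crosses_per_cycle,
                              max_use=config.max_use, budget=config.ocs_budget)
            record["he_t"] = he_t
            record["dsel"] = dsel(plan.pairs, K)
        else:  # cps
            sig2 = engine.cross_sigma2_matrix(pop, beta_hat)
            sigma = np.sqrt(sig2[cand.pair_i, cand.pair_j])
            mu = cand.mean_gebv(g)
            uc = mu + i_cross * 1.0 * sigma
            plan = cps_select(uc, config.pop_size, n_crosses=config.crosses_per_cycle,
                              max_use=config.max_use)
        plan.validate(config.pop_size, config.crosses_per_cycle, config.max_use)
        record.update(pairs=list(plan.pairs), objective=plan.objective,
                      feasible=plan.feasible)
        log.plans.append(record)

        pop = make_crosses(pop, plan.pairs, gmap, config.progeny_per_cross,
                           substream(seed, "progeny", t), generation=f"PIC{t}")
        u = genotypic_value(pop.score, trait.beta)
        log.gpic.append(gain_pic(u, log.baseline_u, log.sigma_g2_init,
                                 config.denominator_mode))
        log.sigma2.append(variance_pic(u))
        log.allele_rates.append(allele_state_rates(pop, trait.beta, trait.qtn_indices))

        if t % 2 == 0:
            g_now = gebv(pop.score, beta_hat)
            sigma_self = np.sqrt(engine.self_sigma2(pop, beta_hat))
            ucs = g_now + i_self * sigma_self
            chosen = sfc_select(ucs, config.sfc_per_year)
            log.sfc_ids[t] = [int(i) for i in chosen]
            u_lines = []
            for rank, ind in enumerate(chosen):
                lines = self_ssd(pop.take([ind]), gmap, n_self=config.n_self,
                                 n_first=config.n_first_self,
                                 rng=substream(seed, "ssd", t, rank))
                u_lines.append(genotypic_value(lines.score, trait.beta))
            u_i8 = np.concatenate(u_lines)
            log.inbred8_u[t] = u_i8
            log.gi8[t] = gain_inbred8(u_i8, log.baseline_u, log.sigma_g2_init,
                                      config.denominator_mode)
    return log


def replicate_runner(config: ProgramConfig, panel: FounderPanel, n_rep: int,
                     base_seed: int, strategies=STRATEGIES) -> dict:
    """Matched replicates: each replicate id shares its seed (hence marker
    subsample, trait, initial population and progeny streams) across all
    strategies, isolating the effect of the selection rule.

    Returns mean GPIC/sigma2 curves and mean GI8 per even cycle for every
    strategy, per-replicate GI8 tables, and per-cycle win fractions (ties
    split equally among the tied strategies).
    """
    logs: dict[str, list[SimulationLog]] = {s: [] for s in strategies}
    for rep in range(n_rep):
        rep_seed = spawn_seed(base_seed, "replicate", rep)
        for strat in strategies:
            cfg = dataclasses.replace(config, strategy=strat, seed=rep_seed)
            logs[strat].append(run_program(cfg, panel))

    even_cycles = sorted(logs[strategies[0]][0].gi8.keys())
    gi8 = {s: np.array([[lg.gi8[t] for t in even_cycles] for lg in logs[s]])
           for s in strategies}
    result = {
        "strategies": list(strategies),
        "even_cycles": even_cycles,
        "gi8": gi8,
        "gi8_mean": {s: gi8[s].mean(axis=0) for s in strategies},
        "gpic_mean": {s: np.mean([lg.gpic for lg in logs[s]], axis=0) for s in strategies},
        "sigma2_mean": {s: np.mean([lg.sigma2 for lg in logs[s]], axis=0)
                        for s in strategies},
        "logs": logs,
    }
    wins = {s: np.zeros(len(even_cycles)) for s in strategies}
    for ci in range(len(even_cycles)):
        for rep in range(n_rep):
            vals = np.array([gi8[s][rep, ci] for s in strategies])
            top = np.flatnonzero(vals == vals.max())
            for k in top:
                wins[strategies[k]][ci] += 1.0 / len(top)
    result["win_fraction"] = {s: wins[s] / n_rep for s in strategies}
    return result
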