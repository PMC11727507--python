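"""Synthetic pedigrees and phenotypes with the generative structure the
analysis assumes.

The generator emulates a managed dairy-sheep-like population: overlapping
generations, few sires and many dams, a mating policy that avoids pairs
sharing a grandparent (keeping mean inbreeding low, with inbreeding arising
only through deeper pedigree loops), repeated lactation records on females
only, flock-year-parity fixed effects, and phenotypes built record by
record as

    y = mu + fixed + f b + u + (K i) + p + e

with (u, i) ~ N(0, G kron A) simulated by Mendelian-sampling recursion
down the pedigree (exact in distribution, no dense factor of A needed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import LoadDesign, build_K
from .model import REMLOptions, likelihood_ratio_test, reml_fit
from .pedigree import (
    Pedigree,
    compute_inbreeding,
    compute_partial_inbreeding,
    pedigree_from_arrays,
)

logger = logging.getLogger("pedload")


@dataclass
class SimConfig:
    """Population, variance and recording structure of one simulation.

    Variance components are on the trait scale (liters / liters squared),
    with the load variance on the per-100%-inbred-descendant scale, which
    makes it roughly an order of magnitude larger than the additive
    variance.  ``b`` is the overall inbreeding depression per unit of
    inbreeding (negative = depression).
    """

    n_founders: int = 120
    n_generations: int = 10
    sires_per_generation: int = 12
    dams_per_generation: int = 110
    offspring_per_dam: int = 3
    mating_policy: str = "avoid_common_grandparents"
    female_ratio: float = 0.5
    # true (co)variance components, near the dairy-sheep milk-yield scale
    sigma_u2: float = 800.0
    sigma_i2: float = 10_000.0
    sigma_ui: float = -300.0
    sigma_p2: float = 400.0
    sigma_e2: float = 1300.0
    b: float = -110.0
    trait_mean: float = 193.0
    n_fixed_levels: int = 12
    fixed_sd: float = 30.0
    records_per_female: float = 3.7
    k_threshold: float = 0.0  # exact generative model
    seed: int = 12345

    def true_components(self):
        from .model import VarianceComponents

        return VarianceComponents(
            sigma_u2=self.sigma_u2,
            sigma_e2=self.sigma_e2,
            sigma_p2=self.sigma_p2,
            sigma_i2=self.sigma_i2,
            sigma_ui=self.sigma_ui,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_pedigree(cfg: SimConfig, seed: int | None = None) -> Pedigree:
    """Overlapping-generation pedigree under the configured mating policy.

    Parents of each generation are drawn from the previous two cohorts.
    Under ``avoid_common_grandparents`` a dam is mated only to a sire with
    whom she shares no ancestor within two generations (self, parents,
    grandparents) — this covers shared grandparents as well as
    parent-offspring and sib matings among founder offspring, so the
    closest permitted inbreeding loops are deeper than two generations.
    When no such sire exists the pair falls back to a random sire (counted
    and logged, never an infinite loop).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    animal, sire, dam, year, sex = [], [], [], [], []
    males: list[list[int]] = [[]]
    females: list[list[int]] = [[]]
    # ancestors within two generations: the animal, its parents, grandparents
    close_anc: dict[int, frozenset] = {}
    parents_of: dict[int, tuple[int, int]] = {}

    next_id = 1
    for _ in range(cfg.n_founders):
        s = "M" if rng.random() >= cfg.female_ratio else "F"
        animal.append(next_id)
        sire.append(0)
        dam.append(0)
        year.append(0)
        sex.append(s)
        close_anc[next_id] = frozenset([next_id])
        (males if s == "M" else females)[0].append(next_id)
        next_id += 1

    fallbacks = 0
    for g in range(1, cfg.n_generations):
        cand_m = [a for coh in males[max(0, g - 2): g] for a in coh]
        cand_f = [a for coh in females[max(0, g - 2): g] for a in coh]
        if not cand_m or not cand_f:
            logger.warning("generation %d infeasible (no candidates); stopping", g)
            break
        ns = min(cfg.sires_per_generation, len(cand_m))
        nd = min(cfg.dams_per_generation, len(cand_f))
        gen_sires = list(rng.choice(cand_m, size=ns, replace=False))
        gen_dams = list(rng.choice(cand_f, size=nd, replace=False))
        males.append([])
        females.append([])
        for dm in gen_dams:
            if cfg.mating_policy == "avoid_common_grandparents":
                ok = [s for s in gen_sires if not (close_anc[dm] & close_anc[s])]
                if ok:
                    sr = ok[rng.integers(len(ok))]
                else:
                    sr = gen_sires[rng.integers(len(gen_sires))]
                    fallbacks += 1
            elif cfg.mating_policy == "random":
                sr = gen_sires[rng.integers(len(gen_sires))]
            else:
                raise ValueError(f"unknown mating policy {cfg.mating_policy!r}")
            ps = parents_of.get(sr, (0, 0))
            pd_ = parents_of.get(dm, (0, 0))
            child_close = frozenset(
                {sr, dm, *(x for x in (*ps, *pd_) if x != 0)}
            )
            for _ in range(cfg.offspring_per_dam):
                s = "M" if rng.random() >= cfg.female_ratio else "F"
                animal.append(next_id)
                sire.append(sr)
                dam.append(dm)
                year.append(g)
                sex.append(s)
                close_anc[next_id] = child_close | {next_id}
                parents_of[next_id] = (sr, dm)
                (males if s == "M" else females)[g].append(next_id)
                next_id += 1
    if fallbacks:
        logger.info(
            "mating policy fell back to a random sire for %d matings", fallbacks
        )
    return pedigree_from_arrays(animal, sire, dam, year=year, sex=sex)


def simulate_genetic_effects(
    ped: Pedigree, F, G_true: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Joint (u, i) effects with covariance G kron A, by pedigree recursion.

    Founders draw N(0, G); a non-founder is the mean of its known parents
    plus a residual with covariance m_j G, where m_j is its
    Mendelian-sampling variance.  Returns an (n, 2) array in pedigree order
    (column 0 = u, column 1 = i); with a 1x1 G a single column.
    """
    from .pedigree import mendelian_sampling_variance_from_parents

    rng = np.random.default_rng(seed)
    G_true = np.atleast_2d(np.asarray(G_true, dtype=float))
    k = G_true.shape[0]
    evals, evecs = np.linalg.eigh(G_true)
    if evals.min() < -1e-8 * max(evals.max(), 1.0):
        raise ValueError("G_true must be positive semi-definite")
    sqrtG = evecs @ np.diag(np.sqrt(np.maximum(evals, 0.0))) @ evecs.T
    Farr = ped.aligned(F)
    z = rng.standard_normal((ped.n, k)) @ sqrtG.T
    out = np.empty((ped.n, k))
    for j in range(ped.n):
        s, d = ped.sire[j], ped.dam[j]
        m = mendelian_sampling_variance_from_parents(
            Farr[s] if s >= 0 else None, Farr[d] if d >= 0 else None
        )
        mean = np.zeros(k)
        if s >= 0:
            mean += 0.5 * out[s]
        if d >= 0:
            mean += 0.5 * out[d]
        out[j] = mean + np.sqrt(m) * z[j]
    return out


def simulate_phenotypes(
    ped: Pedigree,
    F,
    design: LoadDesign,
    effects: np.ndarray,
    cfg: SimConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated records for females under the generative model.

    ``design`` should be built with threshold 0 so that the simulated data
    follow the exact model.  Returns a table with columns
    (animal, y, fyp, f) — one row per lactation record.
    """
    if design.threshold != 0.0:
        logger.warning(
            "phenotypes simulated with thresholded K (%.3g): generative model "
            "is approximate",
            design.threshold,
        )
    rng = np.random.default_rng(seed)
    Farr = ped.aligned(F)
    effects = np.atleast_2d(effects.T).T
    u = effects[:, 0]
    i_eff = effects[:, 1] if effects.shape[1] > 1 else np.zeros(ped.n)
    ki = design.K @ i_eff
    fixed_effects = rng.normal(0.0, cfg.fixed_sd, size=cfg.n_fixed_levels)
    females = (
        np.nonzero(ped.sex == "F")[0] if ped.sex is not None else np.arange(ped.n)
    )
    perm = rng.normal(0.0, np.sqrt(cfg.sigma_p2), size=ped.n)

    rows_animal, rows_y, rows_level, rows_f = [], [], [], []
    for j in females:
        nrec = 1 + rng.poisson(max(cfg.records_per_female - 1.0, 0.0))
        levels = rng.integers(cfg.n_fixed_levels, size=nrec)
        e = rng.normal(0.0, np.sqrt(cfg.sigma_e2), size=nrec)
        base = (
            cfg.trait_mean
            + Farr[j] * cfg.b
            + u[j]
            + ki[j]
            + perm[j]
        )
        for r in range(nrec):
            rows_animal.append(ped.ids[j])
            rows_y.append(base + fixed_effects[levels[r]] + e[r])
            rows_level.append(int(levels[r]))
            rows_f.append(Farr[j])
    return pd.DataFrame(
        {"animal": rows_animal, "y": rows_y, "fyp": rows_level, "f": rows_f}
    )


def simulate_dataset(cfg: SimConfig, seed: int | None = None):
    """Full simulate chain: pedigree, F, decomposition, design, phenotypes.

    Returns (ped, F, partials, design, effects, data).  Seeds for the
    stages are spawned deterministically from the one master seed.
    """
    master = np.random.SeedSequence(cfg.seed if seed is None else seed)
    s_ped, s_eff, s_phen = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(3)]
    ped = simulate_pedigree(cfg, seed=s_ped)
    F = compute_inbreeding(ped)
    partials = compute_partial_inbreeding(ped, F=F)
    design = build_K(partials, threshold=cfg.k_threshold)
    G_true = np.array(
        [[cfg.sigma_u2, cfg.sigma_ui], [cfg.sigma_ui, cfg.sigma_i2]]
    )
    effects = simulate_genetic_effects(ped, F, G_true, seed=s_eff)
    data = simulate_phenotypes(ped, F, design, effects, cfg, seed=s_phen)
    return ped, F, partials, design, effects, data


def recovery_experiment(
    cfg: SimConfig,
    n_replicates: int = 20,
    seed: int = 0,
    reml_opts: REMLOptions | None = None,
) -> pd.DataFrame:
    """Simulate-and-refit study: estimates, SEs, LRT and 2SE coverage.

    One row per replicate.  Non-convergence is recorded in the ``converged``
    column, never fatal.
    """
    rows = []
    truth = {
        "sigma_u2": cfg.sigma_u2,
        "sigma_i2": cfg.sigma_i2,
        "sigma_ui": cfg.sigma_ui,
        "sigma_p2": cfg.sigma_p2,
        "sigma_e2": cfg.sigma_e2,
        "b": cfg.b,
    }
    rep_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    for r, ss in enumerate(rep_seeds):
        rseed = int(ss.generate_state(1)[0] % (2**31))
        ped, F, partials, design, effects, data = simulate_dataset(cfg, seed=rseed)
        fit_rm = reml_fit(
            ped, F, None, data, model="RM", factors=("fyp",), opts=reml_opts
        )
        fit_fm = reml_fit(
            ped, F, design, data, model="FM", factors=("fyp",),
            rm_components=fit_rm.components, opts=reml_opts,
        )
        lrt = likelihood_ratio_test(fit_fm, fit_rm)
        row = {
            "replicate": r,
            "seed": rseed,
            "n_animals": ped.n,
            "n_records": len(data),
            "lrt": lrt.statistic,
            "p_value": lrt.p_value,
            "converged": fit_fm.converged and fit_rm.converged,
        }
        est = {
            "sigma_u2": fit_fm.components.sigma_u2,
            "sigma_i2": fit_fm.components.sigma_i2,
            "sigma_ui": fit_fm.components.sigma_ui,
            "sigma_p2": fit_fm.components.sigma_p2,
            "sigma_e2": fit_fm.components.sigma_e2,
            "b": fit_fm.b_hat,
        }
        ses = {**fit_fm.se, "b": fit_fm.b_se}
        for k, tv in truth.items():
            e = est[k]
            s = ses.get(k, np.nan)
            row[f"true_{k}"] = tv
            row[f"est_{k}"] = e
            row[f"se_{k}"] = s
            covered = (
                e is not None
                and s is not None
                and np.isfinite(s)
                and abs(e - tv) <= 2.0 * s
            )
            row[f"cover_{k}"] = bool(covered)
        rows.append(row)
        logger.info(
            "replicate %d: LRT=%.2f sigma_i2=%.0f (true %.0f)",
            r, lrt.statistic, est["sigma_i2"] or 0.0, cfg.sigma_i2,
        )
    return pd.DataFrame(rows)
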