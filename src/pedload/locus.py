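"""Single-locus theory of the inbreeding load as an additive effect.

With alleles A1/A2 at frequencies p/q and genotypic values (a, d, -a) for
(A1A1, A1A2, A2A2), non-random mating with inbreeding coefficient F changes
the substitution effect from the random-mating regression alpha = a + (q-p)d
to alpha = e/(1+F), where e = a(1+F) + d(q-p)(1-F) is the average excess.
The substitution effect splits as

    alpha_noF = a + (q-p) d
    alpha_F   = -2 F/(1+F) (q-p) d,

and the inbreeding load of a genotype is its centred gene content times
alpha_F.  The load is heritable and additively transmitted, with variance
sigma_i^2 = 2 p q alpha_F^2 and a never-positive covariance with the
ordinary breeding value.  All quantities here are closed forms; an
empirical simulation check is provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("pedload")


@dataclass(frozen=True)
class LocusParams:
    """Allele frequency p (of A1), biological effects a and d, inbreeding F."""

    p: float
    a: float
    d: float
    F: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must lie in (0, 1)")
        if not (0.0 <= self.F <= 1.0):
            raise ValueError("F must lie in [0, 1]")

    @property
    def q(self) -> float:
        return 1.0 - self.p

    def genotype_frequencies(self) -> np.ndarray:
        """(A1A1, A1A2, A2A2) frequencies under inbreeding F."""
        p, q, F = self.p, self.q, self.F
        return np.array([p * p + F * p * q, 2 * p * q * (1 - F), q * q + F * p * q])


@dataclass(frozen=True)
class LocusEffects:
    e: float
    alpha: float
    alpha_noF: float
    alpha_F: float


@dataclass(frozen=True)
class LocusMoments:
    sigma_i2: float
    sigma_u2: float
    sigma_ui: float
    r2_ui: float
    degenerate: bool  # True when a zero variance forced r2_ui := 0


def locus_effects(params: LocusParams) -> LocusEffects:
    """Average excess e, substitution effect alpha and its split.

    ``alpha = e/(1+F)`` with ``e = a(1+F) + d(q-p)(1-F)``;
    ``alpha = alpha_noF + alpha_F`` holds identically (finite at F=1).
    """
    p, q, a, d, F = params.p, params.q, params.a, params.d, params.F
    e = a * (1 + F) + d * (q - p) * (1 - F)
    alpha = e / (1 + F)
    alpha_noF = a + (q - p) * d
    alpha_F = -2.0 * F / (1 + F) * (q - p) * d
    return LocusEffects(e=e, alpha=alpha, alpha_noF=alpha_noF, alpha_F=alpha_F)


def load_values(params: LocusParams) -> tuple[float, float, float]:
    """Inbreeding load per genotype: centred gene content times alpha_F."""
    aF = locus_effects(params).alpha_F
    p = params.p
    return ((2 - 2 * p) * aF, (1 - 2 * p) * aF, (-2 * p) * aF)


def locus_moments(params: LocusParams) -> LocusMoments:
    """Single-locus variance components of load and breeding value.

    sigma_i^2 = 2pq alpha_F^2, sigma_u^2 = 2pq a^2 + 2pq (q-p)^2 d^2,
    sigma_ui = -4pq F/(1+F) (q-p)^2 d^2, and the squared correlation equals
    the dominance fraction 2pq (q-p)^2 d^2 / sigma_u^2 (0 at degenerate
    corners where either variance vanishes).
    """
    p, q, a, d, F = params.p, params.q, params.a, params.d, params.F
    pq = p * q
    aF = locus_effects(params).alpha_F
    sigma_i2 = 2 * pq * aF * aF
    sigma_u2 = 2 * pq * a * a + 2 * pq * (q - p) ** 2 * d * d
    sigma_ui = -4 * pq * F / (1 + F) * (q - p) ** 2 * d * d
    degenerate = sigma_u2 * sigma_i2 == 0.0
    if degenerate:
        r2 = 0.0
    else:
        r2 = 2 * pq * (q - p) ** 2 * d * d / sigma_u2
    return LocusMoments(
        sigma_i2=sigma_i2,
        sigma_u2=sigma_u2,
        sigma_ui=sigma_ui,
        r2_ui=r2,
        degenerate=degenerate,
    )


def empirical_check(params: LocusParams, n: int = 100_000, seed: int = 0) -> dict:
    """Simulation check of the closed forms.

    Draws ``n`` genotypes at the inbred-population frequencies, assigns
    genotypic values (a, d, -a), regresses value on gene content (the
    estimated substitution effect, which must approach ``e/(1+F)``), and
    compares empirical load moments against :func:`locus_moments`.

    Returns a report with estimates, targets, standard errors and a
    ``within_tolerance`` flag (4 standard errors).
    """
    if n < 10_000:
        warnings.warn("n < 1e4 gives unstable single-locus moment estimates")
    rng = np.random.default_rng(seed)
    freqs = params.genotype_frequencies()
    counts = rng.multinomial(n, freqs)
    gene_content = np.repeat([2.0, 1.0, 0.0], counts)
    gvalues = np.repeat([params.a, params.d, -params.a], counts)

    x = gene_content - gene_content.mean()
    sxx = float(x @ x)
    alpha_hat = float(x @ gvalues) / sxx
    resid = gvalues - gvalues.mean() - alpha_hat * x
    se_alpha = float(np.sqrt((resid @ resid) / max(n - 2, 1) / sxx))

    eff = locus_effects(params)
    mom = locus_moments(params)
    loads = np.repeat(load_values(params), counts)
    sigma_i2_hat = float(loads.var())
    # var of the sample variance ~ (m4 - m2^2)/n
    c = loads - loads.mean()
    se_si2 = float(np.sqrt(max((c**4).mean() - sigma_i2_hat**2, 0.0) / n))
    # sigma_i2 is on the transmitted (Hardy-Weinberg) scale; the realized
    # load variance among genotypes drawn at inbred frequencies carries the
    # usual (1+F) inflation of the genic variance
    sigma_i2_realized = (1.0 + params.F) * mom.sigma_i2

    ok_alpha = abs(alpha_hat - eff.alpha) <= 4 * max(se_alpha, 1e-12)
    ok_si2 = abs(sigma_i2_hat - sigma_i2_realized) <= 4 * max(se_si2, 1e-12)
    return {
        "n": n,
        "alpha_hat": alpha_hat,
        "alpha": eff.alpha,
        "se_alpha": se_alpha,
        "sigma_i2_hat": sigma_i2_hat,
        "sigma_i2": mom.sigma_i2,
        "sigma_i2_realized": sigma_i2_realized,
        "se_sigma_i2": se_si2,
        "within_tolerance": bool(ok_alpha and ok_si2),
    }


def theory_table(params: LocusParams) -> dict:
    """All closed-form quantities for one parameter set, as a flat mapping."""
    eff = locus_effects(params)
    mom = locus_moments(params)
    i11, i12, i22 = load_values(params)
    return {
        "p": params.p,
        "q": params.q,
        "a": params.a,
        "d": params.d,
        "F": params.F,
        "e": eff.e,
        "alpha": eff.alpha,
        "alpha_noF": eff.alpha_noF,
        "alpha_F": eff.alpha_F,
        "i_A1A1": i11,
        "i_A1A2": i12,
        "i_A2A2": i22,
        "sigma_i2": mom.sigma_i2,
        "sigma_u2": mom.sigma_u2,
        "sigma_ui": mom.sigma_ui,
        "r2_ui": mom.r2_ui,
    }
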