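"""Independent oracles used by the test suite.

Everything here is deliberately naive (dense algebra, explicit simulation)
and shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Gene-dropping Monte Carlo for partial inbreeding coefficients
# ---------------------------------------------------------------------------

def _cross_merge(sire, dam, start, rng):
    """Walk two fresh allele lineages up from the two slots of ``start``.

    ``start`` is an array of animals (one per replicate, -1 = inactive).
    Fresh, independent inheritance bits are drawn for every animal, so the
    walk is an unconditional sample of the coancestry of the two parental
    gametes of ``start``.  Returns the merge animal per replicate
    (-1 when the lineages never reach a common allele copy).
    """
    n = len(sire)
    m = len(start)
    bitp = rng.integers(0, 2, size=(n, m), dtype=np.int64)
    bitm = rng.integers(0, 2, size=(n, m), dtype=np.int64)
    cols = np.arange(m)

    def lineage(slot0):
        cur_a = np.maximum(start, 0)
        cur_s = np.full(m, slot0, dtype=np.int64)
        active = start >= 0
        steps = []
        for _ in range(n + 1):
            par = np.where(cur_s == 0, sire[cur_a], dam[cur_a])
            active = active & (par >= 0)
            if not active.any():
                break
            nslot = np.where(cur_s == 0, bitp[cur_a, cols], bitm[cur_a, cols])
            steps.append(np.where(active, 2 * np.maximum(par, 0) + nslot, -1))
            cur_a = np.where(active, np.maximum(par, 0), cur_a)
            cur_s = np.where(active, nslot, cur_s)
        return steps

    p1 = lineage(0)
    p2 = lineage(1)
    mask2 = np.zeros(m, dtype=np.uint64)
    for node in p2:
        valid = node >= 0
        mask2[valid] |= np.uint64(1) << node[valid].astype(np.uint64)
    merge = np.full(m, -1, dtype=np.int64)
    found = np.zeros(m, dtype=bool)
    for node in p1:
        valid = (~found) & (node >= 0)
        hit = np.zeros(m, dtype=bool)
        hit[valid] = (
            (mask2[valid] >> node[valid].astype(np.uint64)) & np.uint64(1)
        ) == 1
        merge[hit] = node[hit] >> 1
        found |= hit
    return merge


def gene_drop_partials(sire, dam, focal, n_rep=1_000_000, seed=0):
    """Monte-Carlo partial inbreeding of ``focal`` attributed per ancestor.

    The two allele lineages of the focal animal are traced upward; they are
    identical by descent when they merge into one allele copy of some
    animal x.  The merged probability mass is then attributed over the
    Mendelian-sampling terms of x and its ancestors by a with-replacement
    cascade: pick one parental slot of x at random — an unknown parent
    credits x itself; otherwise draw a fresh with-replacement allele pair
    from that parent p (same slot: recurse into p; different slots: walk
    the two parental gametes of p, crediting x when they fail to coalesce
    and recursing into their merge animal when they do).  The mass credited
    to x is exactly its phi term, so the cascade samples the Mendelian
    decomposition of inbreeding without using the tabular recursion.

    Returns (F_hat, partials, se) where partials maps ancestor index to
    the estimated F_focal(k) and se to its binomial standard error.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    n = len(sire)
    rng = np.random.default_rng(seed)

    start = np.full(n_rep, focal, dtype=np.int64)
    merge = _cross_merge(sire, dam, start, rng)
    F_hat = float((merge >= 0).mean())

    attr = np.full(n_rep, -1, dtype=np.int64)
    pending = merge.copy()  # replicates awaiting an M(x) attribution call
    for _ in range(2 * n + 2):
        active = pending >= 0
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        x = pending[idx]
        rho = rng.integers(0, 2, size=len(idx))
        par = np.where(rho == 0, sire[x], dam[x])
        # unknown parent on the chosen side: the sampling term is x's own
        done = par < 0
        attr[idx[done]] = x[done]
        pending[idx[done]] = -1
        # known parent p: fresh with-replacement pair from p
        idx2 = idx[~done]
        p = par[~done]
        x2 = x[~done]
        s1 = rng.integers(0, 2, size=len(idx2))
        s2 = rng.integers(0, 2, size=len(idx2))
        same = s1 == s2
        pending[idx2[same]] = p[same]  # same copy drawn twice: recurse into p
        # different copies: coancestry walk of p's two gametes
        idx3 = idx2[~same]
        if len(idx3):
            sub = _cross_merge(sire, dam, p[~same], rng)
            no_ibd = sub < 0
            attr[idx3[no_ibd]] = x2[~same][no_ibd]
            pending[idx3[no_ibd]] = -1
            pending[idx3[~no_ibd]] = sub[~no_ibd]
    partials, se = {}, {}
    for k in np.unique(attr[attr >= 0]):
        prob = float((attr == k).mean())
        partials[int(k)] = prob
        se[int(k)] = float(np.sqrt(prob * (1 - prob) / n_rep))
    return F_hat, partials, se


# ---------------------------------------------------------------------------
# Dense mixed-model oracles
# ---------------------------------------------------------------------------

def dense_V(A, Zu, Zi, Zp, vc):
    """Phenotypic covariance matrix V built densely from the model."""
    n = Zu.shape[0]
    G = vc.G
    V = G[0, 0] * (Zu @ A @ Zu.T)
    if Zi is not None and G.shape[0] > 1:
        V = V + G[1, 1] * (Zi @ A @ Zi.T)
        V = V + G[0, 1] * (Zu @ A @ Zi.T + Zi @ A @ Zu.T)
    if Zp is not None and vc.sigma_p2 is not None:
        V = V + vc.sigma_p2 * (Zp @ Zp.T)
    return V + vc.sigma_e2 * np.eye(n)


def dense_reml_m2ll(y, X, V):
    """-2 restricted log-likelihood, constant (n-p) log 2pi included."""
    n, p = X.shape
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return float(
        (n - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + r @ Vi @ r
    )


def dense_gls_blup(y, X, V, A, Zu, Zi, vc):
    """GLS fixed effects and BLUP of u (and i) from the dense V."""
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = Vi @ (y - X @ beta)
    G = vc.G
    if Zi is not None and G.shape[0] > 1:
        u = (G[0, 0] * A @ Zu.T + G[0, 1] * A @ Zi.T) @ r
        i = (G[0, 1] * A @ Zu.T + G[1, 1] * A @ Zi.T) @ r
        return beta, u, i
    u = G[0, 0] * A @ Zu.T @ r
    return beta, u, None


# ---------------------------------------------------------------------------
# Brute-force single-locus moments
# ---------------------------------------------------------------------------

def locus_moments_brute(p, a, d, F):
    """Load moments by enumeration over the three genotype classes.

    The breeding value is decomposed by gene action into an additive part
    (gene count - 2p) a and a dominance part (gene count - 2p)(q-p) d;
    sigma_u2 is the sum of the two parts' Hardy-Weinberg variances,
    sigma_i2 the HW variance of the load (gene count - 2p) alpha_F, and
    sigma_ui the HW covariance of the dominance part with the load.
    """
    q = 1.0 - p
    gene = np.array([2.0, 1.0, 0.0])
    e_avg = a * (1 + F) + d * (q - p) * (1 - F)
    alpha_F = -2.0 * F / (1 + F) * (q - p) * d
    loads = (gene - 2 * p) * alpha_F
    hw = np.array([p * p, 2 * p * q, q * q])

    def var(x):
        m = float(hw @ x)
        return float(hw @ (x - m) ** 2)

    def cov(x, y):
        mx, my = float(hw @ x), float(hw @ y)
        return float(hw @ ((x - mx) * (y - my)))

    u_add = (gene - 2 * p) * a
    u_dom = (gene - 2 * p) * (q - p) * d
    return {
        "sigma_i2": var(loads),
        "sigma_u2": var(u_add) + var(u_dom),
        "sigma_ui": cov(u_dom, loads),
        "e": e_avg,
    }
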