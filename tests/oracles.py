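"""Independent reference implementations used to check the package.

Everything here is deliberately written the slow, direct way (full
enumeration, dense matrices, full-design model fits) and shares no code
with the implementations under test.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats
from scipy.special import gammaln


def hwe_enumeration(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE p-value by direct enumeration of het counts."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    na = 2 * n_hom_alt + n_het          # alt allele count
    nr = 2 * n - na
    if na == 0 or nr == 0:
        return 1.0

    def log_prob(h):
        hom_alt = (na - h) // 2
        hom_ref = n - h - hom_alt
        return (h * np.log(2.0) + gammaln(n + 1) - gammaln(h + 1)
                - gammaln(hom_ref + 1) - gammaln(hom_alt + 1)
                + gammaln(na + 1) + gammaln(nr + 1) - gammaln(2 * n + 1))

    hs = [h for h in range(na % 2, min(na, nr) + 1, 2)]
    logs = np.array([log_prob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hs.index(n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def fisher_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def dense_impute(panel_haps: np.ndarray, positions: np.ndarray,
                 target: np.ndarray, typed_cols: np.ndarray,
                 ne: float, lam: float, cm_per_mb: float = 1.0) -> np.ndarray:
    """Dense Li–Stephens haploid imputation: ALT probability at every site.

    Full transition-matrix forward–backward with dense emission vectors,
    then linear interpolation of the copying marginals in genetic distance
    and a dense carrier-mass sum.
    """
    n, n_sites = panel_haps.shape
    gpos = positions.astype(float) * cm_per_mb / 1e6 / 100.0
    typed_g = gpos[typed_cols]
    T = len(typed_cols)

    emit = np.where(panel_haps[:, typed_cols].T == target[None, :].T, 1 - lam, lam)
    rho = 4.0 * ne * np.diff(typed_g) / n

    fwd = np.empty((T, n))
    f = np.full(n, 1.0 / n) * emit[0]
    f /= f.sum()
    fwd[0] = f
    for t in range(1, T):
        stay = np.exp(-rho[t - 1])
        trans = stay * np.eye(n) + (1 - stay) / n * np.ones((n, n))
        f = (trans.T @ f) * emit[t]
        f /= f.sum()
        fwd[t] = f
    bwd = np.empty((T, n))
    b = np.ones(n)
    bwd[T - 1] = b
    for t in range(T - 2, -1, -1):
        stay = np.exp(-rho[t])
        trans = stay * np.eye(n) + (1 - stay) / n * np.ones((n, n))
        b = trans @ (emit[t + 1] * b)
        b /= b.sum()
        bwd[t] = b
    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)

    out = np.empty(n_sites)
    for j in range(n_sites):
        r = np.searchsorted(typed_g, gpos[j], side="left")
        if r == 0:
            g = post[0]
        elif r >= T:
            g = post[-1]
        else:
            span = typed_g[r] - typed_g[r - 1]
            w = 1.0 if span <= 0 else (typed_g[r] - gpos[j]) / span
            g = w * post[r - 1] + (1 - w) * post[r]
        out[j] = g[panel_haps[:, j] == 1].sum()
    return out


def info_score_direct(probs: np.ndarray) -> float:
    """Info score as one minus a ratio of variances, evaluated directly."""
    e = probs @ np.array([0.0, 1.0, 2.0])
    second = probs @ np.array([0.0, 1.0, 4.0])
    var_post = second - e ** 2
    theta = e.mean() / 2.0
    if theta <= 0 or theta >= 1:
        return 1.0
    return 1.0 - var_post.mean() / (2.0 * theta * (1.0 - theta))


def abf_quadrature(beta: float, se: float, w: float) -> float:
    """Bayes factor by numerical integration of the Gaussian likelihood."""
    def integrand(b):
        return stats.norm.pdf(beta, loc=b, scale=se) * stats.norm.pdf(b, 0.0, np.sqrt(w))

    scale = max(se, np.sqrt(w))
    num, _ = integrate.quad(integrand, -12 * scale, 12 * scale, limit=400)
    den = stats.norm.pdf(beta, loc=0.0, scale=se)
    return num / den


def ols_full_design(y: np.ndarray, g: np.ndarray, covariates: np.ndarray | None):
    """Full-design OLS (beta, SE) for one marker via statsmodels."""
    import statsmodels.api as sm

    x = g[:, None] if covariates is None else np.column_stack([g, covariates])
    res = sm.OLS(y, sm.add_constant(x, prepend=False)).fit()
    return res.params[0], res.bse[0]


def mom_ibd_kinship(ca: np.ndarray, cb: np.ndarray, freqs: np.ndarray) -> float:
    """Allele-frequency-based method-of-moments kinship (PLINK-style).

    Estimates P(IBD=0,1,2) from observed IBS counts and their null
    expectations given allele frequencies, then kinship = pihat / 2.
    """
    both = (ca >= 0) & (cb >= 0)
    ca, cb, p = ca[both].astype(float), cb[both].astype(float), freqs[both]
    q = 1 - p
    ibs0_obs = float(((ca == 2) & (cb == 0)).sum() + ((ca == 0) & (cb == 2)).sum())
    ibs1_obs = float((np.abs(ca - cb) == 1).sum())
    m = len(ca)
    # expected counts per IBD state (autosomal biallelic, HWE)
    e_ibs0_ibd0 = float((2 * p ** 2 * q ** 2).sum())
    e_ibs1_ibd0 = float((4 * p ** 3 * q + 4 * p * q ** 3).sum())
    e_ibs1_ibd1 = float((2 * p ** 2 * q + 2 * p * q ** 2).sum())
    p_ibd0 = ibs0_obs / e_ibs0_ibd0 if e_ibs0_ibd0 > 0 else 0.0
    p_ibd1 = (ibs1_obs - p_ibd0 * e_ibs1_ibd0) / e_ibs1_ibd1 if e_ibs1_ibd1 > 0 else 0.0
    p_ibd0 = min(max(p_ibd0, 0.0), 1.0)
    p_ibd1 = min(max(p_ibd1, 0.0), 1.0 - p_ibd0)
    p_ibd2 = 1.0 - p_ibd0 - p_ibd1
    pihat = 0.5 * p_ibd1 + p_ibd2
    return pihat / 2.0
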