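"""Linear association scans, Wakefield Bayes factors, credible sets, regions.

The scan is the fast residualization trick used by multi-trait GWAS
engines: phenotype and dosages are projected off the covariate space
(intercept included) once, after which each marker costs a single dot
product — numerically identical (Frisch–Waugh) to the full-design OLS fit,
with residual degrees of freedom n - c - 2 for c covariates.

Fine-mapping uses the approximate Bayes factor for a Gaussian effect-size
prior N(0, W):

    ABF = sqrt(SE^2 / (SE^2 + W)) * exp(Z^2 W / (2 (SE^2 + W))),

default prior W = 0.2^2 on the standardized-trait scale.  Under a single
causal marker per region, the posterior for marker i in region r is
pi_ir = BF_ir / sum_k BF_kr, and the 95% credible set is the shortest
prefix of the posterior-sorted markers reaching 0.95 cumulative mass.

HLA association tests build the design columns for the standard risk
models (additive, dominant, recessive, general, homozygote-correction,
conditional-additive, allelic-interaction) and fit logistic regression by
IRLS with Wald p-values; detected separation falls back to a flagged
ridge-penalized fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PRIOR_W = 0.2 ** 2
GENOME_WIDE_P = 5e-8
HLA_TESTS = ("additive", "dominant", "recessive", "general",
             "homozygote-correction", "conditional-additive", "allelic-interaction")


def _residualizer(covariates: np.ndarray | None, n: int):
    """Orthonormal basis of the covariate space (always includes intercept)."""
    if covariates is None:
        x = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        x = np.column_stack([np.ones(n), covariates])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        warnings.warn(f"covariate matrix rank-deficient ({rank} < {x.shape[1]}); "
                      "dependent columns dropped")
    q, _ = np.linalg.qr(x)
    q = q[:, :rank]
    return q, x.shape[1] - 1  # c = covariate count excluding intercept


def linear_scan(dosages: np.ndarray, phenotypes: np.ndarray,
                covariates: np.ndarray | None = None,
                maf: np.ndarray | None = None,
                info: np.ndarray | None = None,
                maf_filter: float = 0.001, info_filter: float = 0.3
                ) -> pd.DataFrame:
    """Per-marker linear association for one or more traits.

    ``dosages`` is (n_samples, n_markers); ``phenotypes`` (n,) or (n, T).
    Samples with missing phenotype or covariates are dropped (complete
    cases).  Zero-variance markers after residualization are flagged
    ``tested=False``.  ``maf``/``info`` are carried through and the
    default release filters recorded in the ``pass_filters`` column.
    """
    dosages = np.asarray(dosages, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    n = dosages.shape[0]
    ok = np.isfinite(y).all(axis=1)
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        ok &= np.isfinite(cov).all(axis=1)
        cov = cov[ok]
    else:
        cov = None
    dosages = dosages[ok]
    y = y[ok]
    n = int(ok.sum())

    q, c = _residualizer(cov, n)
    y_t = y - q @ (q.T @ y)
    g_t = dosages - q @ (q.T @ dosages)
    ssg = (g_t ** 2).sum(axis=0)
    tested = ssg > 1e-12
    dof = n - c - 2
    rows = []
    for t in range(y.shape[1]):
        ssy = float((y_t[:, t] ** 2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = (g_t.T @ y_t[:, t]) / ssg
            sigma2 = (ssy - beta ** 2 * ssg) / dof
            se = np.sqrt(np.maximum(sigma2, 0.0) / ssg)
            z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        df = pd.DataFrame({
            "marker": np.arange(dosages.shape[1]), "trait": t,
            "beta": np.where(tested, beta, np.nan),
            "se": np.where(tested, se, np.nan),
            "z": np.where(tested, z, np.nan),
            "p": np.where(tested, p, np.nan),
            "tested": tested, "n": n,
        })
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out["maf"] = np.tile(maf, y.shape[1]) if maf is not None else np.nan
    out["info"] = np.tile(info, y.shape[1]) if info is not None else np.nan
    passes = out["tested"].to_numpy(copy=True)
    if maf is not None:
        passes &= out["maf"].to_numpy() > maf_filter
    if info is not None:
        passes &= out["info"].to_numpy() > info_filter
    out["pass_filters"] = passes
    if squeeze:
        out = out.drop(columns="trait")
    return out


def residual_phenotype_sd(phenotype: np.ndarray,
                          covariates: np.ndarray | None = None) -> float:
    """SD of the phenotype after regressing out the covariates.

    Used to put effect sizes from different studies on a common
    standardized scale before Bayes-factor computation.
    """
    y = np.asarray(phenotype, dtype=float)
    ok = np.isfinite(y)
    y = y[ok]
    q, _ = _residualizer(
        None if covariates is None else np.asarray(covariates)[ok], len(y))
    resid = y - q @ (q.T @ y)
    return float(resid.std(ddof=1))


def wakefield_abf(beta, se, w: float = DEFAULT_PRIOR_W,
                  scale_sd: float | None = None) -> np.ndarray:
    """Approximate Bayes factor in favour of association.

    ``scale_sd`` optionally divides beta and SE first (residual phenotype
    SD), putting effects on the standardized scale the default prior
    assumes.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("standard errors must be finite and positive")
    if not np.all(np.isfinite(beta)):
        raise ValueError("effect sizes must be finite")
    if scale_sd is not None:
        beta = beta / scale_sd
        se = se / scale_sd
    z2 = (beta / se) ** 2
    shrink = se ** 2 / (se ** 2 + w)
    return np.sqrt(shrink) * np.exp(z2 * (1.0 - shrink) / 2.0)


@dataclass
class CredibleSet:
    members: list          # marker labels, posterior-descending
    posteriors: np.ndarray  # aligned with members
    size: int
    cumulative: float
    prior_w: float


def credible_set(marker_ids, positions, bf, w: float = DEFAULT_PRIOR_W,
                 level: float = 0.95) -> CredibleSet:
    """Smallest posterior-sorted marker set reaching ``level`` cumulative mass.

    Posteriors are bf / sum(bf) (single causal marker per region); ties in
    posterior are broken by smaller position.
    """
    bf = np.asarray(bf, dtype=float)
    if len(bf) == 0:
        raise ValueError("region contains no markers")
    if not np.all(np.isfinite(bf)) or bf.sum() <= 0:
        raise ValueError("Bayes factors must be finite with positive sum")
    positions = np.asarray(positions)
    order = np.lexsort((positions, -bf))
    pi = bf / bf.sum()
    cum = np.cumsum(pi[order])
    size = int(np.searchsorted(cum, level - 1e-12) + 1)
    size = min(size, len(bf))
    chosen = order[:size]
    return CredibleSet(
        members=[marker_ids[i] for i in chosen],
        posteriors=pi[chosen], size=size,
        cumulative=float(cum[size - 1]), prior_w=w,
    )


def define_regions(stats_table: pd.DataFrame, threshold: float = GENOME_WIDE_P,
                   radius: int = 500_000) -> pd.DataFrame:
    """Greedy non-overlapping regions around significant markers.

    Repeatedly takes the most significant remaining marker below the
    threshold, opens a +-radius region, and merges overlapping regions.
    Idempotent: re-running on the regions' own top markers changes nothing.
    """
    sig = stats_table[stats_table["p"] < threshold].sort_values("p", kind="stable")
    regions: list[list] = []  # [chrom, start, end, top_pos, top_p]
    for row in sig.itertuples(index=False):
        covered = any(r[0] == row.chrom and r[1] <= row.pos <= r[2] for r in regions)
        if covered:
            continue
        regions.append([row.chrom, max(1, row.pos - radius), row.pos + radius,
                        row.pos, row.p])
    # merge overlaps per chromosome
    merged: list[list] = []
    for r in sorted(regions, key=lambda r: (str(r[0]), r[1])):
        if merged and merged[-1][0] == r[0] and r[1] <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], r[2])
            if r[4] < merged[-1][4]:
                merged[-1][3], merged[-1][4] = r[3], r[4]
        else:
            merged.append(list(r))
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "top_pos", "top_p"])


def significant_windows(stats_table: pd.DataFrame, threshold: float = GENOME_WIDE_P,
                        window: int = 1_000_000) -> set:
    """1-Mb tiling windows (from position 1) holding >= 1 significant marker."""
    sig = stats_table[stats_table["p"] < threshold]
    return {(row.chrom, (int(row.pos) - 1) // window) for row in sig.itertuples(index=False)}


def window_venn(*window_sets: set) -> dict:
    """Occupancy counts of every intersection pattern across the scans."""
    union = set().union(*window_sets)
    counts: dict[tuple, int] = {}
    for w in union:
        key = tuple(w in s for s in window_sets)
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# HLA risk-model design matrices and logistic tests
# ---------------------------------------------------------------------------

def apply_posterior_cutoff(dosage: np.ndarray, max_posterior: np.ndarray,
                           cutoff: float = 0.7) -> np.ndarray:
    """Set allele-dosage calls with low posterior confidence to missing."""
    dosage = np.asarray(dosage, dtype=float).copy()
    dosage[np.asarray(max_posterior) < cutoff] = np.nan
    return dosage


def hla_design_matrix(dosage_a: np.ndarray, test: str,
                      dosage_b: np.ndarray | None = None) -> np.ndarray:
    """Design columns for one HLA risk model.

    ``dosage_a`` holds best-guess allele counts (0/1/2, NaN missing) for
    the tested allele; conditional and interaction models need
    ``dosage_b`` for the second allele.  The homozygote-correction model
    is the additive column plus a homozygote indicator whose coefficient
    measures departure from additivity (odds ratio < 1: the homozygous
    effect is smaller than additivity predicts).
    """
    a = np.asarray(dosage_a, dtype=float)
    if test not in HLA_TESTS:
        raise ValueError(f"unknown test {test!r}")
    if test == "additive":
        return a[:, None]
    if test == "dominant":
        return (a >= 1).astype(float)[:, None] + np.where(np.isnan(a), np.nan, 0.0)[:, None]
    if test == "recessive":
        return (a == 2).astype(float)[:, None] + np.where(np.isnan(a), np.nan, 0.0)[:, None]
    if test == "general":
        het = (a == 1).astype(float) + np.where(np.isnan(a), np.nan, 0.0)
        hom = (a == 2).astype(float) + np.where(np.isnan(a), np.nan, 0.0)
        return np.column_stack([het, hom])
    if test == "homozygote-correction":
        hom = (a == 2).astype(float) + np.where(np.isnan(a), np.nan, 0.0)
        return np.column_stack([a, hom])
    if dosage_b is None:
        raise ValueError(f"{test} requires a second allele dosage")
    b = np.asarray(dosage_b, dtype=float)
    if test == "conditional-additive":
        return np.column_stack([a, b])
    carrier_a = (a >= 1).astype(float) + np.where(np.isnan(a), np.nan, 0.0)
    carrier_b = (b >= 1).astype(float) + np.where(np.isnan(b), np.nan, 0.0)
    return np.column_stack([carrier_a, carrier_b, carrier_a * carrier_b])


def _ridge_logistic(x: np.ndarray, y: np.ndarray, alpha: float = 1.0,
                    max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """L2-penalized logistic IRLS (intercept unpenalized)."""
    n, k = x.shape
    beta = np.zeros(k)
    pen = np.full(k, alpha)
    pen[0] = 0.0
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu) + 1e-12
        h = (x * w[:, None]).T @ x + np.diag(pen)
        grad = x.T @ (y - mu) - pen * beta
        step = np.linalg.solve(h, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(x @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu) + 1e-12
    cov = np.linalg.inv((x * w[:, None]).T @ x + np.diag(pen))
    return beta, np.sqrt(np.diag(cov))


def fit_hla_test(case_status: np.ndarray, design: np.ndarray,
                 covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Logistic fit with Wald tests; flags and handles separation.

    Returns a row per design column: log-odds estimate, SE, odds ratio
    with 95% CI, Wald p-value, and a ``separation`` flag (ridge-penalized
    fallback fit when the ordinary IRLS diverges).
    """
    import statsmodels.api as sm

    y = np.asarray(case_status, dtype=float)
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] != len(y):
        design = design.T
    cols = [f"x{i}" for i in range(design.shape[1])]
    x = design
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        x = np.column_stack([x, cov])
    ok = np.isfinite(x).all(axis=1) & np.isfinite(y)
    x_full = np.column_stack([np.ones(int(ok.sum())), x[ok]])
    y = y[ok]

    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, x_full).fit(disp=0, maxiter=100)
        params, bse = res.params, res.bse
        if not res.mle_retvals.get("converged", True) or np.max(np.abs(params)) > 15:
            raise RuntimeError("divergence")
    except Exception:
        separation = True
        params, bse = _ridge_logistic(x_full, y)

    z = params / bse
    p = 2.0 * stats.norm.sf(np.abs(z))
    rows = []
    for i, name in enumerate(cols, start=1):
        rows.append({
            "term": name, "log_or": params[i], "se": bse[i],
            "or": np.exp(params[i]),
            "or_low": np.exp(params[i] - 1.959963984540054 * bse[i]),
            "or_high": np.exp(params[i] + 1.959963984540054 * bse[i]),
            "p_wald": p[i], "separation": separation, "n": int(ok.sum()),
        })
    return pd.DataFrame(rows)
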