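"""Haploid Li–Stephens genotype imputation with sparse emission updates.

A pre-phased target haplotype is modelled as an imperfect mosaic copy of
the reference-panel haplotypes: a hidden Markov chain over copying states
(one per panel haplotype) with recombination-driven switching and
mutation-driven miscopying.  Between adjacent typed sites separated by
genetic distance c (Morgans), the chain stays put with probability
exp(-r) and otherwise jumps to a uniformly chosen haplotype, where

    r = 4 * Ne * c / N_hap.

Emission at a typed site is (1 - lambda) when the copied haplotype
matches the observed allele and lambda otherwise, with the Li–Stephens
default lambda = theta / (2 (N_hap + theta)), theta = 1 / sum_{i<N} 1/i.

Two implementation choices keep the computation cheap at panel scale and
are the module's core contracts (checked against a dense forward–backward
oracle in the tests):

* emissions are applied as one uniform scalar multiply plus a sparse
  correction over the per-site carrier index list of the panel;
* marginal copying probabilities are computed only at typed sites and
  linearly interpolated (in genetic distance, or physical distance when
  no map is given) at the untyped sites in between; the imputed allele
  probability at an untyped site is the interpolated copying mass on the
  carriers of the non-reference allele.

Per-sample genotype posteriors are the product of the sample's two
haploid allele distributions; the per-marker IMPUTE-style info score
summarizes imputation quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ReferencePanel, SparsePanelIndex


def default_mutation_rate(n_haplotypes: int) -> float:
    """Li–Stephens miscopy probability: theta / (2 (N + theta))."""
    theta = 1.0 / np.sum(1.0 / np.arange(1, n_haplotypes))
    return float(theta / (2.0 * (n_haplotypes + theta)))


@dataclass
class HMMParams:
    """Copying-model parameters.

    ``ne`` is the effective population size scaling recombination;
    ``cm_per_mb`` supplies a constant-rate genetic map when the panel has
    none.  ``mutation_rate`` defaults to the Li–Stephens value for the
    panel size.  Chunking parameters bound working-set size; interior
    results are identical to an unchunked run.
    """

    ne: float = 20000.0
    mutation_rate: float | None = None
    cm_per_mb: float = 1.0
    markers_per_chunk: int | None = None
    buffer_bp: int = 250_000
    samples_per_block: int = 5000

    def lam(self, n_haplotypes: int) -> float:
        lam = self.mutation_rate if self.mutation_rate is not None \
            else default_mutation_rate(n_haplotypes)
        if not 0.0 < lam < 0.5:
            raise ValueError("mutation rate must be in (0, 0.5)")
        return lam


@dataclass
class ImputedGenotypes:
    """Posterior genotype probabilities, dosages and per-marker info scores."""

    probs: np.ndarray        # (n_samples, n_sites, 3)
    positions: np.ndarray
    ids: np.ndarray
    typed_mask: np.ndarray   # True at sites typed in the target

    @property
    def dosage(self) -> np.ndarray:
        return self.probs[:, :, 1] + 2.0 * self.probs[:, :, 2]

    def info_table(self) -> pd.DataFrame:
        rows = [info_score(self.probs[:, j, :]) for j in range(self.probs.shape[1])]
        return pd.DataFrame({
            "id": self.ids, "pos": self.positions, "typed": self.typed_mask,
            "info": [r[0] for r in rows], "theta_hat": [r[1] for r in rows],
        })


# ---------------------------------------------------------------------------
# trio phasing truth + switch error
# ---------------------------------------------------------------------------

def trio_phase_truth(child: np.ndarray, mother: np.ndarray,
                     father: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Phase a child's genotypes by parental transmission.

    Returns ``(haplotypes (2, L) with rows (maternal, paternal), resolved
    mask, Mendelian-violation count)``.  Heterozygous child sites resolve
    whenever at least one parent is homozygous; triple-heterozygous sites
    and Mendelian violations are masked.
    """
    child = np.asarray(child)
    mother = np.asarray(mother)
    father = np.asarray(father)
    if not (child.shape == mother.shape == father.shape):
        raise ValueError("trio genotype vectors must share one length")
    L = len(child)
    haps = np.zeros((2, L), dtype=np.uint8)
    resolved = np.zeros(L, dtype=bool)
    violations = 0
    for t in range(L):
        gc, gm, gf = int(child[t]), int(mother[t]), int(father[t])
        if min(gc, gm, gf) < 0:
            continue
        # transmissible allele sets
        tm = {0} if gm == 0 else {1} if gm == 2 else {0, 1}
        tf = {0} if gf == 0 else {1} if gf == 2 else {0, 1}
        options = [(am, af) for am in tm for af in tf if am + af == gc]
        if not options:
            violations += 1
            continue
        if len(options) == 1:
            haps[:, t] = options[0]
            resolved[t] = True
        elif gc in (0, 2):           # homozygous child: phase trivial
            haps[:, t] = (gc // 2, gc // 2)
            resolved[t] = True
        # else: child and both parents heterozygous -> unresolved
    return haps, resolved, violations


def switch_error(estimated: np.ndarray, truth: np.ndarray,
                 resolved: np.ndarray | None = None) -> float:
    """Switch error rate of an estimated haplotype pair against truth.

    Computed over truth-resolved *heterozygous* sites: the fraction of
    consecutive such site pairs whose relative phase disagrees with the
    truth, denominator (number of resolved het sites - 1).  Raises when
    fewer than two resolved het sites exist.
    """
    estimated = np.asarray(estimated)
    truth = np.asarray(truth)
    if estimated.shape != truth.shape or estimated.ndim != 2:
        raise ValueError("haplotype arrays must both be (2, L)")
    het = truth[0] != truth[1]
    est_het = estimated[0] != estimated[1]
    mask = het & est_het
    if resolved is not None:
        mask &= np.asarray(resolved, dtype=bool)
    sites = np.flatnonzero(mask)
    if len(sites) < 2:
        raise ValueError("fewer than 2 resolved heterozygous sites")
    agree = estimated[0, sites] == truth[0, sites]
    return float(np.mean(agree[1:] != agree[:-1]))


def cohort_median_switch_error(rates: list[float]) -> float:
    return float(np.median(rates))


# ---------------------------------------------------------------------------
# the sparse haploid HMM
# ---------------------------------------------------------------------------

def match_sites(panel: ReferencePanel, positions: np.ndarray, ref: np.ndarray,
                alt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match target markers to panel sites by position and allele pair.

    Returns (panel site index per matched target marker, indices of
    dropped target markers).  No strand-flipping heuristics: a mismatching
    allele pair is reported and dropped.
    """
    lookup = {(int(p), r, a): j for j, (p, r, a) in
              enumerate(zip(panel.positions, panel.ref, panel.alt))}
    matched, dropped = [], []
    for t, (p, r, a) in enumerate(zip(positions, ref, alt)):
        j = lookup.get((int(p), r, a))
        if j is None:
            dropped.append(t)
        else:
            matched.append(j)
    return np.array(matched, dtype=int), np.array(dropped, dtype=int)


def _genetic_positions(panel: ReferencePanel, params: HMMParams) -> np.ndarray:
    """Cumulative genetic position (Morgans) at every panel site."""
    if panel.genetic_map is not None:
        return np.asarray(panel.genetic_map, dtype=float) / 100.0
    return panel.positions.astype(float) * params.cm_per_mb / 1e6 / 100.0


def _emit_inplace(f: np.ndarray, carriers: np.ndarray, stores_alt: bool,
                  allele: int, lam: float) -> None:
    """Multiply f by the emission vector via scalar + sparse correction."""
    target_stored = (allele == 1) == stores_alt
    if target_stored:
        # stored carriers match the observed allele
        f *= lam
        f[carriers] *= (1.0 - lam) / lam
    else:
        f *= 1.0 - lam
        f[carriers] *= lam / (1.0 - lam)


def _forward_backward(target: np.ndarray, typed_cols: np.ndarray,
                      index: SparsePanelIndex, rho: np.ndarray,
                      lam: float) -> np.ndarray:
    """Marginal copying probabilities (T x N) at the typed sites.

    ``rho`` holds the T-1 inter-typed-site recombination intensities r;
    per-site renormalization keeps the recursion in range and cancels in
    the posterior.
    """
    n = index.n_haplotypes
    T = len(typed_cols)
    fwd = np.empty((T, n))
    f = np.full(n, 1.0 / n)
    carriers0, alt0 = index.alt_carriers(typed_cols[0])
    _emit_inplace(f, carriers0, alt0, int(target[0]), lam)
    f /= f.sum()
    fwd[0] = f
    for t in range(1, T):
        stay = np.exp(-rho[t - 1])
        f = stay * f + (1.0 - stay) / n          # sum(f) == 1 after scaling
        carriers, salt = index.alt_carriers(typed_cols[t])
        _emit_inplace(f, carriers, salt, int(target[t]), lam)
        f /= f.sum()
        fwd[t] = f

    b = np.ones(n)
    post = np.empty((T, n))
    post[T - 1] = fwd[T - 1]
    for t in range(T - 2, -1, -1):
        nxt = b.copy()
        carriers, salt = index.alt_carriers(typed_cols[t + 1])
        _emit_inplace(nxt, carriers, salt, int(target[t + 1]), lam)
        stay = np.exp(-rho[t])
        b = stay * nxt + (1.0 - stay) * nxt.mean()
        b /= b.sum()
        g = fwd[t] * b
        post[t] = g / g.sum()
    return post


def _allele_probs_from_post(post: np.ndarray, typed_cols: np.ndarray,
                            index: SparsePanelIndex, gpos: np.ndarray,
                            site_range: np.ndarray) -> np.ndarray:
    """ALT-allele probability at every panel site in ``site_range``.

    Copying marginals are linearly interpolated between flanking typed
    sites (clamped to the nearest anchor outside the typed span) and the
    carrier mass summed through the sparse index.
    """
    typed_g = gpos[typed_cols]
    out = np.empty(len(site_range))
    # anchor interval per site
    right = np.searchsorted(typed_g, gpos[site_range], side="left")
    for k, j in enumerate(site_range):
        r = right[k]
        if r == 0:
            gl = gr = post[0]
            w = 1.0
        elif r >= len(typed_cols):
            gl = gr = post[-1]
            w = 1.0
        else:
            gl, gr = post[r - 1], post[r]
            span = typed_g[r] - typed_g[r - 1]
            w = 1.0 if span <= 0 else (typed_g[r] - gpos[j]) / span
        carriers, salt = index.alt_carriers(j)
        mass = w * gl[carriers].sum() + (1.0 - w) * gr[carriers].sum()
        out[k] = mass if salt else 1.0 - mass
    return np.clip(out, 0.0, 1.0)


def haploid_impute(target_haps: np.ndarray, typed_panel_sites: np.ndarray,
                   panel: ReferencePanel, params: HMMParams | None = None,
                   index: SparsePanelIndex | None = None) -> ImputedGenotypes:
    """Impute genotype posteriors for pre-phased samples against a panel.

    ``target_haps`` has shape ``(n_samples, 2, n_typed)`` (0/1 alleles at
    the typed sites); ``typed_panel_sites`` gives the panel column of each
    typed site (see :func:`match_sites`).  Execution is chunked over
    imputed markers (with a physical buffer) and over sample blocks when
    the parameters say so; interior posteriors are chunking-invariant.
    """
    params = params or HMMParams()
    if len(typed_panel_sites) == 0:
        raise ValueError("no typed sites overlap the panel")
    target_haps = np.asarray(target_haps)
    if target_haps.ndim != 3 or target_haps.shape[1] != 2:
        raise ValueError("target_haps must be (n_samples, 2, n_typed)")
    if target_haps.shape[2] != len(typed_panel_sites):
        raise ValueError("typed site count mismatch")
    index = index or SparsePanelIndex(panel)
    n_samples = target_haps.shape[0]
    n_sites = panel.n_sites
    typed_panel_sites = np.asarray(typed_panel_sites)
    order = np.argsort(typed_panel_sites)
    typed_panel_sites = typed_panel_sites[order]
    target_haps = target_haps[:, :, order]
    lam = params.lam(panel.n_haplotypes)
    gpos = _genetic_positions(panel, params)

    if params.markers_per_chunk is None:
        chunk_bounds = [(0, n_sites)]
    else:
        step = params.markers_per_chunk
        chunk_bounds = [(lo, min(lo + step, n_sites)) for lo in range(0, n_sites, step)]

    hap_alt = np.empty((n_samples, 2, n_sites))
    for lo, hi in chunk_bounds:
        pos_lo = panel.positions[lo] - params.buffer_bp
        pos_hi = panel.positions[hi - 1] + params.buffer_bp
        in_buf = np.flatnonzero(
            (panel.positions[typed_panel_sites] >= pos_lo)
            & (panel.positions[typed_panel_sites] <= pos_hi)
        )
        if len(in_buf) == 0:  # no typed anchor near this chunk: use all
            in_buf = np.arange(len(typed_panel_sites))
        cols = typed_panel_sites[in_buf]
        rho = 4.0 * params.ne * np.diff(gpos[cols]) / panel.n_haplotypes
        site_range = np.arange(lo, hi)
        for s in range(n_samples):
            for h in range(2):
                post = _forward_backward(target_haps[s, h, in_buf], cols,
                                         index, rho, lam)
                hap_alt[s, h, lo:hi] = _allele_probs_from_post(
                    post, cols, index, gpos, site_range)

    p1a = hap_alt[:, 0, :]
    p1b = hap_alt[:, 1, :]
    probs = np.stack([
        (1 - p1a) * (1 - p1b),
        p1a * (1 - p1b) + (1 - p1a) * p1b,
        p1a * p1b,
    ], axis=-1)
    typed_mask = np.zeros(n_sites, dtype=bool)
    typed_mask[typed_panel_sites] = True
    return ImputedGenotypes(probs=probs, positions=panel.positions.copy(),
                            ids=np.asarray(panel.ids).copy(), typed_mask=typed_mask)


def impute_x_chromosome(target_haps: np.ndarray, typed_panel_sites: np.ndarray,
                        panel: ReferencePanel, sexes: np.ndarray,
                        karyotypes: np.ndarray | None = None,
                        params: HMMParams | None = None,
                        par_mask: np.ndarray | None = None) -> ImputedGenotypes:
    """X-chromosome imputation: haploid males outside the PAR.

    Samples with a called sex-chromosome aneuploidy are excluded (their
    posterior rows are NaN).  XY samples contribute a single haplotype in
    the sex-specific region — the second haploid distribution is replaced
    by a copy of the first so hom/het posteriors collapse to the haploid
    allele probabilities; inside the PAR (``par_mask``) both haplotypes
    are used as on the autosomes.
    """
    out = haploid_impute(target_haps, typed_panel_sites, panel, params)
    sexes = np.asarray(sexes)
    aneuploid = np.zeros(len(sexes), dtype=bool)
    if karyotypes is not None:
        aneuploid = ~np.isin(np.asarray(karyotypes), ["XX", "XY"])
    non_par = np.ones(out.probs.shape[1], dtype=bool)
    if par_mask is not None:
        non_par = ~np.asarray(par_mask, dtype=bool)
    males = np.flatnonzero((sexes == "M") & ~aneuploid)
    for s in males:
        p = out.probs[s]
        # haploid: genotype is 0 or 2 copies of ALT with prob (1-p_alt, p_alt)
        p_alt = p[:, 2] + 0.5 * p[:, 1]
        out.probs[s, non_par, 0] = 1.0 - p_alt[non_par]
        out.probs[s, non_par, 1] = 0.0
        out.probs[s, non_par, 2] = p_alt[non_par]
    out.probs[aneuploid] = np.nan
    return out


def info_score(probs: np.ndarray) -> tuple[float, float]:
    """IMPUTE info score and estimated allele frequency at one marker.

    With expected dosage e_i and second moment f_i = p_i1 + 4 p_i2 per
    sample, theta = sum(e) / 2M and

        info = 1 - sum(f - e^2) / (2 M theta (1 - theta)),

    i.e. one minus the ratio of mean posterior dosage variance to the
    binomial variance at the estimated frequency.  Degenerate posteriors
    give 1; the value is clipped to [0, 1].
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise ValueError("probs must be (M, 3)")
    m = probs.shape[0]
    if m == 0:
        raise ValueError("no samples")
    e = probs[:, 1] + 2.0 * probs[:, 2]
    f = probs[:, 1] + 4.0 * probs[:, 2]
    theta = e.sum() / (2.0 * m)
    if theta <= 0.0 or theta >= 1.0:
        return 1.0, float(np.clip(theta, 0.0, 1.0))
    raw = 1.0 - (f - e ** 2).sum() / (2.0 * m * theta * (1.0 - theta))
    return float(np.clip(raw, 0.0, 1.0)), float(theta)
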