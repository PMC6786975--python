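"""Randomized PCA of the genotype matrix, projection, and ancestry subsets.

Fitting uses the randomized range-finder: multiply the standardized
genotype matrix by a random Gaussian test matrix, take a few power
iterations with QR re-orthonormalization, and eigendecompose the small
projected problem.  This approximates only the top ``n_pcs`` components,
which is what makes PCA practical on biobank-sized matrices; at desk scale
it is checked against a dense eigensolver in the tests.

Genotypes are standardized per marker as (g - 2p) / sqrt(2 p (1-p)) with p
the fitting-set non-reference allele frequency — the binomial scale
standard for genotype PCA — and missing calls are mean-imputed (zero after
centering).  Marker loadings plus the standardization constants make the
model projectable onto any cohort sharing the markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CohortGenotypes


@dataclass
class PCAModel:
    """Fitted randomized-PCA model (loadings + standardization constants)."""

    marker_ids: np.ndarray
    loadings: np.ndarray      # markers x n_pcs, columns orthonormal
    means: np.ndarray         # per-marker 2p
    scales: np.ndarray        # per-marker sqrt(2p(1-p))
    eigenvalues: np.ndarray   # non-increasing
    fitting_sample_ids: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]

    def save(self, prefix: str) -> None:
        pd.DataFrame(
            np.column_stack([self.means, self.scales, self.loadings]),
            index=self.marker_ids,
            columns=["mean", "scale"] + [f"pc{i+1}" for i in range(self.n_pcs)],
        ).to_csv(f"{prefix}.loadings.tsv", sep="\t", index_label="marker")
        pd.Series(self.eigenvalues).to_csv(f"{prefix}.eigenvalues.tsv", sep="\t",
                                           header=["eigenvalue"], index_label="pc")

    @classmethod
    def load(cls, prefix: str) -> "PCAModel":
        tab = pd.read_csv(f"{prefix}.loadings.tsv", sep="\t", index_col="marker")
        eig = pd.read_csv(f"{prefix}.eigenvalues.tsv", sep="\t")["eigenvalue"].to_numpy()
        return cls(
            marker_ids=tab.index.to_numpy(),
            loadings=tab.iloc[:, 2:].to_numpy(),
            means=tab["mean"].to_numpy(),
            scales=tab["scale"].to_numpy(),
            eigenvalues=eig,
            fitting_sample_ids=np.array([]),
        )


def _standardize(calls: np.ndarray, means: np.ndarray, scales: np.ndarray) -> np.ndarray:
    z = np.where(calls >= 0, calls, np.nan).astype(float)
    z = (z - means) / scales
    return np.nan_to_num(z, nan=0.0)  # mean imputation after centering


def ld_prune(cohort: CohortGenotypes, window: int = 50, step: int = 25,
             r2_threshold: float = 0.2) -> np.ndarray:
    """Greedy windowed LD pruning; returns kept marker indices.

    Within each sliding window, while any marker pair has squared
    correlation above the threshold, the lower-MAF marker of the worst pair
    is removed (ties keep the lower position).
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2 threshold must be in (0, 1]")
    maf = cohort.maf()
    pos = cohort.markers["pos"].to_numpy()
    n = cohort.n_markers
    dose = np.where(cohort.calls >= 0, cohort.calls, np.nan).astype(float)
    col_mean = np.nanmean(dose, axis=0)
    dose = np.where(np.isnan(dose), col_mean, dose)
    removed = np.zeros(n, dtype=bool)
    for start in range(0, max(n - 1, 1), step):
        idx = np.arange(start, min(start + window, n))
        idx = idx[~removed[idx]]
        if len(idx) < 2:
            continue
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(dose[:, idx], rowvar=False)
        r2 = np.nan_to_num(corr, nan=0.0) ** 2
        np.fill_diagonal(r2, 0.0)
        alive = np.ones(len(idx), dtype=bool)
        while True:
            sub = r2[np.ix_(alive, alive)]
            if sub.size == 0 or sub.max() <= r2_threshold:
                break
            a_idx = np.flatnonzero(alive)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            gi, gj = idx[a_idx[i]], idx[a_idx[j]]
            if maf[gi] < maf[gj] or (maf[gi] == maf[gj] and pos[gi] > pos[gj]):
                drop = a_idx[i]
            else:
                drop = a_idx[j]
            alive[drop] = False
            removed[idx[drop]] = True
    return np.flatnonzero(~removed)


def randomized_pca(cohort: CohortGenotypes, marker_index: np.ndarray | None = None,
                   fitting_index: np.ndarray | None = None, n_pcs: int = 40,
                   n_iter: int = 10, oversample: int = 10,
                   seed: int = 0) -> tuple[PCAModel, np.ndarray]:
    """Fit the top ``n_pcs`` principal components on the fitting samples.

    Returns the model and the fitting samples' scores.  The sign of each
    component is fixed so that its largest-magnitude loading is positive.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    marker_index = (np.arange(cohort.n_markers) if marker_index is None
                    else np.asarray(marker_index))
    fitting_index = (np.arange(cohort.n_samples) if fitting_index is None
                     else np.asarray(fitting_index))
    calls = cohort.calls[np.ix_(fitting_index, marker_index)]
    if (calls < 0).all(axis=1).any():
        raise ValueError("a fitting sample has 100% missingness on the subset")
    obs = calls >= 0
    p = np.where(obs, calls, 0).sum(axis=0) / np.maximum(2 * obs.sum(axis=0), 1)
    p = np.clip(p, 1.0 / (4 * len(fitting_index)), 1 - 1.0 / (4 * len(fitting_index)))
    means = 2 * p
    scales = np.sqrt(2 * p * (1 - p))
    z = _standardize(calls, means, scales)

    n, m = z.shape
    k = min(n_pcs, n, m)
    l = min(k + oversample, m, n)
    rng = np.random.default_rng(seed)
    omega = rng.standard_normal((m, l))
    y = z @ omega
    for _ in range(n_iter):
        q, _ = np.linalg.qr(y)
        y = z @ (z.T @ q)
    q, _ = np.linalg.qr(y)
    b = q.T @ z                      # l x m
    _, s, vt = np.linalg.svd(b, full_matrices=False)
    v = vt[:k].T                     # m x k loadings
    # sign convention: largest-magnitude loading positive
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    v = v * flip
    scores = z @ v
    eigenvalues = (s[:k] ** 2) / max(n - 1, 1)
    model = PCAModel(
        marker_ids=cohort.markers["id"].to_numpy()[marker_index],
        loadings=v, means=means, scales=scales, eigenvalues=eigenvalues,
        fitting_sample_ids=cohort.samples["sample_id"].to_numpy()[fitting_index],
    )
    return model, scores


def project_samples(model: PCAModel, cohort: CohortGenotypes) -> np.ndarray:
    """Project all cohort samples onto the model's principal components.

    New samples are standardized with the *model's* constants; markers the
    cohort lacks count as missing (mean-imputed).  Refuses when over half
    the model's markers are absent.
    """
    pos = {m: i for i, m in enumerate(cohort.markers["id"])}
    have = np.array([m in pos for m in model.marker_ids])
    if have.sum() < 0.5 * len(model.marker_ids):
        raise ValueError(
            f"only {have.sum()} of {len(model.marker_ids)} model markers present "
            "in cohort (need > 50%)"
        )
    cols = np.array([pos[m] for m in model.marker_ids[have]])
    calls = np.full((cohort.n_samples, len(model.marker_ids)), -1, dtype=np.int8)
    calls[:, np.flatnonzero(have)] = cohort.calls[:, cols]
    z = _standardize(calls, model.means, model.scales)
    return z @ model.loadings


def select_homogeneous_subset(scores: np.ndarray, labels: np.ndarray | None = None,
                              target_label: str | None = None,
                              reference_scores: np.ndarray | None = None,
                              n_pcs: int = 6, k: float = 7.0,
                              mode: str = "label") -> np.ndarray:
    """Select an ancestry-homogeneous sample subset; returns sample indices.

    ``mode="reference"``: keep samples whose robust z-distance (per-PC
    median/MAD of ``reference_scores``) is within ``k`` (default radius 5
    is conventional there).  ``mode="label"``: restrict to samples with
    ``labels == target_label``, then keep those inside the robust ellipsoid
    centred on that stratum's per-PC medians with semi-axes ``k * MAD``.
    """
    scores = np.asarray(scores, dtype=float)[:, :n_pcs]
    if mode == "reference":
        if reference_scores is None:
            raise ValueError("reference mode requires reference_scores")
        ref = np.asarray(reference_scores, dtype=float)[:, :n_pcs]
        center = np.median(ref, axis=0)
        mad = 1.4826 * np.median(np.abs(ref - center), axis=0)
        mad[mad == 0] = 1e-12
        dist = np.linalg.norm((scores - center) / mad, axis=1)
        return np.flatnonzero(dist <= k)
    if labels is None or target_label is None:
        raise ValueError("label mode requires labels and target_label")
    labels = np.asarray(labels)
    stratum = np.flatnonzero(labels == target_label)
    if len(stratum) == 0:
        raise ValueError(f"label {target_label!r} absent from data")
    center = np.median(scores[stratum], axis=0)
    mad = 1.4826 * np.median(np.abs(scores[stratum] - center), axis=0)
    mad[mad == 0] = 1e-12
    inside = ((scores[stratum] - center) / (k * mad)) ** 2
    return stratum[inside.sum(axis=1) <= 1.0]
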