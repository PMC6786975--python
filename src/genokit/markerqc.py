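"""Marker-based quality control battery.

Each marker is tested, batch by batch, for consistency of genotype calling
across experimental factors: genotyping batch, 96-well plate, array
version and inferred sex, plus an exact test of Hardy–Weinberg
equilibrium.  A marker failing a test in one batch has its calls set to
missing *in that batch only*; a marker that is unreliable across batches
is excluded altogether.  Samples are never removed here — QC emits flags.

The per-stratum association test compares non-reference allele counts in
one stratum against the pooled remainder in a 2x2 table, with Fisher's
exact test when any expected cell count is below 5 and a chi-square test
otherwise.  The Hardy–Weinberg test is the exact conditional
(Levene–Haldane) test: the p-value sums the probabilities of all
heterozygote counts, consistent with the observed allele counts, that are
no more probable than the observed one.

Default fail threshold is p < 1e-12 per test per batch: extreme on
purpose, so that at biobank scale the mass of genuinely fine markers is
not set missing by multiple testing.  The cross-batch exclusion rule
(fails in more than half the batches, or fails the array comparison) is a
documented package default; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, CohortGenotypes

DEFAULT_THRESHOLD = 1e-12
STRATUM_MODES = ("batch", "plate", "array", "sex")


def _allele_counts(calls: np.ndarray) -> tuple[int, int]:
    """(non-reference allele count, total allele count) over non-missing calls."""
    obs = calls >= 0
    return int(np.where(obs, calls, 0).sum()), int(2 * obs.sum())


def two_by_two_test(alt1: int, n1: int, alt2: int, n2: int) -> float:
    """Two-sided allele-count homogeneity test on a 2x2 table.

    Fisher's exact test when any expected count is below 5, else the
    chi-square test without continuity correction (large-sample regime).
    """
    if n1 == 0 or n2 == 0:
        return 1.0
    table = np.array([[alt1, n1 - alt1], [alt2, n2 - alt2]], dtype=float)
    if table.sum() == 0 or (alt1 + alt2) == 0 or (alt1 + alt2) == (n1 + n2):
        return 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        return float(stats.fisher_exact(table.astype(int))[1])
    return float(stats.chi2_contingency(table, correction=False)[1])


def stratum_association_test(calls: np.ndarray, strata: np.ndarray,
                             mode: str = "batch") -> dict:
    """Per-stratum vs pooled-remainder allele-count test at one marker.

    Returns ``{stratum label: p-value}``.  Monomorphic markers give p = 1
    by convention; strata with no non-missing calls are skipped.
    """
    if mode not in STRATUM_MODES:
        raise ValueError(f"mode must be one of {STRATUM_MODES}")
    calls = np.asarray(calls)
    strata = np.asarray(strata)
    labels = pd.unique(strata)
    if len(labels) < 2:
        raise ValueError("need at least 2 strata")
    alt_all, n_all = _allele_counts(calls)
    out = {}
    for lab in labels:
        in_stratum = strata == lab
        alt_s, n_s = _allele_counts(calls[in_stratum])
        if n_s == 0:
            continue
        out[lab] = two_by_two_test(alt_s, n_s, alt_all - alt_s, n_all - n_s)
    return out


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy–Weinberg test (Levene–Haldane distribution).

    Conditional on the observed allele counts, heterozygote counts are
    distributed as P(h) ∝ 2^h n! / (h! n_r! n_a!) with n_r, n_a the
    homozygote counts implied by h.  The two-sided p-value sums P over all
    h with the observed parity whose probability does not exceed P(h_obs).
    Computed by the standard stable recurrence, normalized at the end.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0  # monomorphic

    # possible het counts share the parity of the rare-allele count
    h_values = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    probs = np.empty(len(h_values), dtype=float)
    probs[0] = 1.0
    for k in range(1, len(h_values)):
        h = h_values[k]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        # P(h) / P(h-2) = 4 * (rare_hom+1) * (common_hom+1) / (h * (h-1))
        probs[k] = probs[k - 1] * 4.0 * (rare_hom + 1) * (common_hom + 1) / (h * (h - 1.0))
        if probs[k] > 1e280:  # rescale to avoid overflow on large n
            probs[: k + 1] /= probs[k]
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(h_values, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def duplicate_concordance(calls_a: np.ndarray, calls_b: np.ndarray) -> tuple[int, float]:
    """Concordance of a duplicate pair over sites non-missing in both."""
    calls_a = np.asarray(calls_a)
    calls_b = np.asarray(calls_b)
    if calls_a.shape != calls_b.shape:
        raise ValueError("duplicate call vectors must have equal length")
    both = (calls_a >= 0) & (calls_b >= 0)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no comparable (jointly non-missing) sites")
    return n, float((calls_a[both] == calls_b[both]).mean())


@dataclass
class QCOutcome:
    """Per (marker, batch, test) p-values with pass/fail flags."""

    table: pd.DataFrame  # columns: marker, batch, test, p, fail
    threshold: float = DEFAULT_THRESHOLD
    excluded: list = field(default_factory=list)

    def failing_cells(self) -> pd.DataFrame:
        return self.table[self.table["fail"]]

    def batches_failed(self) -> pd.Series:
        """Number of distinct batches in which each marker fails any test."""
        f = self.failing_cells()
        return f.groupby("marker")["batch"].nunique()


def run_marker_qc(cohort: CohortGenotypes, threshold: float = DEFAULT_THRESHOLD,
                  tests: tuple = ("batch", "plate", "array", "sex", "hwe"),
                  sample_index: np.ndarray | None = None) -> QCOutcome:
    """Run the full marker-QC battery.

    ``sample_index`` restricts all tests to an ancestry-homogeneous subset
    (attenuating population-structure artifacts); by default all samples
    are used.  Batch and plate tests compare each batch/plate against the
    remainder; the array and sex tests compare the two labels; HWE is
    tested per batch so a failing batch can be set missing locally.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    sub = cohort if sample_index is None else cohort.subset_samples(sample_index)
    batches = sub.samples["batch"].to_numpy()
    rows = []
    marker_ids = sub.markers["id"].to_numpy()
    for j in range(sub.n_markers):
        calls = sub.calls[:, j]
        alt_all, n_all = _allele_counts(calls)
        if n_all == 0 or alt_all == 0 or alt_all == n_all:
            continue  # monomorphic / fully missing: p = 1 everywhere by convention
        for mode in ("batch", "plate", "array", "sex"):
            if mode not in tests:
                continue
            labels = sub.samples[
                "inferred_sex" if mode == "sex" else mode].to_numpy()
            if len(pd.unique(labels)) < 2:
                continue
            pvals = stratum_association_test(calls, labels, mode=mode)
            for lab, p in pvals.items():
                # batch/plate tests attach to the batch they implicate;
                # array/sex tests apply cohort-wide and attach to every batch
                if mode == "batch":
                    affected = [lab]
                elif mode == "plate":
                    affected = pd.unique(batches[sub.samples["plate"].to_numpy() == lab])
                else:
                    affected = pd.unique(batches)
                for b in affected:
                    rows.append((marker_ids[j], b, mode, p, p < threshold))
        if "hwe" in tests:
            for b in pd.unique(batches):
                c = calls[batches == b]
                p = hwe_exact_test(int((c == 0).sum()), int((c == 1).sum()),
                                   int((c == 2).sum()))
                rows.append((marker_ids[j], b, "hwe", p, p < threshold))
    table = pd.DataFrame(rows, columns=["marker", "batch", "test", "p", "fail"])
    return QCOutcome(table=table, threshold=threshold)


def apply_marker_qc(cohort: CohortGenotypes, outcome: QCOutcome,
                    exclude_batch_fraction: float = 0.5
                    ) -> tuple[CohortGenotypes, list, pd.DataFrame]:
    """Set failing (marker, batch) cells to missing; exclude unreliable markers.

    A marker is excluded entirely when it fails any test in more than
    ``exclude_batch_fraction`` of batches, or fails the array test.
    Returns (cleaned cohort, excluded marker ids, flag table).  Calls in
    passing batches are bitwise untouched.
    """
    if not 0.0 < exclude_batch_fraction <= 1.0:
        raise ValueError("exclude_batch_fraction must be in (0, 1]")
    cleaned = cohort.copy()
    batches = cohort.samples["batch"].to_numpy()
    n_batches = len(pd.unique(batches))
    marker_pos = {m: i for i, m in enumerate(cohort.markers["id"])}

    failing = outcome.failing_cells()
    for marker, batch in failing[["marker", "batch"]].drop_duplicates().itertuples(index=False):
        j = marker_pos.get(marker)
        if j is None:
            continue
        cleaned.calls[batches == batch, j] = MISSING

    batches_failed = outcome.batches_failed()
    array_fail = set(failing.loc[failing["test"] == "array", "marker"])
    excluded = sorted(
        set(batches_failed[batches_failed > exclude_batch_fraction * n_batches].index)
        | array_fail,
        key=marker_pos.get,
    )
    keep = [j for m, j in marker_pos.items() if m not in set(excluded)]
    cleaned = cleaned.subset_markers(np.array(sorted(keep), dtype=int))
    return cleaned, excluded, outcome.table.copy()
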