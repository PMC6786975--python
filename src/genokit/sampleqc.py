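"""Sample-level QC metrics, outlier flags and sex-karyotype calling.

Per-sample missing rate and heterozygosity are computed over a supplied
high-quality marker subset.  Heterozygosity is sensitive to ancestry
(structure, admixture, consanguinity), so before outlier detection it is
adjusted by regressing on the leading principal components and keeping the
residual.  Outliers (missing rate above 5%, or adjusted heterozygosity
unusually *high* — the one-sided direction contamination pushes) are
flagged, never removed.

Sex-chromosome karyotypes are called from per-sample mean log2-ratio
intensity summaries on X and Y by nearest fixed cluster centre with an
unclassified margin; the centres are those the simulator draws from
(:data:`genokit.simdata.KARYOTYPE_CENTERS`), making calls deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CohortGenotypes
from .simdata import KARYOTYPE_CENTERS, KARYOTYPE_SEX

#: Greek cluster labels for the non-XX/XY karyotypes.
GREEK_LABELS = {"X0": "lambda", "XXX": "theta", "XXY": "alpha", "XYY": "pi"}


def sample_metrics(cohort: CohortGenotypes,
                   marker_index: np.ndarray | None = None) -> pd.DataFrame:
    """Missing rate and heterozygosity per sample over a marker subset."""
    calls = cohort.calls if marker_index is None else cohort.calls[:, np.asarray(marker_index)]
    if calls.shape[1] == 0:
        raise ValueError("marker subset is empty")
    non_missing = (calls >= 0).sum(axis=1)
    missing_rate = 1.0 - non_missing / calls.shape[1]
    with np.errstate(invalid="ignore"):
        heterozygosity = np.where(
            non_missing > 0, (calls == 1).sum(axis=1) / np.maximum(non_missing, 1), np.nan
        )
    return pd.DataFrame({
        "sample_id": cohort.samples["sample_id"],
        "missing_rate": missing_rate,
        "heterozygosity": heterozygosity,
        "all_missing": non_missing == 0,
    })


def pc_adjust_heterozygosity(metrics: pd.DataFrame, pc_scores: np.ndarray,
                             n_pcs: int = 6) -> np.ndarray:
    """Residual heterozygosity after least-squares on the first ``n_pcs`` PCs.

    The regression (with intercept) is fitted on samples with defined
    heterozygosity; residuals are NaN elsewhere.
    """
    pc_scores = np.asarray(pc_scores, dtype=float)
    if n_pcs > pc_scores.shape[1]:
        raise ValueError(f"n_pcs={n_pcs} exceeds available PCs ({pc_scores.shape[1]})")
    het = metrics["heterozygosity"].to_numpy(dtype=float)
    ok = np.isfinite(het)
    design = np.column_stack([np.ones(ok.sum()), pc_scores[ok, :n_pcs]])
    coef, *_ = np.linalg.lstsq(design, het[ok], rcond=None)
    resid = np.full_like(het, np.nan)
    resid[ok] = het[ok] - design @ coef
    return resid


def flag_sample_outliers(adjusted_het: np.ndarray, missing_rate: np.ndarray,
                         missing_cut: float = 0.05, het_k: float = 5.0) -> pd.DataFrame:
    """Flag samples with high missing rate or unusually high adjusted heterozygosity.

    Heterozygosity rule: residual above ``median + het_k * MAD`` (MAD scaled
    to be sigma-consistent under normality).  Flags annotate; they do not
    remove samples.
    """
    adjusted_het = np.asarray(adjusted_het, dtype=float)
    missing_rate = np.asarray(missing_rate, dtype=float)
    if len(adjusted_het) == 0:
        raise ValueError("empty cohort")
    ok = np.isfinite(adjusted_het)
    med = np.median(adjusted_het[ok])
    mad = 1.4826 * np.median(np.abs(adjusted_het[ok] - med))
    het_flag = np.zeros(len(adjusted_het), dtype=bool)
    if mad > 0:
        het_flag[ok] = adjusted_het[ok] > med + het_k * mad
    miss_flag = missing_rate > missing_cut
    return pd.DataFrame({
        "het_outlier": het_flag,
        "missing_outlier": miss_flag,
        "outlier": het_flag | miss_flag | ~ok,
    })


def call_sex_karyotype(intensities: pd.DataFrame,
                       reported_sex: np.ndarray | None = None,
                       centers: dict | None = None,
                       unclassified_margin: float = 0.35) -> pd.DataFrame:
    """Nearest-centre karyotype call in the (mean L2R X, mean L2R Y) plane.

    A sample further than ``unclassified_margin`` from every centre, or
    with non-finite intensities, is ``unclassified``.  The sex-mismatch
    flag compares reported sex against the karyotype-implied sex.
    """
    centers = centers or KARYOTYPE_CENTERS
    labels = list(centers)
    cxy = np.array([centers[k] for k in labels], dtype=float)
    xy = intensities[["mean_l2r_x", "mean_l2r_y"]].to_numpy(dtype=float)
    finite = np.isfinite(xy).all(axis=1)
    dists = np.full((len(xy), len(labels)), np.inf)
    dists[finite] = np.linalg.norm(xy[finite, None, :] - cxy[None, :, :], axis=2)
    best = np.argmin(dists, axis=1)
    best_dist = dists[np.arange(len(xy)), best]
    called = np.array([labels[b] for b in best], dtype=object)
    called[(best_dist > unclassified_margin) | ~finite] = "unclassified"
    implied = np.array([KARYOTYPE_SEX.get(k, "") for k in called], dtype=object)
    greek = np.array([GREEK_LABELS.get(k, "") for k in called], dtype=object)
    out = pd.DataFrame({
        "sample_id": intensities["sample_id"]
        if "sample_id" in intensities.columns
        else np.arange(len(xy)),
        "mean_l2r_x": xy[:, 0], "mean_l2r_y": xy[:, 1],
        "karyotype": called, "greek_label": greek, "implied_sex": implied,
    })
    if reported_sex is None and "reported_sex" in intensities.columns:
        reported_sex = intensities["reported_sex"].to_numpy()
    if reported_sex is not None:
        reported = np.asarray(reported_sex, dtype=object)
        out["reported_sex"] = reported
        out["sex_mismatch"] = (implied != "") & (reported != "") & (implied != reported)
    return out
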