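"""Filtering, normalization, imputation and QC for DIA intensity matrices.

The chain mirrors standard label-free practice: log2 transform, per-sample
median centering, removal of proteins with >75% missing cells (strict
inequality — a protein missing in exactly 75% of samples is retained),
minimal-value imputation, and QC summaries (missingness, pairwise Pearson
correlation on complete pairs, PCA-based variance decomposition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import IntensityMatrix, SampleDesign, ValidationError

logger = logging.getLogger("proteoheat")

IMPUTE_STRATEGIES = ("global_min", "per_protein_min", "downshift")


@dataclass
class QcSummary:
    """Missingness, replicate-correlation and variance-structure diagnostics."""

    sample_missing: pd.Series          # per-sample missing fraction
    group_missing: pd.Series           # per (class, day) group missing fraction
    correlation: pd.DataFrame          # pairwise Pearson, complete pairs
    variance_decomposition: pd.DataFrame  # rows: PC1/PC2; cols: day, tolerance_class
    explained_variance_ratio: np.ndarray
    pca_scores: np.ndarray = None  # samples x components


def log2_normalize(m: IntensityMatrix, method: str = "median") -> IntensityMatrix:
    """Log2-transform (if raw) and normalize per sample.

    ``median`` (default): each sample is shifted so its observed median equals
    the global median of sample medians.  ``quantile``: observed values in each
    sample are replaced by the mean reference quantile profile (rank-based).
    Matrices already on the log2 scale are centered without re-transforming.
    """
    if m.scale_flag not in ("raw", "log2"):
        raise ValidationError(f"expected raw or log2 matrix, got {m.scale_flag!r}")
    vals = m.values.copy()
    if m.scale_flag == "raw":
        bad = vals.le(0)
        if bad.any().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValidationError(
                f"nonpositive observed value at protein {vals.index[r]!r}, "
                f"sample {vals.columns[c]!r}: cannot log2-transform"
            )
        vals = np.log2(vals)
    if method == "median":
        medians = vals.median(axis=0, skipna=True)
        target = medians.median()
        shifts = target - medians
        vals = vals + shifts
        logger.info("log2_normalize: median centering, target %.4f", target)
    elif method == "quantile":
        ranked = vals.rank(axis=0, method="average", na_option="keep")
        sorted_cols = np.sort(vals.to_numpy(), axis=0)  # NaN sorts last
        n_obs = vals.notna().sum(axis=0).to_numpy()
        # reference profile over the common grid of quantiles
        grid = np.linspace(0, 1, 101)
        profiles = []
        for j, k in enumerate(n_obs):
            col = sorted_cols[:k, j]
            profiles.append(np.quantile(col, grid))
        ref = np.mean(profiles, axis=0)
        out = vals.to_numpy().copy()
        for j, k in enumerate(n_obs):
            q = (ranked.iloc[:, j].to_numpy() - 1) / max(k - 1, 1)
            obs = ~np.isnan(q)
            out[obs, j] = np.interp(q[obs], grid, ref)
        vals = pd.DataFrame(out, index=vals.index, columns=vals.columns)
        logger.info("log2_normalize: quantile normalization over %d samples", vals.shape[1])
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    return IntensityMatrix(vals, m.mask.copy(), "log2-normalized")


def filter_missing(m: IntensityMatrix, max_missing_fraction: float = 0.75) -> IntensityMatrix:
    """Remove proteins whose missing fraction exceeds the threshold.

    Removal requires *strictly greater than* ``max_missing_fraction``; a
    protein at exactly the boundary is retained.
    """
    frac = (~m.mask).mean(axis=1)
    keep = frac <= max_missing_fraction
    out = IntensityMatrix(m.values.loc[keep], m.mask.loc[keep], m.scale_flag)
    logger.info(
        "filter_missing: retained %d of %d proteins at max_missing=%.2f",
        int(keep.sum()), m.n_proteins, max_missing_fraction,
    )
    return out


def impute_minimal(
    m: IntensityMatrix, strategy: str = "global_min", downshift_k: float = 1.0
) -> IntensityMatrix:
    """Replace missing cells with a minimal-value surrogate.

    Strategies: ``global_min`` fills with the minimum observed value in the
    whole matrix; ``per_protein_min`` with that protein's observed minimum;
    ``downshift`` with the global minimum minus ``downshift_k`` log2 units.
    Observed cells are never altered and the pre-imputation mask is kept.
    """
    if strategy not in IMPUTE_STRATEGIES:
        raise ValidationError(f"unknown imputation strategy {strategy!r}")
    vals = m.values.copy()
    obs_per_protein = m.mask.sum(axis=1)
    if (obs_per_protein == 0).any():
        bad = list(m.protein_ids[obs_per_protein == 0][:5])
        raise ValidationError(
            f"protein(s) with zero observed values reached imputation: {bad}; "
            "run filter_missing first"
        )
    if not vals.isna().any().any():
        return IntensityMatrix(vals, m.mask.copy(), "imputed")
    global_min = np.nanmin(vals.to_numpy())
    if strategy == "global_min":
        fill = vals.fillna(global_min)
    elif strategy == "downshift":
        fill = vals.fillna(global_min - downshift_k)
    else:  # per_protein_min
        row_min = vals.min(axis=1, skipna=True)
        fill = vals.apply(lambda col: col.fillna(row_min))
    logger.info("impute_minimal: strategy=%s filled %d cells",
                strategy, int(vals.isna().sum().sum()))
    return IntensityMatrix(fill, m.mask.copy(), "imputed")


def _between_group_fraction(scores: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of score variance explained by the grouping (eta-squared)."""
    grand = scores.mean()
    ss_total = ((scores - grand) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_between = 0.0
    for lv in np.unique(labels):
        g = scores[labels == lv]
        ss_between += len(g) * (g.mean() - grand) ** 2
    return float(ss_between / ss_total)


def plot_qc(qc: QcSummary, design: SampleDesign, path_prefix) -> list:
    """Static QC figures: sample correlation heatmap and PCA scatter.

    Writes ``<prefix>_correlation.png`` and ``<prefix>_pca.png``; returns
    the paths.  PCA points are colored by sampling day and marked by
    tolerance class, the two groupings the variance decomposition reports.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(qc.correlation.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(qc.correlation)))
    ax.set_xticklabels(qc.correlation.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(qc.correlation)))
    ax.set_yticklabels(qc.correlation.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title("Sample correlation (pairwise-complete)")
    p = f"{path_prefix}_correlation.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    meta = design.table.loc[qc.correlation.index]
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    markers = {c: m for c, m in zip(sorted(meta["tolerance_class"].unique()), "os^D")}
    for (klass, day), sub in meta.groupby(["tolerance_class", "day"]):
        idx = qc.correlation.index.get_indexer(sub.index)
        ax.scatter(qc.pca_scores[idx, 0], qc.pca_scores[idx, 1],
                   marker=markers[klass], label=f"{klass} day {day}")
    evr = qc.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    ax.legend(fontsize=7)
    ax.set_title("Sample PCA")
    p = f"{path_prefix}_pca.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths


def qc_summary(m: IntensityMatrix, design: SampleDesign) -> QcSummary:
    """Missingness, correlation and variance-structure QC.

    Missing fractions come from the original detection mask; correlations use
    pairwise-complete observations; the variance decomposition projects the
    (imputed or complete) matrix onto its leading principal axes and reports
    the between-group variance fraction of each axis under the day grouping
    and the tolerance-class grouping.
    """
    if m.n_samples < 2:
        raise ValidationError("qc_summary needs >= 2 samples")
    design.check_matches(m)
    miss = ~m.mask
    sample_missing = miss.mean(axis=0)
    meta = design.table.loc[m.sample_ids]
    group_key = pd.Series(
        [f"{c}:day{d}" for c, d in zip(meta["tolerance_class"], meta["day"])],
        index=m.sample_ids, name="group",
    )
    group_missing = miss.T.groupby(group_key).mean().mean(axis=1)

    corr = m.values.corr(method="pearson", min_periods=2)

    # PCA on samples: center proteins, eigen-decompose the sample covariance
    filled = m.values
    if filled.isna().any().any():
        filled = filled.fillna(filled.mean(axis=1).mean())  # crude, QC-only
    x = filled.to_numpy().T  # samples x proteins
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s  # samples x components
    evr = s**2 / (s**2).sum()

    days = meta["day"].to_numpy()
    classes = meta["tolerance_class"].to_numpy()
    rows = []
    for pc in (0, 1):
        rows.append({
            "component": f"PC{pc + 1}",
            "day": _between_group_fraction(scores[:, pc], days),
            "tolerance_class": _between_group_fraction(scores[:, pc], classes),
        })
    vdec = pd.DataFrame(rows).set_index("component")
    return QcSummary(
        sample_missing=sample_missing,
        group_missing=group_missing,
        correlation=corr,
        variance_decomposition=vdec,
        explained_variance_ratio=evr,
        pca_scores=scores,
    )
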