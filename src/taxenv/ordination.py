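"""Correspondence analysis of the size-normalized community matrix, with
optional detrending of the second axis by segments (the classical remedy
for the arch effect).

The input is the taxa x environment matrix of average OTUs per sample.
Row (taxa) and column (environment) scores come from the singular value
decomposition of the standardized residual matrix; total inertia equals
the matrix's chi-square statistic divided by its grand total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class OrdinationResult:
    row_scores: pd.DataFrame      # taxa x axes (principal coordinates)
    col_scores: pd.DataFrame      # environments x axes
    inertia: np.ndarray           # per-axis (squared singular values)
    inertia_fraction: np.ndarray
    total_inertia: float = 0.0


def correspondence_analysis(
    x: pd.DataFrame | np.ndarray, n_axes: int = 2
) -> OrdinationResult:
    """Classical correspondence analysis.

    Decomposes S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}, where P is the
    correspondence matrix (X over its grand total) and r, c its margins.
    Scores are principal coordinates; the sum of all squared singular
    values equals chi-square / grand total.  All-zero rows or columns are
    dropped with a warning.
    """
    if isinstance(x, pd.DataFrame):
        df = x.astype(float)
    else:
        arr = np.asarray(x, dtype=float)
        df = pd.DataFrame(
            arr,
            index=[f"row{i}" for i in range(arr.shape[0])],
            columns=[f"col{j}" for j in range(arr.shape[1])],
        )
    if (df.to_numpy() < 0).any():
        raise ValueError("correspondence analysis needs non-negative input")

    zero_rows = df.index[df.sum(axis=1) == 0]
    zero_cols = df.columns[df.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping all-zero rows {list(zero_rows)} and columns {list(zero_cols)}"
        )
        df = df.drop(index=zero_rows, columns=zero_cols)

    total = df.to_numpy().sum()
    if total <= 0:
        raise ValueError("matrix grand total must be positive")

    p = df.to_numpy() / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)

    keep = sv > 1e-12
    if not keep.any():
        # exactly independent matrix: no residual structure, zero inertia
        empty = np.zeros(0)
        return OrdinationResult(
            row_scores=pd.DataFrame(index=df.index),
            col_scores=pd.DataFrame(index=df.columns),
            inertia=empty,
            inertia_fraction=empty,
            total_inertia=0.0,
        )
    u, sv, vt = u[:, keep], sv[keep], vt[keep]
    n_axes = min(n_axes, len(sv))

    inertia_all = sv**2
    total_inertia = float(inertia_all.sum())
    # principal coordinates
    rows = (u * sv) / np.sqrt(r)[:, None]
    cols = (vt.T * sv) / np.sqrt(c)[:, None]

    axes = [f"CA{k + 1}" for k in range(n_axes)]
    return OrdinationResult(
        row_scores=pd.DataFrame(rows[:, :n_axes], index=df.index, columns=axes),
        col_scores=pd.DataFrame(cols[:, :n_axes], index=df.columns, columns=axes),
        inertia=inertia_all[:n_axes],
        inertia_fraction=inertia_all[:n_axes] / total_inertia,
        total_inertia=total_inertia,
    )


def detrend_by_segments(r: OrdinationResult, n_segments: int = 26) -> OrdinationResult:
    """Re-center second-axis scores within equal-width windows of axis 1.

    Rows and columns share the same windows (computed over the combined
    axis-1 range) and the subtracted means pool both point sets, so taxa
    and environments stay on a common detrended scale.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if r.row_scores.shape[1] < 2:
        raise ValueError("detrending needs at least 2 axes")

    ax1 = np.concatenate([r.row_scores.iloc[:, 0], r.col_scores.iloc[:, 0]])
    ax2 = np.concatenate([r.row_scores.iloc[:, 1], r.col_scores.iloc[:, 1]])
    lo, hi = ax1.min(), ax1.max()
    if hi <= lo:
        return r
    edges = np.linspace(lo, hi, n_segments + 1)
    bins = np.clip(np.digitize(ax1, edges[1:-1]), 0, n_segments - 1)
    detrended = ax2.copy()
    for b in range(n_segments):
        mask = bins == b
        if mask.any():
            detrended[mask] -= ax2[mask].mean()

    n_rows = len(r.row_scores)
    new_rows = r.row_scores.copy()
    new_cols = r.col_scores.copy()
    new_rows.iloc[:, 1] = detrended[:n_rows]
    new_cols.iloc[:, 1] = detrended[n_rows:]
    return replace(r, row_scores=new_rows, col_scores=new_cols)


def biplot(result: OrdinationResult, path) -> None:
    """SVG bi-plot of the first two axes, environments labelled."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(
        result.row_scores.iloc[:, 0], result.row_scores.iloc[:, 1],
        s=8, c="grey", alpha=0.6, label="taxa",
    )
    ax.scatter(
        result.col_scores.iloc[:, 0], result.col_scores.iloc[:, 1],
        s=30, c="tab:red", marker="^", label="environments",
    )
    for name, row in result.col_scores.iterrows():
        ax.annotate(str(name), (row.iloc[0], row.iloc[1]), fontsize=7)
    pct = 100 * result.inertia_fraction
    ax.set_xlabel(f"Axis 1 ({pct[0]:.1f}% inertia)")
    if len(pct) > 1:
        ax.set_ylabel(f"Axis 2 ({pct[1]:.1f}% inertia)")
    ax.axhline(0, lw=0.5, c="k")
    ax.axvline(0, lw=0.5, c="k")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
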