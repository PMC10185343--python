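"""Per-cell colocalization (Pearson correlation against organelle markers)
and cell-death (% Annexin V positivity) scoring."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "pearson_per_cell",
    "replicate_median",
    "estimate_background",
    "venus_positive_threshold",
    "percent_annexin_positive",
]


def estimate_background(image: np.ndarray, cell_labels: np.ndarray) -> float:
    """Background level as the mode (most frequent integer value) of the
    non-cell pixels; falls back to their median for non-integer images."""
    bg = np.asarray(image)[np.asarray(cell_labels) == 0]
    if bg.size == 0:
        return 0.0
    if np.issubdtype(bg.dtype, np.integer):
        vals, counts = np.unique(bg, return_counts=True)
        return float(vals[np.argmax(counts)])
    return float(np.median(bg))


def pearson_per_cell(
    query: np.ndarray,
    organelle: np.ndarray,
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray | None = None,
    background: tuple[float, float] | None = None,
    min_intensity: float | None = None,
) -> pd.DataFrame:
    """Pearson correlation between query and organelle channel per cell.

    The correlation is computed over each cell's cytoplasmic pixels (nucleus
    excluded) after subtracting a per-channel background value (estimated
    from non-cell pixels unless given).  Cells whose mean query intensity
    falls below ``min_intensity`` (the transfection-expression threshold)
    are excluded; cells with zero variance in either channel are flagged
    (``valid = False``) and carry ``r = nan``.
    """
    query = np.asarray(query, dtype=float)
    organelle = np.asarray(organelle, dtype=float)
    cells = np.asarray(cell_labels)
    if query.shape != cells.shape or organelle.shape != cells.shape:
        raise ValueError("images and masks must share the same shape")
    if nucleus_labels is not None and np.asarray(nucleus_labels).shape != cells.shape:
        raise ValueError("nucleus mask shape mismatch")

    if background is None:
        background = (
            estimate_background(query, cells),
            estimate_background(organelle, cells),
        )
    q = query - background[0]
    o = organelle - background[1]

    cyto = cells.copy()
    if nucleus_labels is not None:
        cyto[np.asarray(nucleus_labels) > 0] = 0

    rows = []
    for lab in np.unique(cells[cells > 0]):
        m = cyto == lab
        if m.sum() < 3:
            continue
        qv, ov = q[m], o[m]
        mean_q = float(qv.mean())
        if min_intensity is not None and mean_q < min_intensity:
            continue
        valid = qv.std() > 0 and ov.std() > 0
        r = float(np.corrcoef(qv, ov)[0, 1]) if valid else float("nan")
        rows.append(
            {
                "cell_id": int(lab),
                "n_pixels": int(m.sum()),
                "mean_query": mean_q,
                "mean_organelle": float(ov.mean()),
                "pearson_r": r,
                "valid": bool(valid),
            }
        )
    return pd.DataFrame(
        rows, columns=["cell_id", "n_pixels", "mean_query", "mean_organelle", "pearson_r", "valid"]
    )


def replicate_median(records: pd.DataFrame, replicate_column: str = "replicate") -> pd.Series:
    """Median per-cell Pearson coefficient within each replicate.

    Invalid (zero-variance) cells are excluded from the medians.
    """
    df = records
    if "valid" in df.columns:
        df = df[df["valid"]]
    return df.groupby(replicate_column)["pearson_r"].median()


def venus_positive_threshold(untransfected_intensities) -> float:
    """Expression-positivity threshold: mean + 2 population standard
    deviations of the untransfected-well intensities."""
    x = np.asarray(untransfected_intensities, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 untransfected cells")
    return float(x.mean() + 2.0 * x.std(ddof=0))


def percent_annexin_positive(cells: pd.DataFrame, threshold: float) -> float:
    """% Annexin V-positive cells among expression (Venus)-positive cells.

    ``cells`` needs columns ``venus_intensity`` and ``annexin_positive``.
    Returns ``nan`` when no cell passes the expression threshold (the value
    is undefined, not zero).
    """
    venus_pos = cells["venus_intensity"] > threshold
    n_pos = int(venus_pos.sum())
    if n_pos == 0:
        return math.nan
    n_dead = int((venus_pos & cells["annexin_positive"].astype(bool)).sum())
    return 100.0 * n_dead / n_pos
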