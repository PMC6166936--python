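"""Feature-table normalization for the data-clustering path.

The denoised unit-max procedure corrects per-item (column) additive
offset by subtracting the median and multiplicative gain by scaling the
maximum to one, then removes outlier cells — negative values and exact
ones — which belong to distributions other than the bulk.  A follow-up
unit-median rescaling divides each column by the median of its nonzero
values.  Tables are oriented items-as-columns, features-as-rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["denoised_unit_max", "unit_median"]


def denoised_unit_max(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Median-center and max-scale each column, removing outlier cells.

    Per column: subtract the median, divide by the (post-centering)
    maximum; entries that come out negative or exactly one are treated
    as offset/saturation artifacts and zeroed.  All-zero and constant
    columns are dropped, and exactly duplicated feature rows are
    deduplicated.  Returns the cleaned table and a removal report.
    """
    values = table.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("feature table contains non-finite values")
    med = np.median(values, axis=0)
    centered = values - med[None, :]
    col_max = centered.max(axis=0)

    all_zero = (values == 0).all(axis=0)
    constant = (col_max <= 0) & ~all_zero
    keep_cols = ~(all_zero | constant)
    report = {
        "all_zero_columns": table.columns[all_zero].tolist(),
        "constant_columns": table.columns[constant].tolist(),
    }
    centered = centered[:, keep_cols]
    col_max = col_max[keep_cols]
    scaled = centered / col_max[None, :]

    outliers = (scaled < 0) | (scaled == 1.0)
    report["outlier_cells_removed"] = int(outliers.sum())
    scaled[outliers] = 0.0

    out = pd.DataFrame(
        scaled, index=table.index, columns=table.columns[keep_cols]
    )
    dup = out.duplicated(keep="first")
    report["duplicate_rows_removed"] = int(dup.sum())
    out = out.loc[~dup]
    report["n_rows"], report["n_columns"] = out.shape
    return out, report


def unit_median(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each column by the median of its nonzero values.

    Applied after :func:`denoised_unit_max`; columns with no nonzero
    entry are dropped.
    """
    values = table.to_numpy(dtype=float)
    scale = np.ones(values.shape[1])
    keep = np.ones(values.shape[1], dtype=bool)
    for j in range(values.shape[1]):
        nz = values[:, j] != 0
        if not nz.any():
            keep[j] = False
            continue
        scale[j] = np.median(values[nz, j])
    out = values[:, keep] / scale[keep][None, :]
    return pd.DataFrame(out, index=table.index, columns=table.columns[keep])
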