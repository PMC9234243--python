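"""Cross-tissue Pearson correlation of individual lipid species.

Samples are paired by mouse across the two tissues, mice flagged as
outliers (> k sample SDs within either tissue's vector) are removed
before pairing, and only pairwise-complete mouse pairs enter the fit.
The two-sided p-value comes from the exact t transform
``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` with ``n - 2`` degrees of
freedom.  Both temperature groups are pooled in one fit; no multiplicity
correction is applied to correlation p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import AbundanceTable, flag_outliers

__all__ = ["CorrelationRecord", "pearson_with_p", "cross_tissue_correlation"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationRecord:
    lipid: str
    tissue_a: str
    tissue_b: str
    r: float
    p_value: float
    n_pairs: int


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with its exact two-sided t-based p-value.

    Requires equal-length finite vectors of at least 3 values with
    nonzero variance in each.  At |r| = 1 the p-value is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return r, p, n


def cross_tissue_correlation(
    table_a: AbundanceTable,
    table_b: AbundanceTable,
    lipid: str,
    outlier_k: float = 2.0,
) -> CorrelationRecord | None:
    """Correlate one lipid between two tissues, pairing mice.

    Outlier flagging is applied to each tissue's vector of the lipid
    before pairing; flagged mice and mice missing in either tissue are
    dropped (pairwise-complete).  Returns None (logged) when fewer than
    3 complete pairs remain.
    """

    def per_mouse(table: AbundanceTable) -> tuple[pd.Series, str]:
        meta = table.meta.loc[list(table.data.columns)]
        tissues = meta["tissue"].unique()
        if len(tissues) != 1:
            raise ValueError("each table must hold a single tissue")
        if lipid not in table.data.index:
            raise KeyError(f"lipid {lipid!r} absent from {tissues[0]} table")
        vec = table.data.loc[lipid]
        vec.index = meta["mouse_id"].to_numpy()
        flags = flag_outliers(vec.to_numpy(), outlier_k)
        return vec[~flags & np.isfinite(vec.to_numpy())], str(tissues[0])

    a, tissue_a = per_mouse(table_a)
    b, tissue_b = per_mouse(table_b)
    mice = a.index.intersection(b.index)
    if len(mice) < 3:
        logger.info(
            "cross_tissue_correlation: %s %s~%s: only %d complete pairs, no record",
            lipid, tissue_a, tissue_b, len(mice),
        )
        return None
    r, p, n = pearson_with_p(a.loc[mice].to_numpy(), b.loc[mice].to_numpy())
    return CorrelationRecord(lipid, tissue_a, tissue_b, r, p, n)
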