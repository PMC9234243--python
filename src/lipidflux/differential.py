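"""Cold-vs-room differential lipid screen.

For each lipid of a tissue, the two temperature groups (n = 6 mice each by
design) are compared with an equal-variance two-sided Student's t-test on
the IS-normalized abundances; the log2 fold change is cold over room.
Because this is a discovery screen, p-values are corrected per tissue with
the Benjamini-Hochberg step-up procedure and a lipid is called changed at
q < 0.30.  Also provides the Venn-region counts of "increased in cold"
sets across tissues and a tissue-level PCA ordination on the lipids the
tissues share.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .quantify import AbundanceTable, flag_outliers

__all__ = [
    "ttest_screen",
    "bh_adjust",
    "increased_in_cold",
    "overlap_counts",
    "pca_scores",
]

logger = logging.getLogger(__name__)


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Monotone in p, never below the raw p, bounded by 1.  Inputs outside
    [0, 1] are rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ttest_screen(
    table: AbundanceTable,
    tissue: str | None = None,
    q_threshold: float = 0.30,
    outlier_k: float = 2.0,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-lipid cold-vs-room t-test with BH correction over the tissue.

    Outliers (> ``outlier_k`` sample SDs within a temperature group) are
    removed per lipid before testing; lipids with fewer than two retained
    values in either group, or a nonpositive group mean, are skipped with
    a logged reason.  Returns one row per tested lipid with columns
    lipid, tissue, log2_fold_change, t_statistic, p_value, q_value,
    direction ('up_in_cold' / 'down_in_cold' / 'unchanged'), n_cold,
    n_room.  Direction is 'unchanged' exactly when q >= ``q_threshold``.
    """
    meta = table.meta.loc[list(table.data.columns)]
    if tissue is not None:
        cols = meta.index[meta["tissue"] == tissue]
        if len(cols) == 0:
            raise ValueError(f"no samples for tissue {tissue!r}")
    else:
        tissues = meta["tissue"].unique()
        if len(tissues) != 1:
            raise ValueError("table spans multiple tissues; pass tissue=...")
        tissue = tissues[0]
        cols = meta.index
    cold_cols = [c for c in cols if meta.at[c, "temperature"] == "cold"]
    room_cols = [c for c in cols if meta.at[c, "temperature"] == "room"]
    if not cold_cols or not room_cols:
        raise ValueError("both temperature groups must be present")

    rows = []
    for key in table.data.index:
        cold = table.data.loc[key, cold_cols].to_numpy(dtype=float)
        room = table.data.loc[key, room_cols].to_numpy(dtype=float)
        cold = cold[np.isfinite(cold)]
        room = room[np.isfinite(room)]
        cold = cold[~flag_outliers(cold, outlier_k)]
        room = room[~flag_outliers(room, outlier_k)]
        if len(cold) < 2 or len(room) < 2:
            logger.info("ttest_screen: %s skipped (group with <2 values)", key)
            continue
        if cold.mean() <= 0 or room.mean() <= 0:
            logger.info("ttest_screen: %s skipped (nonpositive group mean)", key)
            continue
        t, p = stats.ttest_ind(cold, room, equal_var=equal_var)
        rows.append(
            {
                "lipid": key,
                "tissue": tissue,
                "log2_fold_change": float(np.log2(cold.mean() / room.mean())),
                "t_statistic": float(t),
                "p_value": float(p),
                "n_cold": len(cold),
                "n_room": len(room),
            }
        )
    records = pd.DataFrame(rows)
    if records.empty:
        return records
    records["q_value"] = bh_adjust(records["p_value"].to_numpy())
    records["direction"] = np.where(
        records["q_value"] >= q_threshold,
        "unchanged",
        np.where(records["log2_fold_change"] > 0, "up_in_cold", "down_in_cold"),
    )
    return records


def increased_in_cold(records: pd.DataFrame) -> set[str]:
    """Lipid keys called significantly increased in cold (q below threshold,
    positive fold change)."""
    if records.empty:
        return set()
    return set(records.loc[records["direction"] == "up_in_cold", "lipid"])


def overlap_counts(sets: dict[str, set[str]]):
    """Counts for every region of the Venn partition of up to 3 named sets.

    Returns a dict mapping the tuple of member set names (the region where
    exactly those sets overlap) to its element count.  With more than
    three sets a pairwise-intersection DataFrame is returned instead.
    """
    names = list(sets)
    if len(names) > 3:
        table = pd.DataFrame(index=names, columns=names, dtype=int)
        for a in names:
            for b in names:
                table.at[a, b] = len(sets[a] & sets[b])
        return table
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for members in itertools.combinations(names, k):
            inside = set.intersection(*(sets[m] for m in members)) if members else set()
            outside = set().union(*(sets[m] for m in names if m not in members), set())
            regions[members] = len(inside - outside)
    return regions


def pca_scores(data: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on a complete-case lipid matrix.

    ``data`` is lipids x samples; lipids with any missing value are
    dropped (complete-case restriction), samples are the observations and
    the matrix is feature-centered.  Returns per-sample scores (samples x
    components) and the nonincreasing variance fractions, which sum to 1
    at full rank.  Component signs follow the convention that each
    component's largest-magnitude loading is positive.
    """
    complete = data.dropna(axis=0)
    x = complete.to_numpy(dtype=float).T  # samples x lipids
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(x)
    # deterministic sign: largest-magnitude loading positive per component
    for j in range(pca.components_.shape[0]):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            pca.components_[j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=data.columns, columns=cols), pca.explained_variance_ratio_
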