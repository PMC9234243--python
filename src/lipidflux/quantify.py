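"""Semiquantification against class-matched internal standards, and the
log2 / z-score transform used for regression screening.

Peak areas are converted to pmol per mg tissue (pmol per ml for plasma) by
ratio to the spiked internal standard (IS) of the lipid's class::

    pmol_per_amount = (lipid area / class IS area) * spiked pmol / amount

Statistical screens then work either on these normalized abundances
(t-tests, fold changes, correlations) or on per-lipid standardized values
(log2, mean-centered, scaled to unit sample SD) for the regression model.
Nonpositive or missing measurements are treated as missing data, never as
zeros: log2 of zero is never taken.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nomenclature import lipid_class_of

__all__ = [
    "AbundanceTable",
    "InternalStandardMap",
    "is_normalize",
    "standardize",
    "flag_outliers",
]

logger = logging.getLogger(__name__)

TISSUES = ("plasma", "liver", "BAT", "iWAT", "eWAT", "kidney", "intestine", "lung", "heart", "GSM")
TEMPERATURES = ("cold", "room")

_META_COLUMNS = ("mouse_id", "tissue", "temperature", "amount")


@dataclass
class AbundanceTable:
    """Lipids x samples abundance matrix with per-sample metadata.

    ``data``: DataFrame indexed by canonical lipid key, one column per
    sample; missing measurements are NaN.  ``meta``: DataFrame indexed by
    sample id with columns mouse_id, tissue, temperature ('cold'/'room')
    and amount (mg tissue, or ml for plasma).
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    signed: bool = False  # True after standardization (values may be negative)

    def __post_init__(self) -> None:
        missing_meta = [c for c in self.data.columns if c not in self.meta.index]
        if missing_meta:
            raise ValueError(f"samples without metadata: {missing_meta}")
        for col in _META_COLUMNS:
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks column {col!r}")
        bad_temp = set(self.meta["temperature"]) - set(TEMPERATURES)
        if bad_temp:
            raise ValueError(f"unknown temperature labels: {sorted(bad_temp)}")
        if not (self.meta["amount"] > 0).all():
            raise ValueError("all amounts must be > 0")
        if not self.signed:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                if (self.data.to_numpy() < 0).any():
                    raise ValueError("observed abundances must be >= 0")

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def lipids(self) -> pd.Index:
        return self.data.index

    def samples_at(self, temperature: str) -> list[str]:
        m = self.meta.loc[list(self.data.columns)]
        return list(m.index[m["temperature"] == temperature])

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.data.copy(), self.meta.copy(), signed=self.signed)


@dataclass
class InternalStandardMap:
    """Per-class internal standard: identity, spiked pmol, per-sample areas.

    ``spiked_pmol`` maps lipid class -> pmol spiked per sample (e.g. the
    300 pmol deuterated oleoyl-carnitine used for acylcarnitines).
    ``areas`` is a DataFrame indexed by class with one column per sample.
    ``identities`` optionally names the standard compound per class.
    """

    spiked_pmol: dict[str, float]
    areas: pd.DataFrame
    identities: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.spiked_pmol if c not in self.areas.index]
        if missing:
            raise ValueError(f"IS areas missing for classes: {missing}")
        for cls, pmol in self.spiked_pmol.items():
            if not pmol > 0:
                raise ValueError(f"spiked pmol for {cls} must be > 0")


def is_normalize(
    raw_areas: pd.DataFrame,
    is_map: InternalStandardMap,
    meta: pd.DataFrame,
) -> AbundanceTable:
    """Normalize raw peak areas to pmol per tissue amount.

    Every lipid row is divided by its class IS area in the same sample,
    scaled by the spiked pmol and divided by the sample's tissue amount.
    The result is invariant to joint rescaling of a sample's raw areas
    (lipids and IS alike).  A lipid class without an IS entry, or an IS
    area that is zero/negative in some sample, is a hard error.
    """
    classes = pd.Series({key: lipid_class_of(str(key)) for key in raw_areas.index})
    unmapped = sorted(set(classes) - set(is_map.spiked_pmol))
    if unmapped:
        raise ValueError(f"no internal standard configured for lipid class(es): {unmapped}")

    is_areas = is_map.areas.loc[:, raw_areas.columns]
    bad = is_areas.le(0) | is_areas.isna()
    if bad.to_numpy().any():
        cls, sample = next(
            (c, s) for c in is_areas.index for s in is_areas.columns if bad.at[c, s]
        )
        raise ValueError(f"nonpositive IS area for class {cls} in sample {sample}")

    denom = is_areas.loc[classes.to_numpy()].set_axis(raw_areas.index)
    pmol = pd.Series(is_map.spiked_pmol).loc[classes.to_numpy()].set_axis(raw_areas.index)
    amounts = meta.loc[raw_areas.columns, "amount"]
    values = raw_areas.div(denom).mul(pmol, axis=0).div(amounts, axis=1)
    return AbundanceTable(values, meta)


def standardize(
    table: AbundanceTable, min_values: int = 3
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Per-lipid log2 -> mean-center -> scale to unit sample SD.

    Each retained row has mean 0 and SD 1 (ddof=1) over its non-missing
    cells.  Rows with fewer than ``min_values`` non-missing positive cells
    or zero variance are excluded; the second return value lists them with
    a reason, and the exclusion is logged.  Nonpositive cells are treated
    as missing before the log.
    """
    values = table.data.where(table.data > 0)
    logged = np.log2(values)
    n_obs = logged.notna().sum(axis=1)
    sd = logged.std(axis=1, ddof=1)

    reasons = {}
    for key in logged.index:
        if n_obs[key] < min_values:
            reasons[key] = f"fewer than {min_values} observed values"
        elif not sd[key] > 0:
            reasons[key] = "zero variance"
    excluded = pd.DataFrame(
        {"lipid": list(reasons), "reason": list(reasons.values())}
    ).set_index("lipid")
    if len(excluded):
        logger.info("standardize: excluded %d lipids (%s)", len(excluded),
                    ", ".join(f"{k}: {v}" for k, v in reasons.items()))

    kept = logged.drop(index=list(reasons))
    z = kept.sub(kept.mean(axis=1), axis=0).div(kept.std(axis=1, ddof=1), axis=0)
    return AbundanceTable(z, table.meta, signed=True), excluded


def flag_outliers(values: np.ndarray | pd.Series, k: float = 2.0) -> np.ndarray:
    """Boolean mask of values beyond ``k`` sample SDs of the mean.

    Single pass: mean and SD come from the full vector, never recomputed
    after removal.  NaNs are ignored (never flagged).  With fewer than 3
    observed values no flagging occurs and a warning is logged.
    """
    arr = np.asarray(values, dtype=float)
    obs = np.isfinite(arr)
    flags = np.zeros(arr.shape, dtype=bool)
    if obs.sum() < 3:
        logger.warning("flag_outliers: fewer than 3 values, no flagging performed")
        return flags
    mean = arr[obs].mean()
    sd = arr[obs].std(ddof=1)
    if sd == 0:
        return flags
    flags[obs] = np.abs(arr[obs] - mean) > k * sd
    return flags
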