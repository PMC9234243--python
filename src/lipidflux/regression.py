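"""Lipidome-wide covariate-adjusted regression screen.

Each standardized tissue lipid X is regressed, one at a time, against a
standardized plasma lipid of interest Y with housing temperature as a
covariate::

    Y_plasma = b0 + b1 * Temperature + b2 * X_tissue

Temperature is coded 0 for cold and 1 for room temperature.  A tissue
lipid is flagged significantly predictive only when *both* the
temperature and the lipid coefficient have two-sided P < 0.05 — the dual
criterion — so that predictive power is demonstrated over and above the
shared temperature response.  Positive b2 predictors are read as
candidate tissue contributions to the circulating pool, negative ones as
candidate uptake/consumption.  No multiplicity correction enters the
flag (the screen is deliberately raw-P); BH q-values across each screen
are reported alongside as a diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .quantify import AbundanceTable

__all__ = [
    "OLSResult",
    "ols_fit",
    "temperature_code",
    "screen_plasma_lipid",
    "interaction_term_p",
    "partial_corr_power",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
_DEGENERATE_TOL = 1e-10


@dataclass(frozen=True)
class OLSResult:
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    degenerate: bool  # zero residual variance (exact fit)


def ols_fit(y: np.ndarray, design: np.ndarray) -> OLSResult:
    """Ordinary least squares with t-based coefficient inference.

    ``design`` must include the intercept column and be full rank with at
    least one residual degree of freedom.  Standard errors come from the
    residual variance times the diagonal of (X'X)^-1.  A zero-residual
    (exact) fit is flagged degenerate: standard errors are zero and
    p-values are reported as 0 for nonzero coefficients.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} rows for {k} columns, got {n}")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    tss = float(((y - y.mean()) ** 2).sum())
    degenerate = rss <= _DEGENERATE_TOL * max(tss, 1.0)
    xtx_inv = np.linalg.inv(X.T @ X)
    if degenerate:
        bse = np.zeros(k)
        scale = max(np.abs(beta).max(), 1.0)
        nonzero = np.abs(beta) > 1e-8 * scale
        tvals = np.where(nonzero, np.inf * np.sign(beta), 0.0)
        pvals = np.where(nonzero, 0.0, 1.0)
    else:
        sigma2 = rss / df
        bse = np.sqrt(sigma2 * np.diag(xtx_inv))
        tvals = beta / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    return OLSResult(beta, bse, tvals, pvals, df, degenerate)


def temperature_code(labels) -> np.ndarray:
    """Binary temperature coding: cold -> 0, room -> 1."""
    arr = np.asarray(labels)
    bad = set(np.unique(arr)) - {"cold", "room"}
    if bad:
        raise ValueError(f"unknown temperature labels: {sorted(bad)}")
    return (arr == "room").astype(float)


def _aligned_vectors(
    plasma: AbundanceTable, target: str
) -> tuple[pd.Series, pd.Series]:
    """Plasma target values and temperature labels indexed by mouse_id."""
    if target not in plasma.data.index:
        raise KeyError(f"plasma target {target!r} not in table")
    meta = plasma.meta.loc[list(plasma.data.columns)]
    y = plasma.data.loc[target]
    y.index = meta["mouse_id"].to_numpy()
    temp = pd.Series(meta["temperature"].to_numpy(), index=meta["mouse_id"].to_numpy())
    if y.index.duplicated().any():
        raise ValueError("duplicate mouse_id within plasma table")
    return y, temp


def screen_plasma_lipid(
    plasma_table: AbundanceTable,
    tissue_tables: dict[str, AbundanceTable],
    target: str,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Regress every tissue lipid against one plasma lipid.

    All tables must already be standardized (see ``quantify.standardize``);
    mice align across tissues by mouse_id and a tissue missing a mouse
    drops that mouse from its own fits only.  Returns one row per
    (tissue, tissue lipid): beta0/beta1/beta2, p_temperature, p_lipid,
    the dual-criterion ``significant`` flag, ``predictor_sign`` and a
    diagnostic BH ``q_lipid`` computed across the whole screen.
    """
    if not plasma_table.signed:
        raise ValueError("plasma table must be standardized before screening")
    y_all, temp_all = _aligned_vectors(plasma_table, target)
    rows = []
    for tissue, table in tissue_tables.items():
        if not table.signed:
            raise ValueError(f"{tissue} table must be standardized before screening")
        meta = table.meta.loc[list(table.data.columns)]
        mouse_of_col = meta["mouse_id"]
        for lipid in table.data.index:
            x = table.data.loc[lipid]
            x.index = mouse_of_col.to_numpy()
            mice = [
                m for m in y_all.index
                if m in x.index and np.isfinite(x[m]) and np.isfinite(y_all[m])
            ]
            if len(mice) < 5:  # 3 coefficients + residual df
                logger.info("screen: %s/%s skipped (%d aligned mice)", tissue, lipid, len(mice))
                continue
            yv = y_all.loc[mice].to_numpy(dtype=float)
            xv = x.loc[mice].to_numpy(dtype=float)
            tv = temperature_code(temp_all.loc[mice].to_numpy())
            if len(np.unique(tv)) < 2 or np.std(xv) == 0:
                continue
            X = np.column_stack([np.ones(len(mice)), tv, xv])
            fit = ols_fit(yv, X)
            rows.append(
                {
                    "plasma_lipid": target,
                    "tissue": tissue,
                    "tissue_lipid": lipid,
                    "beta0": fit.params[0],
                    "beta1": fit.params[1],
                    "beta2": fit.params[2],
                    "p_temperature": fit.pvalues[1],
                    "p_lipid": fit.pvalues[2],
                    "n": len(mice),
                    "degenerate": fit.degenerate,
                }
            )
    records = pd.DataFrame(rows)
    if records.empty:
        return records
    records["significant"] = (records["p_temperature"] < alpha) & (records["p_lipid"] < alpha)
    records["predictor_sign"] = np.where(records["beta2"] >= 0, "positive", "negative")
    from .differential import bh_adjust  # local import avoids cycle at module load

    records["q_lipid"] = bh_adjust(records["p_lipid"].to_numpy())
    return records


def interaction_term_p(
    y: np.ndarray, temperature: np.ndarray, x: np.ndarray
) -> tuple[float, bool]:
    """P-value of the temperature-by-lipid interaction term.

    Fits ``y ~ 1 + temperature + x + temperature*x`` and returns the
    two-sided p of the interaction coefficient with the degenerate-fit
    flag.  The interaction model is a diagnostic only; it never enters
    the dual-criterion flag.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(temperature, dtype=float)
    x = np.asarray(x, dtype=float)
    X = np.column_stack([np.ones_like(y), t, x, t * x])
    fit = ols_fit(y, X)
    return float(fit.pvalues[3]), fit.degenerate


def _sample_corr_pdf(r: np.ndarray, rho: float, m: int) -> np.ndarray:
    """Exact density of the sample Pearson correlation (m observations,
    bivariate normal population correlation rho)."""
    r = np.asarray(r, dtype=float)
    log_c = (
        np.log(m - 2)
        + special.gammaln(m - 1)
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(m - 0.5)
        + 0.5 * (m - 1) * np.log1p(-rho * rho)
    )
    log_body = (
        0.5 * (m - 4) * np.log1p(-r * r)
        + (1.5 - m) * np.log1p(-rho * r)
    )
    hyp = special.hyp2f1(0.5, 0.5, m - 0.5, (1.0 + rho * r) / 2.0)
    return np.exp(log_c + log_body) * hyp


def partial_corr_power(
    rho: float, n: int, n_conditioning: int = 1, alpha: float = ALPHA
) -> float:
    """Exact power of the two-sided partial-correlation t-test.

    The sample partial correlation given ``n_conditioning`` covariates is
    distributed as a plain sample correlation on ``n - n_conditioning``
    observations, so the power is the probability mass of that exact
    density beyond the critical |r| of the t-test with
    ``n - 2 - n_conditioning`` degrees of freedom.  Used as the analytic
    reference for the screen's sensitivity at a planted standardized
    effect.
    """
    if not -1 < rho < 1:
        raise ValueError("rho must be in (-1, 1)")
    df = n - 2 - n_conditioning
    if df < 1:
        raise ValueError("not enough observations for the test")
    m = n - n_conditioning
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    r_crit = t_crit / np.sqrt(t_crit**2 + df)
    lo, _ = integrate.quad(_sample_corr_pdf, -1, -r_crit, args=(rho, m), limit=200)
    hi, _ = integrate.quad(_sample_corr_pdf, r_crit, 1, args=(rho, m), limit=200)
    return float(lo + hi)
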