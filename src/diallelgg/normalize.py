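"""Two-channel intensity preprocessing and fixed-effects residualization.

Pipeline: per-subgrid background subtraction -> per-channel robust-affine
arsinh variance-stabilizing transform -> simultaneous cross-slide
calibration (common median 0, MAD 1 for every channel) -> per-gene ordinary
least squares on the technical covariates, keeping the residuals as the
expression traits.

Two residualization models are supported, named by ``model_tag``:

* ``eq1``: h = mu + dye + block + batch + person + eps  (eQTL mapping input)
* ``eq2``: h = mu + dye + block + family + batch + person + eps
  (co-expression network input; the family term absorbs between-cross
  genetic means)

All factors are fixed effects with sum-to-zero coding.  When an individual
is measured on more than one channel, its residuals are averaged.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "subtract_background",
    "vsn_transform",
    "calibrate_across_slides",
    "fit_technical_model",
    "residualize",
    "EQ1_FACTORS",
    "EQ2_FACTORS",
]

EQ1_FACTORS = ("dye", "block", "batch", "person")
EQ2_FACTORS = ("dye", "block", "family", "batch", "person")


def _mad(x: np.ndarray) -> float:
    """Plain median absolute deviation (no consistency scaling)."""
    return float(np.median(np.abs(x - np.median(x))))


def subtract_background(raw: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-subgrid background from every spot's foreground.

    Negative net intensities are retained; the arsinh transform is defined
    on all reals.  Returns a copy with a ``net`` column.
    """
    if "subgrid" not in raw.columns:
        raise ValueError("missing subgrid column")
    if raw["background"].isna().any():
        bad = raw.loc[raw["background"].isna(), "subgrid"].unique()
        raise ValueError(f"missing background for subgrids {list(bad)[:5]}")
    out = raw.copy()
    out["net"] = out["foreground"] - out["background"]
    return out


def vsn_transform(table: pd.DataFrame, value_col: str = "net") -> pd.DataFrame:
    """Robust-affine arsinh stabilization per slide-channel.

    h = arsinh((x - a_c) / b_c) with a_c the channel median and b_c the
    channel MAD; strictly increasing in x, linear near the origin and
    logarithmic for large intensities, so multiplicative noise at high
    signal is damped.
    """
    out = table.copy()
    h = np.empty(len(out))
    for (_s, _c), grp in out.groupby(["slide", "channel"], sort=False):
        x = grp[value_col].to_numpy(dtype=float)
        if np.isfinite(x).sum() < 2:
            raise ValueError(f"channel ({_s}, {_c}) has <2 finite values")
        a, b = np.median(x), _mad(x)
        if b == 0:
            raise ValueError(f"zero MAD (constant channel) for ({_s}, {_c})")
        h[out.index.get_indexer(grp.index)] = np.arcsinh((x - a) / b)
    out["h"] = h
    return out


def calibrate_across_slides(table: pd.DataFrame, value_col: str = "h") -> pd.DataFrame:
    """Rescale every slide-channel to common median 0 and MAD 1.

    Idempotent: applying it to already-calibrated values is the identity to
    numerical tolerance.
    """
    groups = table.groupby(["slide", "channel"], sort=False)
    if groups.ngroups < 2:
        raise ValueError("need >= 2 channels to calibrate across slides")
    out = table.copy()
    v = out[value_col].to_numpy(dtype=float).copy()
    for (_s, _c), grp in groups:
        idx = out.index.get_indexer(grp.index)
        x = v[idx]
        med, mad = np.median(x), _mad(x)
        if mad == 0:
            raise ValueError(f"constant channel ({_s}, {_c})")
        v[idx] = (x - med) / mad
    out[value_col] = v
    return out


def _sum_to_zero_design(cov: pd.DataFrame, factors) -> Tuple[np.ndarray, List[str]]:
    """Intercept + sum-to-zero (deviation) coded columns for each factor."""
    n = len(cov)
    cols = [np.ones(n)]
    names = ["mu"]
    for f in factors:
        levels = sorted(cov[f].astype(str).unique())
        if len(levels) < 2:
            continue  # single-level factor contributes nothing beyond mu
        ref = levels[-1]
        for lv in levels[:-1]:
            col = np.where(cov[f].astype(str) == lv, 1.0, 0.0)
            col[cov[f].astype(str) == ref] = -1.0
            cols.append(col)
            names.append(f"{f}[{lv}]")
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: List[str], factors) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # a factor is aliased when its columns add less than full rank on top of
    # all the other design columns
    aliased = []
    full_rank = np.linalg.matrix_rank(X)
    for f in factors:
        idx = [i for i, nm in enumerate(names) if nm.startswith(f"{f}[")]
        if not idx:
            continue
        others = [i for i in range(X.shape[1]) if i not in idx]
        if full_rank < np.linalg.matrix_rank(X[:, others]) + len(idx):
            aliased.append(f)
    raise ValueError(f"rank-deficient design; aliased factors: {aliased or 'unknown'}")


def fit_technical_model(h: pd.DataFrame, covariates: pd.DataFrame,
                        model_tag: str = "eq1"):
    """Per-gene OLS of stabilized intensities on the technical factors.

    ``h`` is an observations x genes matrix (one row per slide-channel
    measurement); ``covariates`` is row-aligned with columns for the
    model's factors plus ``individual``.  Returns
    ``(residual_matrix, effects)``: residuals averaged per individual
    (rows: individuals, columns: genes; ``attrs['model_tag']`` records the
    model) and the coefficient table (rows: design columns, columns: genes).
    """
    if model_tag not in ("eq1", "eq2"):
        raise ValueError("model_tag must be 'eq1' or 'eq2'")
    factors = EQ1_FACTORS if model_tag == "eq1" else EQ2_FACTORS
    missing = [f for f in factors if f not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks {missing}")
    if covariates[list(factors)].isna().any().any():
        raise ValueError("covariate table has missing entries")
    if len(h) != len(covariates):
        raise ValueError("h and covariates are not row-aligned")

    X, names = _sum_to_zero_design(covariates, factors)
    _check_full_rank(X, names, factors)
    Y = h.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    effects = pd.DataFrame(beta, index=names, columns=h.columns)

    res_obs = pd.DataFrame(resid, index=covariates["individual"].to_numpy(),
                           columns=h.columns)
    res_ind = res_obs.groupby(level=0).mean()
    res_ind.attrs["model_tag"] = model_tag
    return res_ind, effects


def residualize(intensities: pd.DataFrame, model_tag: str = "eq1"):
    """Full preprocessing chain from a raw intensity table to residuals.

    The long table must carry foreground/background/subgrid plus the sample
    and stratum columns (individual, family, block, batch, person); the
    dye factor is the channel.
    """
    net = subtract_background(intensities)
    h = calibrate_across_slides(vsn_transform(net))
    wide = h.pivot_table(index=["slide", "channel"], columns="spot", values="h",
                         sort=False)
    meta = (
        h.groupby(["slide", "channel"], sort=False)
        .first()[["individual", "family", "block", "batch", "person"]]
        .reindex(wide.index)
        .reset_index()
    )
    cov = meta.rename(columns={"channel": "dye"})
    return fit_technical_model(wide.reset_index(drop=True), cov, model_tag)
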