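"""Two-point recombination estimation and map-distance utilities.

The framework linkage map is an *input* to all QTL analyses; this module
provides the Haldane map function (no crossover interference) used by the
meiosis simulator, and a per-parent two-point estimator of the recombination
fraction from transmitted-allele indicators, with a binomial LOD for linkage
against the null r = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TwoPointEstimate",
    "haldane_cm",
    "haldane_r",
    "estimate_recombination",
    "two_point_table",
]


@dataclass(frozen=True)
class TwoPointEstimate:
    """Per-parent two-point recombination estimate between two markers."""

    parent: str
    marker1: str
    marker2: str
    n_informative: int
    n_recombinant: int
    r_hat: float
    lod_linkage: float


def haldane_cm(r) -> float:
    """Map distance in cM for recombination fraction ``r`` (Haldane).

    d = -50 * ln(1 - 2r).  Requires r in [0, 0.5).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("haldane_cm requires 0 <= r < 0.5")
    out = -50.0 * np.log1p(-2.0 * r)
    return float(out) if out.ndim == 0 else out


def haldane_r(d) -> float:
    """Recombination fraction for map distance ``d`` cM (Haldane).

    r = 0.5 * (1 - exp(-2d/100)).  Requires d >= 0.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("haldane_r requires d >= 0")
    out = 0.5 * -np.expm1(-2.0 * d / 100.0)
    return float(out) if out.ndim == 0 else out


def _binomial_linkage_lod(k: int, n: int) -> float:
    """log10 likelihood ratio of r_hat = k/n against r = 0.5.

    LOD = k*log10(r) + (n-k)*log10(1-r) - n*log10(0.5), with the MLE capped
    at 0.5 so the statistic is never negative.
    """
    r = min(k / n, 0.5)
    ll1 = 0.0
    if k > 0:
        ll1 += k * np.log10(r)
    if n - k > 0:
        ll1 += (n - k) * np.log10(1.0 - r)
    ll0 = n * np.log10(0.5)
    return max(ll1 - ll0, 0.0)


def estimate_recombination(genotypes, m1: str, m2: str, parent: str) -> TwoPointEstimate:
    """Two-point recombination fraction between markers for one parent.

    Uses the transmitted-allele indicators of that parent's meioses; a
    meiosis is informative when the indicator is non-missing at both
    markers (the parent is heterozygous at both).  Phase is taken as known.
    """
    x = genotypes.transmissions(parent)
    if m1 not in x.columns or m2 not in x.columns:
        raise KeyError(f"unknown marker among ({m1}, {m2})")
    a = x[m1].to_numpy(dtype=float)
    b = x[m2].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"uninformative pair ({m1}, {m2}) for parent {parent}")
    k = int((a[ok] != b[ok]).sum())
    r_hat = min(k / n, 0.5)
    lod = _binomial_linkage_lod(k, n)
    return TwoPointEstimate(parent, m1, m2, n, k, r_hat, lod)


def two_point_table(genotypes, pairs, parents=None) -> pd.DataFrame:
    """Tabulate two-point estimates for marker pairs, per parent.

    Pairs informative in both parents yield one record per parent.
    Uninformative (parent, pair) combinations are skipped.
    """
    if parents is None:
        parents = list(genotypes.parents)
    rows = []
    for m1, m2 in pairs:
        for p in parents:
            try:
                e = estimate_recombination(genotypes, m1, m2, p)
            except ValueError:
                continue
            rows.append(
                (e.parent, e.marker1, e.marker2, e.n_informative, e.r_hat, e.lod_linkage)
            )
    return pd.DataFrame(rows, columns=["parent", "marker1", "marker2", "n", "r_hat", "lod"])
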