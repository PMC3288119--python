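"""eQTL hotspot detection with a randomization-calibrated cluster threshold.

eQTLs are tallied per framework marker (one count per trait-support-
interval peak).  Departure from a uniform spread along the map is tested
with a Pearson chi-square goodness-of-fit statistic.  The hotspot
threshold is obtained by randomization: drop the observed number of eQTLs
independently and uniformly over the markers, record the largest
per-marker cluster in each replicate, and take the maximum over all
replicates (a 95th-percentile mode is available for sensitivity analysis).
A marker is a hotspot when its count reaches the threshold (inclusive);
hotspots are then classified by the significant pQTLs collocated at the
same marker into none / resistance / growth / both.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import as_rng
from .simdata import GROWTH_TRAITS, RESISTANCE_TRAITS

__all__ = [
    "count_per_marker",
    "gof_uniform",
    "randomization_threshold",
    "declare_hotspots",
    "phenotype_association",
    "default_trait_groups",
]


def default_trait_groups() -> Dict[str, Sequence[str]]:
    return {"resistance": RESISTANCE_TRAITS, "growth": GROWTH_TRAITS}


def count_per_marker(eqtls: pd.DataFrame, gmap) -> pd.Series:
    """Number of eQTLs at each framework marker (zeros included)."""
    markers = gmap.marker_ids
    unknown = set(eqtls["marker_id"]) - set(markers)
    if unknown:
        raise KeyError(f"unknown marker ids in eQTL table: {sorted(unknown)[:5]}")
    counts = eqtls["marker_id"].value_counts()
    return counts.reindex(markers, fill_value=0).astype(int)


def gof_uniform(counts: pd.Series) -> Tuple[float, int, float]:
    """Pearson chi-square test of uniform eQTL spread over the markers.

    Expected count is N/M at every marker; df = M - 1; upper-tail p-value
    from the chi-square distribution.
    """
    obs = np.asarray(counts, dtype=float)
    M = len(obs)
    N = obs.sum()
    if N <= 0:
        raise ValueError("no eQTLs to test")
    if M < 2:
        raise ValueError("need >= 2 markers")
    expected = N / M
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = M - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def randomization_threshold(n_eqtl: int, n_markers: int, n_reps: int = 1000,
                            seed=None, mode: str = "max") -> int:
    """Cluster-size threshold from uniform random placement of the eQTLs.

    Each replicate drops ``n_eqtl`` eQTLs independently and uniformly on
    ``n_markers`` markers.  ``mode='max'`` (default) returns the maximum
    per-marker count over all replicates; ``mode='perc95'`` returns the
    95th percentile of the per-replicate maxima.
    """
    if n_eqtl < 0 or n_markers < 1 or n_reps < 1:
        raise ValueError("need n_eqtl >= 0, n_markers >= 1, n_reps >= 1")
    if mode not in ("max", "perc95"):
        raise ValueError("mode must be 'max' or 'perc95'")
    if n_eqtl == 0:
        return 0
    rng = as_rng(seed)
    pvals = np.full(n_markers, 1.0 / n_markers)
    counts = rng.multinomial(n_eqtl, pvals, size=n_reps)
    rep_max = counts.max(axis=1)
    if mode == "max":
        return int(rep_max.max())
    return int(np.percentile(rep_max, 95, method="higher"))


def declare_hotspots(counts: pd.Series, threshold: int) -> pd.Series:
    """Boolean hotspot flag per marker: count >= threshold (inclusive)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return counts >= threshold


def phenotype_association(hotspot_flags: pd.Series, pqtls: pd.DataFrame,
                          min_pqtl: int = 3,
                          trait_groups: Optional[Dict[str, Sequence[str]]] = None
                          ) -> pd.Series:
    """Classify each hotspot marker by its collocated significant pQTLs.

    Class is 'none' when fewer than ``min_pqtl`` pQTLs collocate, otherwise
    'resistance' / 'growth' / 'both' by the group membership of the
    collocated traits.  Every pQTL trait must belong to a group.
    """
    groups = trait_groups if trait_groups is not None else default_trait_groups()
    trait_to_group = {}
    for gname, traits in groups.items():
        for t in traits:
            trait_to_group[t] = gname
    unknown = set(pqtls["trait_id"]) - set(trait_to_group)
    if unknown:
        raise ValueError(f"traits not in any group: {sorted(unknown)[:5]}")
    out = pd.Series("none", index=hotspot_flags.index, dtype=object)
    by_marker = pqtls.groupby("marker_id")["trait_id"].apply(list)
    for marker, flag in hotspot_flags.items():
        if not flag:
            continue
        traits = by_marker.get(marker, [])
        if len(traits) < min_pqtl:
            continue
        gset = {trait_to_group[t] for t in traits}
        if gset == {"resistance"}:
            out[marker] = "resistance"
        elif gset == {"growth"}:
            out[marker] = "growth"
        else:
            out[marker] = "both"
    return out


def hotspot_report(eqtls: pd.DataFrame, pqtls: pd.DataFrame, gmap,
                   n_reps: int = 1000, seed=None, min_pqtl: int = 3,
                   trait_groups=None, mode: str = "max"):
    """Full hotspot analysis: counts, GOF test, threshold, flags, classes.

    Returns ``(report, summary)``: a per-marker DataFrame and a dict with
    N, M, chi2, df, p and the randomization threshold.
    """
    counts = count_per_marker(eqtls, gmap)
    if counts.sum() > 0:
        chi2, df, p = gof_uniform(counts)
    else:  # degenerate cascade: nothing mapped, nothing to test
        chi2, df, p = float("nan"), len(counts) - 1, float("nan")
    threshold = randomization_threshold(int(counts.sum()), len(counts), n_reps, seed,
                                        mode=mode)
    flags = declare_hotspots(counts, max(threshold, 1))
    classes = phenotype_association(flags, pqtls, min_pqtl, trait_groups)
    n_pqtls = (
        pqtls.groupby("marker_id").size().reindex(counts.index, fill_value=0).astype(int)
    )
    report = gmap.table.copy()
    report["eqtl_count"] = counts.to_numpy()
    report["n_pqtls"] = n_pqtls.to_numpy()
    report["hotspot"] = flags.to_numpy()
    report["class"] = classes.to_numpy()
    summary = {
        "n_eqtls": int(counts.sum()),
        "n_markers": int(len(counts)),
        "chi2": None if chi2 != chi2 else chi2,
        "df": df,
        "p": None if p != p else p,
        "threshold": int(threshold),
        "mode": mode,
    }
    return report, summary
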