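"""Positional candidate genes by eQTL/pQTL collocation permutation.

A gene is a positional candidate for a trait when at least 40% of its
significant eQTLs sit at the trait's significant pQTL markers and a
permutation test supports the collocation at p <= 0.05.  The permutation
null re-places the gene's eQTLs uniformly at random over the mapped
markers (without replacement over the gene's distinct eQTL markers),
conditioning on the observed pQTL landscape, and recomputes the
collocation fraction; 10,000 randomizations by default.

Two p-values are reported.  ``p_perm`` is the add-one estimator
(1 + #{null >= obs}) / (n_perm + 1); it can never be zero and is the value
the candidate rule uses.  Because the null is discrete, ``p_perm`` is
conservative (super-uniform); ``p_rand``, the standard randomized p-value
for discrete nulls, is exactly uniform under the null and is the right
quantity for calibration diagnostics.

"General resistance" candidates are genes that are candidates for every
one of the six resistance traits (yearly attack and oviposition plus their
sums).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd

from ._rng import as_rng
from .simdata import RESISTANCE_TRAITS

__all__ = [
    "CollocationResult",
    "collocation_fraction",
    "collocation_test",
    "candidate_table",
    "general_resistance_candidates",
    "FRACTION_THRESHOLD",
    "ALPHA",
    "N_PERMUTATIONS",
]

FRACTION_THRESHOLD = 0.40
ALPHA = 0.05
N_PERMUTATIONS = 10_000


@dataclass(frozen=True)
class CollocationResult:
    gene_id: str
    trait_id: str
    n_eqtls: int
    collocation_fraction: float
    p_perm: float
    p_rand: float
    candidate: bool


def collocation_fraction(gene_eqtls: Iterable[str], trait_pqtl_markers: Iterable[str]
                         ) -> float:
    """Fraction of the gene's distinct eQTL markers that carry a trait pQTL."""
    genes = set(gene_eqtls)
    if not genes:
        raise ValueError("no eQTLs for gene")
    return len(genes & set(trait_pqtl_markers)) / len(genes)


def _null_counts(M: int, m: int, k: int, n_perm: int, rng) -> np.ndarray:
    """Permutation-null collocation counts: k of M markers drawn uniformly
    without replacement, counting hits in the m pQTL markers."""
    keys = rng.random((n_perm, M))
    picks = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return (picks < m).sum(axis=1)  # pQTL markers occupy indices 0..m-1 wlog


def collocation_test(gene_eqtls: Iterable[str], trait_pqtls: Iterable[str], gmap,
                     n_perm: int = N_PERMUTATIONS, seed=None,
                     gene_id: str = "gene", trait_id: str = "trait",
                     frac_threshold: float = FRACTION_THRESHOLD,
                     alpha: float = ALPHA,
                     null_counts: Optional[np.ndarray] = None) -> CollocationResult:
    """Permutation collocation test for one gene against one trait.

    ``gene_eqtls`` / ``trait_pqtls`` are marker-id collections (duplicates
    collapse to distinct markers).  ``null_counts`` lets callers reuse a
    pre-simulated null for the same (k, pQTL set) configuration.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    markers = set(gmap.marker_ids)
    gene_set = set(gene_eqtls)
    pqtl_set = set(trait_pqtls) & markers
    if not gene_set:
        raise ValueError("no eQTLs for gene")
    if not gene_set <= markers:
        raise KeyError("gene eQTLs reference unmapped markers")
    M, m, k = len(markers), len(pqtl_set), len(gene_set)
    obs_count = len(gene_set & pqtl_set)
    obs_frac = obs_count / k
    rng = as_rng(seed)
    if null_counts is None:
        null_counts = _null_counts(M, m, k, n_perm, rng)
    n_ge = int((null_counts >= obs_count).sum())
    n_eq = int((null_counts == obs_count).sum())
    p_perm = (1 + n_ge) / (len(null_counts) + 1)
    u = rng.random()
    p_rand = ((n_ge - n_eq) + u * (1 + n_eq)) / (len(null_counts) + 1)
    candidate = (obs_frac >= frac_threshold) and (p_perm <= alpha)
    return CollocationResult(gene_id, trait_id, k, obs_frac, p_perm, p_rand, candidate)


def candidate_table(eqtls: pd.DataFrame, pqtls: pd.DataFrame, gmap,
                    n_perm: int = N_PERMUTATIONS, seed=None,
                    frac_threshold: float = FRACTION_THRESHOLD,
                    alpha: float = ALPHA,
                    trait_names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Collocation tests for every (gene, trait) pair in the QTL tables.

    The permutation null depends only on the number of distinct gene eQTL
    markers and the trait's pQTL marker set, so null draws are cached per
    (trait, k); gene order does not change any p-value.  ``trait_names``
    forces a row for traits without any significant pQTL (fraction 0,
    p = 1, never a candidate), so composite rules see every trait.
    """
    rng = as_rng(seed)
    gene_markers = eqtls.groupby("trait_id")["marker_id"].apply(lambda s: set(s))
    trait_markers = pqtls.groupby("trait_id")["marker_id"].apply(lambda s: set(s))
    if trait_names is not None:
        trait_markers = trait_markers.reindex(trait_names).map(
            lambda v: v if isinstance(v, set) else set()
        )
    M = gmap.n_markers
    cache: Dict[tuple, np.ndarray] = {}
    rows = []
    for trait, pset in trait_markers.items():
        m = len(pset)
        if m == 0:
            for gene, gset in gene_markers.items():
                rows.append(CollocationResult(gene, trait, len(gset), 0.0, 1.0,
                                              float(rng.random()), False).__dict__)
            continue
        for gene, gset in gene_markers.items():
            k = len(gset)
            key = (trait, k)
            if key not in cache:
                cache[key] = _null_counts(M, m, k, n_perm, rng)
            r = collocation_test(gset, pset, gmap, n_perm=n_perm, seed=rng,
                                 gene_id=gene, trait_id=trait,
                                 frac_threshold=frac_threshold, alpha=alpha,
                                 null_counts=cache[key])
            rows.append(r.__dict__)
    cols = ["gene_id", "trait_id", "n_eqtls", "collocation_fraction", "p_perm",
            "p_rand", "candidate"]
    return pd.DataFrame(rows, columns=cols)


def general_resistance_candidates(results: pd.DataFrame,
                                  resistance_traits: Sequence[str] = RESISTANCE_TRAITS
                                  ) -> list:
    """Genes that are candidates for all six resistance traits."""
    out = []
    for gene, grp in results.groupby("gene_id"):
        have = set(grp["trait_id"])
        missing = set(resistance_traits) - have
        if missing:
            raise ValueError(f"gene {gene} lacks results for {sorted(missing)}")
        sub = grp[grp["trait_id"].isin(resistance_traits)]
        if sub["candidate"].all():
            out.append(gene)
    return sorted(out)
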