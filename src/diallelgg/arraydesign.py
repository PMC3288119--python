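"""Distant-pair two-color hybridization design.

Pairs individuals within each cross so that the two samples co-hybridized
on a slide are as genetically dissimilar as possible (maximizing allele
contrasts within hybridizations), balances Cy3/Cy5 across replicate
blocks, fabrication batches and experimenters, and quantifies the
improvement of the optimized pairing over random pairing.

Genetic distance between two full sibs is the simple mismatch fraction of
their transmitted-allele states over the cross's segregating loci.  The
optimizer is a greedy farthest-pair construction followed by 2-exchange
hill climbing with random restarts; instances are small (<= 54 individuals
per cross), and brute-force enumeration serves as the exact oracle for
small n in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import as_rng, substream

__all__ = [
    "PairingPlan",
    "genetic_distance",
    "state_frame",
    "distance_matrix",
    "optimize_pairs",
    "matching_objective",
    "improvement_vs_random",
    "assign_dyes",
    "build_design",
]


@dataclass
class PairingPlan:
    """Hybridization plan: one row per slide.

    Columns: slide_id, cross_id, cy3, cy5 and, after :func:`assign_dyes`,
    block, batch, person.  ``objective`` is the mean genetic distance
    between co-hybridized samples.
    """

    frame: pd.DataFrame
    objective: float = float("nan")
    trace: List[float] = field(default_factory=list)

    def __post_init__(self):
        req = {"slide_id", "cross_id", "cy3", "cy5"}
        if not req.issubset(self.frame.columns):
            raise ValueError(f"pairing plan needs columns {sorted(req)}")

    @property
    def individuals(self) -> List[str]:
        return sorted(set(self.frame["cy3"]) | set(self.frame["cy5"]))

    def dye_counts(self) -> pd.DataFrame:
        c3 = self.frame["cy3"].value_counts()
        c5 = self.frame["cy5"].value_counts()
        return pd.DataFrame({"Cy3": c3, "Cy5": c5}).fillna(0).astype(int)

    def to_tsv(self, path) -> None:
        cols = [c for c in ("slide_id", "batch", "person", "block", "cross_id", "cy3", "cy5")
                if c in self.frame.columns]
        self.frame[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PairingPlan":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# genetic distance


def genetic_distance(g_i: pd.Series, g_j: pd.Series) -> float:
    """Mismatch fraction between two genotype-state vectors.

    Loci where either state is missing are excluded from numerator and
    denominator.  Raises if no comparable loci remain.
    """
    a, b = g_i.to_numpy(dtype=object), g_j.to_numpy(dtype=object)
    ok = np.array([x == x and y == y and x is not None and y is not None
                   for x, y in zip(a, b)])
    if not ok.any():
        raise ValueError("zero comparable loci")
    return float((a[ok] != b[ok]).mean())


def state_frame(pop, cross_id: str) -> pd.DataFrame:
    """Genotype states for one cross: combined x_f/x_m strings per marker.

    Columns are the cross's segregating markers; cells are strings such as
    '0/1' ('.' for an uninformative parent side); fully uninformative
    markers are dropped.
    """
    inds = [i for i, c in pop.cross_of.items() if c == cross_id]
    if not inds:
        raise KeyError(f"unknown cross {cross_id!r}")
    f, m = pop.mother_of[inds[0]], pop.father_of[inds[0]]
    xf = pop.transmissions(f).loc[inds]
    xm = pop.transmissions(m).loc[inds]
    seg = pop.heterozygous(f) | pop.heterozygous(m)
    cols = [c for c, s in zip(pop.gmap.marker_ids, seg) if s]

    def fmt(v):
        return "." if not np.isfinite(v) else str(int(v))

    data = {
        c: [f"{fmt(a)}/{fmt(b)}" for a, b in zip(xf[c], xm[c])] for c in cols
    }
    return pd.DataFrame(data, index=inds)


def distance_matrix(pop, cross_id: str) -> pd.DataFrame:
    """Pairwise mismatch-fraction distances within one cross."""
    states = state_frame(pop, cross_id)
    arr = states.to_numpy(dtype=object)
    n = len(states)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = (arr[i] != arr[j]).mean()
    return pd.DataFrame(d, index=states.index, columns=states.index)


# ---------------------------------------------------------------------------
# matching optimizer


def matching_objective(pairs: Sequence[Tuple[str, str]], dist: pd.DataFrame) -> float:
    """Mean genetic distance over the matched pairs."""
    return float(np.mean([dist.at[a, b] for a, b in pairs]))


def _greedy_matching(dist: np.ndarray, order: np.ndarray) -> List[Tuple[int, int]]:
    """Repeatedly match the farthest remaining pair (ties broken by order)."""
    n = dist.shape[0]
    remaining = list(order)
    pairs = []
    while len(remaining) > 1:
        best, bi, bj = -1.0, None, None
        for ii, i in enumerate(remaining):
            for j in remaining[ii + 1:]:
                if dist[i, j] > best:
                    best, bi, bj = dist[i, j], i, j
        pairs.append((bi, bj))
        remaining.remove(bi)
        remaining.remove(bj)
    return pairs


def _two_exchange(pairs: List[Tuple[int, int]], dist: np.ndarray,
                  trace: List[float]) -> List[Tuple[int, int]]:
    """Hill climb on pair swaps until no 2-exchange move improves the total."""
    pairs = [tuple(p) for p in pairs]
    total = sum(dist[a, b] for a, b in pairs)
    trace.append(total)
    improved = True
    while improved:
        improved = False
        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                a, b = pairs[i]
                c, d = pairs[j]
                cur = dist[a, b] + dist[c, d]
                for (p1, p2), (q1, q2) in (((a, c), (b, d)), ((a, d), (b, c))):
                    alt = dist[p1, p2] + dist[q1, q2]
                    if alt > cur + 1e-12:
                        pairs[i], pairs[j] = (p1, p2), (q1, q2)
                        total += alt - cur
                        trace.append(total)
                        cur = alt
                        a, b = pairs[i]
                        c, d = pairs[j]
                        improved = True
    return pairs


def _optimize_single(dist: pd.DataFrame, rng: np.random.Generator,
                     n_restarts: int) -> Tuple[List[Tuple[str, str]], float, List[float]]:
    ids = list(dist.index)
    if len(ids) < 2:
        raise ValueError("need >= 2 individuals in a cross to pair")
    work_ids = list(ids)
    if len(work_ids) % 2 == 1:
        # odd cross size: profile one individual on two slides (dye-balanced
        # downstream); duplicate a random individual as an extra slot
        dup = work_ids[rng.integers(len(work_ids))]
        work_ids = work_ids + [dup]
    n = len(work_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if work_ids[i] != work_ids[j]:
                d[i, j] = dist.at[work_ids[i], work_ids[j]]
    best_pairs, best_obj, best_trace = None, -np.inf, []
    for start in range(max(1, n_restarts)):
        trace: List[float] = []
        if start == 0:
            pairs = _greedy_matching(d, np.arange(n))
        else:
            perm = rng.permutation(n)
            pairs = [(perm[2 * k], perm[2 * k + 1]) for k in range(n // 2)]
        pairs = _two_exchange(pairs, d, trace)
        obj = sum(d[a, b] for a, b in pairs) / len(pairs)
        if obj > best_obj:
            best_obj = obj
            best_pairs = pairs
            best_trace = [t / len(pairs) for t in trace]
    named = [(work_ids[a], work_ids[b]) for a, b in best_pairs]
    return named, best_obj, best_trace


def optimize_pairs(distances: Dict[str, pd.DataFrame], seed=None,
                   n_restarts: int = 10) -> PairingPlan:
    """Best-of-restarts local-optimal matching within each cross.

    ``distances`` maps cross_id -> symmetric distance DataFrame.  Returns a
    plan whose objective is the mean distance over all slides; the
    improvement trace is monotone within each restart.
    """
    rng = as_rng(seed)
    rows = []
    all_dist = []
    trace: List[float] = []
    slide = 0
    for cross_id in sorted(distances):
        pairs, _, tr = _optimize_single(distances[cross_id], rng, n_restarts)
        trace.extend(tr)
        for a, b in pairs:
            slide += 1
            rows.append((f"S{slide:03d}", cross_id, a, b))
            all_dist.append(distances[cross_id].at[a, b])
    frame = pd.DataFrame(rows, columns=["slide_id", "cross_id", "cy3", "cy5"])
    return PairingPlan(frame, objective=float(np.mean(all_dist)), trace=trace)


def _random_matching(ids: List[str], rng: np.random.Generator) -> List[Tuple[str, str]]:
    perm = list(rng.permutation(ids))
    if len(perm) % 2 == 1:
        perm.append(perm[rng.integers(len(perm))])
    return [(perm[2 * k], perm[2 * k + 1]) for k in range(len(perm) // 2)]


def improvement_vs_random(plan: PairingPlan, distances: Dict[str, pd.DataFrame],
                          n_random: int = 200, seed=None) -> float:
    """Percent improvement of the plan's objective over mean random pairing.

    100 * (objective - mean random objective) / mean random objective, where
    random matchings are drawn uniformly within each cross.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if all((d.to_numpy() == 0).all() for d in distances.values()):
        raise ValueError("degenerate distance matrix (all zero)")
    rng = as_rng(seed)
    rand_means = []
    for _ in range(n_random):
        vals = []
        for cross_id, dist in sorted(distances.items()):
            for a, b in _random_matching(list(dist.index), rng):
                vals.append(0.0 if a == b else dist.at[a, b])
        rand_means.append(np.mean(vals))
    mean_random = float(np.mean(rand_means))
    if mean_random == 0:
        raise ValueError("random pairing objective is zero")
    return 100.0 * (plan.objective - mean_random) / mean_random


# ---------------------------------------------------------------------------
# dye / stratum balancing


def assign_dyes(plan: PairingPlan, blocks: Sequence[str] = ("A", "B", "C"),
                batches: Sequence[str] = ("b1", "b2"),
                persons: Sequence[str] = ("p1", "p2", "p3"), seed=None) -> PairingPlan:
    """Assign slides to (block, batch, person) strata and balance dyes.

    Strata are filled round-robin within each cross; within every stratum
    the two slide orientations per cross alternate, so Cy3/Cy5 counts per
    cross differ by at most one.  An individual profiled on two slides gets
    opposite orientations.
    """
    if not blocks or not batches or not persons:
        raise ValueError("infeasible balance: empty stratum dimension")
    rng = as_rng(seed)
    frame = plan.frame.copy().reset_index(drop=True)
    strata = [(bl, ba, pe) for bl in blocks for ba in batches for pe in persons]
    lab = {"block": [], "batch": [], "person": []}
    k = 0
    for _cross, grp in frame.groupby("cross_id", sort=True):
        for _ in grp.index:
            bl, ba, pe = strata[k % len(strata)]
            lab["block"].append(bl)
            lab["batch"].append(ba)
            lab["person"].append(pe)
            k += 1
    for key in lab:
        frame[key] = lab[key]

    # canonicalize each slide (smaller sample id in Cy3), then alternate the
    # orientation within (stratum, cross); finally fix any twice-profiled
    # individual so its two slides use opposite dyes
    flip_state: Dict[Tuple[str, str, str, str], int] = {}
    for idx, row in frame.iterrows():
        a, b = sorted([row["cy3"], row["cy5"]])
        key = (row["block"], row["batch"], row["person"], row["cross_id"])
        n_prev = flip_state.get(key, int(rng.integers(2)))
        frame.loc[idx, ["cy3", "cy5"]] = [b, a] if n_prev % 2 == 1 else [a, b]
        flip_state[key] = n_prev + 1

    counts = frame["cy3"].value_counts().add(frame["cy5"].value_counts(), fill_value=0)
    for ind in counts[counts > 1].index:
        hits = frame.index[(frame["cy3"] == ind) | (frame["cy5"] == ind)]
        want_cy3 = True
        for idx in hits:
            is_cy3 = frame.at[idx, "cy3"] == ind
            if is_cy3 != want_cy3:
                frame.loc[idx, ["cy3", "cy5"]] = [frame.at[idx, "cy5"], frame.at[idx, "cy3"]]
            want_cy3 = not want_cy3
    return PairingPlan(frame, objective=plan.objective, trace=list(plan.trace))


def build_design(pop, seed: int = 0, n_restarts: int = 10,
                 blocks: Sequence[str] = ("A", "B", "C"),
                 batches: Sequence[str] = ("b1", "b2"),
                 persons: Sequence[str] = ("p1", "p2", "p3")) -> PairingPlan:
    """Distance matrices -> optimized pairing -> dye/stratum assignment."""
    crosses = sorted(set(pop.cross_of))
    distances = {c: distance_matrix(pop, c) for c in crosses}
    plan = optimize_pairs(distances, substream(seed, "design:pairs"), n_restarts)
    return assign_dyes(plan, blocks, batches, persons, substream(seed, "design:dyes"))
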