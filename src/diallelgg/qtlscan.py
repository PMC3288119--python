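"""Single-marker LOD mapping in the outbred partial diallel.

At every framework marker the full model

    trait = cross mean + sum_p beta_p * (x_p - 1/2)

is fit by least squares over the parents heterozygous (informative) at that
marker, against the null of cross means only, with

    LOD = (n/2) * log10(RSS0 / RSS1).

``x_p`` is the transmitted-allele indicator of parent ``p`` (0 outside that
parent's progeny), so ``beta_p`` is the allele-substitution effect of the
parent's two haplotypes.  A per-parent LOD from dropping that parent's term
operationalizes "detected in parent p"; a QTL is retained when the overall
LOD reaches the threshold (3.84 by default) and at least one per-parent LOD
does too.  Adjacent significant markers within a support window are merged
to the peak marker, so one broad QTL is counted once.

Ordinal phenotypes are analyzed as numeric class scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "QtlRecord",
    "LOD_THRESHOLD",
    "lod_scan",
    "significant_qtls",
    "classify_cis_trans",
    "classify_eqtls",
    "qtl_table_to_tsv",
    "qtl_table_from_tsv",
]

LOD_THRESHOLD = 3.84
LOD_CAP = 99.0


@dataclass(frozen=True)
class QtlRecord:
    """One (trait, marker) mapping result."""

    trait_id: str
    marker_id: str
    linkage_group: int
    position_cm: float
    lod: float
    effects: Dict[str, float]
    parent_lods: Dict[str, float]
    pve: float
    significant: bool
    detected_in_parents: Tuple[str, ...]


def _rss(X: np.ndarray, Y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid ** 2).sum(axis=0), beta


def _lod_from_rss(rss0: np.ndarray, rss1: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * np.log10(rss0 / rss1)
    lod = np.where(rss1 <= 1e-12 * np.maximum(rss0, 1.0), LOD_CAP, lod)
    lod = np.where(rss0 <= 1e-12, 0.0, lod)
    return np.maximum(np.nan_to_num(lod, nan=0.0), 0.0)


def lod_scan(trait, pop, gmap=None, threshold: float = LOD_THRESHOLD) -> pd.DataFrame:
    """Scan one or many traits at every framework marker.

    ``trait`` is a Series or an individuals x traits DataFrame aligned (or
    alignable) to the population's individuals.  Returns a QtlTable
    DataFrame with one row per (trait, marker) carrying lod, per-parent
    effects and LODs, percent variance explained, and the significance flag.
    Markers with no informative parent are skipped.
    """
    gmap = gmap if gmap is not None else pop.gmap
    if isinstance(trait, pd.Series):
        trait = trait.to_frame(trait.name if trait.name is not None else "trait")
    traits = trait.reindex(pop.individuals)
    if traits.isna().all().any():
        bad = traits.columns[traits.isna().all()]
        raise ValueError(f"all-missing trait(s): {list(bad)[:5]}")

    rows: List[dict] = []
    # group trait columns by missingness pattern so each group is complete
    patterns: Dict[bytes, List[str]] = {}
    for col in traits.columns:
        key = traits[col].notna().to_numpy().tobytes()
        patterns.setdefault(key, []).append(col)
    for key, cols in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        inds = [i for i, m in zip(traits.index, mask) if m]
        if len(inds) < 10:
            raise ValueError("trait defined for <10 genotyped individuals")
        Y = traits.loc[inds, cols].to_numpy(dtype=float)
        rows.extend(_scan_block(Y, cols, inds, pop, gmap, threshold))
    out = pd.DataFrame(rows)
    return out.sort_values(["trait_id", "linkage_group", "position_cm"]).reset_index(drop=True)


def _scan_block(Y, trait_names, inds, pop, gmap, threshold) -> List[dict]:
    n_all = len(inds)
    cross = pop.cross_of.reindex(inds)
    X0_full = pd.get_dummies(cross).to_numpy(dtype=float)
    parents = [p for p in pop.trans]
    # per-parent observable indicators aligned to rows (NaN outside progeny)
    xobs, is_prog = {}, {}
    for p in parents:
        t = pop.transmissions(p)
        xobs[p] = t.reindex(inds).to_numpy(dtype=float)
        is_prog[p] = np.isin(inds, t.index)
    het = {p: pop.heterozygous(p) for p in parents}

    rss0_cache: Dict[bytes, np.ndarray] = {}
    records: List[dict] = []
    mtab = gmap.table.reset_index(drop=True)
    for j in range(gmap.n_markers):
        cols, col_parents, bad = [], [], np.zeros(n_all, dtype=bool)
        for p in parents:
            if not het[p][j]:
                continue
            x = xobs[p][:, j]
            missing = is_prog[p] & ~np.isfinite(x)
            col = np.where(is_prog[p] & np.isfinite(x), x - 0.5, 0.0)
            bad |= missing
            cols.append(col)
            col_parents.append(p)
        if not cols:
            continue
        keep = ~bad
        kcols = []
        kparents = []
        for c, p in zip(cols, col_parents):
            if np.std(c[keep]) > 0:
                kcols.append(c[keep])
                kparents.append(p)
        if not kcols:
            continue
        n = int(keep.sum())
        X0 = X0_full[keep]
        key = keep.tobytes()
        if key not in rss0_cache:
            rss0_cache[key] = _rss(X0, Y[keep])[0]
        rss0 = rss0_cache[key]
        X1 = np.column_stack([X0] + kcols)
        rss1, beta = _rss(X1, Y[keep])
        lod = _lod_from_rss(rss0, rss1, n)
        pve = 100.0 * (1.0 - np.where(rss0 > 0, rss1 / np.maximum(rss0, 1e-300), 1.0))
        pve = np.clip(np.nan_to_num(pve, nan=0.0), 0.0, 100.0)
        k0 = X0.shape[1]
        parent_lods = {}
        for ci, p in enumerate(kparents):
            Xd = np.delete(X1, k0 + ci, axis=1)
            rssd = _rss(Xd, Y[keep])[0]
            parent_lods[p] = _lod_from_rss(rssd, rss1, n)
        lg = int(mtab.at[j, "linkage_group"])
        pos = float(mtab.at[j, "position_cm"])
        marker = mtab.at[j, "marker_id"]
        for ti, tname in enumerate(trait_names):
            plods = {p: float(parent_lods[p][ti]) for p in kparents}
            detected = tuple(p for p, v in plods.items() if v >= threshold)
            records.append(
                dict(
                    trait_id=tname,
                    marker_id=marker,
                    linkage_group=lg,
                    position_cm=pos,
                    lod=float(lod[ti]),
                    effects={p: float(beta[k0 + ci, ti]) for ci, p in enumerate(kparents)},
                    parent_lods=plods,
                    pve=float(pve[ti]),
                    significant=bool(lod[ti] >= threshold),
                    detected_in_parents=detected,
                )
            )
    return records


def significant_qtls(scan: pd.DataFrame, threshold: float = LOD_THRESHOLD,
                     require_any_parent: bool = True,
                     support_cm: float = 10.0) -> pd.DataFrame:
    """Filter to significant QTLs and merge support intervals to peaks.

    Keeps rows with lod >= threshold (inclusive) and, when
    ``require_any_parent``, a non-empty detected-in-parents set.  Each QTL
    carries a support interval of peak +/- ``support_cm``; significant
    markers of one trait on one linkage group whose support intervals
    overlap (distance <= 2 * support_cm) collapse to the peak-LOD marker,
    so one QTL spanning several framework markers -- including markers
    skipped because no parent is informative there -- is counted once.
    """
    if len(scan) == 0:
        raise ValueError("empty scan")
    sig = scan[scan["lod"] >= threshold]
    if require_any_parent:
        sig = sig[sig["detected_in_parents"].map(len) > 0]
    if len(sig) == 0:
        return sig.reset_index(drop=True)
    kept = []
    merge_dist = 2.0 * support_cm
    for (_t, _lg), grp in sig.groupby(["trait_id", "linkage_group"], sort=False):
        grp = grp.sort_values("position_cm")
        pos = grp["position_cm"].to_numpy()
        new_run = np.concatenate([[True], np.diff(pos) > merge_dist])
        run_id = np.cumsum(new_run)
        for _r, run in grp.groupby(run_id):
            kept.append(run.loc[run["lod"].idxmax()])
    out = pd.DataFrame(kept)
    return out.sort_values(["trait_id", "linkage_group", "position_cm"]).reset_index(drop=True)


def classify_cis_trans(qtl, gene_locus_map: Dict[str, Tuple[int, float]],
                       window_cm: float = 10.0) -> str:
    """'cis' when the eQTL lies within the window of the gene's own locus.

    ``qtl`` is a QtlRecord or a QtlTable row; genes without a map position
    classify as 'unknown'.
    """
    trait = qtl.trait_id if hasattr(qtl, "trait_id") else qtl["trait_id"]
    lg = int(qtl.linkage_group if hasattr(qtl, "linkage_group") else qtl["linkage_group"])
    pos = float(qtl.position_cm if hasattr(qtl, "position_cm") else qtl["position_cm"])
    locus = gene_locus_map.get(trait)
    if locus is None:
        return "unknown"
    glg, gpos = locus
    if int(glg) == lg and abs(gpos - pos) <= window_cm:
        return "cis"
    return "trans"


def classify_eqtls(qtls: pd.DataFrame, gene_locus_map, window_cm: float = 10.0
                   ) -> pd.DataFrame:
    out = qtls.copy()
    out["class"] = [classify_cis_trans(row, gene_locus_map, window_cm)
                    for _, row in out.iterrows()]
    return out


# ---------------------------------------------------------------------------
# TSV round trip (Additional-file style layout)


def _fmt_effects(d: Dict[str, float]) -> str:
    return ";".join(f"{p}:{v:.6g}" for p, v in sorted(d.items()))


def _parse_effects(s) -> Dict[str, float]:
    if not isinstance(s, str) or s == "":
        return {}
    return {p: float(v) for p, v in (item.split(":") for item in s.split(";"))}


def qtl_table_to_tsv(qtls: pd.DataFrame, path) -> None:
    out = qtls.copy()
    out["effect"] = out["effects"].map(_fmt_effects)
    out["parent_lod"] = out["parent_lods"].map(_fmt_effects)
    out["parents"] = out["detected_in_parents"].map(lambda t: ",".join(t))
    cols = ["trait_id", "marker_id", "linkage_group", "position_cm", "lod",
            "effect", "parent_lod", "pve", "parents"]
    if "class" in out.columns:
        cols.append("class")
    out[cols].to_csv(path, sep="\t", index=False)


def qtl_table_from_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["effects"] = df["effect"].map(_parse_effects)
    df["parent_lods"] = df["parent_lod"].map(_parse_effects)
    df["detected_in_parents"] = df["parents"].map(
        lambda s: tuple(s.split(",")) if isinstance(s, str) and s else ()
    )
    df["significant"] = df["lod"] >= LOD_THRESHOLD
    return df.drop(columns=["effect", "parent_lod", "parents"])
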