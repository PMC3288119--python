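"""Synthetic diallel populations with planted eQTL/pQTL architectures.

This module generates everything the downstream analysis consumes, with
known ground truth:

* a framework linkage map (13 linkage groups, 252 SNP markers by default);
* a partial diallel of four outbred full-sib families (2 females x 2 males,
  48/36/50/54 progeny by default) with phased parental genotypes and
  per-parent transmitted-allele indicators for every progeny meiosis
  (Haldane map function, no crossover interference);
* raw two-channel microarray intensities built by inverting the
  normalization model (arsinh-scale signal -> sinh -> add subgrid
  background), with planted cis/trans eQTLs, a polygenic background term,
  and additive technical effects for dye, block, batch and person;
* continuous and ordinal phenotypes (tree heights, weevil attack classes,
  oviposition classes and their yearly sums) from a thresholded liability
  model with planted pQTLs.

Every stochastic step draws from a named substream of one global seed, so
all fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import as_rng, substream
from .genmap import haldane_r

__all__ = [
    "GeneticMap",
    "DiallelDesign",
    "PhasedGenotypes",
    "DiallelPopulation",
    "PlantedQtl",
    "ExprTrait",
    "EqtlArchitecture",
    "TechnicalModel",
    "PhenoTrait",
    "PhenoArchitecture",
    "simulate_parents",
    "simulate_cross",
    "simulate_diallel",
    "simulate_expression",
    "simulate_phenotypes",
    "default_map",
    "default_design",
    "default_eqtl_architecture",
    "hotspot_eqtl_architecture",
    "default_pheno_architecture",
    "hotspot_pheno_architecture",
    "RESISTANCE_TRAITS",
    "GROWTH_TRAITS",
    "ALL_TRAITS",
]

ALLELES = ("a", "b", "c", "d")

GROWTH_TRAITS = ("hgt1995", "hgt1997", "hgt1999", "ldr1999")
RESISTANCE_TRAITS = ("atk2000", "atk2001", "sum_atk", "egg2000", "egg2001", "sum_egg")
ALL_TRAITS = GROWTH_TRAITS + RESISTANCE_TRAITS


# ---------------------------------------------------------------------------
# genetic map


@dataclass(frozen=True)
class GeneticMap:
    """Ordered markers with linkage group and cM position.

    The coordinate system for every QTL result in the package.
    """

    table: pd.DataFrame  # columns: marker_id, linkage_group, position_cm

    def __post_init__(self):
        t = self.table
        required = {"marker_id", "linkage_group", "position_cm"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if len(t) == 0:
            raise ValueError("empty genetic map")
        if t["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids")
        if (t["position_cm"] < 0).any():
            raise ValueError("negative cM position")
        for _, grp in t.groupby("linkage_group"):
            if not grp["position_cm"].is_monotonic_increasing:
                raise ValueError("positions must be non-decreasing within a linkage group")

    @property
    def marker_ids(self) -> List[str]:
        return list(self.table["marker_id"])

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def linkage_groups(self) -> List[int]:
        return sorted(self.table["linkage_group"].unique())

    def position_of(self, marker_id: str) -> Tuple[int, float]:
        row = self.table.loc[self.table["marker_id"] == marker_id]
        if row.empty:
            raise KeyError(f"unknown marker {marker_id!r}")
        r = row.iloc[0]
        return int(r["linkage_group"]), float(r["position_cm"])

    def lg_blocks(self):
        """Yield (linkage_group, integer index array into the marker order)."""
        idx = pd.Series(range(self.n_markers))
        for lg, grp in self.table.reset_index(drop=True).groupby("linkage_group", sort=True):
            yield lg, grp.index.to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t"))


def default_map(n_markers: int = 252, n_linkage_groups: int = 13,
                spacing_cm: float = 10.0) -> GeneticMap:
    """Framework map: markers spread over linkage groups at ~10 cM spacing."""
    base, extra = divmod(n_markers, n_linkage_groups)
    rows = []
    for lg in range(1, n_linkage_groups + 1):
        size = base + (1 if lg <= extra else 0)
        for i in range(size):
            rows.append((f"M{lg:02d}_{i + 1:02d}", lg, i * spacing_cm))
    return GeneticMap(pd.DataFrame(rows, columns=["marker_id", "linkage_group", "position_cm"]))


# ---------------------------------------------------------------------------
# diallel design


@dataclass(frozen=True)
class DiallelDesign:
    """Parents and crosses of the partial diallel."""

    females: Tuple[str, ...]
    males: Tuple[str, ...]
    crosses: Tuple[Tuple[str, str, str, int], ...]  # (cross_id, female, male, n_progeny)

    def __post_init__(self):
        ids = [c[0] for c in self.crosses]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cross ids")
        for cid, f, m, n in self.crosses:
            if f not in self.females or m not in self.males:
                raise ValueError(f"cross {cid} references undeclared parent")
            if n < 1:
                raise ValueError(f"cross {cid} must have n_progeny >= 1")

    @property
    def parents(self) -> List[str]:
        return list(self.females) + list(self.males)

    def cross_ids(self) -> List[str]:
        return [c[0] for c in self.crosses]


def default_design() -> DiallelDesign:
    """2 females x 2 males, four crosses with 48/36/50/54 profiled progeny."""
    return DiallelDesign(
        females=("PG87", "PG21"),
        males=("PG165", "PG117"),
        crosses=(
            ("26", "PG87", "PG165", 48),
            ("27", "PG87", "PG117", 36),
            ("29", "PG21", "PG165", 50),
            ("32", "PG21", "PG117", 54),
        ),
    )


# ---------------------------------------------------------------------------
# phased genotypes


@dataclass
class PhasedGenotypes:
    """Phased parents plus progeny transmitted-allele indicators.

    ``parents`` maps parent id -> (2, M) array of allele letters (rows are
    the two haplotypes).  ``trans`` maps parent id -> DataFrame of 0/1
    haplotype-origin indicators (rows: progeny of that parent, columns:
    markers) recording which parental haplotype each meiosis transmitted at
    every marker; these are the simulator's truth.  The *observable*
    indicator x_p is only defined where the parent is heterozygous:
    :meth:`transmissions` masks uninformative markers to NaN.
    """

    gmap: GeneticMap
    parents: Dict[str, np.ndarray]
    trans: Dict[str, pd.DataFrame] = field(default_factory=dict)
    cross_of: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    mother_of: Dict[str, str] = field(default_factory=dict)
    father_of: Dict[str, str] = field(default_factory=dict)

    @property
    def individuals(self) -> List[str]:
        return list(self.cross_of.index)

    def heterozygous(self, parent: str) -> np.ndarray:
        """Boolean mask over markers where ``parent`` is heterozygous."""
        hap = self.parents[parent]
        return hap[0] != hap[1]

    def progeny_of(self, parent: str) -> List[str]:
        return list(self.trans[parent].index) if parent in self.trans else []

    def transmissions(self, parent: str) -> pd.DataFrame:
        """Observable x_p indicators: NaN where the parent is homozygous."""
        t = self.trans[parent].astype(float)
        het = self.heterozygous(parent)
        t.loc[:, ~het] = np.nan
        return t

    def truth_transmissions(self, parent: str) -> pd.DataFrame:
        """Simulator-truth 0/1 indicators at every marker (informative or not)."""
        return self.trans[parent]

    def progeny_alleles(self, ind: str) -> Tuple[np.ndarray, np.ndarray]:
        """(maternal, paternal) allele vectors over markers for one progeny."""
        mo, fa = self.mother_of[ind], self.father_of[ind]
        hm = self.trans[mo].loc[ind].to_numpy()
        hf = self.trans[fa].loc[ind].to_numpy()
        cols = np.arange(self.gmap.n_markers)
        return self.parents[mo][hm, cols], self.parents[fa][hf, cols]

    def n_segregating(self, cross_id: str) -> int:
        """Markers informative in at least one parent of the cross."""
        f, m = None, None
        for ind, cid in self.cross_of.items():
            if cid == cross_id:
                f, m = self.mother_of[ind], self.father_of[ind]
                break
        if f is None:
            raise KeyError(f"unknown cross {cross_id!r}")
        return int((self.heterozygous(f) | self.heterozygous(m)).sum())

    # -- i/o ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Genotype CSV: parent rows phased 'a|b', progeny rows 'x_f/x_m'.

        Missing indicator components (uninformative parent) are '.'; a cell
        with both components missing is 'NA'.
        """
        markers = self.gmap.marker_ids
        rows = {}
        for p, hap in self.parents.items():
            rows[p] = [f"{hap[0, j]}|{hap[1, j]}" for j in range(len(markers))]
        for ind in self.individuals:
            mo, fa = self.mother_of[ind], self.father_of[ind]
            xf = self.transmissions(mo).loc[ind].to_numpy()
            xm = self.transmissions(fa).loc[ind].to_numpy()
            cells = []
            for a, b in zip(xf, xm):
                sa = "." if not np.isfinite(a) else str(int(a))
                sb = "." if not np.isfinite(b) else str(int(b))
                cells.append("NA" if sa == sb == "." else f"{sa}/{sb}")
            rows[ind] = cells
        df = pd.DataFrame.from_dict(rows, orient="index", columns=markers)
        df.index.name = "id"
        meta = pd.DataFrame(
            {
                "cross": [self.cross_of.get(i, "") for i in df.index],
                "mother": [self.mother_of.get(i, "") for i in df.index],
                "father": [self.father_of.get(i, "") for i in df.index],
            },
            index=df.index,
        )
        pd.concat([meta, df], axis=1).to_csv(path)

    @classmethod
    def from_csv(cls, path, gmap: GeneticMap) -> "PhasedGenotypes":
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        markers = gmap.marker_ids
        parents, trans, cross_of, mother_of, father_of = {}, {}, {}, {}, {}
        prog_rows = []
        for ind, row in df.iterrows():
            if row["cross"] == "":  # parent row
                h0, h1 = [], []
                for m in markers:
                    a, b = row[m].split("|")
                    h0.append(a)
                    h1.append(b)
                parents[ind] = np.array([h0, h1])
            else:
                prog_rows.append(ind)
                cross_of[ind] = row["cross"]
                mother_of[ind] = row["mother"]
                father_of[ind] = row["father"]
        for p in parents:
            kids = [i for i in prog_rows if mother_of.get(i) == p or father_of.get(i) == p]
            if not kids:
                continue
            mat = np.zeros((len(kids), len(markers)), dtype=np.int8)
            for r, ind in enumerate(kids):
                which = 0 if mother_of[ind] == p else 1
                for j, m in enumerate(markers):
                    cell = df.at[ind, m]
                    if cell == "NA":
                        continue
                    part = cell.split("/")[which]
                    mat[r, j] = 0 if part == "." else int(part)
            trans[p] = pd.DataFrame(mat, index=kids, columns=markers)
        return cls(
            gmap=gmap,
            parents=parents,
            trans=trans,
            cross_of=pd.Series(cross_of, dtype=object),
            mother_of=mother_of,
            father_of=father_of,
        )


DiallelPopulation = PhasedGenotypes


# ---------------------------------------------------------------------------
# parent and progeny simulation


def simulate_parents(gmap: GeneticMap, parent_ids, het_fraction: float,
                     seed=None) -> PhasedGenotypes:
    """Draw phased parental genotypes, heterozygous at ~het_fraction of markers."""
    if not 0.0 <= het_fraction <= 1.0:
        raise ValueError("het_fraction must be in [0, 1]")
    if gmap.n_markers == 0:
        raise ValueError("empty genetic map")
    if isinstance(parent_ids, int):
        parent_ids = [f"P{i + 1}" for i in range(parent_ids)]
    rng = as_rng(seed)
    M = gmap.n_markers
    parents = {}
    for pid in parent_ids:
        het = rng.random(M) < het_fraction
        hap = np.empty((2, M), dtype="<U1")
        for j in range(M):
            if het[j]:
                a, b = rng.choice(len(ALLELES), size=2, replace=False)
                hap[0, j], hap[1, j] = ALLELES[a], ALLELES[b]
            else:
                a = rng.integers(len(ALLELES))
                hap[0, j] = hap[1, j] = ALLELES[a]
        parents[pid] = hap
    return PhasedGenotypes(gmap=gmap, parents=parents)


def _meioses(gmap: GeneticMap, n: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate n recombinant haplotype-origin vectors (n, M) of 0/1.

    Independent linkage groups; within a group, crossover between adjacent
    markers at distance d cM with probability r = 0.5*(1 - exp(-2d/100)).
    """
    M = gmap.n_markers
    out = np.empty((n, M), dtype=np.int8)
    pos = gmap.table["position_cm"].to_numpy()
    for _, block in gmap.lg_blocks():
        r = haldane_r(np.diff(pos[block]))
        first = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
        if len(block) > 1:
            switches = (rng.random((n, len(block) - 1)) < r).astype(np.int8)
            steps = np.concatenate([first, switches], axis=1)
        else:
            steps = first
        out[:, block] = np.cumsum(steps, axis=1) % 2
    return out


def simulate_cross(parents: PhasedGenotypes, cross, gmap: Optional[GeneticMap] = None,
                   seed=None) -> PhasedGenotypes:
    """Simulate one full-sib family; returns a population holding its progeny."""
    cross_id, female, male, n = cross
    gmap = gmap or parents.gmap
    for p in (female, male):
        if p not in parents.parents:
            raise KeyError(f"unknown parent {p!r}")
    if n < 1:
        raise ValueError("n_progeny must be >= 1")
    rng = as_rng(seed)
    ids = [f"{cross_id}-{i + 1:03d}" for i in range(n)]
    markers = gmap.marker_ids
    tf = pd.DataFrame(_meioses(gmap, n, rng), index=ids, columns=markers)
    tm = pd.DataFrame(_meioses(gmap, n, rng), index=ids, columns=markers)
    pop = PhasedGenotypes(
        gmap=gmap,
        parents=dict(parents.parents),
        trans={female: tf, male: tm},
        cross_of=pd.Series({i: cross_id for i in ids}, dtype=object),
        mother_of={i: female for i in ids},
        father_of={i: male for i in ids},
    )
    return pop


def simulate_diallel(design: DiallelDesign, gmap: GeneticMap, het_fraction: float = 0.28,
                     seed: int = 0, parents: Optional[PhasedGenotypes] = None
                     ) -> DiallelPopulation:
    """Simulate parents plus all crosses of the diallel under one seed.

    A marker segregates in a cross when at least one of its two parents is
    heterozygous there; with independent parents that happens with
    probability 1 - (1 - h)^2.  The default h = 0.28 therefore yields about
    122 of 252 segregating loci per cross, the study-scale average.
    """
    if parents is None:
        parents = simulate_parents(
            gmap, design.parents, het_fraction, substream(seed, "parents")
        )
    trans: Dict[str, List[pd.DataFrame]] = {p: [] for p in design.parents}
    cross_of, mother_of, father_of = {}, {}, {}
    for cross in design.crosses:
        cid, f, m, _n = cross
        sub = simulate_cross(parents, cross, gmap, substream(seed, f"cross:{cid}"))
        trans[f].append(sub.trans[f])
        trans[m].append(sub.trans[m])
        cross_of.update(sub.cross_of.to_dict())
        mother_of.update(sub.mother_of)
        father_of.update(sub.father_of)
    return DiallelPopulation(
        gmap=gmap,
        parents=dict(parents.parents),
        trans={p: pd.concat(frames) for p, frames in trans.items() if frames},
        cross_of=pd.Series(cross_of, dtype=object),
        mother_of=mother_of,
        father_of=father_of,
    )


# ---------------------------------------------------------------------------
# trait architectures


@dataclass(frozen=True)
class PlantedQtl:
    """One planted QTL: marker plus per-parent allele-substitution effects."""

    marker_id: str
    effects: Dict[str, float]  # parent id -> effect of haplotype 1 vs haplotype 0
    cis: bool = False

    def __post_init__(self):
        for p, b in self.effects.items():
            if not np.isfinite(b):
                raise ValueError(f"non-finite effect for parent {p}")


@dataclass(frozen=True)
class ExprTrait:
    trait_id: str
    qtls: Tuple[PlantedQtl, ...] = ()
    gene_locus: Optional[Tuple[int, float]] = None  # (linkage_group, position_cm)
    residual_sd: float = 0.5
    module: Optional[int] = None  # co-expression module membership


@dataclass(frozen=True)
class EqtlArchitecture:
    """Planted eQTL architecture for a panel of expression traits.

    Genes sharing a ``module`` id load on a common latent factor of
    standard deviation ``module_sd`` per individual, emulating pathway
    co-expression; genes with ``module=None`` are conditionally
    independent given their QTLs.
    """

    traits: Tuple[ExprTrait, ...]
    background_sd: float = 0.3  # sd of the polygenic background per trait
    n_background_loci: int = 50
    module_sd: float = 0.5

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for t in self.traits:
            for q in t.qtls:
                for p, b in q.effects.items():
                    rows.append((t.trait_id, q.marker_id, p, b, "eqtl"))
        return pd.DataFrame(rows, columns=["trait_id", "marker_id", "parent", "effect", "kind"])

    def gene_locus_map(self) -> Dict[str, Tuple[int, float]]:
        return {t.trait_id: t.gene_locus for t in self.traits if t.gene_locus is not None}


def _check_sum_zero(name: str, table: Dict[str, float]) -> None:
    if table and abs(sum(table.values())) > 1e-9:
        raise ValueError(f"{name} effects must sum to zero")


@dataclass(frozen=True)
class TechnicalModel:
    """Additive technical-effect model on the arsinh intensity scale.

    h = mu + gene mean + genetic value + dye + block + batch + person + eps.
    Each effect table sums to zero across its levels (identifiability).
    Raw channel intensity is sinh(h) * intensity_scale plus a subgrid
    background, the inverse of the stabilizing transform downstream.
    """

    mu: float = 8.0
    dye: Dict[str, float] = field(default_factory=lambda: {"Cy3": -0.25, "Cy5": 0.25})
    block: Dict[str, float] = field(default_factory=lambda: {"A": -0.2, "B": 0.0, "C": 0.2})
    batch: Dict[str, float] = field(default_factory=lambda: {"b1": -0.15, "b2": 0.15})
    person: Dict[str, float] = field(default_factory=lambda: {"p1": -0.1, "p2": 0.0, "p3": 0.1})
    sigma_eps: float = 0.1
    gene_mean_sd: float = 1.0
    intensity_scale: float = 1.0
    n_subgrids: int = 8
    background_level: float = 40.0

    def __post_init__(self):
        for name in ("dye", "block", "batch", "person"):
            _check_sum_zero(name, getattr(self, name))


@dataclass(frozen=True)
class PhenoTrait:
    """One phenotype: continuous liability or thresholded ordinal classes."""

    name: str
    kind: str  # 'continuous' | 'ordinal'
    qtls: Tuple[PlantedQtl, ...] = ()
    thresholds: Tuple[float, ...] = ()
    mean: float = 0.0
    residual_sd: float = 1.0

    def __post_init__(self):
        if self.kind not in ("continuous", "ordinal"):
            raise ValueError("kind must be 'continuous' or 'ordinal'")
        if self.kind == "ordinal":
            th = np.asarray(self.thresholds, dtype=float)
            if len(th) < 1:
                raise ValueError("ordinal trait needs >= 1 threshold (>= 2 classes)")
            if np.any(np.diff(th) <= 0):
                raise ValueError("thresholds must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.thresholds) + 1 if self.kind == "ordinal" else 0


@dataclass(frozen=True)
class PhenoArchitecture:
    traits: Tuple[PhenoTrait, ...]
    sums: Dict[str, Tuple[str, str]] = field(
        default_factory=lambda: {"sum_atk": ("atk2000", "atk2001"),
                                 "sum_egg": ("egg2000", "egg2001")}
    )
    background_sd: float = 0.3
    n_background_loci: int = 50

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for t in self.traits:
            for q in t.qtls:
                for p, b in q.effects.items():
                    rows.append((t.name, q.marker_id, p, b, "pqtl"))
        return pd.DataFrame(rows, columns=["trait_id", "marker_id", "parent", "effect", "kind"])


# ---------------------------------------------------------------------------
# genetic values


def _qtl_design_column(pop: DiallelPopulation, parent: str, marker: str) -> pd.Series:
    """Centered (x - 0.5) truth indicator for progeny of ``parent``, 0 elsewhere."""
    col = pd.Series(0.0, index=pop.individuals)
    t = pop.truth_transmissions(parent)
    col.loc[t.index] = t[marker].to_numpy() - 0.5
    return col


def genetic_values(pop: DiallelPopulation, qtls: Sequence[PlantedQtl],
                   background_sd: float = 0.0, n_background_loci: int = 50,
                   rng=None) -> pd.Series:
    """Latent genetic value per individual: planted QTLs + polygenic term.

    The polygenic background is a sum of many tiny per-parent effects at
    randomly chosen markers, scaled to have standard deviation roughly
    ``background_sd``; it makes family means differ, so the family term of
    the residualization model is non-trivial.
    """
    marker_set = set(pop.gmap.marker_ids)
    g = pd.Series(0.0, index=pop.individuals)
    for q in qtls:
        if q.marker_id not in marker_set:
            raise KeyError(f"architecture references absent marker {q.marker_id!r}")
        for parent, beta in q.effects.items():
            g += beta * _qtl_design_column(pop, parent, q.marker_id)
    if background_sd > 0 and n_background_loci > 0:
        rng = as_rng(rng)
        markers = pop.gmap.marker_ids
        # each tiny effect has variance beta^2/4 (centered 0/1 indicator)
        beta_sd = 2.0 * background_sd / np.sqrt(n_background_loci * len(pop.parents))
        for parent in pop.parents:
            picks = rng.integers(0, len(markers), size=n_background_loci)
            betas = rng.normal(0.0, beta_sd, size=n_background_loci)
            t = pop.truth_transmissions(parent)
            x = t.to_numpy()[:, picks] - 0.5
            g.loc[t.index] += x @ betas
    return g


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(pop: DiallelPopulation, arch: EqtlArchitecture,
                        tech: TechnicalModel, pairing, seed: int = 0):
    """Simulate raw two-channel intensities for a pairing plan.

    Returns ``(intensities, truth)`` where ``intensities`` is a long table
    with one row per (slide, channel, spot) carrying foreground and
    subgrid background, plus sample/stratum columns, and ``truth`` is a dict
    with the latent genetic value matrix and the planted-eQTL table.
    """
    plan = pairing.frame if hasattr(pairing, "frame") else pairing
    profiled = sorted(set(plan["cy3"]) | set(plan["cy5"]))
    missing = [i for i in profiled if i not in pop.cross_of.index]
    if missing:
        raise KeyError(f"pairing references unknown individuals {missing[:3]}")
    genes = [t.trait_id for t in arch.traits]
    n_genes = len(genes)

    latent = pd.DataFrame(index=pop.individuals, columns=genes, dtype=float)
    rng_g = substream(seed, "expression:genetic")
    rng_e = substream(seed, "expression:noise")
    rng_f = substream(seed, "expression:modules")
    module_ids = sorted({t.module for t in arch.traits if t.module is not None})
    factors = {m: rng_f.normal(0.0, arch.module_sd, size=len(pop.individuals))
               for m in module_ids}
    for t in arch.traits:
        g = genetic_values(pop, t.qtls, arch.background_sd, arch.n_background_loci, rng_g)
        val = g + rng_e.normal(0.0, t.residual_sd, size=len(g))
        if t.module is not None:
            val = val + factors[t.module]
        latent[t.trait_id] = val

    gene_mean = substream(seed, "expression:gene_mean").normal(
        0.0, tech.gene_mean_sd, size=n_genes
    )
    subgrid = np.arange(n_genes) % tech.n_subgrids
    rng_m = substream(seed, "expression:measurement")
    rng_b = substream(seed, "expression:background")

    rows = []
    for _, s in plan.iterrows():
        bg = tech.background_level * (0.5 + rng_b.random(tech.n_subgrids))
        for channel, ind in (("Cy3", s["cy3"]), ("Cy5", s["cy5"])):
            h = (
                tech.mu
                + gene_mean
                + latent.loc[ind].to_numpy()
                + tech.dye[channel]
                + tech.block[s["block"]]
                + tech.batch[s["batch"]]
                + tech.person[s["person"]]
                + rng_m.normal(0.0, tech.sigma_eps, size=n_genes)
            )
            fg = np.sinh(h) * tech.intensity_scale + bg[subgrid]
            for j, gene in enumerate(genes):
                rows.append(
                    (s["slide_id"], channel, int(subgrid[j]), gene, fg[j], bg[subgrid[j]],
                     ind, s["cross_id"], s["block"], s["batch"], s["person"])
                )
    intensities = pd.DataFrame(
        rows,
        columns=["slide", "channel", "subgrid", "spot", "foreground", "background",
                 "individual", "family", "block", "batch", "person"],
    )
    truth = {"latent": latent, "eqtls": arch.truth_table()}
    return intensities, truth


# ---------------------------------------------------------------------------
# phenotype simulation


def simulate_phenotypes(pop: DiallelPopulation, arch: PhenoArchitecture,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate the phenotype table (continuous liabilities, ordinal classes, sums)."""
    rng_g = substream(seed, "phenotype:genetic")
    rng_e = substream(seed, "phenotype:noise")
    out = pd.DataFrame(index=pop.individuals)
    for t in arch.traits:
        g = genetic_values(pop, t.qtls, arch.background_sd, arch.n_background_loci, rng_g)
        liability = t.mean + g + rng_e.normal(0.0, t.residual_sd, size=len(g))
        if t.kind == "continuous":
            out[t.name] = liability
        else:
            out[t.name] = np.searchsorted(np.asarray(t.thresholds), liability)
    for name, (a, b) in arch.sums.items():
        if a in out.columns and b in out.columns:
            out[name] = out[a] + out[b]
    return out


# ---------------------------------------------------------------------------
# default and harness architectures


def _random_effects(parents: Sequence[str], pop_or_none, marker: str,
                    rng, lo: float = 0.4, hi: float = 0.8,
                    n_parents_affected: int = 1) -> Dict[str, float]:
    """Random per-parent effects, restricted to parents informative at the marker."""
    if pop_or_none is not None:
        j = pop_or_none.gmap.marker_ids.index(marker)
        informative = [p for p in parents if pop_or_none.heterozygous(p)[j]]
    else:
        informative = list(parents)
    if not informative:
        informative = list(parents)
    chosen = rng.choice(informative, size=min(n_parents_affected, len(informative)),
                        replace=False)
    return {p: float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])) for p in chosen}


def default_eqtl_architecture(gmap: GeneticMap, pop: Optional[DiallelPopulation] = None,
                              n_genes: int = 428, seed: int = 0,
                              cis_prob: float = 0.4, trans_rate: float = 1.5,
                              residual_sd: float = 0.5) -> EqtlArchitecture:
    """Panel of expression traits with cis/trans eQTLs of detectable size.

    Each gene sits at a random map locus; with probability ``cis_prob`` it
    carries a cis eQTL at its own nearest marker, plus a Poisson(``trans_rate``)
    number of trans eQTLs at uniformly random markers elsewhere.  Half of
    the genes are grouped into co-expression modules of about eight genes
    sharing a latent factor (pathway co-regulation).
    """
    rng = substream(seed, "arch:eqtl")
    markers = gmap.marker_ids
    parents = sorted(pop.parents) if pop is not None else ["PG87", "PG21", "PG165", "PG117"]
    traits = []
    n_module_genes = n_genes // 2
    module_size = 8
    for i in range(n_genes):
        gene_marker = markers[rng.integers(len(markers))]
        lg, pos = gmap.position_of(gene_marker)
        qtls = []
        if rng.random() < cis_prob:
            qtls.append(PlantedQtl(gene_marker, _random_effects(parents, pop, gene_marker, rng),
                                   cis=True))
        for _ in range(rng.poisson(trans_rate)):
            m = markers[rng.integers(len(markers))]
            qtls.append(PlantedQtl(m, _random_effects(parents, pop, m, rng), cis=False))
        module = i // module_size if i < n_module_genes else None
        traits.append(ExprTrait(f"G{i + 1:03d}", tuple(qtls), (lg, pos), residual_sd,
                                module=module))
    return EqtlArchitecture(tuple(traits))


def hotspot_eqtl_architecture(gmap: GeneticMap, pop: Optional[DiallelPopulation] = None,
                              n_genes: int = 428, hotspot_marker: Optional[str] = None,
                              n_hotspot: int = 45, seed: int = 0,
                              effect: float = 0.95, residual_sd: float = 0.75,
                              n_bg_eqtls: int = 3, bg_effect: float = 0.65
                              ) -> Tuple[EqtlArchitecture, str]:
    """Architecture with one planted trans-eQTL hotspot over a uniform background.

    ``n_hotspot`` genes get a trans eQTL at one shared marker; every other
    gene gets ``n_bg_eqtls`` eQTLs at uniformly random markers, so
    per-marker eQTL counts are uniform apart from the planted cluster.  eQTLs are planted
    only at segregating markers (a marker uninformative in every parent
    carries no observable signal), and the hotspot marker is one where at
    least two parents are heterozygous.  Each gene's effect is carried by a
    single parental meiosis, rotating over the parents informative at the
    marker, so the hotspot genes do not all share one causal genotype
    vector (a fully shared vector makes chance finite-sample correlations
    with unlinked markers leak coherently into every gene and can raise
    ghost clusters).  Effect sizes target single-marker LOD scores around
    6-8: strong enough for near-certain detection at the planted marker,
    weak enough that linked markers two map intervals away stay below the
    significance threshold and each gene contributes one eQTL record.
    """
    rng = substream(seed, "arch:hotspot")
    markers = gmap.marker_ids
    parents = sorted(pop.parents) if pop is not None else ["PG87", "PG21", "PG165", "PG117"]
    if pop is not None:
        het = np.column_stack([pop.heterozygous(p) for p in parents])
        # prefer markers segregating in >= 3 parents: the planted effects are
        # spread over more independent meiosis vectors, so no single shared
        # causal vector dominates the hotspot genes
        rich = [m for m, k in zip(markers, het.sum(axis=1)) if k >= 3]
        if not rich:
            rich = [m for m, k in zip(markers, het.sum(axis=1)) if k >= 2]
    else:
        rich = list(markers)
    if hotspot_marker is None:
        hotspot_marker = rich[rng.integers(len(rich))]
    if pop is not None:
        j = markers.index(hotspot_marker)
        hot_parents = [p for p in parents if pop.heterozygous(p)[j]]
    else:
        hot_parents = list(parents)
    traits = []
    for i in range(n_genes):
        gene_marker = markers[rng.integers(len(markers))]
        lg, pos = gmap.position_of(gene_marker)
        if i < n_hotspot:
            m = hotspot_marker
            p = hot_parents[i % len(hot_parents)]
            eff = {p: float(rng.uniform(effect, effect + 0.15) * rng.choice([-1.0, 1.0]))}
            qtls = (PlantedQtl(m, eff, cis=(m == gene_marker)),)
        else:
            # uniform over all framework markers; eQTLs at markers that do
            # not segregate simply go undetected, leaving the detected
            # background uniform
            # background effects are kept moderate so a background eQTL maps
            # to its own marker without raising linked-marker records
            qtls = []
            for _ in range(n_bg_eqtls):
                m = markers[rng.integers(len(markers))]
                eff = _random_effects(parents, pop, m, rng, lo=bg_effect,
                                      hi=bg_effect + 0.15)
                qtls.append(PlantedQtl(m, eff, cis=(m == gene_marker)))
            qtls = tuple(qtls)
        traits.append(ExprTrait(f"G{i + 1:03d}", qtls, (lg, pos), residual_sd))
    return EqtlArchitecture(tuple(traits), background_sd=0.0), hotspot_marker


ATTACK_THRESHOLDS = (-0.4, 0.9)  # 3 classes: no attack / failed attack / top kill
EGG_THRESHOLDS = (-1.2, -0.4, 0.4, 1.2)  # 5 oviposition classes


def default_pheno_architecture(gmap: GeneticMap, pop: Optional[DiallelPopulation] = None,
                               seed: int = 0, n_qtl_per_trait: int = 2,
                               effect: float = 0.8) -> PhenoArchitecture:
    """The ten study phenotypes with a few planted pQTLs each.

    Heights and leader length are continuous; yearly attack is a 3-class
    ordinal trait and yearly oviposition a 5-class ordinal trait on a
    standard-normal-scale liability; sums are derived downstream.
    """
    rng = substream(seed, "arch:pheno")
    markers = gmap.marker_ids
    parents = sorted(pop.parents) if pop is not None else ["PG87", "PG21", "PG165", "PG117"]

    def qtls(n=n_qtl_per_trait):
        out = []
        for _ in range(n):
            m = markers[rng.integers(len(markers))]
            out.append(PlantedQtl(m, _random_effects(parents, pop, m, rng,
                                                     lo=effect, hi=effect + 0.3)))
        return tuple(out)

    traits = [
        PhenoTrait("hgt1995", "continuous", qtls(), mean=30.0, residual_sd=1.0),
        PhenoTrait("hgt1997", "continuous", qtls(), mean=80.0, residual_sd=1.0),
        PhenoTrait("hgt1999", "continuous", qtls(), mean=160.0, residual_sd=1.0),
        PhenoTrait("ldr1999", "continuous", qtls(), mean=40.0, residual_sd=1.0),
        PhenoTrait("atk2000", "ordinal", qtls(), thresholds=ATTACK_THRESHOLDS),
        PhenoTrait("atk2001", "ordinal", qtls(), thresholds=ATTACK_THRESHOLDS),
        PhenoTrait("egg2000", "ordinal", qtls(), thresholds=EGG_THRESHOLDS),
        PhenoTrait("egg2001", "ordinal", qtls(), thresholds=EGG_THRESHOLDS),
    ]
    return PhenoArchitecture(tuple(traits))


def hotspot_pheno_architecture(gmap: GeneticMap, hotspot_marker: str,
                               pop: Optional[DiallelPopulation] = None,
                               seed: int = 0, effect: float = 1.2) -> PhenoArchitecture:
    """Phenotypes with resistance pQTLs co-planted at a hotspot marker.

    Both yearly attack traits and one oviposition trait carry a strong pQTL
    at the hotspot marker, so the derived sums map there too and the
    hotspot classifies as 'resistance'.
    """
    rng = substream(seed, "arch:pheno-hotspot")
    parents = sorted(pop.parents) if pop is not None else ["PG87", "PG21", "PG165", "PG117"]

    def hot_qtl():
        return (PlantedQtl(hotspot_marker,
                           _random_effects(parents, pop, hotspot_marker, rng,
                                           lo=effect, hi=effect + 0.3,
                                           n_parents_affected=2)),)

    traits = [
        PhenoTrait("hgt1995", "continuous", (), mean=30.0, residual_sd=1.0),
        PhenoTrait("hgt1997", "continuous", (), mean=80.0, residual_sd=1.0),
        PhenoTrait("hgt1999", "continuous", (), mean=160.0, residual_sd=1.0),
        PhenoTrait("ldr1999", "continuous", (), mean=40.0, residual_sd=1.0),
        PhenoTrait("atk2000", "ordinal", hot_qtl(), thresholds=ATTACK_THRESHOLDS),
        PhenoTrait("atk2001", "ordinal", hot_qtl(), thresholds=ATTACK_THRESHOLDS),
        PhenoTrait("egg2000", "ordinal", hot_qtl(), thresholds=EGG_THRESHOLDS),
        PhenoTrait("egg2001", "ordinal", (), thresholds=EGG_THRESHOLDS),
    ]
    return PhenoArchitecture(tuple(traits))
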