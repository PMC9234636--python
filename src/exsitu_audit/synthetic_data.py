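"""Synthetic genotype, collection, and geography generators.

Emulates the data structure of a range-wide conservation genetics study of a
two-region shrub oak: ~667 wild diploids in ~36 populations split between a
diverged East and West region, genotyped at 11 microsatellite loci with ~2.6%
missing data; ex situ seedling collections organised as half-sib maternal
families spread over 8 botanic gardens; and occurrence points for every
population scattered over a rectangular ecoregion mosaic.

Population structure is generated hierarchically: ancestral allele
frequencies per locus are Dirichlet-distributed, each region's frequencies
are a Dirichlet draw centred on the ancestral vector with concentration 1/d
(drift magnitude d gives E[F_ST] ~ d/(1+d)), and each population drifts again
from its region.  Ultra-rare alleles are injected as exact single copies so
the singleton/doubleton filtering boundary is exercised deterministically.

All randomness flows from one integer seed through named substreams, so each
stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .ecogeo_coverage import EcoregionLayer, OccurrenceSet
from .genotype_io import MISSING, META_COLUMNS, GenotypeMatrix

# substream tags (arbitrary distinct integers)
_STREAM_FREQS = 1
_STREAM_GENO = 2
_STREAM_MISSING = 3
_STREAM_RARE = 4
_STREAM_EXSITU = 5
_STREAM_GEO = 6


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


@dataclass
class SimulationConfig:
    """Knobs for the wild metapopulation generator.

    ``regional_divergence`` and ``population_divergence`` are Dirichlet drift
    magnitudes d >= 0 (concentration 1/d around the parent frequencies);
    ``n_rare_alleles`` ultra-rare alleles are injected as exact singletons.
    ``individuals_per_population`` may be an int or a per-population list.
    """

    n_regions: int = 2
    populations_per_region: int = 18
    individuals_per_population: "int | list[int]" = 19
    n_loci: int = 11
    alleles_per_locus: int = 22
    regional_divergence: float = 0.05
    population_divergence: float = 0.02
    missing_rate: float = 0.026
    n_rare_alleles: int = 15
    ancestral_concentration: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alleles_per_locus < 2 and (
            self.regional_divergence > 0 or self.population_divergence > 0
        ):
            raise ValueError("divergence needs >= 2 alleles per locus")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")

    @property
    def region_names(self) -> list[str]:
        base = ["East", "West"]
        if self.n_regions <= 2:
            return base[: self.n_regions]
        return base + [f"region_{i}" for i in range(3, self.n_regions + 1)]


@dataclass
class ExSituDesign:
    """Sampling design of the garden collections.

    ``entries`` rows: garden, source_population, n_families, seeds_per_family.
    Seeds of one maternal family are half-sibs: the mother's genotype is
    fixed and each seed's paternal allele is drawn from the source
    population's pooled allele frequencies.
    """

    entries: pd.DataFrame
    germination_rate: float = 1.0

    def __post_init__(self) -> None:
        need = {"garden", "source_population", "n_families", "seeds_per_family"}
        if not need.issubset(self.entries.columns):
            raise ValueError(f"entries need columns {sorted(need)}")
        if not 0 <= self.germination_rate <= 1:
            raise ValueError("germination_rate must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Wild metapopulation
# ---------------------------------------------------------------------------


def _dirichlet_drift(rng, parent: np.ndarray, d: float) -> np.ndarray:
    if d <= 0:
        return parent.copy()
    alpha = np.maximum(parent / d, 1e-9)
    return rng.dirichlet(alpha)


def simulate_metapopulation(cfg: SimulationConfig) -> GenotypeMatrix:
    """Simulate the wild (in situ) cohort under hierarchical drift.

    Region base frequencies drift from an ancestral Dirichlet draw, each
    population drifts from its region, and diploid genotypes are sampled
    under random mating within population.  Missing calls are injected at
    ``cfg.missing_rate`` and ``cfg.n_rare_alleles`` brand-new alleles are
    each planted as one copy in one random individual.
    """
    rng_f = _rng(cfg.seed, _STREAM_FREQS)
    A = cfg.alleles_per_locus
    allele_codes = 100 + 2 * np.arange(A)  # fragment-length-like, 3-digit

    ancestral = [
        rng_f.dirichlet(np.full(A, cfg.ancestral_concentration) + 1e-6)
        for _ in range(cfg.n_loci)
    ]
    pop_freqs: dict[str, list[np.ndarray]] = {}
    pop_region: dict[str, str] = {}
    for region in cfg.region_names:
        region_base = [
            _dirichlet_drift(rng_f, anc, cfg.regional_divergence) for anc in ancestral
        ]
        for p in range(cfg.populations_per_region):
            pop = f"{region[0]}{p + 1:02d}"
            pop_region[pop] = region
            pop_freqs[pop] = [
                _dirichlet_drift(rng_f, rb, cfg.population_divergence)
                for rb in region_base
            ]

    pops = list(pop_freqs)
    if isinstance(cfg.individuals_per_population, int):
        sizes = [cfg.individuals_per_population] * len(pops)
    else:
        sizes = list(cfg.individuals_per_population)
        if len(sizes) != len(pops):
            raise ValueError(
                f"{len(sizes)} population sizes for {len(pops)} populations"
            )

    rng_g = _rng(cfg.seed, _STREAM_GENO)
    individuals: list[str] = []
    meta_pop: list[str] = []
    meta_region: list[str] = []
    blocks = []
    for pop, n in zip(pops, sizes):
        calls = np.empty((n, cfg.n_loci, 2), dtype=np.int64)
        for l in range(cfg.n_loci):
            draws = rng_g.choice(A, size=(n, 2), p=pop_freqs[pop][l])
            calls[:, l, :] = allele_codes[draws]
        blocks.append(calls)
        individuals.extend(f"{pop}_{i + 1:03d}" for i in range(n))
        meta_pop.extend([pop] * n)
        meta_region.extend([pop_region[pop]] * n)
    calls = np.concatenate(blocks, axis=0)

    rng_m = _rng(cfg.seed, _STREAM_MISSING)
    if cfg.missing_rate > 0:
        mask = rng_m.random((calls.shape[0], cfg.n_loci)) < cfg.missing_rate
        calls[mask] = MISSING

    rng_r = _rng(cfg.seed, _STREAM_RARE)
    next_code = int(allele_codes.max()) + 101  # codes disjoint from base set
    for j in range(cfg.n_rare_alleles):
        for _ in range(1000):
            i = rng_r.integers(calls.shape[0])
            l = rng_r.integers(cfg.n_loci)
            if calls[i, l, 0] != MISSING:
                calls[i, l, rng_r.integers(2)] = next_code + 2 * j
                break
        else:  # pragma: no cover - only if nearly everything is missing
            raise RuntimeError("could not place rare allele; too much missing data")

    meta = pd.DataFrame(
        {c: pd.Series([None] * len(individuals), dtype=object) for c in META_COLUMNS},
        index=pd.Index(individuals, name="id"),
    )
    meta["population"] = meta_pop
    meta["region"] = meta_region
    meta["cohort"] = "in_situ"
    return GenotypeMatrix(individuals, [f"loc{l + 1}" for l in range(cfg.n_loci)],
                          calls, meta)


# ---------------------------------------------------------------------------
# Ex situ seedlings (half-sib maternal families)
# ---------------------------------------------------------------------------


def simulate_ex_situ(
    in_situ: GenotypeMatrix, design: ExSituDesign, seed: int = 0
) -> GenotypeMatrix:
    """Simulate garden seedlings from wild mothers under the design.

    Per family: one mother sampled (without replacement within a design row)
    from the source population; each seed inherits one of her two alleles
    uniformly and a paternal allele drawn from the source population's pooled
    frequencies at that locus.  Loci where the mother's call is missing are
    missing in the seed.  Seeds germinate independently with
    ``design.germination_rate``.
    """
    rng = _rng(seed, _STREAM_EXSITU)
    meta_in = in_situ.meta
    # pooled per-population allele frequencies (the pollen cloud)
    pool: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}

    def pop_pool(pop: str):
        if pop not in pool:
            ids = list(meta_in.index[meta_in["population"] == pop])
            sub = in_situ.subset(ids)
            per_locus = []
            for l in range(sub.n_loci):
                codes = sub.calls[:, l, :].ravel()
                codes = codes[codes != MISSING]
                vals, counts = np.unique(codes, return_counts=True)
                per_locus.append((vals, counts / counts.sum()))
            pool[pop] = per_locus
        return pool[pop]

    individuals: list[str] = []
    rows = []
    meta_rows = []
    for entry in design.entries.itertuples():
        pop = entry.source_population
        ids = list(meta_in.index[meta_in["population"] == pop])
        if not ids:
            raise ValueError(f"source population {pop!r} not in the wild cohort")
        if entry.n_families > len(ids):
            raise ValueError(
                f"{entry.n_families} families requested from {pop!r} "
                f"which has only {len(ids)} candidate mothers"
            )
        mothers = rng.choice(len(ids), size=entry.n_families, replace=False)
        region = meta_in.loc[ids[0], "region"]
        per_locus = pop_pool(pop)
        for f_idx, m_idx in enumerate(mothers):
            mother_id = ids[m_idx]
            mother_calls = in_situ.calls[in_situ.individuals.index(mother_id)]
            family = f"{mother_id}_fam"
            for s in range(entry.seeds_per_family):
                if rng.random() > design.germination_rate:
                    continue
                seed_calls = np.zeros((in_situ.n_loci, 2), dtype=np.int64)
                for l in range(in_situ.n_loci):
                    if mother_calls[l, 0] == MISSING and mother_calls[l, 1] == MISSING:
                        continue  # seed inherits a missing call
                    maternal = mother_calls[l, rng.integers(2)]
                    vals, probs = per_locus[l]
                    paternal = rng.choice(vals, p=probs)
                    seed_calls[l] = (maternal, paternal)
                sid = f"{entry.garden}_{mother_id}_s{s + 1}"
                individuals.append(sid)
                rows.append(seed_calls)
                meta_rows.append(
                    {"population": str(entry.garden), "region": region,
                     "cohort": "ex_situ", "garden": str(entry.garden),
                     "maternal_line": family, "source_population": pop}
                )
    if not individuals:
        calls = np.zeros((0, in_situ.n_loci, 2), dtype=np.int64)
    else:
        calls = np.stack(rows)
    meta = pd.DataFrame(meta_rows, index=pd.Index(individuals, name="id"),
                        columns=META_COLUMNS)
    return GenotypeMatrix(individuals, list(in_situ.loci), calls, meta)


def combine(in_situ: GenotypeMatrix, ex_situ: GenotypeMatrix) -> GenotypeMatrix:
    """Stack the wild and garden cohorts into one matrix."""
    if in_situ.loci != ex_situ.loci:
        raise ValueError("cohorts must share loci")
    individuals = in_situ.individuals + ex_situ.individuals
    calls = np.concatenate([in_situ.calls, ex_situ.calls], axis=0)
    meta = pd.concat([in_situ.meta, ex_situ.meta])
    return GenotypeMatrix(individuals, list(in_situ.loci), calls, meta)


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


def simulate_landscape(
    populations: pd.DataFrame,
    sampled_populations: "set[str] | list[str]",
    seed: int = 0,
    extra_per_population: int = 2,
    cluster_sd_deg: float = 0.8,
    grid_shape: tuple[int, int] = (3, 3),
    level4_subdiv: int = 2,
) -> tuple[OccurrenceSet, EcoregionLayer]:
    """Place populations in two disjoint clusters and build an ecoregion grid.

    ``populations`` needs columns population, region.  One occurrence point
    per population plus ``extra_per_population`` scattered wild records;
    populations in ``sampled_populations`` additionally get an
    ``ex_situ_source`` point snapped to the population's locality.  The
    ecoregion layer is a rectangular grid: Level III = coarse cells over the
    bounding box, Level IV = each cell subdivided.
    """
    rng = _rng(seed, _STREAM_GEO)
    centers = {"East": (-99.0, 34.5), "West": (-105.5, 34.0)}
    sampled = set(sampled_populations)

    rows = []
    for rec in populations.drop_duplicates("population").itertuples():
        cx, cy = centers.get(rec.region, (-95.0, 40.0))
        lon = cx + rng.normal(0, cluster_sd_deg)
        lat = cy + rng.normal(0, cluster_sd_deg / 2)
        rows.append({"lon": lon, "lat": lat, "role": "in_situ",
                     "region": rec.region, "population": rec.population})
        for _ in range(extra_per_population):
            rows.append({"lon": lon + rng.normal(0, 0.15),
                         "lat": lat + rng.normal(0, 0.1),
                         "role": "in_situ", "region": rec.region,
                         "population": rec.population})
        if rec.population in sampled:
            rows.append({"lon": lon, "lat": lat, "role": "ex_situ_source",
                         "region": rec.region, "population": rec.population})
    occ = OccurrenceSet(pd.DataFrame(rows))

    pts = occ.points
    margin = 0.5
    x0, x1 = pts["lon"].min() - margin, pts["lon"].max() + margin
    y0, y1 = pts["lat"].min() - margin, pts["lat"].max() + margin
    nr, nc = grid_shape
    dx, dy = (x1 - x0) / nc, (y1 - y0) / nr
    feats = []
    for r in range(nr):
        for c in range(nc):
            l3 = f"L3_{r}{c}"
            sx, sy = dx / level4_subdiv, dy / level4_subdiv
            for rr in range(level4_subdiv):
                for cc in range(level4_subdiv):
                    feats.append({
                        "level3": l3,
                        "level4": f"L4_{r}{c}_{rr}{cc}",
                        "geometry": box(x0 + c * dx + cc * sx,
                                        y0 + r * dy + rr * sy,
                                        x0 + c * dx + (cc + 1) * sx,
                                        y0 + r * dy + (rr + 1) * sy),
                    })
    return occ, EcoregionLayer(pd.DataFrame(feats))


# ---------------------------------------------------------------------------
# Paper-like preset
# ---------------------------------------------------------------------------


def paper_like_config(seed: int = 0) -> SimulationConfig:
    """Study-scale wild cohort: 667 diploids, 36 populations, 11 loci."""
    # 667 = 19 populations of 19 + 17 populations of 18
    sizes = [19] * 19 + [18] * 17
    return SimulationConfig(
        n_regions=2,
        populations_per_region=18,
        individuals_per_population=sizes,
        n_loci=11,
        alleles_per_locus=30,
        ancestral_concentration=0.5,
        regional_divergence=0.05,
        population_divergence=0.03,
        missing_rate=0.026,
        n_rare_alleles=15,
        seed=seed,
    )


def paper_like_design(in_situ: GenotypeMatrix, seed: int = 0) -> ExSituDesign:
    """Garden design at study scale: 8 gardens, 26 source populations,
    66 maternal families, ~290 seedlings, East-weighted sourcing."""
    rng = _rng(seed, _STREAM_EXSITU + 100)
    meta = in_situ.meta
    east_pops = sorted(pd.unique(meta.loc[meta["region"] == "East", "population"]))
    west_pops = sorted(pd.unique(meta.loc[meta["region"] == "West", "population"]))
    src_east = list(rng.choice(east_pops, size=17, replace=False))
    src_west = list(rng.choice(west_pops, size=9, replace=False))
    # unequal garden holdings (real metacollections span an order of
    # magnitude in collection size); weights sum to the 26 source pops
    weights = {"garden_1": 6, "garden_2": 5, "garden_3": 4, "garden_4": 3,
               "garden_5": 3, "garden_6": 2, "garden_7": 2, "garden_8": 1}
    assignment = [g for g, w in weights.items() for _ in range(w)]
    assignment = list(rng.permutation(assignment))
    rows = []
    # East: 48 families of 5 seeds (240); West: 18 families of 3 seeds (54)
    fam_east = [3] * 14 + [2] * 3  # 48 families over 17 populations
    for i, pop in enumerate(src_east):
        rows.append({"garden": assignment[i], "source_population": pop,
                     "n_families": fam_east[i], "seeds_per_family": 5})
    for i, pop in enumerate(src_west):
        rows.append({"garden": assignment[17 + i], "source_population": pop,
                     "n_families": 2, "seeds_per_family": 3})
    return ExSituDesign(entries=pd.DataFrame(rows), germination_rate=1.0)


def paper_like_dataset(seed: int = 0):
    """Full synthetic study: returns (combined GenotypeMatrix, OccurrenceSet,
    EcoregionLayer, ExSituDesign)."""
    cfg = paper_like_config(seed)
    wild = simulate_metapopulation(cfg)
    design = paper_like_design(wild, seed=seed)
    garden = simulate_ex_situ(wild, design, seed=seed)
    gm = combine(wild, garden)
    pops = wild.meta[["population", "region"]].drop_duplicates()
    occ, layer = simulate_landscape(
        pops, set(design.entries["source_population"]), seed=seed,
        grid_shape=(4, 5), level4_subdiv=2,
    )
    return gm, occ, layer, design
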