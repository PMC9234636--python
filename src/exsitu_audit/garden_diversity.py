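"""Per-garden capture, capture-vs-size regressions, and garden-region F_ST.

Each botanic garden's holdings are scored against the pooled wild allele
catalog, summarised with collection-size covariates (plants, maternal
accessions, source populations), and regressed on those covariates under
identity, square-root, and log transforms.  Genetic differentiation between
each garden and the two wild regions is measured with the Weir & Cockerham
(1984) theta estimator of F_ST, combining variance components as a ratio of
sums over alleles and loci (negative single-locus components are retained;
no truncation).  A paired t-test across gardens contrasts the garden-vs-East
and garden-vs-West theta vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .allele_capture import AlleleCatalog, CaptureReport, capture_report
from .genotype_io import MISSING, GenotypeMatrix

TRANSFORMS = {"identity": lambda x: x, "sqrt": np.sqrt, "log": np.log}


@dataclass
class GardenSummary:
    """One garden's holdings: sizes and capture percentages per allele class."""

    garden: str
    n_plants: int
    n_accessions: int
    n_populations: int
    n_populations_east: int
    n_populations_west: int
    capture: CaptureReport


@dataclass
class TransformRegression:
    """OLS of class capture percent on a transformed size predictor."""

    predictor: str
    transform: str
    class_label: str
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    best: bool = False


@dataclass
class FstContrast:
    """Per-garden theta against pooled East and West wild cohorts, paired-t."""

    gardens: list[str]
    fst_vs_east: np.ndarray
    fst_vs_west: np.ndarray
    t_statistic: float
    p_value: float

    @property
    def mean_vs_east(self) -> float:
        return float(np.mean(self.fst_vs_east))

    @property
    def mean_vs_west(self) -> float:
        return float(np.mean(self.fst_vs_west))


# ---------------------------------------------------------------------------
# Garden summaries and regressions
# ---------------------------------------------------------------------------


def garden_summaries(gm: GenotypeMatrix, ref: AlleleCatalog) -> list[GardenSummary]:
    """Capture report plus size covariates for every garden with >=1 plant."""
    ex = gm.select(cohort="ex_situ")
    if ex.n_individuals == 0:
        raise ValueError("no ex situ individuals")
    pop_region = (
        gm.select(cohort="in_situ").meta.groupby("population")["region"].first()
    )
    out = []
    for garden, sub in ex.meta.groupby("garden", sort=True):
        ids = list(sub.index)
        rep = capture_report(ref, gm.subset(ids), scope=str(garden))
        src = sub["source_population"]
        pops = pd.unique(src)
        regions = pop_region.reindex(pops)
        out.append(
            GardenSummary(
                garden=str(garden),
                n_plants=len(ids),
                n_accessions=int(sub["maternal_line"].nunique()),
                n_populations=len(pops),
                n_populations_east=int((regions == "East").sum()),
                n_populations_west=int((regions == "West").sum()),
                capture=rep,
            )
        )
    return out


def fit_transform_regressions(
    summaries: list[GardenSummary],
    predictor: str = "n_plants",
    class_label: str = "all",
) -> list[TransformRegression]:
    """OLS of capture percent on {x, sqrt(x), log(x)}; flags highest adj R^2.

    ``predictor`` is one of n_plants / n_accessions / n_populations.  The
    adjusted R^2 is 1 - (1-R^2)(n-1)/(n-2) for the single-predictor model.
    """
    if len(summaries) < 3:
        raise ValueError("need >= 3 gardens for a regression")
    x = np.array([getattr(s, predictor) for s in summaries], dtype=float)
    y = np.array([s.capture.percent(class_label) for s in summaries])
    results = []
    for name, fn in TRANSFORMS.items():
        if name == "log" and np.any(x <= 0):
            raise ValueError("log transform requires positive predictor values")
        X = sm.add_constant(fn(x))
        fit = sm.OLS(y, X).fit()
        results.append(
            TransformRegression(
                predictor=predictor, transform=name, class_label=class_label,
                slope=float(fit.params[1]), intercept=float(fit.params[0]),
                r_squared=float(fit.rsquared),
                adj_r_squared=float(fit.rsquared_adj),
            )
        )
    best = max(range(len(results)), key=lambda i: results[i].adj_r_squared)
    results[best].best = True
    return results


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------


def _wc84_components(cohorts: list[GenotypeMatrix]) -> tuple[float, float]:
    """Sums of the a and a+b+c variance components over loci and alleles."""
    r = len(cohorts)
    loci = cohorts[0].loci
    sum_a = 0.0
    sum_abc = 0.0
    for l in range(len(loci)):
        calls = [c.calls[:, l, :] for c in cohorts]
        nonmiss = [~np.all(cl == MISSING, axis=1) for cl in calls]
        n = np.array([m.sum() for m in nonmiss], dtype=float)
        if np.any(n < 1):
            continue
        nbar = n.mean()
        if nbar <= 1:
            continue
        n_c = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
        if n_c <= 0:
            continue
        alleles = np.unique(
            np.concatenate([cl[m].ravel() for cl, m in zip(calls, nonmiss)])
        )
        alleles = alleles[alleles != MISSING]
        for al in alleles:
            p = np.empty(r)
            h = np.empty(r)
            for i in range(r):
                sub = calls[i][nonmiss[i]]
                hits = (sub == al).sum(axis=1)
                p[i] = hits.sum() / (2 * n[i])
                h[i] = (hits == 1).mean()
            pbar = (n * p).sum() / (r * nbar)
            s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n * h).sum() / (r * nbar)
            inner = pbar * (1 - pbar) - (r - 1) / r * s2
            a = (nbar / n_c) * (s2 - (inner - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            sum_a += a
            sum_abc += a + b + c
    return sum_a, sum_abc


def pairwise_fst(cohort_a: GenotypeMatrix, cohort_b: GenotypeMatrix) -> float:
    """Multi-locus Weir & Cockerham theta between two cohorts.

    Ratio of summed variance components across loci and alleles; missing
    calls are excluded per locus.  Raises if no locus is polymorphic across
    the pair (the denominator vanishes).
    """
    if cohort_a.n_individuals < 2 or cohort_b.n_individuals < 2:
        raise ValueError("each cohort needs >= 2 individuals")
    if cohort_a.loci != cohort_b.loci:
        raise ValueError("cohorts must share the same loci")
    sum_a, sum_abc = _wc84_components([cohort_a, cohort_b])
    if sum_abc == 0.0:
        raise ValueError("no polymorphic loci shared by the two cohorts")
    return float(sum_a / sum_abc)


def fst_contrast(gm: GenotypeMatrix) -> FstContrast:
    """Theta of each garden against pooled East and West wild cohorts.

    Two-sided paired t-test across gardens on the two theta vectors.
    """
    east = gm.select(cohort="in_situ", region="East")
    west = gm.select(cohort="in_situ", region="West")
    ex = gm.select(cohort="ex_situ")
    gardens = sorted(pd.unique(ex.meta["garden"]))
    if len(gardens) < 2:
        raise ValueError("paired t-test needs >= 2 gardens")
    vs_east, vs_west = [], []
    for g in gardens:
        sub = gm.subset(list(ex.meta.index[ex.meta["garden"] == g]))
        vs_east.append(pairwise_fst(sub, east))
        vs_west.append(pairwise_fst(sub, west))
    vs_east = np.array(vs_east)
    vs_west = np.array(vs_west)
    if np.allclose(vs_west, vs_east):
        t, p = 0.0, 1.0  # zero difference everywhere: no evidence either way
    else:
        t, p = stats.ttest_rel(vs_west, vs_east)
    return FstContrast(
        gardens=[str(g) for g in gardens], fst_vs_east=vs_east,
        fst_vs_west=vs_west, t_statistic=float(t), p_value=float(p),
    )
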