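"""Simulated seed-collection subsampling: allele accumulation curves and
minimum sample sizes.

The sampling model is an idealised range-wide collector who visits wild plants
uniformly at random without replacement and takes one seed or cutting per
plant, so each sampled individual contributes both of its allele copies.  For
each subsample size n the mean percent of reference alleles captured is
estimated over R replicate draws; the smallest n whose mean meets a threshold
(default 95%) is the recommended minimum sample size.

The Monte-Carlo scheme draws one random permutation of the cohort per
replicate and takes its prefixes: the size-n prefix of a uniform permutation
is exactly a uniform without-replacement sample of size n, so every n is
scored in a single pass per replicate, and each replicate's curve is
non-decreasing in n by construction.

An exact companion, :func:`expected_capture_closed_form`, gives the
expectation in closed form: an allele carried by m of N individuals is missed
by a size-n subsample with probability C(N-m, n)/C(N, n).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .allele_capture import CLASS_LABELS, AlleleCatalog
from .genotype_io import GenotypeMatrix


@dataclass
class AccumulationCurve:
    """Mean percent of reference alleles captured per subsample size.

    ``mean_percent`` and ``sd_percent`` are dicts keyed by class label
    (``"all"`` plus any frequency classes present in the reference) holding
    arrays aligned with ``n_values``.  ``sd_percent`` is the across-replicate
    standard deviation, so the Monte-Carlo standard error of a mean is
    ``sd / sqrt(replicates)``.
    """

    n_values: np.ndarray
    mean_percent: dict[str, np.ndarray]
    sd_percent: dict[str, np.ndarray]
    replicates: int
    view: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        data = {"n": self.n_values}
        for label, vals in self.mean_percent.items():
            data[label] = vals
        return pd.DataFrame(data)


@dataclass
class MinimumSampleSize:
    """Smallest n whose mean capture meets the threshold percent."""

    threshold: float
    n_min: int
    scope: str = "overall"
    view: str = "full"
    class_label: str = "all"


@dataclass
class LogRegressionReference:
    """OLS of percent-alleles-conserved on ln(collection size) across taxa."""

    intercept: float
    slope: float
    points: pd.DataFrame

    def predict(self, n) -> np.ndarray:
        return self.intercept + self.slope * np.log(np.asarray(n, dtype=float))

    def residual(self, n: float, percent: float) -> float:
        """Observed minus predicted; negative means below the reference trend."""
        return float(percent - self.predict(n))


# ---------------------------------------------------------------------------


def _carrier_matrix(
    ref: AlleleCatalog, cohort: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean individuals x reference-alleles carrier matrix + class labels.

    carriers[i, j] is True when individual i holds >=1 copy of reference
    allele j (missing calls contribute nothing, but the individual still
    counts toward n when sampled).
    """
    locus_idx = {loc: l for l, loc in enumerate(cohort.loci)}
    n_alleles = len(ref.entries)
    carriers = np.zeros((cohort.n_individuals, n_alleles), dtype=bool)
    for j, (loc, al) in enumerate(zip(ref.entries["locus"], ref.entries["allele"])):
        l = locus_idx[loc]
        carriers[:, j] = np.any(cohort.calls[:, l, :] == al, axis=1)
    labels = ref.entries["class_label"].to_numpy(dtype=object)
    return carriers, labels


def accumulation_curve(
    ref: AlleleCatalog,
    cohort: GenotypeMatrix,
    replicates: int = 75_000,
    seed: int = 0,
    n_values: np.ndarray | None = None,
) -> AccumulationCurve:
    """Monte-Carlo allele accumulation curve over subsample sizes 1..N.

    Each replicate permutes the cohort uniformly and scores the cumulative
    union of carried reference alleles along the permutation, yielding the
    captured percent for every n at once.  Percentages are reported for the
    "all" class and for each frequency class present in the reference.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    carriers, labels = _carrier_matrix(ref, cohort)
    N = cohort.n_individuals
    if n_values is None:
        n_values = np.arange(1, N + 1)
    n_values = np.asarray(n_values, dtype=int)
    if n_values.min() < 1 or n_values.max() > N:
        raise ValueError("n_values must lie in 1..N")

    class_cols: dict[str, np.ndarray] = {"all": np.arange(carriers.shape[1])}
    for label in CLASS_LABELS:
        cols = np.flatnonzero(labels == label)
        if cols.size:
            class_cols[label] = cols
    for label, cols in class_cols.items():
        if cols.size == 0:
            raise ValueError(f"class {label!r} has zero reference alleles")

    rng = np.random.default_rng(seed)
    sums = {label: np.zeros(len(n_values)) for label in class_cols}
    sq_sums = {label: np.zeros(len(n_values)) for label in class_cols}
    prefix_rows = n_values - 1

    for _ in range(replicates):
        perm = rng.permutation(N)
        cum = np.cumsum(carriers[perm].astype(np.int32), axis=0) > 0
        hits = cum[prefix_rows]  # len(n_values) x n_alleles
        for label, cols in class_cols.items():
            pct = 100.0 * hits[:, cols].sum(axis=1) / cols.size
            sums[label] += pct
            sq_sums[label] += pct**2

    mean = {lb: sums[lb] / replicates for lb in class_cols}
    sd = {
        lb: np.sqrt(np.maximum(sq_sums[lb] / replicates - mean[lb] ** 2, 0.0))
        for lb in class_cols
    }
    return AccumulationCurve(
        n_values=n_values, mean_percent=mean, sd_percent=sd,
        replicates=replicates, view=ref.view, seed=seed,
    )


def expected_capture_closed_form(
    carrier_counts: np.ndarray, N: int, n: int
) -> float:
    """Exact expected percent of alleles captured by a uniform size-n subsample.

    ``carrier_counts[a]`` is the number of individuals (of N) carrying >=1
    copy of allele a.  Returns ``100 * mean_a [1 - C(N-m_a, n) / C(N, n)]``.
    """
    m = np.asarray(carrier_counts, dtype=int)
    if np.any(m <= 0):
        raise ValueError("every allele needs at least one carrier")
    if not 0 <= n <= N:
        raise ValueError("n must lie in 0..N")
    denom = comb(N, n)
    probs = [1.0 - comb(N - int(mi), n) / denom if N - int(mi) >= n else 1.0
             for mi in m]
    return 100.0 * float(np.mean(probs))


def carrier_counts(ref: AlleleCatalog, cohort: GenotypeMatrix) -> np.ndarray:
    """Number of cohort individuals carrying each reference allele."""
    carriers, _ = _carrier_matrix(ref, cohort)
    return carriers.sum(axis=0)


def minimum_sample_size(
    curve: AccumulationCurve,
    threshold: float = 95.0,
    class_label: str = "all",
    scope: str = "overall",
) -> MinimumSampleSize:
    """Smallest n whose mean capture percent meets the threshold (>= compare)."""
    if threshold > 100.0:
        raise ValueError("threshold above 100% is unreachable")
    mean = curve.mean_percent[class_label]
    idx = np.flatnonzero(mean >= threshold)
    if idx.size == 0:
        raise ValueError(
            f"threshold {threshold}% never reached (max {mean.max():.2f}%)"
        )
    return MinimumSampleSize(
        threshold=threshold, n_min=int(curve.n_values[idx[0]]),
        scope=scope, view=curve.view, class_label=class_label,
    )


def fit_log_reference(points) -> LogRegressionReference:
    """OLS of percent conserved on ln(ex situ collection size) across taxa.

    ``points`` is an iterable of (n, percent) pairs or a two-column DataFrame.
    Used to situate a focal species against the multi-taxon trend: a negative
    residual means less diversity is conserved than the collection size
    predicts.
    """
    df = pd.DataFrame(points)
    if df.shape[1] != 2:
        raise ValueError("points must have two columns: n, percent")
    df.columns = ["n", "percent"]
    if len(df) < 3:
        raise ValueError("need at least 3 reference points")
    if (df["n"] < 1).any():
        raise ValueError("collection sizes must be >= 1")
    x = np.log(df["n"].to_numpy(dtype=float))
    if np.allclose(x, x[0]):
        raise ValueError("degenerate design: all collection sizes identical")
    X = sm.add_constant(x)
    fit = sm.OLS(df["percent"].to_numpy(dtype=float), X).fit()
    return LogRegressionReference(
        intercept=float(fit.params[0]), slope=float(fit.params[1]), points=df
    )
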