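"""Allele catalogs, frequency classes, and ex situ capture accounting.

The reference catalog pools all wild (in situ) individuals and records, per
locus, each allele's copy count and pooled frequency.  Alleles are binned by
frequency — rare (<1%), low-frequency (1–5%), common (5–10%), very common
(>=10%) — and capture is the presence of each wild (locus, allele) pair at
least once among the ex situ holdings.  A "reduced" view drops alleles seen in
at most two copies in the reference cohort (likely genotyping artefacts or
highly deleterious variants); class labels are assigned on the full data and
kept unchanged in the reduced view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix

#: Frequency-class labels, most to least frequent.
CLASS_LABELS = ["very_common", "common", "low_frequency", "rare"]

_CLASS_ORDER = ["all"] + CLASS_LABELS


@dataclass
class AlleleCatalog:
    """Per-locus allele identities, copy counts, pooled frequencies, classes.

    ``entries`` has columns ``locus, allele, count, freq, class_label``;
    ``reference_n_copies`` maps locus -> number of non-missing gene copies in
    the reference cohort; ``view`` is ``"full"`` or ``"reduced"``.
    """

    entries: pd.DataFrame
    reference_n_copies: dict[str, int]
    view: str = "full"

    @property
    def n_alleles(self) -> int:
        return len(self.entries)

    def allele_set(self) -> set[tuple[str, int]]:
        return set(zip(self.entries["locus"], self.entries["allele"]))

    def of_class(self, label: str) -> pd.DataFrame:
        """Entries of one class; ``"all"`` returns every entry."""
        if label == "all":
            return self.entries
        return self.entries[self.entries["class_label"] == label]


@dataclass
class CaptureReport:
    """Percent of reference alleles present in a target cohort, by class.

    ``counts`` maps each label in ``all, very_common, common, low_frequency,
    rare`` to ``(captured, total)``; ``percent(label)`` is 100*captured/total.
    """

    counts: dict[str, tuple[int, int]]
    scope: str = "overall"
    view: str = "full"
    n_target: int = 0

    def percent(self, label: str = "all") -> float:
        cap, tot = self.counts[label]
        return 100.0 * cap / tot if tot else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in _CLASS_ORDER:
            cap, tot = self.counts.get(label, (0, 0))
            rows.append(
                {"class": label, "captured": cap, "total": tot,
                 "percent": self.percent(label) if tot else np.nan}
            )
        df = pd.DataFrame(rows)
        df.insert(0, "scope", self.scope)
        df.insert(1, "view", self.view)
        df.insert(2, "n_target", self.n_target)
        return df


# ---------------------------------------------------------------------------


def observed_alleles(gm: GenotypeMatrix) -> set[tuple[str, int]]:
    """Set of (locus, allele) pairs seen at least once among non-missing calls."""
    out: set[tuple[str, int]] = set()
    for l, locus in enumerate(gm.loci):
        codes = gm.calls[:, l, :].ravel()
        for a in np.unique(codes[codes != MISSING]):
            out.add((locus, int(a)))
    return out


def build_catalog(gm: GenotypeMatrix) -> AlleleCatalog:
    """Pool a cohort into an allele catalog with copy counts and frequencies.

    Frequencies divide each allele's copy count by the locus's non-missing
    gene-copy count.  A locus with zero non-missing calls in the cohort is an
    error (it cannot anchor a denominator).
    """
    if gm.n_individuals == 0:
        raise ValueError("cohort is empty")
    rows = []
    ref_copies: dict[str, int] = {}
    for l, locus in enumerate(gm.loci):
        codes = gm.calls[:, l, :].ravel()
        codes = codes[codes != MISSING]
        if codes.size == 0:
            raise ValueError(f"locus {locus!r} has zero non-missing calls in cohort")
        ref_copies[locus] = int(codes.size)
        alleles, counts = np.unique(codes, return_counts=True)
        for a, c in zip(alleles, counts):
            rows.append({"locus": locus, "allele": int(a), "count": int(c),
                         "freq": c / codes.size})
    entries = pd.DataFrame(rows)
    entries["class_label"] = pd.NA
    return AlleleCatalog(entries=entries, reference_n_copies=ref_copies, view="full")


def classify_alleles(cat: AlleleCatalog) -> AlleleCatalog:
    """Label each entry by pooled frequency.

    Half-open-from-below bins: rare [0, 0.01), low_frequency [0.01, 0.05),
    common [0.05, 0.10), very_common [0.10, 1].
    """
    f = cat.entries["freq"].to_numpy()
    labels = np.select(
        [f < 0.01, f < 0.05, f < 0.10],
        ["rare", "low_frequency", "common"],
        default="very_common",
    )
    entries = cat.entries.copy()
    entries["class_label"] = labels
    return AlleleCatalog(entries, dict(cat.reference_n_copies), view=cat.view)


def reduce_catalog(cat: AlleleCatalog) -> AlleleCatalog:
    """Drop singleton/doubleton alleles (copy count <= 2 in the reference).

    Frequencies and class labels are *not* recomputed after the drop; the
    reduced view keeps the full-data values so the class structure is
    comparable between views.
    """
    if cat.view != "full":
        raise ValueError("reduce_catalog expects a full-view catalog")
    entries = cat.entries[cat.entries["count"] > 2].reset_index(drop=True)
    return AlleleCatalog(entries, dict(cat.reference_n_copies), view="reduced")


def capture_report(
    ref: AlleleCatalog,
    target: GenotypeMatrix,
    scope: str = "overall",
) -> CaptureReport:
    """Percent of reference alleles present at least once in the target cohort.

    Alleles observed in the target but absent from the reference are ignored:
    the denominator is fixed by the wild catalog.
    """
    if target.n_individuals == 0:
        raise ValueError("target cohort is empty")
    present = observed_alleles(target)
    counts: dict[str, tuple[int, int]] = {}
    for label in _CLASS_ORDER:
        sub = ref.of_class(label)
        total = len(sub)
        captured = sum(
            (loc, al) in present for loc, al in zip(sub["locus"], sub["allele"])
        )
        counts[label] = (captured, total)
    return CaptureReport(counts=counts, scope=scope, view=ref.view,
                         n_target=target.n_individuals)


def regional_catalog(gm: GenotypeMatrix, region: str, view: str = "full") -> AlleleCatalog:
    """Catalog of alleles present in one region's in situ populations.

    Copy counts, frequencies, classes — and the reduced view's <=2-copy drop —
    all derive from the regional in situ pool.
    """
    wild = gm.select(cohort="in_situ", region=region)
    if wild.n_individuals == 0:
        raise ValueError(f"no in situ individuals in region {region!r}")
    cat = classify_alleles(build_catalog(wild))
    if view == "reduced":
        cat = reduce_catalog(cat)
    elif view != "full":
        raise ValueError("view must be 'full' or 'reduced'")
    return cat


def regional_capture(gm: GenotypeMatrix, region: str, view: str = "full") -> CaptureReport:
    """Capture of one region's wild alleles by ex situ seedlings sourced there.

    Reference = alleles in the region's in situ populations; target = ex situ
    individuals whose *source population* lies in that region.
    """
    cat = regional_catalog(gm, region, view=view)
    wild_pops = set(gm.select(cohort="in_situ", region=region).meta["population"])
    ex = gm.select(cohort="ex_situ")
    srcs = ex.meta["source_population"]
    ids = list(srcs.index[srcs.isin(wild_pops)])
    if not ids:
        raise ValueError(f"region {region!r} has no ex situ seedlings")
    return capture_report(cat, gm.subset(ids), scope=region)


def capture_chi_square(
    east: CaptureReport, west: CaptureReport, correction: bool = True
) -> tuple[float, float]:
    """Chi-square contrast of East vs West allele capture.

    Builds the 2x2 table [[captured, not captured]] per region from the "all"
    class and applies Pearson's test, with Yates continuity correction by
    default.  Returns (statistic, two-sided p).  A warning is attached when any
    expected cell count falls below 1.
    """
    ec, et = east.counts["all"]
    wc, wt = west.counts["all"]
    table = np.array([[ec, et - ec], [wc, wt - wc]], dtype=float)
    res = stats.chi2_contingency(table, correction=correction)
    if np.any(res.expected_freq < 1):
        warnings.warn("chi-square expected cell count < 1; p-value unreliable",
                      stacklevel=2)
    return float(res.statistic), float(res.pvalue)
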