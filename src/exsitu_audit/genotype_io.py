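"""Reading, validating, and clone-filtering diploid microsatellite genotypes.

The central container is :class:`GenotypeMatrix`: an individuals x loci table of
unordered diploid allele-code pairs (microsatellite fragment lengths), plus a
per-individual metadata record (population, East/West region, in situ / ex situ
cohort, garden, maternal line, source population).  Genotypes are exchanged in
the GENEPOP text dialect: a title line, locus names, then ``Pop``-delimited
blocks of ``indID , a1a2 a1a2 ...`` lines with fixed-width (2- or 3-digit)
allele codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel allele code for a missing call.  Real allele codes are strictly
#: positive, so 0 is unambiguous.
MISSING = 0

META_COLUMNS = [
    "population",
    "region",
    "cohort",
    "garden",
    "maternal_line",
    "source_population",
]

REGIONS = ("East", "West")
COHORTS = ("in_situ", "ex_situ")


class GenepopParseError(ValueError):
    """Raised when a GENEPOP file violates the dialect."""


@dataclass
class GenotypeMatrix:
    """Diploid multilocus genotypes with per-individual metadata.

    Parameters
    ----------
    individuals : list of str
        Ordered, globally unique individual identifiers.
    loci : list of str
        Ordered locus names.
    calls : ndarray of shape (n_individuals, n_loci, 2), int
        Allele codes; each within-locus pair is stored sorted ascending
        (allele order within a call carries no meaning).  Both slots equal to
        :data:`MISSING` mark a missing call.
    meta : pandas.DataFrame or None
        Indexed by individual ID with columns ``population, region, cohort,
        garden, maternal_line, source_population``.  ``region`` is East/West
        and ``cohort`` is in_situ/ex_situ; garden / maternal_line /
        source_population may be null for wild individuals.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if np.any(self.calls < 0):
            raise ValueError("allele codes must be non-negative")
        # enforce unordered-pair (multiset) storage
        self.calls = np.sort(self.calls, axis=2)
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual IDs must be unique")

    # -- basic views -----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing calls."""
        return np.all(self.calls == MISSING, axis=2)

    def subset(self, ids: "list[str] | np.ndarray") -> "GenotypeMatrix":
        """Return the sub-matrix restricted to ``ids`` (order preserved)."""
        idx = {ind: i for i, ind in enumerate(self.individuals)}
        missing_ids = [i for i in ids if i not in idx]
        if missing_ids:
            raise KeyError(f"unknown individual IDs: {missing_ids[:5]}")
        rows = [idx[i] for i in ids]
        meta = self.meta.loc[list(ids)] if self.meta is not None else None
        return GenotypeMatrix(list(ids), list(self.loci), self.calls[rows], meta)

    def select(self, **conditions) -> "GenotypeMatrix":
        """Subset by metadata equality, e.g. ``select(cohort="in_situ", region="East")``."""
        if self.meta is None:
            raise ValueError("metadata not attached")
        mask = pd.Series(True, index=self.meta.index)
        for col, val in conditions.items():
            mask &= self.meta[col] == val
        return self.subset(list(self.meta.index[mask]))

    def populations(self) -> list[str]:
        if self.meta is None:
            raise ValueError("metadata not attached")
        return list(pd.unique(self.meta["population"]))


@dataclass
class CloneReport:
    """Groups of individuals sharing one complete multilocus genotype.

    ``groups`` partitions the clone-flagged individuals; exactly one
    representative per group is ``retained`` and the rest are ``dropped``.
    """

    groups: list[list[str]]
    retained: list[str]
    dropped: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


# ---------------------------------------------------------------------------
# GENEPOP I/O
# ---------------------------------------------------------------------------


def _is_pop_line(line: str) -> bool:
    return line.strip().lower() == "pop"


def read_genepop(path, missing_code: str = "0000") -> GenotypeMatrix:
    """Parse a GENEPOP file into a :class:`GenotypeMatrix`.

    The per-allele digit width (2 or 3) is auto-detected from token length and
    must be consistent across the whole file.  Tokens equal to ``missing_code``
    become missing calls at both slots.  Population assignment follows the
    ``Pop`` blocks, recorded as ``pop_1, pop_2, ...`` in a metadata skeleton
    (only the ``population`` column is filled; use :func:`attach_metadata` for
    the full record).

    Raises
    ------
    GenepopParseError
        On malformed token lengths (naming the line number), duplicate
        individual IDs, or an empty file (zero loci or zero individuals).
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw:
        raise GenepopParseError("empty file")

    # title line is raw[0]; locus names run until the first Pop line
    loci: list[str] = []
    i = 1
    while i < len(raw) and not _is_pop_line(raw[i]):
        line = raw[i].strip()
        if line:
            loci.extend(name.strip() for name in line.split(",") if name.strip())
        i += 1
    if not loci:
        raise GenepopParseError("zero loci declared before first Pop line")
    if i == len(raw):
        raise GenepopParseError("no Pop line found")

    individuals: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    digits: int | None = None
    pop_idx = 0

    for lineno in range(i, len(raw)):
        line = raw[lineno].strip()
        if not line:
            continue
        if _is_pop_line(line):
            pop_idx += 1
            continue
        if "," not in line:
            raise GenepopParseError(f"line {lineno + 1}: expected 'id , genotypes'")
        ind_id, _, geno = line.partition(",")
        ind_id = ind_id.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"line {lineno + 1}: {len(tokens)} genotype tokens for {len(loci)} loci"
            )
        calls_row: list[tuple[int, int]] = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenepopParseError(
                    f"line {lineno + 1}: malformed genotype token {tok!r}"
                )
            tok_digits = len(tok) // 2
            if digits is None:
                digits = tok_digits
            elif digits != tok_digits:
                raise GenepopParseError(
                    f"line {lineno + 1}: mixed {2 * digits}- and {len(tok)}-character "
                    "tokens; 2- and 3-digit encodings cannot be mixed"
                )
            if tok == missing_code:
                calls_row.append((MISSING, MISSING))
            else:
                a1, a2 = int(tok[:digits]), int(tok[digits:])
                calls_row.append((a1, a2))
        individuals.append(ind_id)
        pops.append(f"pop_{pop_idx}")
        rows.append(calls_row)

    if not individuals:
        raise GenepopParseError("zero individuals")
    dupes = pd.Series(individuals)
    dupes = dupes[dupes.duplicated()].tolist()
    if dupes:
        raise GenepopParseError(f"duplicate individual IDs: {sorted(set(dupes))}")

    meta = pd.DataFrame(
        {col: pd.Series([None] * len(individuals), dtype=object) for col in META_COLUMNS},
        index=pd.Index(individuals, name="id"),
    )
    meta["population"] = pops
    return GenotypeMatrix(individuals, loci, np.array(rows), meta)


def write_genepop(gm: GenotypeMatrix, path, missing_code: str = "0000",
                  title: str = "exsitu-audit export") -> None:
    """Write a GENEPOP file; Pop blocks follow the ``population`` metadata column
    (or one block if no metadata)."""
    digits = len(missing_code) // 2
    max_code = int(gm.calls.max()) if gm.calls.size else 0
    if max_code >= 10 ** digits:
        raise ValueError(
            f"allele code {max_code} does not fit {digits}-digit encoding"
        )

    if gm.meta is not None and gm.meta["population"].notna().any():
        pop_of = gm.meta["population"]
    else:
        pop_of = pd.Series("pop_1", index=gm.individuals)

    lines = [title]
    lines.extend(gm.loci)
    last_pop = None
    for i, ind in enumerate(gm.individuals):
        pop = pop_of[ind]
        if pop != last_pop:
            lines.append("Pop")
            last_pop = pop
        toks = []
        for l in range(gm.n_loci):
            a1, a2 = gm.calls[i, l]
            if a1 == MISSING and a2 == MISSING:
                toks.append(missing_code)
            else:
                toks.append(f"{a1:0{digits}d}{a2:0{digits}d}")
        lines.append(f"{ind} , " + " ".join(toks))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------


def attach_metadata(gm: GenotypeMatrix, table: pd.DataFrame) -> GenotypeMatrix:
    """Join a metadata table (keyed by individual ID) onto the matrix.

    ``table`` needs an ``id`` column (or an index named ``id``) and the columns
    ``population, region, cohort, garden, maternal_line, source_population``.
    Every genotyped individual must appear in the table; extra table rows are
    reported with a warning and ignored.
    """
    if "id" in table.columns:
        table = table.set_index("id")
    missing_cols = [c for c in META_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"metadata table lacks columns: {missing_cols}")

    absent = [i for i in gm.individuals if i not in table.index]
    if absent:
        raise ValueError(f"individuals missing from metadata table: {absent}")
    extra = [i for i in table.index if i not in set(gm.individuals)]
    if extra:
        warnings.warn(f"{len(extra)} metadata rows match no genotyped individual: "
                      f"{extra[:5]}", stacklevel=2)

    meta = table.loc[gm.individuals, META_COLUMNS].copy()
    meta = meta.where(pd.notna(meta), None)
    bad_region = meta.index[~meta["region"].isin(REGIONS)].tolist()
    if bad_region:
        raise ValueError(f"region must be one of {REGIONS}; bad rows: {bad_region[:5]}")
    bad_cohort = meta.index[~meta["cohort"].isin(COHORTS)].tolist()
    if bad_cohort:
        raise ValueError(f"cohort must be one of {COHORTS}; bad rows: {bad_cohort[:5]}")
    ex = meta[meta["cohort"] == "ex_situ"]
    incomplete = ex.index[ex["garden"].isna() | ex["source_population"].isna()].tolist()
    if incomplete:
        raise ValueError(
            f"ex_situ individuals need garden and source_population: {incomplete[:5]}"
        )
    return replace(gm, meta=meta)


def missing_rate(gm: GenotypeMatrix) -> float:
    """Fraction of individual x locus calls that are missing."""
    if gm.n_individuals == 0 or gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    return float(gm.missing_mask().mean())


# ---------------------------------------------------------------------------
# Clones
# ---------------------------------------------------------------------------


def identify_clones(gm: GenotypeMatrix) -> CloneReport:
    """Group individuals with identical complete multilocus genotypes.

    Comparison is within population (clonal spread is local), treats each call
    as an unordered pair, and is strict: an individual with a missing call at
    any locus is never matched.  The first-encountered member of each group is
    retained.
    """
    if gm.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    if gm.meta is not None:
        pop_of = gm.meta["population"]
    else:
        pop_of = pd.Series("pop_1", index=gm.individuals)

    seen: dict[tuple, list[str]] = {}
    order: list[tuple] = []
    any_missing = gm.missing_mask().any(axis=1)
    for i, ind in enumerate(gm.individuals):
        if any_missing[i]:
            continue  # missing data disqualifies clone matching
        key = (pop_of[ind],) + tuple(map(tuple, gm.calls[i]))
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(ind)

    groups = [seen[k] for k in order if len(seen[k]) > 1]
    retained = [g[0] for g in groups]
    dropped = [m for g in groups for m in g[1:]]
    return CloneReport(groups=groups, retained=retained, dropped=dropped)


def drop_clones(gm: GenotypeMatrix, report: CloneReport | None = None) -> GenotypeMatrix:
    """Return the matrix with all but one representative of each clone group."""
    if report is None:
        report = identify_clones(gm)
    dropped = set(report.dropped)
    keep = [i for i in gm.individuals if i not in dropped]
    return gm.subset(keep)
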