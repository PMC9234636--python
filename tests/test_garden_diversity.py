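"""Garden summaries, transform regressions, and Weir-Cockerham theta."""

import numpy as np
import pandas as pd
import pytest

from exsitu_audit.allele_capture import build_catalog, classify_alleles
from exsitu_audit.garden_diversity import (
    fit_transform_regressions,
    fst_contrast,
    garden_summaries,
    pairwise_fst,
)
from exsitu_audit.genotype_io import MISSING

from conftest import make_gm


# ---------------------------------------------------------------------------
# Independent WC84 oracle: plain-loop transcription of the 1984 variance
# components for r populations, organised per genotype count rather than per
# call slot, so it shares no code path with the implementation.
# ---------------------------------------------------------------------------


def wc84_oracle(pop_calls):
    """pop_calls: list (one per population) of (n_ind, n_loci, 2) arrays."""
    r = len(pop_calls)
    num = 0.0
    den = 0.0
    n_loci = pop_calls[0].shape[1]
    for locus in range(n_loci):
        genos = []
        for calls in pop_calls:
            g = [tuple(c) for c in calls[:, locus, :]
                 if not (c[0] == MISSING and c[1] == MISSING)]
            genos.append(g)
        sizes = [len(g) for g in genos]
        if min(sizes) < 1:
            continue
        nbar = sum(sizes) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(s * s for s in sizes) / (r * nbar)) / (r - 1)
        alleles = sorted({a for g in genos for pair in g for a in pair})
        for al in alleles:
            p = []
            h = []
            for g in genos:
                copies = sum(pair.count(al) for pair in g)
                hets = sum(1 for pair in g if pair.count(al) == 1)
                p.append(copies / (2 * len(g)))
                h.append(hets / len(g))
            pbar = sum(s * pi for s, pi in zip(sizes, p)) / (r * nbar)
            s2 = sum(s * (pi - pbar) ** 2 for s, pi in zip(sizes, p)) / ((r - 1) * nbar)
            hbar = sum(s * hi for s, hi in zip(sizes, h)) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


def random_cohort_pair(rng, n_a=8, n_b=10, n_loci=4, n_alleles=5,
                       missing_rate=0.05):
    def draw(n, name):
        calls = {}
        for k in range(n):
            row = []
            for _ in range(n_loci):
                if rng.random() < missing_rate:
                    row.append((MISSING, MISSING))
                else:
                    row.append(tuple(sorted(rng.integers(1, n_alleles + 1, 2))))
            calls[f"{name}{k}"] = row
        return calls
    a = make_gm(draw(n_a, "a"))
    b = make_gm(draw(n_b, "b"))
    return a, b


class TestPairwiseFst:
    def test_agrees_with_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a, b = random_cohort_pair(rng)
            try:
                theta = pairwise_fst(a, b)
            except ValueError:
                continue  # no polymorphic locus in this draw
            oracle = wc84_oracle([a.calls, b.calls])
            assert theta == pytest.approx(oracle, abs=1e-12)

    def test_fixed_differences_give_theta_one(self):
        a = make_gm({f"a{k}": [(1, 1), (3, 3)] for k in range(10)})
        b = make_gm({f"b{k}": [(2, 2), (4, 4)] for k in range(10)})
        assert pairwise_fst(a, b) == pytest.approx(1.0)

    def test_identical_cohorts_near_zero(self):
        rng = np.random.default_rng(1)
        calls = {f"i{k}": [tuple(sorted(rng.integers(1, 5, 2)))
                           for _ in range(6)] for k in range(60)}
        a = make_gm(calls)
        b = make_gm({f"j{k}": v for k, (_, v) in enumerate(calls.items())})
        assert abs(pairwise_fst(a, b)) < 0.02

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        a, b = random_cohort_pair(rng)
        assert pairwise_fst(a, b) == pairwise_fst(b, a)

    def test_invariant_to_allele_relabeling_and_locus_order(self):
        rng = np.random.default_rng(9)
        a, b = random_cohort_pair(rng, missing_rate=0.0)
        theta = pairwise_fst(a, b)
        relabel = {1: 104, 2: 98, 3: 222, 4: 7, 5: 51}

        def remap(gm, flip_loci):
            order = list(reversed(range(gm.n_loci))) if flip_loci else range(gm.n_loci)
            return make_gm({
                ind: [tuple(sorted(relabel[x] for x in gm.calls[i, l]))
                      for l in order]
                for i, ind in enumerate(gm.individuals)
            })
        assert pairwise_fst(remap(a, True), remap(b, True)) == pytest.approx(
            theta, abs=1e-12
        )

    def test_monomorphic_only_rejected(self):
        a = make_gm({"a1": [(1, 1)], "a2": [(1, 1)]})
        b = make_gm({"b1": [(1, 1)], "b2": [(1, 1)]})
        with pytest.raises(ValueError, match="polymorphic"):
            pairwise_fst(a, b)


class TestGardenSummaries:
    def garden_gm(self):
        wild = {
            "w1": [(1, 1)], "w2": [(2, 2)], "w3": [(3, 3)], "w4": [(1, 2)],
        }
        ex = {
            "g1a": [(1, 1)], "g1b": [(2, 2)],   # garden g1 holds {1,2}
            "g2a": [(3, 3)],                    # garden g2 holds {3}
            "g3a": [(1, 3)],                    # garden g3 holds {1,3}
        }
        meta = {}
        for k, g in [("g1a", "g1"), ("g1b", "g1"), ("g2a", "g2"), ("g3a", "g3")]:
            meta[k] = {"cohort": "ex_situ", "garden": g, "maternal_line": f"m_{k}",
                       "source_population": "pop_1"}
        return make_gm({**wild, **ex}, meta=meta)

    def test_hand_counted_set_intersections(self):
        gm = self.garden_gm()
        cat = classify_alleles(build_catalog(gm.select(cohort="in_situ")))
        summaries = {s.garden: s for s in garden_summaries(gm, cat)}
        # wild alleles {1,2,3}
        assert summaries["g1"].capture.counts["all"] == (2, 3)
        assert summaries["g2"].capture.counts["all"] == (1, 3)
        assert summaries["g3"].capture.counts["all"] == (2, 3)
        assert summaries["g1"].n_plants == 2
        assert summaries["g1"].n_accessions == 2
        assert summaries["g1"].n_populations == 1

    def test_pooled_capture_at_least_each_garden(self):
        gm = self.garden_gm()
        cat = classify_alleles(build_catalog(gm.select(cohort="in_situ")))
        from exsitu_audit.allele_capture import capture_report
        pooled = capture_report(cat, gm.select(cohort="ex_situ"))
        for s in garden_summaries(gm, cat):
            for lb in pooled.counts:
                assert pooled.counts[lb][0] >= s.capture.counts[lb][0]

    def test_single_garden_holding_everything_is_100(self):
        wild = {"w1": [(1, 2)], "w2": [(3, 3)]}
        ex = {"x1": [(1, 2)], "x2": [(3, 3)]}
        meta = {k: {"cohort": "ex_situ", "garden": "g", "maternal_line": "m",
                    "source_population": "pop_1"} for k in ex}
        gm = make_gm({**wild, **ex}, meta=meta)
        cat = classify_alleles(build_catalog(gm.select(cohort="in_situ")))
        (s,) = garden_summaries(gm, cat)
        assert s.capture.percent("all") == 100.0


class TestTransformRegressions:
    def make_summaries(self, x, y):
        from exsitu_audit.allele_capture import CaptureReport
        from exsitu_audit.garden_diversity import GardenSummary
        out = []
        for i, (xi, yi) in enumerate(zip(x, y)):
            rep = CaptureReport(counts={"all": (int(round(yi)), 100)})
            out.append(GardenSummary(garden=f"g{i}", n_plants=int(xi),
                                     n_accessions=1, n_populations=1,
                                     n_populations_east=1, n_populations_west=0,
                                     capture=rep))
        return out

    def test_exact_sqrt_relationship_wins(self):
        x = np.array([1, 4, 9, 16, 25])
        y = 10 + 5 * np.sqrt(x)
        res = fit_transform_regressions(self.make_summaries(x, y))
        by = {r.transform: r for r in res}
        assert by["sqrt"].adj_r_squared == pytest.approx(1.0)
        assert by["sqrt"].best
        assert by["sqrt"].slope == pytest.approx(5.0)

    def test_four_point_normal_equations(self):
        x = np.array([2.0, 5.0, 11.0, 17.0])
        y = np.array([20.0, 45.0, 60.0, 90.0])
        n, sx, sxx, sy, sxy = 4, x.sum(), (x**2).sum(), y.sum(), (x * y).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
        intercept = (sy - slope * sx) / n
        res = fit_transform_regressions(self.make_summaries(x, y))
        lin = next(r for r in res if r.transform == "identity")
        assert lin.slope == pytest.approx(slope)
        assert lin.intercept == pytest.approx(intercept)
        # hand-checked adjusted R^2: 1 - (1-R2)(n-1)/(n-2)
        yhat = intercept + slope * x
        r2 = 1 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert lin.adj_r_squared == pytest.approx(1 - (1 - r2) * 3 / 2)

    def test_log_with_nonpositive_predictor_rejected(self):
        res = self.make_summaries([0, 2, 3], [10, 20, 30])
        with pytest.raises(ValueError, match="log"):
            fit_transform_regressions(res)

    def test_fewer_than_three_gardens_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_transform_regressions(self.make_summaries([1, 2], [10, 20]))


class TestFstContrast:
    def test_three_garden_paired_t_matches_hand_arithmetic(self):
        # Build wild East/West plus three gardens with distinct compositions
        rng = np.random.default_rng(0)

        def pop(name, freq_hi, n=15):
            return {f"{name}{k}": [tuple(sorted(
                rng.choice([1, 2], size=2, p=[freq_hi, 1 - freq_hi])))
                for _ in range(3)] for k in range(n)}

        wild_e = pop("e", 0.9)
        wild_w = pop("w", 0.3)
        g1 = pop("x", 0.85, n=6)
        g2 = pop("y", 0.6, n=6)
        g3 = pop("z", 0.4, n=6)
        meta = {k: {"region": "West", "population": "pw"} for k in wild_w}
        for grp, g in [(g1, "g1"), (g2, "g2"), (g3, "g3")]:
            for k in grp:
                meta[k] = {"cohort": "ex_situ", "garden": g, "maternal_line": k,
                           "source_population": "pop_1"}
        gm = make_gm({**wild_e, **wild_w, **g1, **g2, **g3}, meta=meta)
        con = fst_contrast(gm)

        d = con.fst_vs_west - con.fst_vs_east
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert con.t_statistic == pytest.approx(t_hand)
        east = gm.select(cohort="in_situ", region="East")
        g1_gm = gm.subset([k for k in g1])
        assert con.fst_vs_east[con.gardens.index("g1")] == pytest.approx(
            pairwise_fst(g1_gm, east)
        )

    def test_identical_vectors_give_t0_p1(self):
        # East and West wild cohorts share one genotype multiset, so every
        # garden's theta-vs-East equals its theta-vs-West exactly
        rng = np.random.default_rng(3)
        wild_base = [[tuple(sorted(rng.integers(1, 4, 2)))] for _ in range(20)]
        wild_e = {f"e{k}": wild_base[k] for k in range(20)}
        wild_w = {f"w{k}": wild_base[k] for k in range(20)}
        g1 = {f"x{k}": [tuple(sorted(rng.integers(1, 4, 2)))] for k in range(8)}
        g2 = {f"y{k}": [tuple(sorted(rng.integers(1, 4, 2)))] for k in range(8)}
        meta = {k: {"region": "West", "population": "pw"} for k in wild_w}
        for grp, g in [(g1, "g1"), (g2, "g2")]:
            for k in grp:
                meta[k] = {"cohort": "ex_situ", "garden": g, "maternal_line": k,
                           "source_population": "pop_1"}
        gm = make_gm({**wild_e, **wild_w, **g1, **g2}, meta=meta)
        con = fst_contrast(gm)
        assert con.t_statistic == 0.0
        assert con.p_value == 1.0

    def test_single_garden_rejected(self):
        wild = {"e1": [(1, 2)], "e2": [(1, 1)], "w1": [(2, 2)], "w2": [(1, 2)]}
        ex = {"x1": [(1, 1)], "x2": [(1, 2)]}
        meta = {k: {"region": "West", "population": "pw"} for k in ("w1", "w2")}
        for k in ex:
            meta[k] = {"cohort": "ex_situ", "garden": "g1", "maternal_line": k,
                       "source_population": "pop_1"}
        gm = make_gm({**wild, **ex}, meta=meta)
        with pytest.raises(ValueError, match="2 gardens"):
            fst_contrast(gm)
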