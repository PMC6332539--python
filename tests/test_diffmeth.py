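"""M-values, variance filter, probe clustering, bump hunting, classification."""

import numpy as np
import pandas as pd
import pytest

from lncstrat.annotation import GeneModel
from lncstrat.diffmeth import (BumpHunter, annotate_dmrs, beta_to_m, bumphunt,
                               classify_dmrs, cluster_probes,
                               filter_variant_quartile)


def clustered_manifest(n_clusters=41, per=5, gap=300, between=100_000):
    rows = []
    for c in range(n_clusters):
        base = between * c + 1000
        for j in range(per):
            rows.append((f"cg{c:03d}{j}", "chrS", base + gap * j))
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])


def null_m(man, n, sd, seed):
    r = np.random.default_rng(seed)
    return pd.DataFrame(r.normal(0.0, sd, (len(man), n)),
                        index=man["probe_id"].tolist(),
                        columns=[f"s{i}" for i in range(n)])


class TestBetaToM:
    @pytest.mark.parametrize("beta,expected", [
        (0.5, 0.0),
        (0.8, 2.0),
        (1.0, np.log2(0.999 / 0.001)),
        (0.0, -np.log2(0.999 / 0.001)),
    ])
    def test_closed_form_with_clamping(self, beta, expected):
        assert beta_to_m(beta) == pytest.approx(expected, abs=1e-9)


class TestVariantQuartileFilter:
    def test_keeps_top_quartile_by_variance(self, rng):
        vals = np.array([rng.normal(0, np.sqrt(v), 10) for v in range(1, 9)])
        M = pd.DataFrame(vals, index=[f"p{i}" for i in range(8)])
        ranked = M.var(axis=1, ddof=1).sort_values(ascending=False)
        kept = filter_variant_quartile(M)
        assert len(kept) == 2  # ceil(8/4)
        assert set(kept.index) == set(ranked.index[:2])

    def test_size_exact_under_ties(self):
        M = pd.DataFrame(np.tile([0.0, 1.0], (9, 5)), index=[f"p{i}" for i in range(9)])
        kept = filter_variant_quartile(M)
        assert len(kept) == 3  # ceil(9/4), ties broken by row order
        assert list(kept.index) == ["p0", "p1", "p2"]

    def test_constant_matrix_warns_and_keeps_first(self):
        M = pd.DataFrame(np.ones((8, 6)), index=[f"p{i}" for i in range(8)])
        with pytest.warns(UserWarning, match="zero variance"):
            kept = filter_variant_quartile(M)
        assert list(kept.index) == ["p0", "p1"]


class TestClusterProbes:
    def test_gap_examples(self):
        man = pd.DataFrame({"probe_id": ["a", "b", "c"], "chrom": ["c1"] * 3,
                            "pos": [100, 500, 1200]})
        assert cluster_probes(man, maxgap=500) == [["a", "b"], ["c"]]

    def test_all_singletons_when_gaps_large(self):
        man = pd.DataFrame({"probe_id": list("abc"), "chrom": ["c1"] * 3,
                            "pos": [100, 1000, 2000]})
        assert cluster_probes(man, maxgap=500) == [["a"], ["b"], ["c"]]

    def test_matches_bruteforce_on_random_manifests(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            pos = np.sort(rng.integers(1, 50_000, n))
            chrom = rng.choice(["c1", "c2"], n)
            man = pd.DataFrame({"probe_id": [f"p{i}" for i in range(n)],
                                "chrom": chrom, "pos": pos})
            got = cluster_probes(man, maxgap=700)
            # brute force: scan sorted probes, break on chrom change or gap
            df = man.sort_values(["chrom", "pos"], kind="stable")
            expected, cur = [], []
            last = None
            for pid, ch, p in df.itertuples(index=False):
                if cur and ch == last[0] and p - last[1] <= 700:
                    cur.append(pid)
                else:
                    if cur:
                        expected.append(cur)
                    cur = [pid]
                last = (ch, p)
            expected.append(cur)
            assert got == expected


class TestBumphunt:
    def test_planted_region_detected_with_high_overlap(self):
        man = clustered_manifest()
        M = null_m(man, 20, 0.5, seed=42)
        grp = np.zeros(20, bool)
        grp[:10] = True
        planted = [f"cg{20:03d}{j}" for j in range(5)]
        M.loc[planted, M.columns[grp]] += 1.5
        regions, _ = bumphunt(M, grp, man, B=200, seed=1)
        sig = [r for r in regions if r.p_perm <= 0.05]
        assert len(sig) == 1
        got = set(sig[0].probe_ids)
        jac = len(got & set(planted)) / len(got | set(planted))
        assert jac >= 0.6

    def test_pvalue_monotone_in_effect_size(self):
        man = clustered_manifest()
        base = null_m(man, 20, 0.5, seed=7)
        grp = np.zeros(20, bool)
        grp[:10] = True
        planted = [f"cg{10:03d}{j}" for j in range(5)]
        pvals = []
        for shift in (0.5, 1.0, 1.5, 2.5):
            M = base.copy()
            M.loc[planted, M.columns[grp]] += shift
            regions, _ = bumphunt(M, grp, man, B=100, seed=3)
            overlapping = [r.p_perm for r in regions
                           if set(r.probe_ids) & set(planted)]
            pvals.append(min(overlapping) if overlapping else 1.0)
        assert all(a >= b - 1e-12 for a, b in zip(pvals, pvals[1:]))

    def test_label_swap_negates_coefficients(self):
        man = clustered_manifest(n_clusters=10)
        M = null_m(man, 12, 0.5, seed=9)
        grp = np.zeros(12, bool)
        grp[:6] = True
        M.loc[M.index[:5], M.columns[grp]] += 1.5
        r1, _ = bumphunt(M, grp, man, B=0, seed=0)
        with pytest.warns(UserWarning):
            r2, _ = bumphunt(M, ~grp, man, B=0, seed=0)
        v1 = {tuple(r.probe_ids): r.value for r in r1}
        v2 = {tuple(r.probe_ids): r.value for r in r2}
        assert set(v1) == set(v2)
        for k in v1:
            assert v1[k] == pytest.approx(-v2[k], abs=1e-12)

    def test_b_zero_returns_na_with_warning(self):
        man = clustered_manifest(n_clusters=5)
        M = null_m(man, 10, 0.5, seed=2)
        grp = np.repeat([True, False], 5)
        with pytest.warns(UserWarning, match="B=0"):
            regions, _ = bumphunt(M, grp, man, B=0)
        assert all(np.isnan(r.p_perm) for r in regions)

    def test_small_group_rejected(self):
        man = clustered_manifest(n_clusters=3)
        M = null_m(man, 5, 0.5, seed=2)
        grp = np.array([True, False, False, False, False])
        with pytest.raises(ValueError, match="2 samples"):
            bumphunt(M, grp, man, B=10)


class TestClassifyDmrs:
    def _region(self, probe_ids, p):
        from lncstrat.diffmeth import DMRegion

        return DMRegion("chrS", 1, 2, probe_ids, value=0.0, area=1.0, p_perm=p)

    def _beta(self, diff):
        # 4 probes x 6 samples; first 3 samples are the subtype
        base = np.full((4, 6), 0.4)
        base[:, :3] += diff
        return pd.DataFrame(base, index=list("abcd"),
                            columns=[f"s{i}" for i in range(6)])

    @pytest.mark.parametrize("diff,p,expected", [
        (0.25, 0.01, "hyper"),
        (-0.05, 0.01, "hypo"),
        (0.10, 0.01, "unclassified"),
        (0.0, 0.01, "hypo"),     # boundary: Methods-style <= 0
        (0.25, 0.2, "ns"),
    ])
    def test_direction_thresholds(self, diff, p, expected):
        grp = np.repeat([True, False], 3)
        regions = classify_dmrs([self._region(list("abcd"), p)], self._beta(diff), grp)
        assert regions[0].direction == expected
        assert regions[0].beta_diff == pytest.approx(diff, abs=1e-12)

    def test_label_swap_negates_beta_diff(self):
        grp = np.repeat([True, False], 3)
        r1 = classify_dmrs([self._region(list("abcd"), 0.01)], self._beta(0.3), grp)
        r2 = classify_dmrs([self._region(list("abcd"), 0.01)], self._beta(0.3), ~grp)
        assert r1[0].beta_diff == pytest.approx(-r2[0].beta_diff, abs=1e-12)


class TestAnnotateDmrs:
    def test_promoter_and_body_assignment(self):
        from lncstrat.diffmeth import DMRegion

        lnc = GeneModel("L1", "chrS", "+", 10_000, 30_000, ((10_000, 30_000),),
                        "lncRNA")
        pc = GeneModel("P1", "chrS", "+", 200_000, 210_000,
                       ((200_000, 210_000),), "protein_coding")
        prom = DMRegion("chrS", 9_000, 9_400, ["a"], 0.0, 1.0)
        body = DMRegion("chrS", 19_000, 19_400, ["b"], 0.0, 1.0)
        ig = DMRegion("chrS", 100_000, 100_400, ["c"], 0.0, 1.0)
        pc_body = DMRegion("chrS", 205_000, 205_200, ["d"], 0.0, 1.0)
        annotate_dmrs([prom, body, ig, pc_body], [lnc, pc])
        assert (prom.category, prom.gene_id, prom.is_lnc) == ("promoter-TSS", "L1", True)
        assert body.category == "exon" and body.is_lnc
        assert ig.category == "intergenic" and not ig.is_lnc
        assert pc_body.gene_id == "P1" and not pc_body.is_lnc


class TestBumpHunterModel:
    def test_end_to_end_recovers_planted_dmrs(self, demo_setup):
        spec, cohort = demo_setup["spec"], demo_setup["cohort"]
        bundle = demo_setup["bundle"]
        for g, kind, st, shift, n in spec.planted_dmrs:
            if abs(shift) < 0.25 or n < 4:
                continue
            pids = set(cohort.truth["planted_dmr_probes"][f"{g}:{kind}:{st}"])
            hits = [r for r in bundle["dmr"][st].significant()
                    if pids & set(r.probe_ids)]
            assert hits, f"planted DMR {g} ({st}) not recovered"
            want = "hyper" if shift > 0 else "hypo"
            assert any(r.direction == want for r in hits)

    def test_summary_reports_counts(self, demo_setup):
        s = demo_setup["bundle"]["dmr"]["DUX4"].summary()
        assert "candidate regions" in s and "permutations" in s
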