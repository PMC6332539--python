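"""Synthetic cohort generator: planted truth, determinism, invariants."""

import dataclasses
import hashlib
import json

import numpy as np
import pytest
from scipy import stats

from lncstrat.diffexp import logcpm
from lncstrat.synthetic import (TruthSpec, fpkm_from_counts, make_annotation,
                                simulate_cohort, write_annotation, write_cohort)


def small_spec(**kw):
    base = dict(n_patients=8, paired_fraction=1.0,
                subtype_labels=(("A", 4), ("B", 4)), n_lnc=15, n_pc=30, seed=5)
    base.update(kw)
    return TruthSpec(**base)


class TestTruthSpec:
    def test_json_roundtrip_lossless(self):
        spec = small_spec(planted_subtype_de=(("LNC0001", "A", 2.0),),
                          planted_dmrs=(("LNC0002", "promoter", "A", 0.3, 5),),
                          planted_epi_coupled=(("LNC0002", -1, 1.0),),
                          planted_pathways=(("PW", ("PC0001", "PC0002")),))
        assert TruthSpec.from_json(spec.to_json()) == spec

    def test_subtype_counts_must_sum(self):
        with pytest.raises(ValueError, match="sum"):
            small_spec(n_patients=9)

    def test_positive_counts_required(self):
        with pytest.raises(ValueError):
            TruthSpec(n_patients=0, subtype_labels=())


class TestMakeAnnotation:
    def test_every_lnc_has_cis_and_trans_partner(self):
        from lncstrat.annotation import assign_neighbors

        ann = make_annotation(small_spec())
        pcs = [g for g in ann.genes if g.biotype == "protein_coding"]
        for lnc in (g for g in ann.genes if g.biotype == "lncRNA"):
            cis, trans = assign_neighbors(lnc, pcs)
            assert cis, lnc.gene_id
            assert trans, lnc.gene_id

    def test_gene_count_and_disjoint_spans(self):
        spec = small_spec(n_lnc=50, n_pc=100)
        ann = make_annotation(spec)
        assert len(ann.genes) == 150
        spans = sorted((g.start, g.end) for g in ann.genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_probes_tile_promoter_body_intergenic(self):
        ann = make_annotation(small_spec())
        by_id = {g.gene_id: g for g in ann.genes}
        for (gid, kind), pids in ann.probe_regions.items():
            g = by_id[gid]
            pos = ann.probes.set_index("probe_id").loc[pids, "pos"]
            if kind == "promoter":
                assert (abs(pos - g.tss) <= 2000).all()
            elif kind == "body":
                assert ((pos > g.start) & (pos < g.end)).all()
            else:
                assert ((pos > g.end + 2000) | (pos < g.start - 2000)).all()

    def test_no_planted_pathways_still_emits_random_sets(self):
        ann = make_annotation(small_spec())
        assert len(ann.gene_sets) == small_spec().n_random_sets
        assert all(name.startswith("RANDSET") for name in ann.gene_sets)

    def test_segmentation_covers_chromosome_with_required_states(self):
        ann = make_annotation(small_spec())
        states = {s for _c, _s, _e, s in ann.chrom_states}
        assert {"Enhancer", "Insulator"} <= states
        assert ann.chrom_states[0][1] == 1
        assert ann.chrom_states[-1][2] == ann.chrom_length
        for (_, _, e1, _), (_, s2, _, _) in zip(ann.chrom_states, ann.chrom_states[1:]):
            assert s2 == e1 + 1

    def test_layout_sizing_errors(self):
        with pytest.raises(ValueError, match="infeasible"):
            make_annotation(small_spec(locus_span=50_000))
        with pytest.raises(ValueError, match="infeasible"):
            make_annotation(small_spec(n_lnc=31, n_pc=30,
                                       subtype_labels=(("A", 4), ("B", 4))))


def _hash_dir(d):
    out = {}
    for p in sorted(d.iterdir()):
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


class TestSimulateCohort:
    def test_fpkm_identity(self):
        spec = small_spec()
        cohort = simulate_cohort(spec, make_annotation(spec))
        recomputed = fpkm_from_counts(cohort.counts, cohort.gene_lengths)
        assert np.allclose(recomputed.to_numpy(), cohort.fpkm.to_numpy(), atol=1e-9)

    def test_betas_open_interval_and_manifest_order(self):
        spec = small_spec()
        ann = make_annotation(spec)
        cohort = simulate_cohort(spec, ann)
        b = cohort.beta.to_numpy()
        assert (b > 0).all() and (b < 1).all()
        assert list(cohort.beta.index) == ann.probes["probe_id"].tolist()

    def test_paired_fraction_one_gives_two_samples_per_patient(self):
        spec = small_spec(paired_fraction=1.0)
        cohort = simulate_cohort(spec, make_annotation(spec))
        per_patient = cohort.samples.groupby("patient_id")["timepoint"].agg(list)
        assert all(sorted(v) == ["ID", "REL"] for v in per_patient)

    def test_unpaired_patients_contribute_one_sample(self):
        spec = small_spec(paired_fraction=0.5)
        cohort = simulate_cohort(spec, make_annotation(spec))
        counts = cohort.samples.groupby("patient_id").size()
        assert set(counts) == {1, 2}
        assert (counts == 2).sum() == 4  # round(0.5 * 4) paired per subtype

    def test_seed_determinism_and_divergence(self, tmp_path):
        spec = small_spec()
        ann = make_annotation(spec)
        c1 = simulate_cohort(spec, ann)
        c2 = simulate_cohort(spec, ann)
        assert c1.counts.equals(c2.counts) and c1.beta.equals(c2.beta)
        spec3 = dataclasses.replace(spec, seed=spec.seed + 1)
        c3 = simulate_cohort(spec3, make_annotation(spec3))
        assert not c1.counts.equals(c3.counts)
        assert not c1.beta.equals(c3.beta)

    def test_outputs_byte_identical_across_runs(self, tmp_path):
        spec = small_spec()
        for sub in ("r1", "r2"):
            ann = make_annotation(spec)
            cohort = simulate_cohort(spec, ann)
            write_annotation(ann, tmp_path / sub)
            write_cohort(cohort, tmp_path / sub)
        assert _hash_dir(tmp_path / "r1") == _hash_dir(tmp_path / "r2")

    def test_planted_subtype_effect_recovered_in_fpkm(self):
        # plant on a protein-coding gene (higher baseline, FPKM > 0)
        spec = TruthSpec(n_patients=20, paired_fraction=1.0,
                         subtype_labels=(("S", 10), ("R", 10)), n_lnc=15, n_pc=30,
                         planted_subtype_de=(("PC0005", "S", 2.0),), seed=9)
        cohort = simulate_cohort(spec, make_annotation(spec))
        in_s = (cohort.samples.set_index("sample_id")["subtype"] == "S")
        lf = np.log2(cohort.fpkm.loc["PC0005"] + 1e-6)
        diff = lf[in_s[lf.index]].mean() - lf[~in_s[lf.index]].mean()
        assert abs(diff - 2.0) < 0.5

    def test_null_cohort_tstat_pvalues_uniform(self):
        spec = TruthSpec(n_patients=20, paired_fraction=0.0,
                         subtype_labels=(("A", 10), ("B", 10)),
                         n_lnc=1000, n_pc=1000, patient_sd=0.0, seed=17)
        cohort = simulate_cohort(spec, make_annotation(spec))
        y = logcpm(cohort.counts).to_numpy()
        in_a = (cohort.samples["subtype"] == "A").to_numpy()
        p = stats.ttest_ind(y[:, in_a], y[:, ~in_a], axis=1).pvalue
        assert stats.kstest(p, "uniform").statistic < 0.1

    def test_intra_patient_correlation_tracks_patient_sd(self):
        def paired_corr(patient_sd):
            spec = small_spec(n_lnc=150, n_pc=150, patient_sd=patient_sd, seed=23)
            cohort = simulate_cohort(spec, make_annotation(spec))
            y = logcpm(cohort.counts)
            s = cohort.samples
            id_cols = s.loc[s["timepoint"] == "ID"].sort_values("patient_id")["sample_id"]
            rel_cols = s.loc[s["timepoint"] == "REL"].sort_values("patient_id")["sample_id"]
            a = y[id_cols].to_numpy()
            b = y[rel_cols].to_numpy()
            a = a - a.mean(axis=1, keepdims=True)
            b = b - b.mean(axis=1, keepdims=True)
            num = (a * b).sum(axis=1)
            den = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
            return float(np.nanmean(num / den))

        assert paired_corr(1.0) > 0.3
        assert abs(paired_corr(0.0)) < 0.1

    def test_missing_planted_id_named_in_error(self):
        spec = small_spec(planted_subtype_de=(("LNC9999", "A", 2.0),))
        with pytest.raises(ValueError, match="LNC9999"):
            simulate_cohort(spec, make_annotation(small_spec()))

    def test_truth_record_roundtrips_through_json(self, tmp_path):
        spec = small_spec(planted_dmrs=(("LNC0001", "promoter", "A", 0.3, 5),))
        cohort = simulate_cohort(spec, make_annotation(spec))
        write_cohort(cohort, tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth == json.loads(json.dumps(cohort.truth))
        assert TruthSpec(**truth["spec"]) == spec
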