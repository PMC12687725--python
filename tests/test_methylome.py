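import numpy as np
import pandas as pd
import pytest

from oomethkit import synthetic_data as synth
from oomethkit.core_io import GenomicInterval
from oomethkit.methylome import (
    DilutionModel,
    MethCallTable,
    classical_mds,
    cluster_cgi_methylomes,
    merge_genotype,
    methylation_levels,
    passive_dilution,
    qc_libraries,
    tile_mds,
)


def _calls(rows, total_reads=int(2e7), name="lib"):
    return MethCallTable(
        pd.DataFrame(rows, columns=["chrom", "pos", "context", "methylated", "total"]),
        total_reads=total_reads,
        name=name,
    )


class TestLevels:
    def test_pooled_ratio(self):
        t = _calls([("chr1", 1, "CpG", 2, 4), ("chr1", 2, "CpG", 1, 2),
                    ("chr1", 3, "CpG", 3, 4)])
        out = methylation_levels(t, [GenomicInterval("chr1", 0, 10, id="r")])
        assert out["r"] == pytest.approx(60.0)

    def test_uncovered_region_is_na(self):
        t = _calls([("chr1", 1, "CpG", 0, 0)])
        out = methylation_levels(t, [GenomicInterval("chr1", 0, 10, id="r")])
        assert np.isnan(out["r"])

    def test_non_cpg_context_ignored(self):
        t = _calls([("chr1", 1, "CpG", 0, 4), ("chr1", 2, "CHH", 4, 4)])
        out = methylation_levels(t, [GenomicInterval("chr1", 0, 10, id="r")])
        assert out["r"] == 0.0


class TestQC:
    @staticmethod
    def _sim_lib(truth, conversion_failure, depth, seed, name=None):
        spec = synth.LibrarySpec(conversion_failure=conversion_failure, depth=depth,
                                 coverage=15, seed=seed)
        lib = synth.simulate_wgbs(truth, spec, n_cpg_per_region=4, n_chh_sites=1500)
        if name:
            lib.name = name
        return lib

    def test_conversion_and_size_thresholds(self, truth_pair):
        ctrl, _ = truth_pair
        libs = [
            self._sim_lib(ctrl, 0.08, 2e7, 1, "badconv"),
            self._sim_lib(ctrl, 0.03, 2e7, 2, "ok"),
            self._sim_lib(ctrl, 0.005, 5e6, 3, "small"),
        ]
        report = qc_libraries(libs)
        assert not report.loc["badconv", "pass"]
        assert "non-CpG" in report.loc["badconv", "reasons"]
        assert report.loc["ok", "pass"]
        assert not report.loc["small", "pass"]
        assert "library size" in report.loc["small", "reasons"]

    def test_boundary_exactly_1e7_reads_fails(self, truth_pair):
        ctrl, _ = truth_pair
        lib = self._sim_lib(ctrl, 0.005, 1e7, 4, "edge")
        report = qc_libraries([lib])
        assert not report.loc["edge", "pass"]

    def test_qc_depends_only_on_stated_statistics(self, truth_pair):
        """Metamorphic: renaming a library must not change its verdict."""
        ctrl, _ = truth_pair
        lib = self._sim_lib(ctrl, 0.03, 2e7, 5, "a")
        v1 = qc_libraries([lib])["pass"].iloc[0]
        lib.name = "renamed"
        v2 = qc_libraries([lib])["pass"].iloc[0]
        assert v1 == v2


class TestMds:
    def test_isosceles_triangle_distances_reproduced(self):
        # points (0,0), (4,0), (2,3): 2-embeddable, distances hand-computable
        pts = np.array([[0.0, 0], [4, 0], [2, 3]])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, strain = classical_mds(d, 2)
        d2 = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, d, atol=1e-8)
        assert strain < 1e-8

    def test_duplicate_libraries_coincide(self, truth_pair):
        ctrl, _ = truth_pair
        spec = synth.LibrarySpec(coverage=15, seed=6)
        a = synth.simulate_wgbs(ctrl, spec, 4, 500)
        b = synth.simulate_wgbs(ctrl, spec, 4, 500)
        b.name = "dup"
        c = synth.simulate_wgbs(ctrl, synth.LibrarySpec(coverage=15, seed=7), 4, 500)
        c.name = "other"
        emb, _ = tile_mds([a, b, c], n_tiles=500, seed=0)
        dist = emb.attrs["distances"]
        assert dist.loc[a.name, "dup"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_outlier_flagged(self, annotation, truth_pair):
        ctrl, _ = truth_pair
        libs = [
            synth.simulate_wgbs(ctrl, synth.LibrarySpec(coverage=15, seed=s), 4, 500)
            for s in (10, 11, 12, 13)
        ]
        for i, lib in enumerate(libs):
            lib.name = f"rep{i}"
        # outlier: an unrelated random methylome (flat 80%)
        params = synth.EffectParams(beta0=0.8, beta_k36me2=0, beta_k36me3=0,
                                    beta_k4me3=0, noise_sd=0)
        odd_truth = synth.simulate_truth(annotation, "ctrl", params, seed=3)
        odd = synth.simulate_wgbs(odd_truth, synth.LibrarySpec(coverage=15, seed=14),
                                  4, 500)
        odd.name = "outlier"
        emb, flags = tile_mds(libs + [odd], n_tiles=500, seed=0,
                              genotypes=["ctrl"] * 5)
        assert flags["outlier"]
        assert not any(flags[f"rep{i}"] for i in range(4))


class TestMerge:
    def test_sitewise_count_addition(self):
        a = _calls([("chr1", 1, "CpG", 2, 4)])
        b = _calls([("chr1", 1, "CpG", 1, 6)])
        m = merge_genotype([a, b])
        row = m.calls.iloc[0]
        assert (row["methylated"], row["total"]) == (3, 10)

    def test_single_library_identity(self):
        a = _calls([("chr1", 1, "CpG", 2, 4), ("chr1", 5, "CHH", 0, 3)])
        m = merge_genotype([a])
        got = m.calls.sort_values("pos").reset_index(drop=True)
        want = a.calls.sort_values("pos").reset_index(drop=True)
        pd.testing.assert_frame_equal(
            got[["chrom", "pos", "context", "methylated", "total"]],
            want[["chrom", "pos", "context", "methylated", "total"]],
        )

    def test_merged_level_is_count_weighted_mean(self, truth_pair):
        ctrl, _ = truth_pair
        libs = [
            synth.simulate_wgbs(ctrl, synth.LibrarySpec(coverage=10, seed=s), 4, 100)
            for s in (20, 21, 22)
        ]
        merged = merge_genotype(libs)
        tot_m = sum(l.calls.query("context=='CpG'")["methylated"].sum() for l in libs)
        tot_t = sum(l.calls.query("context=='CpG'")["total"].sum() for l in libs)
        cpg = merged.calls.query("context=='CpG'")
        assert cpg["methylated"].sum() == tot_m
        assert cpg["total"].sum() == tot_t


class TestCgiClustering:
    def test_three_planted_methylome_classes_fully_recovered(self):
        rng = np.random.default_rng(0)
        levels = []
        truth = []
        for mean, n in ((0.0, 40), (50.0, 40), (95.0, 40)):
            levels.append(np.clip(rng.normal(mean, 2.0, size=(n, 2)), 0, 100))
            truth += [mean] * n
        df = pd.DataFrame(np.vstack(levels), columns=["ctrl", "mut"])
        labels = cluster_cgi_methylomes(df, k=3, seed=1)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == 1.0

    def test_labels_ordered_by_first_condition_methylation(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "c1": np.concatenate([rng.normal(90, 1, 20), rng.normal(5, 1, 20)]),
            "c2": rng.normal(50, 1, 40),
        })
        labels = cluster_cgi_methylomes(df, k=2, seed=0)
        assert (labels.iloc[:20] == 0).all()  # most methylated in c1 first

    def test_k1_single_cluster(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert set(cluster_cgi_methylomes(df, k=1)) == {0}

    def test_na_rows_excluded(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3, 4], "b": [1.0, 2, 3, 4]})
        labels = cluster_cgi_methylomes(df, k=2)
        assert 1 not in labels.index

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(0, 100, size=(60, 3)))
        l1 = cluster_cgi_methylomes(df, k=4, seed=7)
        l2 = cluster_cgi_methylomes(df, k=4, seed=7)
        pd.testing.assert_series_equal(l1, l2)


class TestPassiveDilution:
    def test_two_halvings_fourfold(self):
        m, fold = passive_dilution(DilutionModel(0.8, 2, 0.0, False))
        assert m == pytest.approx(0.2) and fold == pytest.approx(4.0)

    def test_post_replication_eightfold(self):
        m, fold = passive_dilution(DilutionModel(0.8, 2, 0.0, True))
        assert m == pytest.approx(0.1) and fold == pytest.approx(8.0)

    def test_full_maintenance_conserves(self):
        m, fold = passive_dilution(DilutionModel(0.8, 2, 1.0, False))
        assert m == pytest.approx(0.8) and fold == pytest.approx(1.0)

    def test_monotone_in_maintenance(self):
        vals = [passive_dilution(DilutionModel(0.5, 3, p, False))[0]
                for p in np.linspace(0, 1, 11)]
        assert all(a <= b + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_semigroup_property(self):
        direct, _ = passive_dilution(DilutionModel(0.7, 5, 0.4, False))
        step1, _ = passive_dilution(DilutionModel(0.7, 2, 0.4, False))
        step2, _ = passive_dilution(DilutionModel(step1, 3, 0.4, False))
        assert step2 == pytest.approx(direct)

    def test_zero_final_reports_infinite_fold(self):
        m, fold = passive_dilution(DilutionModel(0.0, 2, 0.0, False))
        assert m == 0.0 and fold == np.inf

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DilutionModel(1.5, 2, 0.0)
        with pytest.raises(ValueError):
            DilutionModel(0.5, 2, -0.1)
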