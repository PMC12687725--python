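import numpy as np
import pandas as pd
import pytest

from oomethkit import synthetic_data as synth
from oomethkit.cgi_model import trinuc_freq
from oomethkit.core_io import make_windows


class TestAnnotation:
    def test_seeded_determinism(self):
        a = synth.simulate_annotation(n_genes=20, n_cgis=25, n_tiles=4, seed=1)
        b = synth.simulate_annotation(n_genes=20, n_cgis=25, n_tiles=4, seed=1)
        assert [(g.chrom, g.start, g.end, g.strand) for g in a.genes] == [
            (g.chrom, g.start, g.end, g.strand) for g in b.genes
        ]
        assert [c.sequence for c in a.cgis] == [c.sequence for c in b.cgis]

    def test_zero_trinuc_spectrum_gives_motif_free_sequences(self):
        ann = synth.simulate_annotation(n_genes=5, n_cgis=15, n_tiles=2,
                                        trinuc_spectrum=(0.0, 0.0), seed=2)
        for c in ann.cgis:
            assert "CCG" not in c.sequence and "CGG" not in c.sequence

    def test_nonzero_spectrum_lands_near_target(self):
        ann = synth.simulate_annotation(n_genes=5, n_cgis=30, n_tiles=2,
                                        trinuc_spectrum=(3.0, 3.0), seed=4)
        densities = [trinuc_freq(c.sequence) for c in ann.cgis]
        assert 2.0 < np.mean(densities) < 4.0

    def test_tiles_cut_into_20_bins(self):
        ann = synth.simulate_annotation(n_genes=5, n_cgis=5, n_tiles=10, seed=1)
        bins = make_windows(ann, "tiles", tile_width=500)
        assert len(bins) == 10 * 20

    def test_genes_do_not_overlap(self, annotation):
        auto = sorted(
            [(g.start, g.end) for g in annotation.genes if g.chrom == "chr1"]
        )
        for (s1, e1), (s2, e2) in zip(auto, auto[1:]):
            assert e1 <= s2

    def test_cgi_sequences_match_widths(self, annotation):
        for c in annotation.cgis:
            assert len(c.sequence) == c.width


class TestTruth:
    def test_ctrl_prc1_cgis_unmethylated(self, truth_pair):
        ctrl, _ = truth_pair
        cgis = ctrl.regions.query("kind == 'cgi' and cluster_label == 'PRC1-CGI'")
        assert cgis["meth_frac"].mean() < 0.05

    def test_double_mutant_loses_h2ak119u1(self, truth_pair):
        ctrl, mut = truth_pair
        assert (mut.regions["h2ak119u1"] <= 0.05 * ctrl.regions["h2ak119u1"] + 1e-9).all()

    def test_mutant_gains_k36me2_only_where_permissive(self, truth_pair):
        ctrl, mut = truth_pair
        gain = mut.regions["h3k36me2"] - ctrl.regions["h3k36me2"]
        perm = ctrl.regions["permissive"]
        assert (gain[~perm].abs() < 1e-9).all()
        prc1_perm = perm & (ctrl.regions["h2ak119u1"] > 3)
        assert (gain[prc1_perm] > 1.0).all()

    def test_ols_on_noise_free_truth_recovers_planted_betas(self, annotation):
        params = synth.EffectParams(noise_sd=0.0)
        truth = synth.simulate_truth(annotation, "ctrl", params, seed=3)
        reg = truth.regions[~truth.regions["clamped"]]
        x = reg[["h3k36me2", "h3k36me3", "h3k4me3"]].to_numpy() / params.mark_scale
        a = np.column_stack([np.ones(len(reg)), x])
        beta = np.linalg.lstsq(a, reg["meth_frac"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(
            beta, [params.beta0, *params.betas], atol=1e-10
        )

    def test_truths_share_baseline_across_genotypes(self, truth_pair):
        ctrl, mut = truth_pair
        pd.testing.assert_series_equal(
            ctrl.regions["h3k4me3"], mut.regions["h3k4me3"]
        )

    def test_unknown_genotype_rejected(self, annotation):
        with pytest.raises(ValueError, match="genotype"):
            synth.simulate_truth(annotation, "nonsense")


class TestCounts:
    def test_pure_background_counts_track_window_width(self, truth_pair):
        ctrl, _ = truth_pair
        from oomethkit.core_io import GenomicInterval

        windows = [
            GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), id=rid)
            for rid, r in ctrl.regions.iterrows()
        ]
        spec = synth.LibrarySpec(depth=2e6, background_rate=1.0, seed=5)
        t = synth.simulate_cutrun_counts(ctrl, windows, "h3k36me2", spec)
        widths = np.array([w.width for w in windows], dtype=float)
        expected = 2e6 * widths / widths.sum()
        obs = t.counts.iloc[:, 0].to_numpy()
        # Poisson: all counts within 5 SD of the width-proportional mean
        assert (np.abs(obs - expected) < 5 * np.sqrt(expected) + 5).all()

    def test_depth_ratio_preserved_in_raw_counts(self, truth_pair):
        """A 3x depth difference shows up as a ~3x raw count ratio (the
        distortion the stable-gene normalization must undo)."""
        ctrl, _ = truth_pair
        from oomethkit.core_io import GenomicInterval

        windows = [
            GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), id=rid)
            for rid, r in ctrl.regions.iterrows()
        ]
        t1 = synth.simulate_cutrun_counts(
            ctrl, windows, "h3k36me2", synth.LibrarySpec(depth=1e6, seed=6))
        t3 = synth.simulate_cutrun_counts(
            ctrl, windows, "h3k36me2", synth.LibrarySpec(depth=3e6, seed=7))
        ratio = t3.counts.sum().iloc[0] / t1.counts.sum().iloc[0]
        assert ratio == pytest.approx(3.0, rel=0.02)

    def test_rnaseq_doubling_depth_doubles_totals(self, truth_pair):
        # dispersion ~0 so the sampled totals concentrate on the expected
        # depth; the expectation itself scales linearly with depth
        ctrl, _ = truth_pair
        genes = [g for g in _chr1_genes(ctrl)]
        kw = dict(dispersion_range=(1e-8, 1e-8))
        t1 = synth.simulate_counts(ctrl, genes, "rnaseq",
                                   synth.LibrarySpec(depth=5e5, seed=8), **kw)
        t2 = synth.simulate_counts(ctrl, genes, "rnaseq",
                                   synth.LibrarySpec(depth=1e6, seed=9), **kw)
        assert t2.counts.sum().iloc[0] / t1.counts.sum().iloc[0] == pytest.approx(
            2.0, rel=0.02
        )


def _chr1_genes(truth):
    from oomethkit.core_io import Gene

    out = []
    for gid, row in truth.gene_expr.iterrows():
        if row["chrom"] == "chr1":
            gb = truth.regions.loc[f"gb_{gid}"]
            out.append(Gene("chr1", int(gb["start"]), int(gb["end"]), strand="+",
                            id=gid, exonic_length=int(row["exonic_length"])))
    return out


class TestWgbs:
    def test_perfect_conversion_zero_meth_truth_all_unmethylated(self, annotation):
        params = synth.EffectParams(beta0=0.0, beta_k36me2=0.0, beta_k36me3=0.0,
                                    beta_k4me3=0.0, noise_sd=0.0)
        truth = synth.simulate_truth(annotation, "ctrl", params, seed=3)
        spec = synth.LibrarySpec(conversion_failure=0.0, coverage=5, seed=10)
        calls = synth.simulate_wgbs(truth, spec, n_cpg_per_region=3, n_chh_sites=200)
        assert calls.calls["methylated"].sum() == 0

    def test_noncpg_methylation_estimates_conversion_failure(self, truth_pair):
        ctrl, _ = truth_pair
        spec = synth.LibrarySpec(conversion_failure=0.08, coverage=20, seed=11)
        calls = synth.simulate_wgbs(ctrl, spec, n_cpg_per_region=3, n_chh_sites=3000)
        est = calls.noncpg_methylation()
        n = calls.calls.query("context != 'CpG'")["total"].sum()
        sd = np.sqrt(0.08 * 0.92 / n)
        assert abs(est - 0.08) < 3 * sd

    def test_pooled_level_matches_true_fraction(self, annotation):
        # flat methylome at a chosen global level, recovered from deep data
        params = synth.EffectParams(beta0=0.358, beta_k36me2=0.0, beta_k36me3=0.0,
                                    beta_k4me3=0.0, noise_sd=0.0)
        truth = synth.simulate_truth(annotation, "ctrl", params, seed=3)
        spec = synth.LibrarySpec(conversion_failure=0.0, coverage=40, seed=12)
        calls = synth.simulate_wgbs(truth, spec, n_cpg_per_region=10, n_chh_sites=10)
        cpg = calls.calls.query("context == 'CpG'")
        level = cpg["methylated"].sum() / cpg["total"].sum()
        assert level == pytest.approx(0.358, abs=0.005)


class TestHybridReads:
    def test_error_free_maternal_read_mismatch_pattern(self):
        t = synth.simulate_hybrid_reads(500, (1.0, 0.0), ("fixed", 2),
                                        error_rate=0.0, seed=1)
        assert (t.reads["mismatches_maternal"] == 0).all()
        assert (t.reads["mismatches_paternal"] == 2).all()

    def test_snp_free_reads_have_no_mismatches(self):
        t = synth.simulate_hybrid_reads(200, (0.0, 0.0), ("poisson", 2.0),
                                        error_rate=0.0, seed=2)
        assert (t.reads[["mismatches_maternal", "mismatches_paternal"]] == 0).all().all()

    def test_origin_fractions_respected(self):
        t = synth.simulate_hybrid_reads(20_000, (0.3, 0.6), ("poisson", 2.0),
                                        error_rate=0.0, seed=3)
        fr = t.reads["true_origin"].value_counts(normalize=True)
        assert fr["maternal"] == pytest.approx(0.3, abs=0.02)
        assert fr["paternal"] == pytest.approx(0.6, abs=0.02)

    def test_invalid_fracs_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_hybrid_reads(10, (0.7, 0.7))
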