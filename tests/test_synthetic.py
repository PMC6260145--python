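import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csrnc import locus_map as lm, quantify as q, synthetic_data as sd
from oracles import motif_bin_counts_oracle


def _uniform_config(**kwargs):
    low = np.full(19, 1.0)
    defaults = dict(
        n_samples=200,
        tissues=[("t", "arch", 1.0)],
        archetypes={"arch": low + 2.0},
        zero_sample_fraction=0.0,
        dropout_fraction=0.0,
        noise_sd=0.0,
        seed=0,
    )
    defaults.update(kwargs)
    return sd.SyntheticCohortConfig(**defaults)


class TestCohortConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(sd.ConfigError):
            _uniform_config(tissues=[("a", "arch", 0.5), ("b", "arch", 0.4)])

    def test_probabilities_in_unit_interval(self):
        with pytest.raises(sd.ConfigError):
            _uniform_config(zero_sample_fraction=1.2)

    def test_archetype_length_checked(self):
        with pytest.raises(sd.ConfigError):
            _uniform_config(archetypes={"arch": np.ones(5)})

    def test_default_config_valid(self):
        config = sd.SyntheticCohortConfig()
        assert abs(sum(f for _, _, f in config.tissues) - 1.0) < 1e-9


class TestGenerateCohort:
    def test_seed_determinism(self):
        config = sd.SyntheticCohortConfig(n_samples=50, seed=9)
        meta1, i1, c1 = sd.generate_cohort(config)
        meta2, i2, c2 = sd.generate_cohort(config)
        pd.testing.assert_frame_equal(meta1, meta2)
        pd.testing.assert_frame_equal(i1.values, i2.values)
        pd.testing.assert_frame_equal(c1.values, c2.values)

    def test_degenerate_zero_fraction_one(self):
        _, imat, _ = sd.generate_cohort(_uniform_config(zero_sample_fraction=1.0))
        assert (imat.values.to_numpy() == 0).all()

    def test_noiseless_rows_equal_archetype(self):
        config = _uniform_config()
        _, imat, cmat = sd.generate_cohort(config)
        expected = np.power(2.0, np.asarray(config.archetypes["arch"]))
        combined = np.hstack([imat.values.to_numpy(), cmat.values.to_numpy()])
        assert combined == pytest.approx(np.tile(expected, (200, 1)))

    def test_zero_fraction_within_binomial_ci(self):
        frac = 0.375
        config = sd.SyntheticCohortConfig(n_samples=400, zero_sample_fraction=frac, seed=4)
        _, imat, _ = sd.generate_cohort(config)
        all_zero = (imat.values.to_numpy() == 0).all(axis=1)
        lo, hi = stats.binom.interval(0.99, 400, frac)
        assert lo <= all_zero.sum() <= hi

    def test_per_tissue_means_track_archetypes(self, two_archetype_cohort):
        meta, imat, _ = two_archetype_cohort
        log2 = imat.log2()
        means = log2.groupby(meta.set_index("sample_id")["archetype"]).mean()
        gap = means.loc["high_all"] - means.loc["low_all"]
        assert gap.to_numpy() == pytest.approx(4.0, abs=0.5)

    def test_coding_noncoding_correlation(self):
        config = sd.SyntheticCohortConfig(
            n_samples=4000, zero_sample_fraction=0.0, dropout_fraction=0.0,
            coding_noncoding_rho=0.6, seed=12,
        )
        _, imat, cmat = sd.generate_cohort(config)
        li, lc = imat.log2(), cmat.log2()
        rhos = []
        for i_name, c_name in sd.PAIRED_C_GENE.items():
            resid_i = li[i_name] - li[i_name].mean()
            resid_c = lc[c_name] - lc[c_name].mean()
            # correlate within tissue groups to remove archetype structure
            rhos.append(np.corrcoef(resid_i, resid_c)[0, 1])
        # archetype structure inflates the pooled correlation; it must at
        # least reach the configured latent-factor level on average
        assert np.mean(rhos) >= 0.5


class TestGenerateLocus:
    def test_no_planted_regions_background_only(self):
        spec = sd.SyntheticLocusSpec(length_bp=5000, background_gc=0.0, seed=0)
        seq = sd.generate_locus(spec)
        assert set(seq) <= {"A", "T"}
        profile = lm.scan_motif_density(
            seq, lm.MotifScanConfig(span=lm.GenomicInterval("chr14", 1, 5000))
        )
        assert profile.counts.sum() == 0

    def test_planted_region_meets_per_bin_target(self):
        spec = sd.SyntheticLocusSpec(
            length_bp=20_000, planted_s_regions=[(8001, 12_000, 20)], seed=3
        )
        seq = sd.generate_locus(spec)
        region = seq[8000:12_000]
        counts = motif_bin_counts_oracle(region, "AGCT", 500)
        assert len(counts) == 8
        assert all(c >= 20 for c in counts)

    def test_overlapping_planted_regions_rejected(self):
        with pytest.raises(sd.ConfigError):
            sd.SyntheticLocusSpec(
                length_bp=10_000,
                planted_s_regions=[(1000, 2000, 10), (1500, 3000, 10)],
            )

    def test_seed_reproducibility(self):
        spec = sd.SyntheticLocusSpec(length_bp=3000, seed=7)
        assert sd.generate_locus(spec) == sd.generate_locus(spec)


class TestGenerateCoverage:
    def _catalog(self):
        ivs = tuple(
            lm.GenomicInterval("chr14", 1000 + 2000 * j, 1000 + 2000 * j + 999,
                               f"r{j}", "I_exon")
            for j in range(10)
        )
        return lm.RegionCatalog(ivs)

    def test_zero_rpkm_gives_flat_zero_track(self):
        catalog = self._catalog()
        expr = q.ExpressionMatrix(
            pd.DataFrame(np.zeros((2, 10)), index=["s0", "s1"],
                         columns=[f"r{j}" for j in range(10)])
        )
        tracks = sd.generate_coverage(expr, catalog)
        assert tracks["s0"].total_auc == 0.0

    def test_planted_auc_inverts_rpkm_arithmetic(self):
        # RPKM 100 over 1 kb, 1e6-read library, 100 bp reads -> AUC 10,000
        catalog = lm.RegionCatalog(
            (lm.GenomicInterval("chr14", 1000, 1999, "r0", "I_exon"),)
        )
        expr = q.ExpressionMatrix(pd.DataFrame({"r0": [100.0]}, index=["s0"]))
        tracks = sd.generate_coverage(expr, catalog, read_length=100, library_size=1_000_000)
        assert q.region_auc(tracks["s0"], catalog.get("r0")) == pytest.approx(10_000)

    def test_round_trip_recovers_rpkm(self):
        catalog = self._catalog()
        rng = np.random.default_rng(6)
        vals = rng.lognormal(2, 1.5, size=(5, 10))
        vals[rng.random((5, 10)) < 0.2] = 0.0
        expr = q.ExpressionMatrix(
            pd.DataFrame(vals, index=[f"s{i}" for i in range(5)],
                         columns=[f"r{j}" for j in range(10)])
        )
        tracks = sd.generate_coverage(expr, catalog, library_size=2_000_000)
        recovered = q.quantify_tracks(
            tracks, catalog,
            library_reads={s: 2_000_000 for s in expr.sample_ids},
        )
        orig = expr.values.to_numpy()
        rec = recovered.values[expr.region_names].to_numpy()
        nz = orig > 0
        rel_err = np.abs(rec[nz] - orig[nz]) / orig[nz]
        assert rel_err.max() <= 0.05

    def test_region_outside_span_rejected(self):
        catalog = self._catalog()
        expr = q.ExpressionMatrix(
            pd.DataFrame(np.ones((1, 10)), index=["s0"],
                         columns=[f"r{j}" for j in range(10)])
        )
        span = lm.GenomicInterval("chr14", 1, 5000)
        with pytest.raises(sd.ConfigError, match="outside"):
            sd.generate_coverage(expr, catalog, span=span)
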