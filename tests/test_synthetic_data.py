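"""Generator: determinism, noise model, layout guarantees, persistence."""

import math

import numpy as np
import pytest
from scipy import stats

import methylfollicle as mf
from methylfollicle.synthetic_data import ConfigError, beta_binomial


class TestConfigValidation:
    def test_infeasible_planted_region(self):
        with pytest.raises(ConfigError, match="host planted"):
            mf.SimulationConfig(
                seed=1,
                cpgs_per_target=(2, 2),
                planted_regions=[mf.PlantedRegion("treated", 40.0, n_cpgs=5)],
            )

    def test_unknown_planted_group(self):
        with pytest.raises(ConfigError, match="unknown group"):
            mf.SimulationConfig(
                seed=1, planted_regions=[mf.PlantedRegion("ghost", 40.0)]
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"baseline_meth": 0.0},
            {"dispersion": 1.0},
            {"island_fraction": 1.5},
            {"coverage_mean": 0.0},
            {"n_per_group": {"a": 0}},
        ],
    )
    def test_bad_parameters(self, kwargs):
        with pytest.raises(ConfigError):
            mf.SimulationConfig(seed=1, **kwargs)

    def test_small_n_cpgs_rejected(self):
        with pytest.raises(ConfigError, match="n_cpgs"):
            mf.PlantedRegion("treated", 40.0, n_cpgs=2)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        cfg = dict(seed=42, n_targets=20, planted_regions=[])
        a = mf.simulate_cohort(mf.SimulationConfig(**cfg))
        b = mf.simulate_cohort(mf.SimulationConfig(**cfg))
        assert a.records == b.records
        assert a.islands == b.islands
        assert a.genes == b.genes
        assert a.gene_sets.sets == b.gene_sets.sets

    def test_layout_matches_cohort_layout(self):
        cfg = mf.SimulationConfig(seed=9, n_targets=15)
        sites, islands, genes, gene_sets = mf.simulate_genome_layout(cfg)
        cohort = mf.simulate_cohort(cfg)
        assert {(r.chrom, r.pos) for r in cohort.records} == set(sites)
        assert cohort.islands == islands


class TestIslandFraction:
    @pytest.mark.parametrize("fraction,expected", [(1.0, {"island"}), (0.0, {"other"})])
    def test_extremes(self, fraction, expected):
        cfg = mf.SimulationConfig(seed=3, n_targets=15, island_fraction=fraction)
        cohort = mf.simulate_cohort(cfg)
        index = mf.AnnotationIndex(cohort.islands, [])
        contexts = {
            index.classify_cpg_context(r.chrom, r.pos) for r in cohort.records
        }
        assert contexts == expected


class TestNoiseModel:
    def test_binomial_reduction_matches_baseline(self):
        """rho=0, delta=0: pooled methylated fraction ~ pi0 within 3 MC SE."""
        cfg = mf.SimulationConfig(
            seed=5,
            n_per_group={"g": 1},
            n_targets=200,
            cpgs_per_target=(10, 10),
            dispersion=0.0,
            baseline_meth=0.3,
        )
        cohort = mf.simulate_cohort(cfg)
        meth = sum(r.count_meth for r in cohort.records)
        total = sum(r.coverage for r in cohort.records)
        se = math.sqrt(0.3 * 0.7 / total)
        assert abs(meth / total - 0.3) < 3 * se

    def test_planted_shift_recovers_delta(self):
        """delta=+40 at pi0=0.3: observed group difference ~ +40pp within 3 SE."""
        regions = [mf.PlantedRegion("treated", 40.0, n_cpgs=5) for _ in range(50)]
        cfg = mf.SimulationConfig(
            seed=6,
            n_per_group={"treated": 10, "control": 10},
            n_targets=50,
            planted_regions=regions,
            dispersion=0.0,
            baseline_meth=0.3,
        )
        cohort = mf.simulate_cohort(cfg)
        mt = tt = mc = tc = 0
        for r in cohort.records:
            if not any(t.contains(r.chrom, r.pos) for t in cohort.truth):
                continue
            if r.group == "treated":
                mt += r.count_meth
                tt += r.coverage
            else:
                mc += r.count_meth
                tc += r.coverage
        diff = 100 * (mt / tt - mc / tc)
        se = 100 * math.sqrt(0.7 * 0.3 / tt + 0.3 * 0.7 / tc)
        assert abs(diff - 40.0) < 3 * se

    def test_beta_binomial_rho_zero_is_binomial(self):
        """Chi-square GOF of rho=0 draws against the Binomial(30, 0.3) pmf."""
        rng = np.random.default_rng(12)
        n, pi, n_draws = 30, 0.3, 5000
        draws = beta_binomial(rng, np.full(n_draws, n), np.full(n_draws, pi), 0.0)
        pmf = stats.binom.pmf(np.arange(n + 1), n, pi)
        expected = pmf * n_draws
        observed = np.bincount(draws, minlength=n + 1).astype(float)
        # merge the sparse tails so every bin has expected count >= 5
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        stat = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(stat, df=len(obs) - 1)
        assert p > 0.01

    def test_beta_binomial_variance_inflation(self):
        """rho>0 inflates the variance by the factor 1 + (n-1)*rho."""
        rng = np.random.default_rng(13)
        n, pi, rho = 30, 0.3, 0.1
        draws = beta_binomial(rng, np.full(20_000, n), np.full(20_000, pi), rho)
        expected_var = n * pi * (1 - pi) * (1 + (n - 1) * rho)
        assert abs(draws.var() / expected_var - 1) < 0.1


class TestLayoutGuarantees:
    def test_planted_regions_cover_enough_cpgs(self, planted_cohort):
        sites = {(r.chrom, r.pos) for r in planted_cohort.records}
        for region in planted_cohort.truth:
            covered = sum(1 for c, p in sites if region.contains(c, p))
            assert covered >= region.n_cpgs
            assert region.end - region.start <= 1000

    def test_all_genic_classes_populated(self, planted_cohort, annotation_index):
        labels = set()
        for r in planted_cohort.records[:: max(1, len(planted_cohort.records) // 3000)]:
            labels.update(annotation_index.annotate_genic((r.chrom, r.pos)))
        assert {"promoter", "1-5 kb", "exon", "intron", "intergenic"} <= labels


class TestPersistence:
    def test_write_then_load_roundtrip(self, tmp_path, planted_cohort):
        mf.write_truth(planted_cohort, tmp_path)
        back = mf.load_cohort(tmp_path)
        assert sorted(back.records, key=lambda r: (r.sample_id, r.chrom, r.pos)) == sorted(
            planted_cohort.records, key=lambda r: (r.sample_id, r.chrom, r.pos)
        )
        assert back.truth == planted_cohort.truth
        assert back.islands == planted_cohort.islands
        assert back.genes == planted_cohort.genes
        assert back.gene_sets.sets == planted_cohort.gene_sets.sets

    def test_one_coverage_file_per_sample(self, tmp_path, planted_cohort):
        mf.write_truth(planted_cohort, tmp_path)
        cov_files = sorted(p.name for p in tmp_path.glob("*.cov.gz"))
        assert len(cov_files) == 24
        assert "untreated_04.cov.gz" in cov_files

    def test_empty_truth_gives_header_only(self, tmp_path):
        cfg = mf.SimulationConfig(seed=2, n_targets=5)
        mf.write_truth(mf.simulate_cohort(cfg), tmp_path)
        lines = (tmp_path / "truth.tsv").read_text().splitlines()
        assert len(lines) == 1
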