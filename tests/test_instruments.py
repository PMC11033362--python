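"""Instrument selection: cis window, LD clumping, strength grading."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from targetmr import (
    ConfigurationError,
    DomainError,
    EmptyInstrumentSetError,
    GeneRegion,
    GenotypeRef,
    InstrumentCriteria,
    MissingSNPError,
    SummaryStat,
    f_from_beta_se,
    f_statistic,
    filter_weak,
    ld_clump,
    load_ovarian_instruments,
    select_cis,
    variance_explained,
)


def snp(i, pval, beta=0.1):
    return SummaryStat(f"rs{i}", "A", beta, 0.01, pval, other_allele="G")


REGION = GeneRegion("1", 1_000_000, 1_050_000, "GENE")


class TestSelectCis:
    def test_window_boundary_is_closed(self):
        crit = InstrumentCriteria(window_bp=100_000)
        positions = {"rs1": ("1", 900_000)}  # exactly start - window
        kept = select_cis([snp(1, 1e-9)], REGION, positions, crit)
        assert [s.snp_id for s in kept] == ["rs1"]

    def test_p_threshold_is_strict(self):
        crit = InstrumentCriteria()
        positions = {"rs1": ("1", 1_010_000)}
        assert select_cis([snp(1, 6e-8)], REGION, positions, crit) == []
        assert select_cis([snp(1, 5e-8)], REGION, positions, crit) == []

    def test_counts_and_off_chromosome(self):
        crit = InstrumentCriteria()
        positions = {
            "rs1": ("1", 1_020_000),
            "rs2": ("1", 1_030_000),
            "rs3": ("1", 1_040_000),
            "rs4": ("2", 1_020_000),
        }
        stats = [snp(1, 1e-9), snp(2, 1e-10), snp(3, 0.5), snp(4, 1e-12)]
        kept = select_cis(stats, REGION, positions, crit)
        assert [s.snp_id for s in kept] == ["rs1", "rs2"]

    def test_region_chromosome_absent_raises(self):
        crit = InstrumentCriteria()
        with pytest.raises(ConfigurationError, match="chromosome"):
            select_cis([snp(1, 1e-9)], REGION, {"rs1": ("7", 5)}, crit)

    def test_wide_window_loose_p_keeps_same_chromosome(self):
        crit = InstrumentCriteria(window_bp=10**9, p_threshold=0.999999)
        positions = {f"rs{i}": ("1", i * 10**6) for i in range(1, 6)}
        stats = [snp(i, 0.5) for i in range(1, 6)]
        assert len(select_cis(stats, REGION, positions, crit)) == 5


def _brute_force_greedy(stats, corr2, threshold):
    """Independent re-statement of greedy clumping on a correlation matrix."""
    order = sorted(range(len(stats)), key=lambda i: (stats[i].pval, stats[i].snp_id))
    chosen = []
    for i in order:
        if all(corr2[i][j] < threshold for j in chosen):
            chosen.append(i)
    return sorted(stats[i].snp_id for i in chosen)


class TestLdClump:
    def test_perfectly_correlated_pair_keeps_lower_p(self):
        g = np.random.default_rng(1).integers(0, 3, size=(500, 1)).astype(float)
        ref = GenotypeRef(["rs1", "rs2"], np.hstack([g, g]))
        kept = ld_clump([snp(1, 1e-9), snp(2, 1e-8)], ref, 0.3)
        assert [s.snp_id for s in kept] == ["rs1"]

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(2)
        ref = GenotypeRef(
            [f"rs{i + 1}" for i in range(4)],
            rng.binomial(2, 0.4, size=(5000, 4)).astype(float),
        )
        stats = [snp(i + 1, 10 ** -(9 + i)) for i in range(4)]
        kept = ld_clump(stats, ref, 0.3)
        assert sorted(s.snp_id for s in kept) == [f"rs{i + 1}" for i in range(4)]

    def test_matches_brute_force_on_known_correlation(self):
        """Greedy result equals an independent enumeration on 5 SNPs."""
        rng = np.random.default_rng(3)
        n = 3000
        base = rng.standard_normal(n)
        cols = np.column_stack(
            [
                base + 0.3 * rng.standard_normal(n),
                base + 0.3 * rng.standard_normal(n),
                rng.standard_normal(n),
                -base + 0.3 * rng.standard_normal(n),
                rng.standard_normal(n),
            ]
        )
        dos = 2 * (cols - cols.min(0)) / (cols.max(0) - cols.min(0))
        ref = GenotypeRef([f"rs{i + 1}" for i in range(5)], dos)
        stats = [snp(i + 1, p) for i, p in enumerate([1e-9, 1e-12, 1e-7, 1e-10, 1e-8])]
        corr2 = np.corrcoef(dos, rowvar=False) ** 2
        expected = _brute_force_greedy(stats, corr2, 0.3)
        kept = ld_clump(stats, ref, 0.3)
        assert sorted(s.snp_id for s in kept) == expected

    def test_output_independent_of_input_order(self):
        rng = np.random.default_rng(4)
        dos = rng.binomial(2, 0.3, size=(2000, 5)).astype(float)
        ref = GenotypeRef([f"rs{i + 1}" for i in range(5)], dos)
        stats = [snp(i + 1, p) for i, p in enumerate([1e-9, 1e-12, 1e-7, 1e-10, 1e-8])]
        for perm in itertools.permutations(range(5)):
            kept = ld_clump([stats[i] for i in perm], ref, 0.3)
            assert [s.snp_id for s in kept] == [s.snp_id for s in ld_clump(stats, ref, 0.3)]

    def test_missing_snp_raises_with_name(self):
        ref = GenotypeRef(["rs1"], np.random.default_rng(5).binomial(2, 0.5, (100, 1)).astype(float))
        with pytest.raises(MissingSNPError, match="rs99"):
            ld_clump([snp(99, 1e-9)], ref, 0.3)


class TestStrengthMetrics:
    def test_variance_explained_closed_forms(self):
        assert variance_explained(0.0, 0.3) == 0.0
        assert variance_explained(1.0, 0.5) == 0.5
        with pytest.raises(DomainError):
            variance_explained(0.1, 1.5)

    def test_variance_explained_matches_empirical_r2(self):
        """2*b^2*f*(1-f) equals the regression R^2 on simulated data."""
        rng = np.random.default_rng(6)
        n, f, beta = 10_000, 0.3, 0.4
        g = rng.binomial(2, f, n).astype(float)
        # trait scaled to unit variance: genetic part + environmental filler
        var_g = 2 * beta**2 * f * (1 - f)
        y = beta * g + rng.normal(0, np.sqrt(1 - var_g), n)
        r = np.corrcoef(g, y)[0, 1]
        assert variance_explained(beta, f) == pytest.approx(r * r, abs=0.02)

    def test_f_statistic_consistent_with_bundled_row(self, all_sets):
        """Inverting F = r2 (n-2)/(1-r2) for the strongest CASP1 instrument
        gives a whole-number-scale sample size; recomputing F from it
        reproduces the tabulated value."""
        row = all_sets["CASP1"].rows.set_index("snp_id").loc["rs34146979"]
        r2, f = row["r2_exposure"], row["f_stat"]
        n_implied = f * (1 - r2) / r2 + 2
        assert f_statistic(r2, n_implied) == pytest.approx(f, rel=1e-12)
        assert n_implied == pytest.approx(3934, abs=1)

    def test_f_statistic_monotone_and_edges(self):
        assert f_statistic(0.0, 100) == 0.0
        f_vals = [f_statistic(r2, 500) for r2 in (0.01, 0.05, 0.1, 0.3)]
        assert f_vals == sorted(f_vals)
        n_vals = [f_statistic(0.05, n) for n in (50, 500, 5000)]
        assert n_vals == sorted(n_vals)
        with pytest.raises(DomainError):
            f_statistic(1.0, 100)

    def test_f_from_beta_se(self):
        assert f_from_beta_se(0.2, 0.1) == pytest.approx(4.0)


class TestFilterWeak:
    def test_threshold(self):
        from conftest import make_hset

        h = make_hset([0.1, 0.1, 0.1], [0.0, 0.0, 0.0], [0.1, 0.1, 0.1])
        h.rows["f_stat"] = [12.9, 9.9, 255.3]
        kept = filter_weak(h, 10.0)
        assert kept.snp_ids == ["rs1", "rs3"]

    def test_f_min_zero_is_identity(self, all_sets):
        casp3 = all_sets["CASP3"]
        assert filter_weak(casp3, 0.0).snp_ids == casp3.snp_ids

    def test_bundled_casp3_loses_one_weak_instrument(self, all_sets):
        kept = filter_weak(all_sets["CASP3"], 10.0)
        assert kept.n_snp == 10
        assert "rs2171835" not in kept.snp_ids

    def test_all_dropped_raises(self, all_sets):
        with pytest.raises(EmptyInstrumentSetError):
            filter_weak(all_sets["FNTA"], 1e9)
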