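"""Ground-truth generator: mode construction, count model, ASE splits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybmode.classify import classify_gene, fold_ratio
from hybmode.synthetic import (
    MODES,
    SimConfig,
    SimConfigError,
    low_noise_config,
    simulate_ase,
    simulate_counts,
    simulate_truth,
    simulate_variants,
)


def _only(mode):
    return {m: (1.0 if m == mode else 0.0) for m in MODES}


class TestSimConfig:
    def test_proportions_must_sum_to_one(self):
        props = _only("conserved")
        props["additive"] = 0.2
        with pytest.raises(SimConfigError):
            SimConfig(mode_proportions=props)

    @pytest.mark.parametrize("field,value", [
        ("sd_log2_expression", 0.0),
        ("nb_dispersion", -1.0),
        ("frac_all_zero", 1.5),
        ("n_genes", 0),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(SimConfigError):
            SimConfig(**{field: value})


class TestSimulateTruth:
    def test_degenerate_conserved_mixture(self):
        cfg = SimConfig(n_genes=10, mode_proportions=_only("conserved"),
                        frac_all_zero=0.0, seed=0)
        truth = simulate_truth(cfg)
        assert len(truth) == 10
        assert all(t.true_mode == "conserved" for t in truth)
        for t in truth:
            assert abs(np.log2(t.mu_cor / t.mu_wl)) <= np.log2(1.1) + 1e-12

    def test_mode_counts_follow_mixture(self):
        props = {"conserved": 0.5, "additive": 0.1, "cor_dominant": 0.1,
                 "wl_dominant": 0.1, "over_dominant": 0.1, "under_dominant": 0.1}
        cfg = SimConfig(n_genes=1000, mode_proportions=props, frac_all_zero=0.0, seed=3)
        truth = simulate_truth(cfg)
        n_conserved = sum(t.true_mode == "conserved" for t in truth)
        # binomial(1000, 0.5) central 99% interval
        lo, hi = stats.binom.interval(0.99, 1000, 0.5)
        assert lo <= n_conserved <= hi

    def test_all_zero_count_exact(self):
        cfg = SimConfig(n_genes=100, frac_all_zero=0.1, seed=1)
        truth = simulate_truth(cfg)
        zeros = [t for t in truth if t.true_mode == "all_zero"]
        assert len(zeros) == 10
        assert all(t.mu_cor == t.mu_wl == t.mu_hybrid == 0.0 for t in zeros)

    def test_expected_means_respect_mode_margins(self):
        """Noise-free classification of expected abundances recovers every mode."""
        cfg = SimConfig(n_genes=3000, seed=5)
        for t in simulate_truth(cfg):
            if t.true_mode == "all_zero":
                continue
            assert classify_gene(t.mu_cor, t.mu_wl, t.mu_hybrid) == t.true_mode
            # non-similar contrasts clear the margin, similar ones stay inside it
            for fold in (fold_ratio(t.mu_hybrid, t.mu_cor), fold_ratio(t.mu_hybrid, t.mu_wl)):
                assert fold <= cfg.conserved_margin + 1e-9 or fold >= cfg.nonconserved_margin - 1e-9

    def test_cis_ratio_mirrors_parents_only_when_cis_driven(self):
        cfg = SimConfig(n_genes=2000, cis_fraction=0.5, seed=9)
        truth = simulate_truth(cfg)
        dom = [t for t in truth if t.true_mode in ("cor_dominant", "wl_dominant")]
        cis = [t for t in dom if t.cis_ratio != 1.0]
        assert 0 < len(cis) < len(dom)
        for t in cis:
            assert t.cis_ratio == pytest.approx(t.mu_cor / t.mu_wl)
        assert all(t.cis_ratio == 1.0 for t in truth if t.true_mode not in
                   ("cor_dominant", "wl_dominant"))


class TestSimulateCounts:
    def test_deterministic_for_same_seed(self, small_sim):
        cfg, truth, matrix, ase = small_sim
        again = simulate_counts(simulate_truth(cfg), cfg)
        pd.testing.assert_frame_equal(matrix.counts, again.counts)
        ase2 = simulate_ase(simulate_truth(cfg), again, cfg)
        pd.testing.assert_frame_equal(ase, ase2)

    def test_different_seed_differs(self, small_sim):
        cfg, truth, matrix, _ = small_sim
        cfg2 = SimConfig(**{**cfg.__dict__, "seed": cfg.seed + 1})
        assert not matrix.counts.equals(simulate_counts(simulate_truth(cfg2), cfg2).counts)

    def test_column_layout(self, small_sim):
        cfg, _, matrix, _ = small_sim
        assert matrix.counts.shape[1] == 4 * 2 * cfg.n_replicates
        assert "CC_M_1" in matrix.counts.columns and "LC_F_3" in matrix.counts.columns

    def test_all_zero_genes_emit_zero_everywhere(self, small_sim):
        cfg, truth, matrix, _ = small_sim
        zero_ids = [t.gene_id for t in truth if t.true_mode == "all_zero"]
        assert zero_ids, "fixture should contain silent genes"
        assert (matrix.counts.loc[zero_ids] == 0).all().all()

    def test_near_poisson_means_match_expectation(self):
        """With huge dispersion and equal libraries, sample means track mu."""
        cfg = SimConfig(n_genes=300, n_replicates=30, nb_dispersion=1e9,
                        library_size=3_000_000, frac_all_zero=0.0, seed=13)
        truth = simulate_truth(cfg)
        matrix = simulate_counts(truth, cfg)
        mus = np.array([t.mu_cor for t in truth])
        expected = mus / mus.sum() * cfg.library_size
        cc = matrix.counts[[c for c in matrix.counts.columns if c.startswith("CC_")]]
        observed = cc.mean(axis=1).to_numpy()
        se = np.sqrt(expected / cc.shape[1])
        ok = np.abs(observed - expected) <= 3 * se
        assert ok.mean() >= 0.99


class TestSimulateAse:
    def test_allele_counts_sum_to_informative_total(self, small_sim):
        cfg, truth, matrix, ase = small_sim
        assert (ase["cor_count"] >= 0).all() and (ase["wl_count"] >= 0).all()
        # totals bounded by the unit's summed reads per gene
        for unit, grp in ase.groupby("unit"):
            cross, sex = unit.split("_")
            cols = [c for c in matrix.counts.columns if c.startswith(f"{cross}_{sex}_")]
            totals = matrix.counts[cols].sum(axis=1)
            assert ((grp["cor_count"] + grp["wl_count"]).to_numpy()
                    <= totals.loc[grp["gene_id"]].to_numpy()).all()

    def test_zero_snp_genes_absent(self, small_sim):
        cfg, truth, matrix, ase = small_sim
        no_snp = {t.gene_id for t in truth if t.n_snps == 0}
        assert no_snp, "fixture should include genes without informative SNPs"
        assert no_snp.isdisjoint(set(ase["gene_id"]))

    def test_balanced_cis_ratio_gives_half_share(self):
        cfg = low_noise_config(n_genes=200, seed=17, cis_fraction=0.0,
                               snps_per_gene=5.0, frac_all_zero=0.0)
        truth = simulate_truth(cfg)
        matrix = simulate_counts(truth, cfg)
        ase = simulate_ase(truth, matrix, cfg)
        total = int((ase["cor_count"] + ase["wl_count"]).sum())
        cor = int(ase["cor_count"].sum())
        lo, hi = stats.binom.interval(0.99, total, 0.5)
        assert lo <= cor <= hi

    def test_cis_ratio_three_gives_expected_share(self):
        """cor share of a cis_ratio=3 gene concentrates near 0.75."""
        rng = np.random.default_rng(0)
        cor = rng.binomial(4000, 3 / (1 + 3))
        assert 0.72 < cor / 4000 < 0.78


def test_simulate_variants_consistent_with_reference():
    reference, snps = simulate_variants(seed=4, n_snps=40)
    assert len(snps) == 40
    for s in snps:
        assert reference[s.chrom][s.pos - 1] == s.ref_allele
        assert s.alt_allele != s.ref_allele
    z = [s for s in snps if s.chrom == "Z"]
    assert all(s.chromosome_class == "Z" for s in z)
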