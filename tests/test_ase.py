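"""ASE filtering, direction split, and log-log regression."""

import numpy as np
import pandas as pd
import pytest

from hybmode.ase import (
    AseError,
    ase_regression,
    filter_ase,
    fits_to_json,
    split_by_parental_direction,
)


def ase_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "unit", "cor_count", "wl_count", "n_snps"])


class TestFilterAse:
    def test_boundary_kept_below_removed(self):
        # single unit: depth scaling to the mean is the identity
        ase = ase_frame([("g1", "CL_M", 5, 5, 1), ("g2", "CL_M", 5, 4, 1)])
        kept = filter_ase(ase, min_normalized_reads=10)
        assert kept["gene_id"].tolist() == ["g1"]  # 10 kept, 9.x removed

    def test_empty_input(self):
        assert filter_ase(ase_frame([])).empty

    def test_depth_scaling_equalizes_units(self):
        # unit B sequenced twice as deep; after scaling to the mean depth a
        # 12-read gene in B falls below the floor while 8 reads in A survive
        ase = ase_frame([
            ("g1", "A", 4, 4, 1), ("g2", "A", 92, 0, 1),
            ("g3", "B", 6, 6, 1), ("g4", "B", 94, 94, 1),
        ])
        kept = filter_ase(ase, min_normalized_reads=10)
        # totals: A=100, B=200, mean depth 150 -> factors 1.5 and 0.75
        assert set(kept["gene_id"]) == {"g1", "g2", "g4"}

    def test_percent_scaling_option(self):
        ase = ase_frame([("g1", "A", 30, 30, 1), ("g2", "A", 20, 20, 1)])
        kept = filter_ase(ase, min_normalized_reads=50, scaling="percent")
        assert kept["gene_id"].tolist() == ["g1"]  # 60% vs 40%


class TestSplitByParentalDirection:
    def test_partition(self):
        calls = pd.DataFrame({
            "gene_id": ["a", "b", "c"],
            "mode": ["cor_dominant", "wl_dominant", "cor_dominant"],
            "p_cor": [2.0, 1.0, 1.0],
            "p_wl": [1.0, 2.0, 1.0],
        })
        gt, lt = split_by_parental_direction(calls)
        assert gt == {"a"} and lt == {"b"}  # tied gene c excluded

    def test_non_dominant_rejected(self):
        calls = pd.DataFrame({
            "gene_id": ["a"], "mode": ["conserved"], "p_cor": [1.0], "p_wl": [2.0],
        })
        with pytest.raises(AseError, match="non-dominant"):
            split_by_parental_direction(calls)


class TestAseRegression:
    def _profile(self, pc, pw):
        idx = [f"g{i}" for i in range(len(pc))]
        return pd.DataFrame({"Cor_M": pc, "WL_M": pw}, index=idx)

    def test_pure_cis_identity(self):
        """Allele pairs equal to parental pairs: both strata fit identically."""
        rng = np.random.default_rng(0)
        pc = rng.uniform(10, 100, 20)
        pw = pc / rng.uniform(1.5, 2.5, 20)
        prof = self._profile(pc, pw)
        ase = ase_frame([(g, "CL_M", pc[i], pw[i], 1) for i, g in enumerate(prof.index)])
        res = ase_regression(prof, ase, set(prof.index))
        assert res["hybrid_alleles"].slope == pytest.approx(res["parents"].slope)
        assert res["hybrid_alleles"].intercept == pytest.approx(res["parents"].intercept)
        assert res["ratio_pearson_r"] == pytest.approx(1.0)
        assert res["ratio_pearson_p"] < 0.05

    def test_pure_trans_allele_fit_is_identity_line(self):
        """Equal allele counts for every gene: slope 1, intercept 0 on log scale."""
        rng = np.random.default_rng(1)
        pc = rng.uniform(10, 100, 15)
        prof = self._profile(pc, pc / 2.0)
        ase = ase_frame([(g, "CL_M", 7 * (i + 1), 7 * (i + 1), 1)
                         for i, g in enumerate(prof.index)])
        res = ase_regression(prof, ase, set(prof.index))
        assert res["hybrid_alleles"].slope == pytest.approx(1.0)
        assert res["hybrid_alleles"].intercept == pytest.approx(0.0, abs=1e-12)

    def test_ols_matches_normal_equations(self):
        """Slope/intercept agree with the closed-form solution to 1e-10."""
        rng = np.random.default_rng(2)
        pc = rng.uniform(5, 500, 40)
        pw = pc * rng.uniform(0.3, 0.9, 40)
        prof = self._profile(pc, pw)
        ac = rng.integers(20, 4000, 40)
        aw = rng.integers(20, 4000, 40)
        ase = ase_frame([(g, "CL_M", ac[i], aw[i], 2) for i, g in enumerate(prof.index)])
        res = ase_regression(prof, ase, set(prof.index))
        for stratum, x, y in (("parents", pc, pw), ("hybrid_alleles", ac, aw)):
            X = np.column_stack([np.ones(40), np.log2(x)])
            beta = np.linalg.solve(X.T @ X, X.T @ np.log2(y))
            fit = res[stratum]
            assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
            assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_scale_invariance_of_slope(self):
        """Rescaling all allele counts shifts only the intercept."""
        rng = np.random.default_rng(3)
        pc = rng.uniform(5, 50, 12)
        prof = self._profile(pc, pc * 0.6)
        ac, aw = rng.integers(10, 999, 12), rng.integers(10, 999, 12)
        base = ase_frame([(g, "CL_M", ac[i], aw[i], 1) for i, g in enumerate(prof.index)])
        scaled = base.assign(cor_count=base.cor_count * 64, wl_count=base.wl_count * 64)
        r1 = ase_regression(prof, base, set(prof.index))
        r2 = ase_regression(prof, scaled, set(prof.index))
        assert r2["hybrid_alleles"].slope == pytest.approx(r1["hybrid_alleles"].slope)
        assert r2["ratio_pearson_r"] == pytest.approx(r1["ratio_pearson_r"])

    def test_zero_values_dropped_and_min_n_enforced(self):
        prof = self._profile([10.0, 20.0, 30.0, 0.0], [5.0, 10.0, 15.0, 1.0])
        ase = ase_frame([("g0", "CL_M", 5, 5, 1), ("g1", "CL_M", 5, 0, 1),
                         ("g2", "CL_M", 4, 4, 1), ("g3", "CL_M", 9, 9, 1)])
        with pytest.raises(AseError, match="usable"):
            ase_regression(prof, ase, set(prof.index))  # only 2 usable

    def test_json_serialisable(self):
        prof = self._profile([10.0, 20.0, 40.0], [5.0, 8.0, 30.0])
        ase = ase_frame([(g, "CL_M", 5 + i, 6 + i, 1) for i, g in enumerate(prof.index)])
        out = fits_to_json(ase_regression(prof, ase, set(prof.index)))
        import json

        json.dumps(out)
        assert out["parents"]["stratum"] == "parents"
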