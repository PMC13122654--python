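"""Proteome preprocessing and DEP calling: filter, kNN imputation,
log-median normalization, pooled t-test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from quadromics.containers import ExpressionMatrix, call_status
from quadromics.errors import ValidationError
from quadromics.proteome import (
    cv_below_fraction,
    filter_proteins,
    impute_knn,
    normalize_log_median,
    protein_de,
)
from quadromics.simulate import SyntheticConfig, generate_paired_dataset

from conftest import make_matrix

NA = np.nan


def protein_matrix(rows, n_per_group=6):
    return make_matrix(rows, "protein", n_per_group=n_per_group)


class TestFilterProteins:
    def test_missingness_boundary_is_strict(self):
        rows = {
            "HALF": [2.0] * 6 + [NA] * 6,  # 6/12 = 0.5 -> retained
            "OVER": [2.0] * 5 + [NA] * 7,  # 7/12 -> removed
            "FULL": [2.0] * 12,
        }
        retained, report = filter_proteins(protein_matrix(rows))
        assert "HALF" in retained.gene_symbols
        assert "OVER" not in retained.gene_symbols
        assert report.n_missingness_removed == 1

    def test_loc_prefix_removed(self):
        rows = {"LOC999": [2.0] * 12, "GPX1": [2.0] * 12}
        retained, report = filter_proteins(protein_matrix(rows))
        assert list(retained.gene_symbols) == ["GPX1"]
        assert report.n_loc_removed == 1

    def test_imputed_cell_count_is_missing_among_retained(self):
        rows = {"A": [2.0] * 10 + [NA, NA], "B": [3.0] * 12, "OVER": [2.0] * 3 + [NA] * 9}
        _, report = filter_proteins(protein_matrix(rows))
        assert report.n_imputed_cells == 2  # OVER's cells don't count


class TestImputeKnn:
    def test_identity_without_missing(self):
        rows = {"A": list(np.arange(1.0, 13.0)), "B": [5.0] * 12}
        m = protein_matrix(rows)
        out = impute_knn(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_duplicate_neighbors_determine_imputed_value(self):
        """With two exact duplicate rows as the only close neighbors, the
        imputed value equals their value in the missing sample."""
        target = [4.0, 8.0, 16.0, NA] + [4.0] * 8
        dup = [4.0, 8.0, 16.0, 32.0] + [4.0] * 8
        far = [1000.0] * 12
        m = protein_matrix({"T": target, "D1": dup, "D2": dup, "F": far})
        out = impute_knn(m, k=2)
        assert out.values.loc["T"].iloc[3] == pytest.approx(32.0, rel=1e-9)

    def test_imputed_within_donor_range(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(3, 0.5, size=(10, 12))
        values[2, 4] = np.nan
        m = protein_matrix({f"P{i}": values[i] for i in range(10)})
        out = impute_knn(m, k=3)
        filled = out.values.iloc[2, 4]
        col = np.delete(values[:, 4], 2)
        assert np.nanmin(col) <= filled <= np.nanmax(col)

    def test_observed_cells_unchanged(self):
        rows = {"A": [2.0, NA] + [3.0] * 10, "B": [2.5, 4.0] + [3.0] * 10, "C": [9.0] * 12}
        m = protein_matrix(rows)
        out = impute_knn(m)
        observed = ~m.values.isna()
        pd.testing.assert_frame_equal(out.values[observed], m.values[observed])

    def test_fixed_point_after_completion(self):
        rows = {"A": [2.0, NA] + [3.0] * 10, "B": [2.5, 4.0] + [3.0] * 10}
        once = impute_knn(protein_matrix(rows))
        twice = impute_knn(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_fully_missing_protein_rejected(self):
        with pytest.raises(ValidationError, match="no observed value"):
            impute_knn(protein_matrix({"A": [NA] * 12, "B": [2.0] * 12}))


class TestNormalizeLogMedian:
    def test_constant_column_maps_to_zero(self):
        m = protein_matrix({"A": [8.0] * 12, "B": [8.0] * 12, "C": [8.0] * 12})
        out = normalize_log_median(m)
        assert np.allclose(out.values.to_numpy(), 0.0)

    def test_per_sample_median_is_zero(self, rng):
        values = rng.lognormal(5, 1, size=(21, 12))
        m = protein_matrix({f"P{i}": values[i] for i in range(21)})
        out = normalize_log_median(m)
        assert np.allclose(np.median(out.values.to_numpy(), axis=0), 0.0)

    def test_scale_invariance_per_sample(self, rng):
        values = rng.lognormal(5, 1, size=(15, 12))
        m = protein_matrix({f"P{i}": values[i] for i in range(15)})
        scaled = m.values.copy()
        scaled["GRA_1"] = scaled["GRA_1"] * 2
        m2 = ExpressionMatrix(values=scaled, groups=m.groups, layer="protein")
        a, b = normalize_log_median(m), normalize_log_median(m2)
        np.testing.assert_allclose(
            a.values["GRA_1"], b.values["GRA_1"], atol=1e-12
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            normalize_log_median(protein_matrix({"A": [0.0] + [1.0] * 11}))


def normalized_matrix(rows, n_per_group=6):
    """Rows already on the normalized log2 scale (bypass positivity checks)."""
    return make_matrix(rows, "protein", n_per_group=n_per_group)


class TestProteinDe:
    def test_identical_groups_ns(self):
        de = protein_de(normalized_matrix({"A": [1.0, 2.0, 3.0] * 4}))
        assert de.table.loc["A", "status"] == "NS"
        assert de.table.loc["A", "log2fc"] == pytest.approx(0.0)

    def test_pooled_t_matches_textbook_value(self):
        gra, sup = [3.0, 4.0, 5.0], [6.0, 7.0, 8.0]
        de = protein_de(normalized_matrix({"A": gra + sup}, n_per_group=3))
        # textbook pooled t: sp^2 = 1, t = 3 / sqrt(1 * (1/3 + 1/3))
        t = 3.0 / np.sqrt(2.0 / 3.0)
        expected_p = 2 * stats.t.sf(t, df=4)
        assert de.table.loc["A", "log2fc"] == pytest.approx(3.0)
        assert de.table.loc["A", "pvalue"] == pytest.approx(expected_p, rel=1e-9)

    def test_p_close_to_exact_permutation_distribution(self):
        rng = np.random.default_rng(11)
        values = np.concatenate([rng.normal(0, 1, 6), rng.normal(1.2, 1, 6)])
        de = protein_de(normalized_matrix({"A": values}))
        observed_t = abs(stats.ttest_ind(values[6:], values[:6], equal_var=True).statistic)
        perm_ts = []
        for idx in itertools.combinations(range(12), 6):
            grp = values[list(idx)]
            rest = values[[i for i in range(12) if i not in idx]]
            perm_ts.append(abs(stats.ttest_ind(grp, rest, equal_var=True).statistic))
        perm_p = np.mean(np.asarray(perm_ts) >= observed_t - 1e-12)
        assert de.table.loc["A", "pvalue"] == pytest.approx(perm_p, abs=0.05)

    def test_zero_variance_degeneracies(self):
        de = protein_de(
            normalized_matrix({"EQ": [2.0] * 12, "DIFF": [2.0] * 6 + [3.0] * 6})
        )
        assert de.table.loc["EQ", "pvalue"] == 1.0
        assert de.table.loc["DIFF", "pvalue"] == 0.0
        assert de.table.loc["DIFF", "status"] == "Up"

    def test_boundary_fold_cutoff_strict(self):
        assert call_status(0.263, 0.001, 0.263, 0.05) == "NS"

    def test_raw_p_policy_changes_decision_column(self, rng):
        rows = {f"P{i}": rng.normal(0, 1, 12) for i in range(40)}
        rows["SIG"] = np.concatenate([rng.normal(0, 0.1, 6), rng.normal(0.8, 0.1, 6)])
        m = normalized_matrix(rows)
        adj = protein_de(m, p_policy="adjusted")
        raw = protein_de(m, p_policy="raw")
        n_adj = (adj.table["status"] != "NS").sum()
        n_raw = (raw.table["status"] != "NS").sum()
        assert n_raw >= n_adj  # raw policy can only be more liberal


def test_low_cv_synthetic_data_mostly_below_threshold():
    """With a 10% within-group CV, at least 90% of proteins report CV < 0.3
    in each group."""
    config = SyntheticConfig(n_genes=300, protein_cv=0.1, missing_rate=0.0, seed=3)
    ds = generate_paired_dataset(config)
    fractions = cv_below_fraction(ds.protein_abundance)
    assert fractions["GRA"] >= 0.9
    assert fractions["SUP"] >= 0.9
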