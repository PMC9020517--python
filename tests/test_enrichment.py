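"""Staged differential-enrichment statistics: filters, imputation,
moderated permutation ANOVA, bead filter, clustering, family partition."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phosphoubl.enrichment import (
    DEFAULT_GROUPS,
    IntensityMatrix,
    anova_s0,
    bead_filter,
    cluster_and_zscore,
    correlation_and_venn,
    impute,
    preprocess,
    read_maxquant,
    run_aems,
    write_maxquant,
)
from phosphoubl.errors import ImputationError, ParameterError, ZScoreError
from phosphoubl.simulate import AEMSTruth, make_aems_matrix


def _matrix(values: np.ndarray, groups, reps, log2=True, ids=None, control="beads"):
    cols = pd.MultiIndex.from_tuples(
        [(g, r + 1) for g in groups for r in range(reps)], names=["group", "replicate"]
    )
    ids = ids or [f"P{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=ids, columns=cols)
    flags = pd.DataFrame(
        {"is_reverse": False, "is_contaminant": False}, index=frame.index
    )
    return IntensityMatrix(values=frame, flags=flags, control_group=control,
                           log2_transformed=log2)


# --------------------------------------------------------------------------
# preprocess


class TestPreprocess:
    def _raw(self, pattern):
        """pattern: dict group -> number of observed replicates (of 6)."""
        groups = ["A", "B", "beads"]
        vals = np.full((1, 18), np.nan)
        for gi, g in enumerate(groups):
            n = pattern.get(g, 0)
            vals[0, gi * 6 : gi * 6 + n] = 1000.0
        return _matrix(vals, groups, 6, log2=False)

    def test_fully_observed_row_retained(self):
        out = preprocess(self._raw({"A": 6, "B": 6, "beads": 6}))
        assert len(out.values) == 1
        assert out.log2_transformed

    def test_three_of_six_everywhere_dropped(self):
        out = preprocess(self._raw({"A": 3, "B": 3, "beads": 3}))
        assert len(out.values) == 0

    def test_four_of_six_in_single_group_suffices(self):
        out = preprocess(self._raw({"A": 4}))
        assert len(out.values) == 1

    def test_flagged_rows_dropped_and_log2_applied(self):
        m = _matrix(np.full((3, 12), 1024.0), ["A", "B"], 6, log2=False)
        m.flags.loc["P0", "is_reverse"] = True
        m.flags.loc["P1", "is_contaminant"] = True
        out = preprocess(m)
        assert list(out.values.index) == ["P2"]
        assert (out.values.to_numpy() == 10.0).all()  # log2(1024)

    def test_min_valid_above_replicates_rejected(self):
        with pytest.raises(ParameterError):
            preprocess(self._raw({"A": 6}), min_valid=7)


# --------------------------------------------------------------------------
# imputation


class TestImpute:
    def _with_missing(self, n_missing=10000, n_observed=2000, seed=0):
        rng = np.random.default_rng(seed)
        n = n_missing + n_observed
        vals = np.column_stack([
            np.concatenate([rng.normal(25, 2, n_observed), np.full(n_missing, np.nan)]),
            rng.normal(25, 2, n),
            rng.normal(25, 2, n),
            rng.normal(25, 2, n),
        ])
        return _matrix(vals, ["A", "B"], 2)

    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng.normal(25, 2, (50, 12)), ["A", "B"], 6)
        out = impute(m, seed=3)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_downshifted_distribution(self):
        """Column mu=25, sd=2 -> imputed draws ~ N(22.6, 0.6^2)."""
        m = self._with_missing()
        col = m.values.columns[0]
        observed = m.values[col].dropna()
        mu, sd = observed.mean(), observed.std(ddof=1)
        out = impute(m, width=0.3, shift=1.2, seed=5)
        imputed = out.values.loc[m.values[col].isna(), col]
        assert imputed.mean() == pytest.approx(mu - 1.2 * sd, abs=0.03)
        assert imputed.std() == pytest.approx(0.3 * sd, abs=0.02)

    def test_observed_values_untouched_and_deterministic(self):
        m = self._with_missing(n_missing=50, n_observed=100)
        a = impute(m, seed=7)
        b = impute(m, seed=7)
        pd.testing.assert_frame_equal(a.values, b.values)
        mask = m.values.notna().to_numpy()
        np.testing.assert_array_equal(
            a.values.to_numpy()[mask], m.values.to_numpy()[mask]
        )
        c = impute(m, seed=8)
        assert not a.values.equals(c.values)

    def test_underobserved_column_is_an_error(self):
        vals = np.full((5, 4), np.nan)
        vals[:, 1:] = 25.0
        vals[0, 0] = 25.0  # single observed value in first column
        with pytest.raises(ImputationError):
            impute(_matrix(vals, ["A", "B"], 2), seed=0)


# --------------------------------------------------------------------------
# moderated permutation ANOVA


def _oracle_q(rows, g1, g2, s0):
    """Brute-force exhaustive-permutation q-values (independent loops)."""

    def stat(row, idx_a, idx_b):
        vals = [row[i] for i in idx_a] + [row[i] for i in idx_b]
        n, g = len(vals), 2
        grand = sum(vals) / n
        ssb = 0.0
        ssw = 0.0
        for idx in (idx_a, idx_b):
            mean_g = sum(row[i] for i in idx) / len(idx)
            ssb += len(idx) * (mean_g - grand) ** 2
            ssw += sum((row[i] - mean_g) ** 2 for i in idx)
        msb = ssb / (g - 1)
        msw = ssw / (n - g)
        return msb / ((msw**0.5) + s0) ** 2

    observed = [stat(r, g1, g2) for r in rows]
    cols = sorted(g1 + g2)
    null = []
    n_perm = 0
    for combo in itertools.combinations(cols, len(g1)):
        rest = [c for c in cols if c not in combo]
        n_perm += 1
        for r in rows:
            null.append(stat(r, list(combo), rest))
    q_raw = []
    for d in observed:
        efp = sum(1 for v in null if v >= d) / n_perm
        called = sum(1 for v in observed if v >= d)
        q_raw.append(min(1.0, efp / called))
    q_adj = [
        min(q_raw[j] for j in range(len(observed)) if observed[j] <= observed[i])
        for i in range(len(observed))
    ]
    return observed, q_adj


def test_exhaustive_permutation_q_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    rows = rng.normal(20, 1, (5, 6))
    rows[0, :3] += 5.0  # one clearly shifted protein
    m = _matrix(rows, ["A", "B"], 3, control="B")
    res = anova_s0(m, fdr=0.02, s0=1.0, n_perm=1000)  # 20 assignments -> exhaustive
    assert res.params["exhaustive"]
    obs, q = _oracle_q([list(r) for r in rows], [0, 1, 2], [3, 4, 5], s0=1.0)
    np.testing.assert_allclose(res.stats["f_s0"].to_numpy(), obs, rtol=1e-12)
    np.testing.assert_allclose(res.stats["q"].to_numpy(), q, rtol=1e-12)


def test_null_data_significant_fraction_bounded_by_fdr():
    """Empirical type-I error of the permutation FDR on pure-null data."""
    rng = np.random.default_rng(42)
    n = 500
    vals = rng.normal(25, 1, (n, 42))
    m = _matrix(vals, DEFAULT_GROUPS, 6)
    res = anova_s0(m, fdr=0.02, s0=1.0, n_perm=200, seed=1)
    frac = res.stats["significant"].mean()
    assert frac <= 0.02 + 2 * np.sqrt(0.02 * 0.98 / n)


def test_spiked_proteins_detected():
    """20 proteins with a 4-sigma group shift among 480 nulls: >=90% found."""
    rng = np.random.default_rng(7)
    vals = rng.normal(25, 1, (500, 42))
    vals[:20, 6:12] += 4.0  # shift in the second group
    m = _matrix(vals, DEFAULT_GROUPS, 6)
    res = anova_s0(m, fdr=0.02, s0=1.0, n_perm=300, seed=2)
    assert res.stats["significant"].iloc[:20].mean() >= 0.90


def test_zero_variance_protein_is_finite_under_s0():
    vals = np.vstack([np.full(12, 25.0), np.random.default_rng(0).normal(25, 1, 12)])
    m = _matrix(vals, ["A", "B"], 6)
    res = anova_s0(m, s0=1.0, n_perm=1000)
    assert np.isfinite(res.stats["f_s0"]).all()


def test_incomplete_matrix_rejected():
    vals = np.full((3, 12), 25.0)
    vals[0, 0] = np.nan
    with pytest.raises(ParameterError, match="complete"):
        anova_s0(_matrix(vals, ["A", "B"], 6))


# --------------------------------------------------------------------------
# bead filter


def test_bead_filter_rule_and_oracle():
    rng = np.random.default_rng(3)
    vals = rng.normal(25, 1, (40, 18))
    m = _matrix(vals, ["A", "B", "beads"], 6)
    res = anova_s0(m, fdr=1.0 - 1e-9, s0=0.0, n_perm=150, seed=0)  # everything significant
    assert res.stats["significant"].all()
    filtered = bead_filter(res, m)
    means = m.values.T.groupby(level=0, sort=False).mean().T
    expected = set(
        means.index[(means["beads"] > means[["A", "B"]].max(axis=1))]
    )
    assert set(filtered.bead_filtered) == expected
    assert not filtered.stats.loc[list(expected), "significant"].any()


def test_bead_filter_keeps_protein_with_one_higher_bait():
    vals = np.zeros((1, 18))
    vals[0, 0:6] = 29.0  # bait A
    vals[0, 6:12] = 31.0  # bait B above control
    vals[0, 12:18] = 30.0  # beads
    m = _matrix(vals, ["A", "B", "beads"], 6)
    res = anova_s0(m, fdr=0.999999, s0=0.0, n_perm=120, seed=0)
    res.stats["significant"] = True
    out = bead_filter(res, m)
    assert out.bead_filtered == []


def test_bead_filter_requires_control_group():
    m = _matrix(np.random.default_rng(0).normal(25, 1, (5, 12)), ["A", "B"], 6,
                control="beads")
    res = anova_s0(m, n_perm=1000)
    with pytest.raises(ParameterError):
        bead_filter(res, m)


# --------------------------------------------------------------------------
# clustering / z-score


def _significant_result(m):
    res = anova_s0(m, fdr=0.5, s0=0.0, n_perm=150, seed=0)
    res.stats["significant"] = True
    return res


def test_identical_rows_cluster_together_and_opposite_rows_apart():
    base = np.array([24.0, 24, 24, 28, 28, 28, 26, 26, 26, 22, 22, 22])
    vals = np.vstack([base, base, -base + 50])
    m = _matrix(vals, ["A", "B"], 6)
    res = cluster_and_zscore(_significant_result(m), m, n_clusters=2,
                             include_control=True)
    c = res.row_clusters
    assert c["P0"] == c["P1"]
    assert c["P2"] != c["P0"]


def test_zscored_rows_have_zero_mean_unit_sd():
    rng = np.random.default_rng(5)
    m = _matrix(rng.normal(25, 2, (30, 42)), DEFAULT_GROUPS, 6)
    res = cluster_and_zscore(_significant_result(m), m, n_clusters=3)
    z = res.z_matrix.to_numpy()
    np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
    np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)


def test_constant_row_raises_zscore_error():
    vals = np.vstack([np.full(12, 25.0), np.random.default_rng(0).normal(25, 1, 12)])
    m = _matrix(vals, ["A", "B"], 6)
    with pytest.raises(ZScoreError):
        cluster_and_zscore(_significant_result(m), m, n_clusters=2, include_control=True)


def test_planted_interactor_classes_recovered_exactly():
    """Zero-noise 3-class fixture: 3-cut clustering has ARI = 1."""
    truth = AEMSTruth(replicate_sd=0.0, dropout=False, n_bead_binder=0)
    m, labels = make_aems_matrix(truth, seed=0)
    res, imp = run_aems(m, n_perm=150, seed=1)
    res = cluster_and_zscore(res, imp, n_clusters=3, include_control=True)
    sig = res.significant
    truth_labels = labels.loc[sig]
    assert set(truth_labels) == {"ub_only", "shared", "nedd8_only"}
    assert adjusted_rand_score(truth_labels, res.row_clusters.loc[sig]) == 1.0


# --------------------------------------------------------------------------
# correlation and family partition


def test_bait_self_correlation_is_one():
    rng = np.random.default_rng(9)
    m = _matrix(rng.normal(25, 2, (30, 42)), DEFAULT_GROUPS, 6)
    res = correlation_and_venn(_significant_result(m), m)
    np.testing.assert_allclose(np.diag(res.correlation.to_numpy()), 1.0, atol=1e-12)
    assert list(res.correlation.columns) == m.bait_groups


def test_family_partition_rule():
    vals = np.zeros((3, 42))
    vals[:, :] = 25.0
    vals[0, 0:18] = 29.0   # Ub family baits only
    vals[1, 18:36] = 29.0  # NEDD8 family baits only
    vals[2, 0:36] = 29.0   # both families
    m = _matrix(vals, DEFAULT_GROUPS, 6)
    res = correlation_and_venn(_significant_result(m), m)
    assert res.venn.loc["P0", "label"] == "Ub_only"
    assert res.venn.loc["P1", "label"] == "NEDD8_only"
    assert res.venn.loc["P2", "label"] == "shared"


def test_planted_family_composition_recovered_noise_free():
    truth = AEMSTruth(replicate_sd=0.0, dropout=False)
    m, labels = make_aems_matrix(truth, seed=0)
    res, _ = run_aems(m, n_perm=150, seed=1)
    assert res.venn_counts() == {"Ub_only": 126, "shared": 58, "NEDD8_only": 36}
    assert len(res.bead_filtered) == truth.n_bead_binder


# --------------------------------------------------------------------------
# pipeline determinism and I/O


def test_pipeline_is_deterministic_per_seed():
    m, _ = make_aems_matrix(AEMSTruth(n_background=80, n_ub_only=10, n_shared=5,
                                      n_nedd8_only=5, n_bead_binder=5), seed=4)
    r1, i1 = run_aems(m, n_perm=150, seed=9)
    r2, i2 = run_aems(m, n_perm=150, seed=9)
    pd.testing.assert_frame_equal(r1.stats, r2.stats)
    pd.testing.assert_frame_equal(i1.values, i2.values)
    if r1.z_matrix is not None:
        pd.testing.assert_frame_equal(r1.z_matrix, r2.z_matrix)
        pd.testing.assert_series_equal(r1.row_clusters, r2.row_clusters)


def test_maxquant_round_trip(tmp_path):
    m, _ = make_aems_matrix(AEMSTruth(n_background=30, n_ub_only=5, n_shared=5,
                                      n_nedd8_only=5, n_bead_binder=2), seed=2)
    mat_path, design_path = tmp_path / "pg.tsv", tmp_path / "design.tsv"
    write_maxquant(m, mat_path, design_path)
    back = read_maxquant(mat_path, design_path)
    assert back.groups == m.groups
    np.testing.assert_allclose(
        back.values.to_numpy(), m.values.to_numpy(), rtol=1e-9, equal_nan=True
    )
    pd.testing.assert_frame_equal(back.flags, m.flags)
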