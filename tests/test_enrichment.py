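"""Size factors, the NB contrast test, and the dual-contrast target rule."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snortkit.enrichment import (
    CountMatrix,
    call_targets,
    median_enrichment_partition,
    nb_contrast_test,
    normalize_size_factors,
)
from snortkit.errors import (
    DegenerateSampleError,
    SnortkitError,
    UndefinedMedianError,
)

from conftest import MC_SEED, make_count_matrix, nb_counts


class TestSizeFactors:
    def test_identical_samples_get_equal_factors(self):
        col = np.array([[10], [200], [3]])
        cm = make_count_matrix(np.tile(col, (1, 10)))
        sf = normalize_size_factors(cm)
        assert np.allclose(list(sf.values()), 1.0)

    def test_doubled_sample_gets_double_factor(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=(100, 1))
        counts = np.tile(base, (1, 10))
        counts[:, 3] *= 2
        cm = make_count_matrix(counts)
        sf = normalize_size_factors(cm)
        vals = list(sf.values())
        assert vals[3] / vals[0] == pytest.approx(2.0)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(MC_SEED)
        counts = nb_counts(rng, 10 ** rng.uniform(0, 3, size=(300, 10)))
        cm = make_count_matrix(counts)
        sf = normalize_size_factors(cm)
        # independent brute-force recomputation
        pos = counts[np.all(counts > 0, axis=1)].astype(float)
        ref = np.exp(np.log(pos).mean(axis=1))
        for j, s in enumerate(cm.sample_ids):
            assert sf[s] == pytest.approx(float(np.median(pos[:, j] / ref)))

    def test_all_zero_sample_rejected(self):
        counts = np.ones((5, 10), dtype=np.int64)
        counts[:, 2] = 0
        with pytest.raises(DegenerateSampleError):
            normalize_size_factors(make_count_matrix(counts))


class TestNBContrast:
    def test_flat_feature_has_zero_lfc_and_p_one(self):
        counts = np.full((3, 10), 7, dtype=np.int64)
        counts[1] = np.arange(10) + 1  # give the matrix some variation
        counts[2] = 50
        res = nb_contrast_test(make_count_matrix(counts), "RIP_vs_INPUT")
        assert res.loc[0, "log2fc"] == pytest.approx(0.0)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_all_zero_feature_gets_sentinel(self):
        rng = np.random.default_rng(1)
        counts = nb_counts(rng, np.full((20, 10), 50.0))
        counts[5] = 0
        res = nb_contrast_test(make_count_matrix(counts), "RIP_vs_INPUT")
        assert np.isnan(res.loc[5, "p"]) and np.isnan(res.loc[5, "padj"])

    def test_low_count_features_filtered_from_bh_family(self):
        rng = np.random.default_rng(2)
        counts = nb_counts(rng, np.full((50, 10), 100.0))
        counts[7] = 0
        counts[7, 0] = 1  # mean normalised count << 1
        res = nb_contrast_test(make_count_matrix(counts), "RIP_vs_INPUT")
        assert np.isnan(res.loc[7, "padj"])
        assert np.isfinite(res.loc[7, "p"])

    def test_null_type_i_error_calibrated(self):
        """Empirical P(p <= alpha) on 2000 null NB features (mean 100,
        dispersion 0.1, 5 vs 5) inside the 99% binomial interval, for
        alpha in {0.01, 0.05}."""
        rng = np.random.default_rng(MC_SEED)
        counts = nb_counts(rng, np.full((2000, 10), 100.0))
        res = nb_contrast_test(make_count_matrix(counts), "RIP_vs_INPUT")
        for alpha in (0.05, 0.01):
            frac = float((res["p"] <= alpha).mean())
            lo, hi = stats.binom.ppf([0.005, 0.995], 2000, alpha) / 2000
            assert lo <= frac <= hi, f"alpha={alpha}: {frac} not in [{lo},{hi}]"

    def test_planted_enrichment_power(self):
        """>= 90% of 200 features with 8-fold RIP enrichment are recovered
        at padj <= 0.05 against a null background."""
        rng = np.random.default_rng(MC_SEED)
        mean = np.full((2200, 10), 100.0)
        mean[:200, :5] *= 8.0  # RIP columns of the planted features
        res = nb_contrast_test(
            make_count_matrix(nb_counts(rng, mean)), "RIP_vs_INPUT"
        )
        assert float((res["padj"][:200] <= 0.05).mean()) >= 0.9

    def test_bh_monotone_in_p_rank(self):
        rng = np.random.default_rng(4)
        mean = np.full((500, 10), 80.0)
        mean[:50, :5] *= 4
        res = nb_contrast_test(
            make_count_matrix(nb_counts(rng, mean)), "RIP_vs_INPUT"
        )
        sub = res.dropna(subset=["padj"]).sort_values("p")
        assert (np.diff(sub["padj"]) >= -1e-12).all()
        assert (sub["padj"] >= sub["p"] - 1e-12).all()

    def test_scale_invariance_of_calls(self):
        rng = np.random.default_rng(5)
        mean = np.tile(10 ** rng.uniform(1, 3, size=(400, 1)), (1, 10))
        mean[:40, :5] *= 8
        counts = nb_counts(rng, mean)
        scaled = counts.copy()
        scaled[:, 2] *= 4
        r1 = nb_contrast_test(make_count_matrix(counts), "RIP_vs_INPUT")
        r2 = nb_contrast_test(make_count_matrix(scaled), "RIP_vs_INPUT")
        calls1 = (r1["padj"] <= 0.05).fillna(False)
        calls2 = (r2["padj"] <= 0.05).fillna(False)
        assert (calls1 == calls2).mean() > 0.99

    def test_requires_two_replicates(self):
        counts = np.ones((5, 3), dtype=np.int64)
        cm = CountMatrix(
            feature_ids=[f"F{i}" for i in range(5)],
            sample_ids=["RIP_1", "INPUT_1", "INPUT_2"],
            condition={"RIP_1": "RIP", "INPUT_1": "INPUT", "INPUT_2": "INPUT"},
            counts=counts,
        )
        with pytest.raises(SnortkitError, match="replicates"):
            nb_contrast_test(cm, "RIP_vs_INPUT")


def _results(rows):
    return pd.DataFrame(
        [
            {
                "feature_id": fid,
                "contrast": "x",
                "log2fc": lfc,
                "p": p,
                "padj": padj,
                "mean_norm_count": 100.0,
            }
            for fid, lfc, p, padj in rows
        ]
    )


class TestCallTargets:
    def test_rule_application(self):
        rip = _results(
            [("A", 2.0, 0.001, 0.01), ("B", 2.0, 0.001, 0.01),
             ("C", 1.0, 0.1, 0.20), ("D", -1.5, 0.001, 0.01)]
        )
        igg = _results(
            [("A", 0.1, 0.4, 0.50), ("B", 1.0, 0.001, 0.01),
             ("C", 0.0, 0.9, 0.95), ("D", 0.0, 0.9, 0.95)]
        )
        out = call_targets(rip, igg).set_index("feature_id")
        assert bool(out.loc["A", "is_target"])
        assert not out.loc["B", "is_target"]
        assert out.loc["B", "reason"] == "igg_enriched"
        assert not out.loc["C", "is_target"]
        assert out.loc["C", "reason"] == "rip_not_significant"
        assert not out.loc["D", "is_target"]
        assert out.loc["D", "reason"] == "rip_not_enriched"

    def test_igg_depletion_does_not_disqualify(self):
        rip = _results([("A", 2.0, 0.001, 0.01)])
        igg = _results([("A", -2.0, 0.001, 0.01)])  # significant but depleted
        out = call_targets(rip, igg)
        assert bool(out.loc[0, "is_target"])

    def test_nan_padj_counts_as_not_significant(self):
        rip = _results([("A", 2.0, 0.001, np.nan)])
        igg = _results([("A", 0.0, 0.9, np.nan)])
        out = call_targets(rip, igg)
        assert not out.loc[0, "is_target"]

    def test_mismatched_feature_sets_rejected(self):
        rip = _results([("A", 2.0, 0.001, 0.01)])
        igg = _results([("B", 0.0, 0.9, 0.95)])
        with pytest.raises(SnortkitError, match="A"):
            call_targets(rip, igg)


class TestMedianPartition:
    def test_subset_equals_all_targets_odd_count(self):
        rows = [(f"F{i}", float(i), 0.001, 0.01) for i in range(7)]
        rip = _results(rows)
        targets = [f"F{i}" for i in range(7)]
        above, total = median_enrichment_partition(targets, rip, targets)
        assert (above, total) == (3, 7)  # (n-1)/2 strictly above the median

    def test_disjoint_from_top_half(self):
        rows = [(f"F{i}", float(i), 0.001, 0.01) for i in range(10)]
        rip = _results(rows)
        targets = [f"F{i}" for i in range(10)]
        bottom = [f"F{i}" for i in range(5)]
        above, total = median_enrichment_partition(targets, rip, bottom)
        assert (above, total) == (0, 5)

    def test_matches_brute_force_on_random_targets(self):
        rng = np.random.default_rng(MC_SEED)
        lfc = rng.normal(size=51)
        rows = [(f"F{i}", float(v), 0.001, 0.01) for i, v in enumerate(lfc)]
        rip = _results(rows)
        targets = [f"F{i}" for i in range(51)]
        subset = [f"F{i}" for i in rng.choice(51, size=20, replace=False)]
        above, total = median_enrichment_partition(targets, rip, subset)
        med = sorted(lfc)[25]
        expect = sum(lfc[int(s[1:])] > med for s in subset)
        assert (above, total) == (expect, 20)

    def test_empty_targets_rejected(self):
        with pytest.raises(UndefinedMedianError):
            median_enrichment_partition([], _results([]), [])
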