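"""Detection filter, median-of-ratios, stand-in DE test, BH, and log-PCA."""

import numpy as np
import pandas as pd
import pytest

from costress import (
    CountMatrix,
    DEConfig,
    bh_adjust,
    filter_min_detected,
    log_pca,
    median_of_ratios,
    naive_contrast,
    normalize,
)

from conftest import brute_force_bh


def make_cm(counts, conditions, tissue="shoot"):
    counts = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(len(counts))],
        columns=[f"s{j}" for j in range(len(conditions))],
    )
    reps = {}
    sheet = []
    for j, cond in enumerate(conditions):
        reps[cond] = reps.get(cond, 0) + 1
        sheet.append(
            {"sample_id": f"s{j}", "condition": cond, "tissue": tissue, "replicate": reps[cond]}
        )
    return CountMatrix(counts=counts, samples=pd.DataFrame(sheet).set_index("sample_id"))


class TestCountMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_cm([[-1, 2]], ["C", "C"])
        with pytest.raises(ValueError, match="condition"):
            make_cm([[1, 2]], ["C", "X"])

    def test_condition_samples(self):
        cm = make_cm([[1, 2, 3, 4]], ["C", "C", "S", "S"])
        assert cm.condition_samples("S") == ["s2", "s3"]


class TestDetectionFilter:
    def test_sporadic_gene_removed_and_consistent_gene_kept(self):
        # per condition: gene 0 seen in a single replicate, gene 1 in 3 of 4
        conds = ["C"] * 4 + ["S"] * 4
        counts = [
            [5, 0, 0, 0, 7, 0, 0, 0],
            [3, 4, 5, 0, 0, 0, 0, 0],
        ]
        cm = filter_min_detected(make_cm(counts, conds), DEConfig())
        assert cm.gene_ids == ["g1"]

    def test_condition_scope_keeps_stress_specific_genes(self):
        conds = ["C"] * 4 + ["S"] * 4
        counts = [[0, 0, 0, 0, 10, 12, 9, 11]]
        assert filter_min_detected(make_cm(counts, conds), scope="condition").gene_ids == ["g0"]

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="every gene"):
            filter_min_detected(make_cm([[0, 0, 0, 0]], ["C"] * 4))


class TestMedianOfRatios:
    def test_hand_computed_example(self):
        # geometric means sqrt(200), sqrt(1800); all ratios 1/sqrt(2), sqrt(2)
        sf = median_of_ratios(pd.DataFrame([[10, 20], [30, 60]]))
        assert sf.to_numpy() == pytest.approx([0.7071, 1.4142], abs=1e-4)

    def test_identical_columns_give_equal_factors(self):
        sf = median_of_ratios(pd.DataFrame([[5, 5, 5], [100, 100, 100]]))
        assert sf.to_numpy() == pytest.approx([1.0, 1.0, 1.0])

    def test_scale_equivariance_and_gene_order_invariance(self, rng):
        # scaling one library by c rescales the geometric-mean reference by
        # c^(1/m), so the exact invariant lives on factor ratios: the scaled
        # sample's ratio to every other sample grows by exactly c
        for _ in range(20):
            mat = pd.DataFrame(rng.integers(1, 1000, size=(30, 5)))
            sf = median_of_ratios(mat)
            scaled = mat.copy()
            c = 3.0
            scaled[2] = mat[2] * c
            sf2 = median_of_ratios(scaled)
            others = [j for j in mat.columns if j != 2]
            for k in others:
                assert sf2[2] / sf2[k] == pytest.approx(c * sf[2] / sf[k], rel=1e-12)
            ratios_before = (sf[others] / sf[others[0]]).to_numpy()
            ratios_after = (sf2[others] / sf2[others[0]]).to_numpy()
            assert ratios_after == pytest.approx(ratios_before, rel=1e-12)
            shuffled = mat.sample(frac=1.0, random_state=0)
            assert median_of_ratios(shuffled).to_numpy() == pytest.approx(sf.to_numpy())

    def test_no_all_positive_gene_errors(self):
        with pytest.raises(ValueError, match="positive"):
            median_of_ratios(pd.DataFrame([[0, 5], [5, 0]]))


class TestNormalize:
    def test_unit_factors_identity_and_zeros_stay_zero(self):
        cm = make_cm([[10, 0], [3, 7]], ["C", "C"])
        sf = pd.Series([1.0, 1.0], index=["s0", "s1"])
        out = normalize(cm, sf)
        assert np.array_equal(out.to_numpy(), cm.counts.to_numpy())

    def test_equalizes_the_worked_example(self):
        cm = make_cm([[10, 20], [30, 60]], ["C", "S"])
        out = normalize(cm, median_of_ratios(cm.counts))
        assert out["s0"].to_numpy() == pytest.approx(out["s1"].to_numpy())


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_matches_brute_force_definition(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 300))
            p = rng.random(m)
            assert bh_adjust(p) == pytest.approx(brute_force_bh(p), abs=1e-12)

    def test_bounds_and_rejects_out_of_range(self, rng):
        p = rng.random(100)
        q = bh_adjust(p)
        assert np.all(q >= p) and np.all(q <= 1)
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestNaiveContrast:
    def test_identical_groups_give_zero_log2fc(self):
        block = [[10, 10, 10, 10], [55, 55, 55, 55]]
        cm = make_cm([row * 2 for row in block], ["C"] * 4 + ["S"] * 4)
        out = naive_contrast(cm, "S")
        assert out["log2fc"].to_numpy() == pytest.approx([0.0, 0.0])

    def test_doubled_counts_give_log2fc_one(self):
        cm = make_cm(
            [[100, 100, 200, 200], [50, 50, 100, 100]], ["C", "C", "S", "S"]
        )
        sf = pd.Series(1.0, index=cm.counts.columns)
        out = naive_contrast(cm, "S", cfg=DEConfig(pseudocount=0.0), size_factors=sf)
        assert out["log2fc"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_flag_logic_and_untestable_genes(self):
        cm = make_cm(
            [[100, 100, 800, 800], [0, 0, 0, 0], [20, 20, 20, 20]],
            ["C", "C", "S", "S"],
        )
        sf = pd.Series(1.0, index=cm.counts.columns)
        out = naive_contrast(cm, "S", size_factors=sf)
        assert bool(out.loc[1, "untestable"])
        assert out.loc[1, "log2fc"] == 0.0 and out.loc[1, "pvalue"] == 1.0
        assert (out["is_high"] <= out["is_sdeg"]).all()

    def test_null_pvalues_roughly_uniform(self, rng):
        n = 2000
        base = rng.lognormal(np.log(100), 0.5, n)
        counts = rng.poisson(np.tile(base[:, None], (1, 8)))
        cm = make_cm(counts, ["C"] * 4 + ["S"] * 4)
        out = naive_contrast(cm, "S")
        from scipy import stats

        ks = stats.kstest(out["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_requires_two_replicates(self):
        cm = make_cm([[1, 2]], ["C", "S"])
        with pytest.raises(ValueError, match="replicates"):
            naive_contrast(cm, "S")


class TestLogPCA:
    def test_duplicated_samples_coincide_and_variance_sums_below_one(self):
        cm = make_cm(
            [[10, 10, 200, 200], [90, 90, 5, 5], [50, 50, 50, 50]],
            ["C", "C", "S", "S"],
        )
        scores, var = log_pca(cm, n_components=2)
        assert scores.loc["s0"].to_numpy() == pytest.approx(scores.loc["s1"].to_numpy())
        assert var.sum() <= 1.0 + 1e-12

    def test_separates_two_condition_groups(self, rng):
        n = 300
        base = rng.lognormal(np.log(100), 1.0, n)
        effect = np.where(rng.random(n) < 0.3, 2.0 ** rng.normal(0, 2, n), 1.0)
        cols = []
        for cond_effect in (np.ones(n),) * 4 + (effect,) * 4:
            cols.append(rng.poisson(base * cond_effect))
        cm = make_cm(np.array(cols).T, ["C"] * 4 + ["S"] * 4)
        scores, _ = log_pca(cm, n_components=2)
        pc1 = scores["PC1"].to_numpy()
        assert max(pc1[:4]) < min(pc1[4:]) or min(pc1[:4]) > max(pc1[4:])

    def test_too_many_components_rejected(self):
        cm = make_cm([[1, 2], [3, 4]], ["C", "S"])
        with pytest.raises(ValueError):
            log_pca(cm, n_components=3)
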