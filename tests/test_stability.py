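import itertools

import numpy as np
import pandas as pd
import pytest

from rgstab import (
    CtMatrix,
    EfficiencyModel,
    bestkeeper,
    deltact,
    genorm,
    normfinder,
    relative_quantities,
    run_all,
)
from rgstab.synth import SynthConfig, generate, _split_seed

from conftest import make_matrix


def add_sample_offsets(m: CtMatrix, offsets) -> CtMatrix:
    return CtMatrix(m.values.add(pd.Series(offsets, index=m.values.columns)))


# ---------------------------------------------------------------------------
# relative quantities
# ---------------------------------------------------------------------------

class TestRelativeQuantities:
    def test_ideal_efficiency_gives_powers_of_two(self):
        q = relative_quantities(make_matrix([[20, 21, 22]]))
        assert q.values.to_numpy().tolist() == [[1.0, 0.5, 0.25]]

    def test_custom_efficiency(self):
        q = relative_quantities(make_matrix([[20, 21, 22]]), 0.9)
        np.testing.assert_allclose(
            q.values.to_numpy()[0], [1.0, 1 / 1.9, 1.9**-2], atol=1e-4
        )

    def test_constant_gene_is_all_ones(self):
        q = relative_quantities(make_matrix([[20, 20, 20]]))
        assert (q.values.to_numpy() == 1.0).all()

    def test_max_per_gene_is_one(self, random_matrix):
        q = relative_quantities(random_matrix(seed=2))
        np.testing.assert_allclose(q.values.max(axis=1), 1.0)
        assert (q.values.to_numpy() > 0).all()

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_efficiency_out_of_range(self, bad):
        with pytest.raises(ValueError, match="outside"):
            EfficiencyModel(bad)

    def test_incomplete_matrix_rejected(self):
        v = pd.DataFrame([[20.0, np.nan]], index=["g"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="complete"):
            relative_quantities(CtMatrix(v))


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

class TestBestKeeper:
    def test_mean_absolute_deviation(self):
        tab = bestkeeper(make_matrix([[19, 21]]))
        assert tab.values["g1"] == pytest.approx(1.0)

    def test_constant_gene_ranks_first(self, toy_matrix):
        tab = bestkeeper(toy_matrix)
        assert tab.values["g1"] == 0.0
        assert tab.ranks["g1"] == 1

    def test_dispersion_below_sample_sd(self, random_matrix):
        # the MAD dispersion is never larger than the n-1 sample SD
        m = random_matrix(seed=4)
        mad = bestkeeper(m).values
        sd = m.values.std(axis=1, ddof=1)
        assert (mad <= sd + 1e-12).all()


# ---------------------------------------------------------------------------
# geNorm (with brute-force oracle)
# ---------------------------------------------------------------------------

def genorm_bruteforce(ct: np.ndarray, genes):
    """Independent stepwise exclusion recomputing every pairwise SD of
    log ratios from scratch each round (E = 1)."""
    y = -np.asarray(ct, dtype=float)  # log2 of 2^-Ct up to per-gene shift
    remaining = list(range(len(genes)))
    exclusions = []
    while len(remaining) > 2:
        m_vals = []
        for j in remaining:
            vs = [np.std(y[j] - y[k], ddof=1) for k in remaining if k != j]
            m_vals.append(np.mean(vs))
        m_arr = np.array(m_vals)
        worst_pos = max(i for i, v in enumerate(m_arr) if v == m_arr.max())
        exclusions.append((genes[remaining[worst_pos]], m_arr[worst_pos]))
        remaining.pop(worst_pos)
    j, k = remaining
    final_m = np.std(y[j] - y[k], ddof=1)
    return exclusions, (genes[j], genes[k]), final_m


class TestGeNorm:
    def test_worked_toy_example(self, toy_matrix):
        tab, trace = genorm(relative_quantities(toy_matrix))
        # initial M = (1, 1.5, 1.5); tie excludes the later gene g3 first
        assert trace.exclusions == [("g3", pytest.approx(1.5))]
        assert trace.final_pair == ("g1", "g2")
        assert trace.final_m == pytest.approx(1.0)
        assert tab.ranks.to_dict() == {"g1": 1, "g2": 2, "g3": 3}
        assert tab.values.to_dict() == pytest.approx({"g1": 1.0, "g2": 1.0, "g3": 1.5})

    def test_shared_offsets_cancel(self):
        # two genes differing by a constant, plus arbitrary per-sample offsets
        base = np.array([20.0, 22.0, 19.0, 21.0])
        offsets = np.array([0.3, -0.2, 0.8, 0.0])
        m = make_matrix(np.vstack([base + offsets, base + 3 + offsets,
                                   base + offsets + [0, 1, 0, 0]]))
        tab, trace = genorm(relative_quantities(m))
        assert trace.final_pair == ("g1", "g2")
        assert trace.final_m == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_genes", [3, 4, 5, 6])
    def test_matches_bruteforce_oracle(self, n_genes, random_matrix):
        for seed in range(5):
            m = random_matrix(n_genes=n_genes, n_samples=8, seed=100 * n_genes + seed)
            tab, trace = genorm(relative_quantities(m))
            exc, pair, final_m = genorm_bruteforce(m.values.to_numpy(), m.gene_ids)
            assert [g for g, _ in trace.exclusions] == [g for g, _ in exc]
            np.testing.assert_allclose(
                [v for _, v in trace.exclusions], [v for _, v in exc], atol=1e-9
            )
            assert set(trace.final_pair) == set(pair)
            assert trace.final_m == pytest.approx(final_m, abs=1e-9)

    def test_trace_length_is_n_minus_2(self, random_matrix):
        m = random_matrix(n_genes=9, seed=1)
        _, trace = genorm(relative_quantities(m))
        assert len(trace.exclusions) == 7

    def test_needs_three_genes(self):
        with pytest.raises(ValueError, match="3 genes"):
            genorm(relative_quantities(make_matrix([[20, 21], [19, 22]])))


# ---------------------------------------------------------------------------
# comparative delta-Ct
# ---------------------------------------------------------------------------

class TestDeltaCt:
    def test_duplicate_gene_pair_has_zero_stability(self):
        m = make_matrix([[20, 21, 23], [20, 21, 23]])
        tab = deltact(m)
        np.testing.assert_allclose(tab.values, 0.0, atol=1e-12)

    def test_worked_toy_example(self, toy_matrix):
        tab = deltact(toy_matrix)
        assert tab.values.to_dict() == pytest.approx(
            {"g1": 1.0, "g2": 1.5, "g3": 1.5}
        )
        assert tab.ranks.to_dict() == {"g1": 1, "g2": 2, "g3": 3}  # tie -> input order

    def test_equals_mean_of_genorm_pairwise_v(self, random_matrix):
        # cross-method identity at E = 1 on the full gene set
        m = random_matrix(n_genes=8, n_samples=10, seed=21)
        y = -m.values.to_numpy()
        n = m.n_genes
        expected = [
            np.mean([np.std(y[g] - y[k], ddof=1) for k in range(n) if k != g])
            for g in range(n)
        ]
        np.testing.assert_allclose(deltact(m).values, expected, atol=1e-9)


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

class TestNormFinder:
    def test_identical_rows_with_offsets_have_zero_rho(self, grouped_design):
        base = np.array([20.0, 21.0, 19.0, 22.0, 20.5, 21.5])
        offsets = np.array([0.4, -0.3, 0.1, 0.0, 0.8, -0.5])
        m = make_matrix(np.vstack([base + offsets, base + 2 + offsets,
                                   base - 1 + offsets]))
        design = grouped_design({"A": 3, "B": 3})
        for use_groups in (False, True):
            tab, res = normfinder(
                relative_quantities(m), design, use_groups=use_groups
            )
            np.testing.assert_allclose(tab.values, 0.0, atol=1e-9)
            np.testing.assert_allclose(res.sigma2.to_numpy(), 0.0, atol=1e-12)

    def test_planted_group_shift_gets_largest_rho(self):
        # one gene shifted +2 cycles in one group, everything else i.i.d.
        cfg = SynthConfig(n_stable=0, n_unstable=0, n_shifted=1,
                          noise_sd=1.0, shift_cycles=2.0)
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            m, design, truth = generate(cfg, seed=_split_seed(42, i))
            tab, _ = normfinder(relative_quantities(m), design, use_groups=True)
            shifted = truth.roles[truth.roles == "group_shifted"].index[0]
            hits += tab.values.idxmax() == shifted
        assert hits / n_rep >= 0.95

    def test_intragroup_variance_clipped_at_zero(self, random_matrix, grouped_design):
        m = random_matrix(n_genes=6, n_samples=8, seed=8)
        design = grouped_design({"A": 4, "B": 4})
        _, res = normfinder(relative_quantities(m), design, use_groups=True)
        assert (res.sigma2.to_numpy() >= 0).all()

    def test_unshrunk_deviations_sum_to_zero_per_group(self, random_matrix,
                                                       grouped_design):
        m = random_matrix(n_genes=7, n_samples=9, seed=13)
        design = grouped_design({"A": 3, "B": 3, "C": 3})
        _, res = normfinder(relative_quantities(m), design, use_groups=True)
        np.testing.assert_allclose(res.d_hat.sum(axis=0), 0.0, atol=1e-9)

    def test_singleton_group_is_error(self, random_matrix, grouped_design):
        m = random_matrix(n_genes=5, n_samples=4, seed=3)
        design = grouped_design({"A": 3, "B": 1})
        with pytest.raises(ValueError, match="fewer than 2"):
            normfinder(relative_quantities(m), design, use_groups=True)


# ---------------------------------------------------------------------------
# orchestration and cross-method properties
# ---------------------------------------------------------------------------

class TestRunAll:
    def test_four_tables_with_permutation_ranks(self, grouped_design):
        m = make_matrix([[20, 20, 20, 20], [20, 21, 22, 21], [20, 19, 18, 19]])
        tables = run_all(m, grouped_design({"A": 2, "B": 2}), dataset="pooled")
        assert set(tables) == {"bestkeeper", "genorm", "deltact", "normfinder"}
        for tab in tables.values():
            assert sorted(tab.ranks) == [1, 2, 3]
            assert tab.dataset == "pooled"

    def test_constant_matrix_all_zero_values(self, grouped_design):
        m = make_matrix(np.full((4, 6), 20.0))
        design = grouped_design({"A": 3, "B": 3})
        for ds in ("pooled", "A"):
            tables = run_all(m, design, dataset=ds)
            for tab in tables.values():
                np.testing.assert_allclose(tab.values, 0.0, atol=1e-9)
                assert sorted(tab.ranks) == [1, 2, 3, 4]

    def test_single_group_dataset_subsets_samples(self, random_matrix,
                                                  grouped_design):
        m = random_matrix(n_genes=5, n_samples=7, seed=17)
        design = grouped_design({"A": 3, "B": 4})
        tables = run_all(m, design, dataset="B")
        # BestKeeper on the subset must equal a direct run on those samples
        direct = bestkeeper(m.subset_samples(design.samples_in("B")), dataset="B")
        pd.testing.assert_series_equal(tables["bestkeeper"].values, direct.values)


class TestStabilityProperties:
    def test_offset_invariance_both_directions(self, random_matrix, grouped_design):
        m = random_matrix(n_genes=8, n_samples=8, seed=31)
        design = grouped_design({"A": 4, "B": 4})
        rng = np.random.default_rng(5)
        shifted = add_sample_offsets(m, rng.normal(0, 2, m.n_samples))
        base = run_all(m, design, dataset="pooled")
        moved = run_all(shifted, design, dataset="pooled")
        for meth in ("genorm", "deltact", "normfinder"):
            np.testing.assert_allclose(
                base[meth].values, moved[meth].values, atol=1e-9
            )
        assert not np.allclose(
            base["bestkeeper"].values, moved["bestkeeper"].values, atol=1e-9
        )

    def test_scaling_deviations_scales_bestkeeper_and_deltact(self, random_matrix):
        m = random_matrix(n_genes=6, n_samples=10, seed=37)
        alpha = 1.7
        mean = m.values.mean(axis=1)
        scaled = CtMatrix(
            m.values.sub(mean, axis=0).mul(alpha).add(mean, axis=0)
        )
        np.testing.assert_allclose(
            bestkeeper(scaled).values, alpha * bestkeeper(m).values, atol=1e-9
        )
        np.testing.assert_allclose(
            deltact(scaled).values, alpha * deltact(m).values, atol=1e-9
        )

    @pytest.mark.parametrize("method", ["bestkeeper", "genorm", "deltact",
                                        "normfinder"])
    def test_noisier_gene_never_improves_rank(self, method, grouped_design):
        # raise one gene's noise SD, all other draws held fixed
        rng = np.random.default_rng(77)
        n_genes, n_samples = 8, 12
        base_noise = rng.normal(0, 1.0, (n_genes, n_samples))
        target_draws = rng.normal(0, 1.0, n_samples)
        baselines = rng.uniform(14, 25, n_genes)[:, None]
        design = grouped_design({"A": 6, "B": 6})
        prev_rank = 0
        for sd in (0.5, 1.5, 3.0):
            noise = base_noise.copy()
            noise[0] = sd * target_draws
            m = make_matrix(baselines + noise)
            tables = run_all(m, design, dataset="pooled")
            rank = int(tables[method].ranks.iloc[0])
            assert rank >= prev_rank
            prev_rank = rank
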