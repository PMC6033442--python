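import itertools

import numpy as np
import pandas as pd
import pytest

from pasi.errors import InputError
from pasi.evaluation import (
    bh_fdr,
    fdr_ratio,
    gene_level_arm,
    group_comparison,
    make_mock,
    mean_fdr,
    pasi_score_fn,
    run_fdr_ratio_experiment,
    sample_size_experiment,
    uncertainty_experiment,
    wilcoxon_groups,
)
from pasi.expression import preprocess
from pasi.simulate import (
    SimulationConfig,
    make_t1d1_like,
    pathway_id_for,
    simulate,
)

from conftest import labels_for


def frame(rows, n_case, n_control):
    labels = labels_for(n_case, n_control)
    values = pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=[f"r{i}" for i in range(len(rows))],
        columns=labels.index,
    )
    return values, labels


class TestWilcoxonGroups:
    def test_fully_separated_small_groups(self):
        values, labels = frame([[1, 2, 3, 4, 5, 6]], 3, 3)
        assert wilcoxon_groups(values, labels).iloc[0] == pytest.approx(0.1)

    def test_rank_sum_at_its_expectation_gives_p_one(self):
        values, labels = frame([[1, 4, 2, 3]], 2, 2)
        assert wilcoxon_groups(values, labels).iloc[0] == 1.0

    def test_constant_rows_carry_no_evidence(self):
        values, labels = frame([[5, 5, 5, 5], [1, 2, 3, 4]], 2, 2)
        p = wilcoxon_groups(values, labels)
        assert p.iloc[0] == 1.0
        assert p.iloc[1] < 1.0 or p.iloc[1] == pytest.approx(2 / 3)

    def test_degenerate_groups_are_an_error(self):
        values, labels = frame([[1, 2, 3, 4]], 2, 2)
        with pytest.raises(InputError):
            wilcoxon_groups(values, labels.iloc[:3])

    def test_ties_fall_back_to_corrected_normal_approximation(self):
        values, labels = frame([[1, 1, 2, 2, 3, 3]], 3, 3)
        p = wilcoxon_groups(values, labels)
        assert 0 < p.iloc[0] <= 1


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert bh_fdr(np.array([0.03])).tolist() == [0.03]
        assert bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])).tolist() == pytest.approx(
            [0.04] * 4
        )
        assert bh_fdr(np.array([0.005, 0.5])).tolist() == pytest.approx([0.01, 0.5])

    def test_out_of_range_p_is_an_error(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(InputError):
                bh_fdr(np.array(bad))


class TestMakeMock:
    def test_smallest_target_design_pools_into_twelve_twelve(self):
        labels = labels_for(13, 11)
        split = make_mock(labels, seed=1)
        assert (split.labels == "control").sum() == 12
        assert (split.labels == "case").sum() == 12

    def test_odd_pool_differs_by_one(self):
        labels = labels_for(4, 3)
        split = make_mock(labels, seed=1)
        assert sorted([(split.labels == g).sum() for g in ("case", "control")]) == [3, 4]

    def test_seeded_determinism_and_minimum_size(self):
        labels = labels_for(3, 3)
        assert make_mock(labels, 9).labels.equals(make_mock(labels, 9).labels)
        with pytest.raises(InputError):
            make_mock(labels_for(2, 1).iloc[:3], seed=0)


class TestFdrRatio:
    def test_examples(self):
        assert fdr_ratio(0.4, [0.4, 0.4]) == 0.0
        assert fdr_ratio(0.13, [0.71] * 10) == pytest.approx(2.449, abs=1e-3)
        assert fdr_ratio(0.25, [0.5, 1.0]) == pytest.approx(np.log2(3))

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.uniform(0.01, 1, size=2)
            assert fdr_ratio(a, [b]) == pytest.approx(-fdr_ratio(b, [a]))

    def test_nonpositive_inputs_are_an_error(self):
        with pytest.raises(InputError):
            fdr_ratio(0.0, [0.5])
        with pytest.raises(InputError):
            fdr_ratio(0.5, [0.5, 0.0])


@pytest.fixture(scope="module")
def small_effect_dataset():
    cfg = SimulationConfig(
        n_pathways=15,
        effect_pathways=tuple(pathway_id_for(i) for i in range(6)),
        effect_size=1.8,
        seed=5,
    )
    ds = simulate(cfg)
    return preprocess(ds.expression), ds


class TestFdrRatioExperiment:
    def test_mock_count_contract_and_determinism(self, small_effect_dataset):
        scaled, ds = small_effect_dataset
        fn = pasi_score_fn(scaled, ds.pathways)
        res = run_fdr_ratio_experiment(fn, scaled.labels, n_mock=3, seed=4)
        again = run_fdr_ratio_experiment(fn, scaled.labels, n_mock=3, seed=4)
        assert len(res.fdr_mock) == 3
        assert res.ratio == again.ratio
        assert res.ratio == pytest.approx(
            -np.log2(res.fdr_real / np.mean(res.fdr_mock))
        )

    def test_effect_data_beats_matched_null_in_paired_seeds(self):
        wins = 0
        n_pairs = 6
        for seed in range(n_pairs):
            ratios = {}
            for eff in (1.0, 2.0):
                cfg = SimulationConfig(
                    n_pathways=15,
                    effect_pathways=tuple(pathway_id_for(i) for i in range(6)),
                    effect_size=eff,
                    seed=seed,
                )
                ds = simulate(cfg)
                scaled = preprocess(ds.expression)
                fn = pasi_score_fn(scaled, ds.pathways)
                ratios[eff] = run_fdr_ratio_experiment(
                    fn, scaled.labels, n_mock=5, seed=seed
                ).ratio
            wins += ratios[2.0] > ratios[1.0]
        assert wins >= n_pairs - 1


class TestGeneLevelArm:
    def test_equals_group_testing_machinery_on_the_gene_matrix(self, small_effect_dataset):
        scaled, _ = small_effect_dataset
        arm = gene_level_arm(scaled)
        direct = group_comparison(scaled.values, scaled.labels)
        assert arm.mean_fdr == direct.mean_fdr
        assert len(arm.table) == len(scaled.gene_ids)

    def test_null_data_has_mean_fdr_near_one(self):
        cfg = SimulationConfig(n_pathways=8, effect_size=1.0, seed=7)
        ds = simulate(cfg)
        scaled = preprocess(ds.expression)
        assert gene_level_arm(scaled).mean_fdr > 0.8


@pytest.fixture(scope="module")
def wide_dataset():
    cfg = SimulationConfig(
        n_pathways=10,
        n_case=14,
        n_control=24,
        n_genes_background=100,
        effect_pathways=tuple(pathway_id_for(i) for i in range(4)),
        effect_size=2.0,
        seed=2,
    )
    return simulate(cfg)


class TestSampleSizeExperiment:
    def test_one_mean_per_size_per_arm_and_determinism(self, wide_dataset):
        table = sample_size_experiment(
            wide_dataset.expression, wide_dataset.pathways,
            sizes=(4, 6), which="case", n_reps=2, seed=3,
        )
        assert len(table) == 4  # 2 sizes x 2 arms
        assert set(table.arm) == {"real", "mock"}
        again = sample_size_experiment(
            wide_dataset.expression, wide_dataset.pathways,
            sizes=(4, 6), which="case", n_reps=2, seed=3,
        )
        assert table.mean_fdr.tolist() == again.mean_fdr.tolist()

    def test_oversized_request_is_an_error(self, wide_dataset):
        with pytest.raises(InputError):
            sample_size_experiment(
                wide_dataset.expression, wide_dataset.pathways, sizes=(50,),
            )

    def test_power_grows_with_case_sample_size(self):
        diffs = []
        for master in range(4):
            cfg = SimulationConfig(
                n_pathways=10,
                n_case=14,
                n_control=40,
                n_genes_background=100,
                effect_pathways=tuple(pathway_id_for(i) for i in range(4)),
                effect_size=2.5,
                seed=100 + master,
            )
            ds = simulate(cfg)
            table = sample_size_experiment(
                ds.expression, ds.pathways, sizes=(4, 14), which="case",
                n_reps=3, seed=master,
            )
            real = table[table.arm == "real"].set_index("size").mean_fdr
            diffs.append(real.loc[14] - real.loc[4])
        assert np.mean(diffs) <= 0


class TestUncertaintyExperiment:
    def test_zero_fraction_detects_intact_top_pathway(self):
        ds = make_t1d1_like(0, effect_size=2.0, n_pathways=40)
        scaled = preprocess(ds.expression)
        table = uncertainty_experiment(
            scaled, ds.pathways, pathway_id_for(0),
            fractions=(0.0,), what="nodes", n_reps=3, top_k=10, seed=0,
        )
        assert table.detection_rate.iloc[0] == 1.0

    def test_rates_reported_for_all_fractions_and_modes(self):
        ds = make_t1d1_like(1, effect_size=2.0, n_pathways=20)
        scaled = preprocess(ds.expression)
        fractions = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
        tables = [
            uncertainty_experiment(
                scaled, ds.pathways, pathway_id_for(0),
                fractions=fractions, what=what, n_reps=2, top_k=5, seed=1,
            )
            for what in ("nodes", "relations")
        ]
        combined = pd.concat(tables)
        assert len(combined) == 12
        assert set(combined.what) == {"nodes", "relations"}
        assert combined.fraction.tolist() == list(fractions) * 2
        assert ((combined.detection_rate >= 0) & (combined.detection_rate <= 1)).all()

    def test_unknown_target_is_an_error(self):
        ds = make_t1d1_like(0, effect_size=1.0, n_pathways=8)
        scaled = preprocess(ds.expression)
        with pytest.raises(InputError):
            uncertainty_experiment(scaled, ds.pathways, "nope")
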