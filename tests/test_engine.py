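"""Wave-synchronous tree simulation: stopping rules, growth, integrity."""

import math

import numpy as np
import pytest
from scipy import stats

from rddsim import (
    Individual,
    MixingModel,
    MomentSpec,
    RecruiterTypeTable,
    RunConfig,
    bb_from_moments,
    offspring_pmf,
    point_mass,
    simulate_batch,
    simulate_tree,
)
from rddsim.engine import trees_to_edge_frame, trees_to_summary_frame
from rddsim.fixtures import overall_mixing_tables

from conftest import homogeneous_config, survival_frequency


class TestStoppingRules:
    def test_no_invitations(self, rng, seed_individual):
        cfg = homogeneous_config(0, 0, 1.0)
        tree = simulate_tree(seed_individual, cfg, rng, check=True)
        assert (tree.size, tree.max_wave, tree.stop_reason) == (0, 0, "no_invitations")

    def test_none_accepted(self, rng, seed_individual):
        cfg = homogeneous_config(4, 0, 0.0)
        tree = simulate_tree(seed_individual, cfg, rng, check=True)
        assert tree.size == 0
        assert tree.stop_reason == "none_accepted"
        assert tree.seed.n_sent == 4 and tree.seed.n_accepted == 0

    def test_deterministic_four_ary_tree(self, rng, seed_individual):
        # every member sends 4, all accepted: waves 4, 16, 64, 256, 1024
        cfg = homogeneous_config(4, 0, 1.0, cap=1000)
        tree = simulate_tree(seed_individual, cfg, rng, check=True)
        assert tree.wave_sizes().tolist() == [0, 4, 16, 64, 256, 1024]
        assert tree.size == 1364
        assert tree.max_wave == 5
        assert tree.stop_reason == "cap_exceeded"

    def test_cap_truncates_recruitment_not_the_wave(self, rng, seed_individual):
        # the wave that crosses the cap is retained in full
        cfg = homogeneous_config(4, 0, 1.0, cap=100)
        tree = simulate_tree(seed_individual, cfg, rng)
        assert tree.wave_sizes().tolist() == [0, 4, 16, 64, 256]
        assert tree.size >= 100

    def test_subcritical_never_reaches_cap(self, seed_individual):
        # mean successful invitations 0.5: extinction is certain
        cfg = homogeneous_config(2.5, 2.0, 0.2, cap=1000)
        for i in range(1000):
            rng = np.random.default_rng(np.random.SeedSequence(5, spawn_key=(i, 1)))
            tree = simulate_tree(seed_individual, cfg, rng)
            assert tree.stop_reason in ("no_invitations", "none_accepted")
            assert tree.size < 1000


class TestBatch:
    def test_reproducible_under_master_seed(self, seed_individual):
        cfg = homogeneous_config(1.5, 1.2, 0.5)
        a = simulate_batch([seed_individual], cfg, 20, master_seed=42)
        b = simulate_batch([seed_individual], cfg, 20, master_seed=42)
        sizes_a = [[t.size for t in d] for d in a]
        assert sizes_a == [[t.size for t in d] for d in b]
        for da, db in zip(a, b):
            for ta, tb in zip(da, db):
                assert np.array_equal(ta.sex_code, tb.sex_code)

    def test_one_seed_many_runs(self, seed_individual):
        cfg = homogeneous_config(1.0, 1.0, 0.5)
        datasets = simulate_batch([seed_individual], cfg, 100, master_seed=1)
        assert len(datasets) == 100 and all(len(d) == 1 for d in datasets)

    def test_expected_total_progeny_subcritical(self, seed_individual):
        # homogeneous subcritical chain: E[tree size] = m / (1 - m)
        mu, s2, p = 2.0, 2.0, 0.3  # m = 0.6
        cfg = homogeneous_config(mu, s2, p)
        datasets = simulate_batch([seed_individual], cfg, 4000, master_seed=9)
        sizes = np.array([d[0].size for d in datasets])
        expected = 0.6 / 0.4
        assert abs(sizes.mean() - expected) < 3 * sizes.std(ddof=1) / math.sqrt(sizes.size)


class TestGrowthAndAgreement:
    def test_wave_growth_ratio_matches_reproduction_number(self, seed_individual):
        # successive wave totals grow by m = mu * p on average
        mu, s2, p = 2.0, 2.0, 0.4  # m = 0.8, subcritical: every member acts
        cfg = homogeneous_config(mu, s2, p)
        datasets = simulate_batch([seed_individual], cfg, 5000, master_seed=17)
        counts = np.zeros(30)
        for d in datasets:
            ws = d[0].wave_sizes()
            counts[: ws.size] += ws
        counts[0] = len(datasets)  # wave 0 = the seeds
        m = mu * p
        d_off = offspring_pmf(bb_from_moments(MomentSpec(mu, s2), 4), p)
        var_off = sum(k * k * pk for k, pk in enumerate(d_off.pmf)) - m * m
        for w in range(0, 3):
            ratio = counts[w + 1] / counts[w]
            se = math.sqrt(var_off / counts[w])
            assert abs(ratio - m) < 3 * se

    def test_mean_size_monotone_in_acceptance(self, seed_individual):
        means = []
        for p in (0.3, 0.5, 0.7):
            cfg = homogeneous_config(2.0, 2.0, p, cap=500)
            ds = simulate_batch([seed_individual], cfg, 800, master_seed=23)
            means.append(np.mean([d[0].size for d in ds]))
        assert means[0] < means[1] < means[2]

    def test_survival_matches_pgf_fixed_point(self):
        # two quick parameter sets; the full 6-point design runs in the
        # acceptance suite
        for mu, s2, p, master in [(1.5, 1.2, 1.0, 31), (2.0, 3.5, 1.0, 32)]:
            d = offspring_pmf(bb_from_moments(MomentSpec(mu, s2), 4), p)
            from rddsim import extinction_probability

            q = extinction_probability(d)
            sim = survival_frequency(mu, s2, p, 1000, master)
            se = math.sqrt(q * (1 - q) / 1000)
            assert abs(sim - (1 - q)) < 3 * se + 0.01


class TestSeedRecruiteeStratification:
    def test_seed_stratum_controls_wave_zero_only(self, rng, seed_individual):
        # seeds send nothing -> tree dies immediately even though
        # recruitees would be highly active
        table = RecruiterTypeTable.homogeneous(
            point_mass(4, 4), 1.0, seed_invitations=point_mass(0, 4)
        )
        cfg = RunConfig(types=table, mixing=MixingModel.random())
        tree = simulate_tree(seed_individual, cfg, rng)
        assert tree.size == 0 and tree.stop_reason == "no_invitations"

        # seeds send 4, recruitees nothing -> exactly one wave
        table2 = RecruiterTypeTable.homogeneous(
            point_mass(0, 4), 1.0, seed_invitations=point_mass(4, 4), seed_acceptance=1.0
        )
        cfg2 = RunConfig(types=table2, mixing=MixingModel.random())
        tree2 = simulate_tree(seed_individual, cfg2, rng)
        assert tree2.size == 4 and tree2.max_wave == 1


@pytest.fixture(scope="module")
def trees():
    seed = Individual(
        id="s0", recruiter_id=None, wave=0, sex="M", age_group="a1", education="A"
    )
    cfg = homogeneous_config(
        1.96, 2.61, 1.0, cap=300,
        mixing=MixingModel(tables=overall_mixing_tables()),
    )
    ds = simulate_batch([seed], cfg, 50, master_seed=77)
    return [t for d in ds for t in d]


class TestTreeIntegrity:
    def test_waves_contiguous_and_ids_unique(self, trees):
        for tree in trees:
            if tree.size == 0:
                continue
            waves = np.unique(tree.wave)
            assert waves.tolist() == list(range(1, tree.max_wave + 1))
            ids = [i.id for i in tree.all_individuals()]
            assert len(ids) == len(set(ids))
            # every recruitee's wave is its recruiter's wave + 1
            parent_wave = np.where(
                tree.recruiter_index < 0, 0, tree.wave[np.maximum(tree.recruiter_index, 0)]
            )
            assert np.all(tree.wave == parent_wave + 1)
            assert np.all(tree.n_accepted <= tree.n_sent)
            assert np.all(tree.n_sent <= 4)

    def test_edge_and_summary_export(self, trees):
        edges = trees_to_edge_frame([trees[:3]])
        assert {"dataset", "run", "tree_id", "recruitee_id", "wave", "sex"} <= set(edges.columns)
        summary = trees_to_summary_frame([trees[:3]])
        assert summary["size"].tolist() == [t.size for t in trees[:3]]

    def test_grandparent_independent_given_parent(self, trees):
        # first-order Markov chain in characteristics: conditional on the
        # direct recruiter's sex, a recruitee's sex is independent of the
        # grandparent's sex
        table = np.zeros((2, 2, 2))  # parent sex x grandparent sex x child sex
        for tree in trees:
            seed_sex = 0 if tree.seed.sex == "F" else 1
            for i in np.flatnonzero(tree.wave >= 2):
                p = int(tree.recruiter_index[i])
                g = int(tree.recruiter_index[p])
                gs = seed_sex if g < 0 else int(tree.sex_code[g])
                table[int(tree.sex_code[p]), gs, int(tree.sex_code[i])] += 1
        for ps in (0, 1):
            sub = table[ps]
            if sub.sum(axis=1).min() > 20:
                assert stats.chi2_contingency(sub).pvalue > 0.001
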