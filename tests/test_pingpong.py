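import numpy as np
import pytest
from sklearn.base import clone

from conftest import make_tensor, module_of, split_branch
from oracle import naive_improving_substitutions
from tfrewire import (
    BlockShape,
    EnumerationTooLargeError,
    PingPongMaximizer,
    SignShortageError,
    ValidationError,
    brute_force_best_block,
    run_pingpong,
    skew_matrix,
    step_g,
    step_tf,
    verify_max_block,
)
from tfrewire.synthetic import random_tensor


class TestStepTF:
    def test_two_factors_one_each_side(self):
        P = np.zeros((2, 1, 4))
        P[0, 0, :2] = 0.9  # positive skew
        P[1, 0, 2:] = 0.9  # negative skew
        tensor = make_tensor(P)
        T, T_star = step_tf(tensor, ["g001"], BlockShape(1, 1, 1), split_branch(tensor, 2))
        assert T == ("TF001",) and T_star == ("TF002",)

    def test_top_m_matches_full_sort(self):
        tensor = random_tensor(21, 6, 4, 6)
        branch = split_branch(tensor, 3)
        G = tensor.gene_ids[:3]
        S = skew_matrix(tensor, branch, G)
        scores = {x: S[tensor.tf_index[x]].mean() for x in tensor.tf_ids}
        ranked = sorted(tensor.tf_ids, key=lambda x: (-round(scores[x], 8), x))
        n_pos = sum(round(s, 8) > 0 for s in scores.values())
        n_neg = sum(round(s, 8) < 0 for s in scores.values())
        m, m_star = min(2, n_pos), min(1, n_neg)
        if m and m_star:
            T, T_star = step_tf(tensor, G, BlockShape(m, m_star, len(G)), branch)
            assert set(T) == set(ranked[:m])
            assert set(T_star) == set(ranked[-m_star:])

    def test_sign_shortage_raises(self):
        # all factors skewed the same way: no negative scores available
        P = np.zeros((3, 2, 4))
        P[:, :, :2] = 0.9
        tensor = make_tensor(P)
        with pytest.raises(SignShortageError):
            step_tf(tensor, tensor.gene_ids, BlockShape(1, 1, 2), split_branch(tensor, 2))

    def test_rounded_tie_breaks_alphabetically(self):
        P = np.zeros((3, 1, 4))
        P[0, 0, :2] = 0.8  # TF001 and TF002 tie exactly
        P[1, 0, :2] = 0.8
        P[2, 0, 2:] = 0.8
        tensor = make_tensor(P)
        T, _ = step_tf(tensor, ["g001"], BlockShape(1, 1, 1), split_branch(tensor, 2))
        assert T == ("TF001",)

    def test_module51_planted_teams(self, m51):
        T, T_star = step_tf(m51.tensor, list(m51.block.G), BlockShape(3, 1, 19), m51.branch)
        assert T == ("FHL1", "RAP1", "SFP1")
        assert T_star == ("TBF1",)


class TestStepG:
    def test_mg_equals_module_returns_all(self):
        tensor = random_tensor(31, 4, 5, 6)
        module = module_of(tensor)
        branch = split_branch(tensor, 3)
        G = step_g(tensor, ["TF001"], ["TF002"], module, 5, branch)
        assert set(G) == set(tensor.gene_ids)

    def test_top_genes_match_exhaustive_scoring(self):
        tensor = random_tensor(32, 4, 6, 6)
        module = module_of(tensor)
        branch = split_branch(tensor, 3)
        T, T_star = ["TF001", "TF003"], ["TF002"]
        S = skew_matrix(tensor, branch, tensor.gene_ids)
        t_rows = [tensor.tf_index[x] for x in T]
        ts_rows = [tensor.tf_index[x] for x in T_star]
        contrast = {g: S[t_rows, i].mean() - S[ts_rows, i].mean()
                    for i, g in enumerate(tensor.gene_ids)}
        ranked = sorted(tensor.gene_ids, key=lambda g: (-round(contrast[g], 8), g))
        G = step_g(tensor, T, T_star, module, 3, branch)
        assert set(G) == set(ranked[:3])

    def test_mg_larger_than_module_rejected(self):
        tensor = random_tensor(33, 3, 4, 6)
        with pytest.raises(ValidationError):
            step_g(tensor, ["TF001"], ["TF002"], module_of(tensor), 5,
                   split_branch(tensor, 3))

    def test_planted_signal_genes_selected(self, planted):
        block = planted.block
        G = step_g(planted.tensor, block.T, block.T_star, planted.module, 19,
                   planted.branch)
        assert set(G) == set(block.G)


class TestRunPingPong:
    def test_planted_block_is_a_one_iteration_fixed_point(self, planted):
        result = run_pingpong(planted.tensor, planted.module, planted.block.G,
                              BlockShape(3, 1, 19), planted.branch)
        assert result.iterations == 1
        assert not result.terminated_early
        assert result.score_trace[0] == result.score_trace[-1]
        assert set(result.block.G) == set(planted.block.G)
        assert set(result.block.T) == set(planted.block.T)

    def test_trace_monotone_and_final_score_consistent(self):
        from tfrewire.skewness import block_skew

        for seed in range(10):
            tensor = random_tensor(seed + 100, 5, 6, 6)
            module = module_of(tensor)
            branch = split_branch(tensor, 3)
            try:
                result = run_pingpong(tensor, module, tensor.gene_ids[:3],
                                      BlockShape(1, 1, 3), branch)
            except SignShortageError:
                continue
            trace = result.score_trace
            assert all(a <= b for a, b in zip(trace, trace[1:]))
            assert round(block_skew(tensor, result.block), 8) == pytest.approx(
                round(result.block.score, 8), abs=0
            )

    def test_fixed_point_idempotence(self):
        for seed in range(10):
            tensor = random_tensor(seed + 200, 5, 6, 6)
            module = module_of(tensor)
            branch = split_branch(tensor, 3)
            try:
                result = run_pingpong(tensor, module, tensor.gene_ids[:2],
                                      BlockShape(2, 1, 2), branch)
            except SignShortageError:
                continue
            if result.terminated_early:
                continue
            block = result.block
            T, T_star = step_tf(tensor, block.G, block.shape, branch)
            assert (T, T_star) == (block.T, block.T_star)
            G = step_g(tensor, T, T_star, module, len(block.G), branch)
            assert G == block.G

    def test_wrong_g0_size_rejected(self):
        tensor = random_tensor(42, 3, 4, 6)
        with pytest.raises(ValidationError):
            run_pingpong(tensor, module_of(tensor), tensor.gene_ids[:2],
                         BlockShape(1, 1, 3), split_branch(tensor, 3))


class TestVerifyMaxBlock:
    def test_converged_blocks_verify(self):
        for seed in range(8):
            tensor = random_tensor(seed + 300, 5, 5, 6)
            module = module_of(tensor)
            branch = split_branch(tensor, 3)
            try:
                result = run_pingpong(tensor, module, tensor.gene_ids[:2],
                                      BlockShape(1, 1, 2), branch)
            except SignShortageError:
                continue
            if result.terminated_early:
                continue
            ok, witnesses = verify_max_block(tensor, module, result.block)
            assert ok, witnesses

    def test_weakened_block_yields_witness(self, planted):
        from dataclasses import replace

        block = planted.block
        # swap one signal gene for a background gene: strictly worse
        weak_g = tuple(sorted(set(block.G) - {block.G[0]} | {"g030"}))
        weak = replace(block, G=weak_g)
        ok, witnesses = verify_max_block(planted.tensor, planted.module, weak)
        assert not ok
        assert any(cls == "G" and inserted == block.G[0]
                   for cls, _, inserted, _ in witnesses)

    def test_agrees_with_naive_substitution_search(self):
        for seed in range(5):
            tensor = random_tensor(seed + 400, 4, 4, 6)
            module = module_of(tensor)
            branch = split_branch(tensor, 2)
            try:
                result = run_pingpong(tensor, module, tensor.gene_ids[:2],
                                      BlockShape(1, 1, 2), branch)
            except SignShortageError:
                continue
            ok, _ = verify_max_block(tensor, module, result.block)
            _, improving = naive_improving_substitutions(tensor, module, result.block)
            assert ok == (not improving)


class TestBruteForce:
    def test_tiny_enumeration_beats_or_matches_pingpong(self):
        tensor = random_tensor(7, 3, 3, 6)
        module = module_of(tensor)
        branch = split_branch(tensor, 3)
        best = brute_force_best_block(tensor, module, BlockShape(1, 1, 1), branch)
        try:
            pp = run_pingpong(tensor, module, tensor.gene_ids[:1],
                              BlockShape(1, 1, 1), branch)
            assert round(best.score, 8) >= round(pp.block.score, 8)
        except SignShortageError:
            pass
        assert round(best.score, 8) >= -2.0

    def test_recovers_planted_block_on_small_instance(self):
        from tfrewire.synthetic import PlantSpec, plant_tensor

        result = plant_tensor(PlantSpec(n_tfs=4, n_genes=5, n_species=6, n_clade=3,
                                        m=1, m_star=1, m_g=2, noise=0.02, seed=5))
        module = module_of(result.tensor)
        best = brute_force_best_block(result.tensor, module, BlockShape(1, 1, 2),
                                      result.branch)
        assert set(best.T) == set(result.block.T)
        assert set(best.T_star) == set(result.block.T_star)
        assert set(best.G) == set(result.block.G)

    def test_refuses_large_instances(self):
        tensor = random_tensor(8, 6, 6, 4)
        with pytest.raises(EnumerationTooLargeError):
            brute_force_best_block(tensor, module_of(tensor), BlockShape(2, 2, 3),
                                   split_branch(tensor, 2), max_blocks=10)


class TestEstimator:
    def test_fit_sets_attributes_and_clones(self, planted):
        est = PingPongMaximizer(module=planted.module, branch=planted.branch,
                                m=3, m_star=1, m_g=19,
                                initial_genes=list(planted.block.G))
        cloned = clone(est)  # sklearn param contract
        cloned.fit(planted.tensor)
        assert cloned.score_ == pytest.approx(planted.block.score, abs=1e-9)
        assert cloned.n_iter_ == 1
        assert not cloned.terminated_early_
        assert set(cloned.get_params()) >= {"module", "branch", "m", "m_star", "m_g"}
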