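import numpy as np
import pytest

from conftest import make_tensor, module_of, split_branch
from tfrewire import (
    Block,
    BlockFinder,
    DegenerateBlockError,
    attrition_step,
    block_skew,
    find_block,
    importance_scores,
)
from tfrewire.synthetic import PlantSpec, plant_tensor


def _two_species_tensor(pair_skews, genes=None):
    """Tensor with one species per side so skew(x, g) = P_m - P_ms exactly.

    `pair_skews` is an (n_tf, n_gene) array of desired skews in [-1, 1].
    """
    sk = np.asarray(pair_skews, dtype=float)
    P = np.zeros((sk.shape[0], sk.shape[1], 2))
    P[:, :, 0] = np.clip(sk, 0, None)
    P[:, :, 1] = np.clip(-sk, 0, None)
    return make_tensor(P, genes=genes)


class TestImportance:
    def test_ratios_within_each_class(self):
        # T scores +0.5/+0.25; T* scores -0.2/-0.4; single gene
        tensor = _two_species_tensor([[0.5], [0.25], [-0.2], [-0.4]])
        branch = split_branch(tensor, 1)
        block = Block(["TF001", "TF002"], ["TF003", "TF004"], ["g001"], branch, 0.0)
        table = importance_scores(tensor, block).set_index("element")
        assert table.loc["TF001", "importance"] == pytest.approx(1.0)
        assert table.loc["TF002", "importance"] == pytest.approx(0.5)
        assert table.loc["TF003", "importance"] == pytest.approx(0.5)
        assert table.loc["TF004", "importance"] == pytest.approx(1.0)
        assert table.loc["g001", "importance"] == pytest.approx(1.0)

    def test_weak_gene_importance_is_its_contrast_ratio(self):
        # gene 2 carries half the contrast of gene 1
        tensor = _two_species_tensor([[0.8, 0.4], [-0.2, -0.1]])
        branch = split_branch(tensor, 1)
        block = Block(["TF001"], ["TF002"], ["g001", "g002"], branch, 0.0)
        table = importance_scores(tensor, block).set_index("element")
        assert table.loc["g002", "importance"] == pytest.approx(0.5)

    def test_degenerate_team_rejected(self):
        tensor = _two_species_tensor([[-0.5], [-0.2]])
        branch = split_branch(tensor, 1)
        block = Block(["TF001"], ["TF002"], ["g001"], branch, 0.0)
        with pytest.raises(DegenerateBlockError):
            importance_scores(tensor, block)


class TestAttritionStep:
    def test_unique_minimum_gene_removed(self):
        tensor = _two_species_tensor([[0.8, 0.8, 0.1], [-0.8, -0.8, -0.1]])
        branch = split_branch(tensor, 1)
        block = Block(["TF001"], ["TF002"], ["g001", "g002", "g003"], branch, 0.0)
        shape, element, cls = attrition_step(tensor, module_of(tensor), block)
        assert (cls, element) == ("G", "g003")
        assert shape.as_tuple() == (1, 1, 2)

    def test_tied_minimum_removed_alphabetically(self):
        tensor = _two_species_tensor([[0.8, 0.1, 0.1], [-0.8, -0.1, -0.1]])
        branch = split_branch(tensor, 1)
        block = Block(["TF001"], ["TF002"], ["g001", "g002", "g003"], branch, 0.0)
        _, element, cls = attrition_step(tensor, module_of(tensor), block)
        assert (cls, element) == ("G", "g002")

    def test_emptying_a_class_signals_stop(self):
        from tfrewire.exceptions import AttritionStopSignal

        tensor = _two_species_tensor([[0.8, 0.8], [-0.1, -0.1]])
        branch = split_branch(tensor, 1)
        block = Block(["TF001"], ["TF002"], ["g001", "g002"], branch, 0.0)
        with pytest.raises(AttritionStopSignal):
            attrition_step(tensor, module_of(tensor), block)


class TestFindBlock:
    def test_threshold_one_shrinks_to_minimal_block(self):
        result = plant_tensor(PlantSpec(n_tfs=6, n_genes=8, n_species=8, n_clade=4,
                                        m=2, m_star=1, m_g=4, seed=3))
        found = find_block(result.tensor, result.module, result.branch,
                           importance_threshold=1.0)
        assert found.block.shape.as_tuple() == (1, 1, 1)
        assert found.converged

    def test_threshold_near_zero_keeps_first_max_block(self):
        # every gene carries signal, so all first-round importances are ~1
        result = plant_tensor(PlantSpec(n_tfs=6, n_genes=6, n_species=10, n_clade=5,
                                        m=2, m_star=2, m_g=6, noise=0.0, seed=4))
        found = find_block(result.tensor, result.module, result.branch,
                           importance_threshold=1e-6)
        assert found.converged
        assert len(found.trajectory) == 1
        assert set(found.block.G) == set(result.tensor.gene_ids)

    def test_recovers_planted_block(self, planted):
        found = find_block(planted.tensor, planted.module, planted.branch)
        assert found.converged and found.reportable
        assert set(found.block.T) == set(planted.block.T)
        assert set(found.block.T_star) == set(planted.block.T_star)
        assert set(found.block.G) == set(planted.block.G)

    def test_trajectory_shrinks_in_unit_steps_with_monotone_score(self, planted):
        found = find_block(planted.tensor, planted.module, planted.branch)
        deletions = [r for r in found.trajectory if r.removed_element is not None]
        totals = [r.shape.total for r in deletions] + [found.trajectory[-1].shape.total]
        assert all(a - b == 1 for a, b in zip(totals, totals[1:]))
        scores = [r.score for r in found.trajectory if not r.terminated_early]
        assert all(a <= b for a, b in zip(scores, scores[1:]))

    def test_final_importances_reach_threshold(self, planted):
        found = find_block(planted.tensor, planted.module, planted.branch,
                           importance_threshold=0.5)
        assert float(found.importances["importance"].min()) >= 0.5

    def test_final_score_recomputable(self, planted):
        found = find_block(planted.tensor, planted.module, planted.branch)
        assert block_skew(planted.tensor, found.block) == pytest.approx(
            found.block.score, abs=0
        )

    def test_deterministic_trajectories(self, planted):
        a = find_block(planted.tensor, planted.module, planted.branch)
        b = find_block(planted.tensor, planted.module, planted.branch)
        assert a.block == b.block
        assert [(r.shape, r.removed_element) for r in a.trajectory] == [
            (r.shape, r.removed_element) for r in b.trajectory
        ]

    def test_custom_start_set_reaches_same_block(self, planted):
        rng = np.random.default_rng(0)
        g0 = list(rng.choice(planted.tensor.gene_ids, size=36, replace=False))
        found = find_block(planted.tensor, planted.module, planted.branch,
                           initial_genes=g0)
        assert set(found.block.G) == set(planted.block.G)
        assert set(found.block.T) == set(planted.block.T)

    def test_removed_factor_can_reenter_later(self, planted):
        # attrition may delete a factor/gene whose name later reappears in a
        # block: membership is recomputed from scratch every round, so
        # nothing is permanently banned.  Assert the mechanism: the planted
        # team members survive every deletion round despite churn around them.
        found = find_block(planted.tensor, planted.module, planted.branch)
        removed = {r.removed_element for r in found.trajectory if r.removed_element}
        assert not removed & set(planted.block.T)
        assert not removed & set(planted.block.T_star)


class TestBlockFinderEstimator:
    def test_fit_attributes(self, planted):
        est = BlockFinder(module=planted.module, branch=planted.branch).fit(planted.tensor)
        assert est.converged_
        assert set(est.block_.T) == set(planted.block.T)
        assert est.score_ == pytest.approx(planted.block.score, abs=0.1)
        params = est.get_params()
        assert params["importance_threshold"] == 0.5
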