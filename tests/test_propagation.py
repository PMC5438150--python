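"""The double label propagation core: updates, termination, full runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlpca import (
    UNASSIGNED,
    DlpcaConfig,
    LabelState,
    PathogenicAnnotation,
    derive_lambda_params,
    has_converged,
    init_labels,
    lambda_params_from_averages,
    run_dlpca,
    run_mlpa,
    update_category_label,
    update_pathogenic_label,
)

from conftest import manual_seed_set, net_from_weights, random_network


def make_cfg(**kw):
    kw.setdefault("m", 2)
    return DlpcaConfig(**kw)


def state_with(net, category, pathogenic):
    return LabelState(
        node_ids=net.node_ids,
        category=np.asarray(category, dtype=int),
        pathogenic=np.asarray(pathogenic, dtype=float),
    )


class TestInitLabels:
    def test_training_genes_get_signed_scores(self, two_cliques, small_annotation):
        seeds = manual_seed_set(["a0", "b0"])
        state = init_labels(two_cliques, seeds, small_annotation)
        lookup = state.pathogenic_of()
        assert lookup["a0"] == 1.0 and lookup["a1"] == 1.0
        assert lookup["b0"] == -1.0 and lookup["b1"] == -1.0
        assert lookup["a3"] == 0.0

    def test_seed_categories_and_unassigned_rest(self, two_cliques, small_annotation):
        seeds = manual_seed_set(["a0", "b0"])
        state = init_labels(two_cliques, seeds, small_annotation)
        cats = state.category_of()
        assert cats["a0"] == 0 and cats["b0"] == 1
        assert cats["a1"] == UNASSIGNED

    def test_empty_seed_set_rejected(self, two_cliques, small_annotation):
        from dlpca import SeedSet

        with pytest.raises(ValueError, match="empty"):
            init_labels(two_cliques, SeedSet((), ()), small_annotation)

    def test_unknown_annotation_genes_warned_and_ignored(
        self, two_cliques, caplog
    ):
        annot = PathogenicAnnotation(frozenset({"a0", "ghost"}), frozenset())
        seeds = manual_seed_set(["a0"])
        import logging

        with caplog.at_level(logging.WARNING, logger="dlpca.propagation"):
            state = init_labels(two_cliques, seeds, annot)
        assert "ghost" in caplog.text
        assert state.pathogenic_of()["a0"] == 1.0


class TestCategoryUpdate:
    def test_single_candidate_label_wins(self, two_cliques):
        category = [0] + [UNASSIGNED] * 11
        state = state_with(two_cliques, category, np.zeros(12))
        cfg = make_cfg()
        assert update_category_label(two_cliques, state, cfg, "a3") == 0

    def test_pathogenic_term_breaks_weight_degree_tie(self):
        # node i (l=1) with one neighbour per label, equal weight and count;
        # the f1 neighbour has l=+1, the f2 neighbour l=-1
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.2
        W[0, 2] = W[2, 0] = 0.2
        net = net_from_weights(W, node_ids=["i", "n1", "n2", "x"])
        state = state_with(net, [UNASSIGNED, 0, 1, UNASSIGNED], [1.0, 1.0, -1.0, 0.0])
        cfg = make_cfg(lambda1=1.0, lambda2=1.0, lambda3=1.0)
        # hand evaluation: score(f1) = 0.2 + 1 + 1, score(f2) = 0.2 + 1 - 1
        assert update_category_label(net, state, cfg, "i") == 0

    def test_no_labelled_neighbour_stays_unassigned(self, two_cliques):
        state = state_with(two_cliques, [UNASSIGNED] * 12, np.zeros(12))
        assert (
            update_category_label(two_cliques, state, make_cfg(), "a0") == UNASSIGNED
        )

    def test_isolated_node_stays_unassigned(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        net = net_from_weights(W)
        state = state_with(net, [0, 0, UNASSIGNED], [0, 0, 0])
        assert update_category_label(net, state, make_cfg(), "g2") == UNASSIGNED

    def test_reduces_to_weighted_majority_without_degree_and_pathogenic(self):
        rng = np.random.default_rng(5)
        net = random_network(rng, 12, p=0.5, isolated_ok=False)
        category = rng.integers(0, 3, size=12)
        state = state_with(net, category, rng.uniform(-1, 1, size=12))
        cfg = make_cfg(lambda1=1.0, lambda2=0.0, lambda3=0.0)
        for node in net.node_ids:
            i = net.index(node)
            votes = {}
            for j in np.flatnonzero(net.A[i]):
                votes[category[j]] = votes.get(category[j], 0.0) + net.W[i, j]
            best = max(votes.values())
            winners = [lab for lab, v in votes.items() if v >= best - 1e-12]
            expect = category[i] if category[i] in winners else min(winners)
            assert update_category_label(net, state, cfg, node) == expect


class TestPathogenicUpdate:
    def test_zero_state_is_fixed_point(self, two_cliques):
        state = state_with(two_cliques, [0] * 6 + [1] * 6, np.zeros(12))
        assert update_pathogenic_label(two_cliques, state, make_cfg(), "a2") == 0.0

    def test_consensus_value_follows_term_weights(self, two_cliques):
        # all scores 1, all of a node's neighbours share its label:
        # new value is beta1 * 1 + beta3 * 1
        cfg = make_cfg(beta1=0.15, beta2=0.15, beta3=0.7)
        state = state_with(two_cliques, [0] * 6 + [1] * 6, np.ones(12))
        got = update_pathogenic_label(two_cliques, state, cfg, "a2")
        assert got == pytest.approx(cfg.beta1 + cfg.beta3)

    def test_matches_direct_term_by_term_sum(self):
        rng = np.random.default_rng(31)
        net = random_network(rng, 10, p=0.5)
        category = rng.integers(-1, 3, size=10)  # includes UNASSIGNED
        labels = rng.uniform(-1, 1, size=10)
        state = state_with(net, category, labels)
        cfg = make_cfg(beta1=0.2, beta2=0.1, beta3=0.7)
        for node in net.node_ids:
            i = net.index(node)
            same = diff = 0.0
            for j in np.flatnonzero(net.A[i]):
                if category[i] != UNASSIGNED and category[j] == category[i]:
                    same += net.P[i, j] * labels[j]
                else:
                    diff += net.P[i, j] * labels[j]
            expected = cfg.beta1 * same + cfg.beta2 * diff + cfg.beta3 * labels[i]
            got = update_pathogenic_label(net, state, cfg, node)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_clamped_training_genes_keep_initial_scores(self, two_cliques):
        annot = PathogenicAnnotation(frozenset({"a0"}), frozenset({"b0"}))
        cfg = make_cfg(clamp_training_labels=True, pathogenic_tol=1e-6, max_iter=5)
        result = run_dlpca(
            two_cliques, annot, cfg, seeds=manual_seed_set(["a0", "b0"])
        )
        assert result.pathogenic["a0"] == 1.0
        assert result.pathogenic["b0"] == -1.0


class TestHasConverged:
    def setup_method(self):
        self.net = None

    def _states(self, two_cliques, cat_change, delta):
        a = state_with(two_cliques, [0] * 12, np.zeros(12))
        cat = [0] * 12
        if cat_change:
            cat[3] = 1
        b = state_with(two_cliques, cat, np.full(12, delta))
        return a, b

    def test_identical_states_converged(self, two_cliques):
        a, b = self._states(two_cliques, cat_change=False, delta=0.0)
        assert has_converged(a, b, make_cfg())

    def test_both_conditions_failing_continues(self, two_cliques):
        a, b = self._states(two_cliques, cat_change=True, delta=0.5)
        assert not has_converged(a, b, make_cfg(pathogenic_tol=0.1))

    def test_small_pathogenic_change_suffices_despite_category_flip(
        self, two_cliques
    ):
        a, b = self._states(two_cliques, cat_change=True, delta=0.05)
        assert has_converged(a, b, make_cfg(pathogenic_tol=0.1))

    def test_and_semantics_requires_both(self, two_cliques):
        a, b = self._states(two_cliques, cat_change=True, delta=0.05)
        assert not has_converged(a, b, make_cfg(termination="and"))

    def test_mismatched_node_sets_rejected(self, two_cliques, triangle):
        a = state_with(two_cliques, [0] * 12, np.zeros(12))
        c = state_with(triangle, [0] * 3, np.zeros(3))
        with pytest.raises(ValueError, match="node sets"):
            has_converged(a, c, make_cfg())


class TestRuns:
    def test_two_cliques_recovered_quickly(self, two_cliques, small_annotation):
        cfg = make_cfg(rng_seed=3)
        result = run_dlpca(
            two_cliques, small_annotation, cfg, seeds=manual_seed_set(["a0", "b0"])
        )
        modules = result.partition.modules
        assert sorted(map(sorted, modules.values())) == [
            [f"a{i}" for i in range(6)],
            [f"b{i}" for i in range(6)],
        ]
        assert result.iterations <= 3
        assert result.converged

    def test_mlpa_recovers_cliques_and_single_seed_floods(self, two_cliques):
        result = run_mlpa(two_cliques, make_cfg(), seeds=manual_seed_set(["a0", "b0"]))
        assert result.partition.n_modules == 2
        lone = run_mlpa(two_cliques, make_cfg(m=1), seeds=manual_seed_set(["a0"]))
        # label floods its own component; the other clique is unreachable
        assigned = set(lone.partition.assignment)
        assert assigned == {f"a{i}" for i in range(6)}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dlpca_without_extra_terms_equals_mlpa(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, 25, p=0.25, isolated_ok=False)
        cfg = make_cfg(
            m=5, lambda1=1.0, lambda2=0.0, lambda3=0.0,
            pathogenic_tol=1e-9, rng_seed=seed,
        )
        annot = PathogenicAnnotation(
            frozenset(list(net.node_ids)[:3]), frozenset(list(net.node_ids)[3:6])
        )
        a = run_dlpca(net, annot, cfg)
        b = run_mlpa(net, cfg)
        assert a.partition.assignment == b.partition.assignment
        assert a.partition.scatters == b.partition.scatters

    def test_identical_seeds_give_identical_results(self):
        rng = np.random.default_rng(8)
        net = random_network(rng, 20, p=0.3, isolated_ok=False)
        annot = PathogenicAnnotation(
            frozenset(list(net.node_ids)[:4]), frozenset(list(net.node_ids)[4:8])
        )
        cfg = make_cfg(m=4, rng_seed=99)
        a = run_dlpca(net, annot, cfg)
        b = run_dlpca(net, annot, cfg)
        assert a.partition == b.partition
        assert a.pathogenic == b.pathogenic
        assert a.iterations == b.iterations

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 1000),
        b1=st.floats(0.05, 0.45),
        b2=st.floats(0.05, 0.45),
    )
    def test_pathogenic_scores_stay_bounded(self, seed, b1, b2):
        rng = np.random.default_rng(seed)
        net = random_network(rng, 15, p=0.3, isolated_ok=False)
        annot = PathogenicAnnotation(
            frozenset(list(net.node_ids)[:5]), frozenset(list(net.node_ids)[5:10])
        )
        cfg = make_cfg(
            m=3, beta1=b1, beta2=b2, beta3=1.0 - b1 - b2,
            pathogenic_tol=1e-6, max_iter=30, rng_seed=seed,
        )
        result = run_dlpca(net, annot, cfg)
        for _, _, max_abs in result.history:
            assert max_abs <= 1.0 + 1e-9

    def test_nonconvergence_is_a_warning_not_an_error(self, two_cliques):
        annot = PathogenicAnnotation(frozenset({"a0"}), frozenset({"b0"}))
        cfg = make_cfg(max_iter=1, pathogenic_tol=1e-12, termination="and")
        with pytest.warns(RuntimeWarning, match="did not converge"):
            result = run_dlpca(
                two_cliques, annot, cfg, seeds=manual_seed_set(["a0", "b0"])
            )
        assert not result.converged


class TestLambdaDerivation:
    def test_reported_network_averages_give_published_ratio(self):
        l1, l2, _ = lambda_params_from_averages(65.23, 18.97)
        assert l1 == 3.44
        assert l2 == 1.0

    def test_equal_averages_give_unit_ratio(self):
        assert lambda_params_from_averages(12.0, 12.0)[0] == 1.0

    def test_lambda3_is_inverse_squared_mean_pathogenic(self):
        _, _, l3 = lambda_params_from_averages(10.0, 5.0, 0.236)
        assert l3 == pytest.approx(round(1 / 0.236**2, 2))
        assert l3 == 17.95

    def test_network_route_matches_average_route(self, two_cliques):
        pathogenic = {n: 0.5 for n in two_cliques.node_ids}
        l1, l2, l3 = derive_lambda_params(two_cliques, pathogenic)
        mean_deg = two_cliques.degrees.mean()
        mean_wc = two_cliques.weighted_connectivity.mean()
        assert (l1, l2, l3) == lambda_params_from_averages(mean_deg, mean_wc, 0.5)

    def test_zero_pathogenic_mean_rejected(self, two_cliques):
        with pytest.raises(ValueError, match="pathogenic"):
            derive_lambda_params(two_cliques, {n: 0.0 for n in two_cliques.node_ids})
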