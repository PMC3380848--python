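import numpy as np
import pytest

from thermoflux import (BudgetExceededError, DirectionAssignment, LoopCertificate,
                        SolverConfig, UnrepairableLoopError, catalogue_loops,
                        correct_directions, find_loop, lp_feasibility_oracle,
                        remove_loop, verify_loop_certificate)
from thermoflux.loops import certified_feasibility
from thermoflux.synthetic import (FixtureSpec, generate_network,
                                  plant_feasible_directions, plant_loop,
                                  random_direction_assignment)
from thermoflux.thermo_core import PotentialVector


def forward(n):
    return DirectionAssignment(np.ones(n, dtype=int))


class TestVerifyCertificate:
    def test_three_cycle_unit_weights(self, cycle_network):
        cert = LoopCertificate((0, 1, 2), (1.0, 1.0, 1.0), (1, 1, 1))
        assert verify_loop_certificate(cycle_network, cert)

    def test_flipped_sign_breaks_it(self, cycle_network):
        cert = LoopCertificate((0, 1, 2), (1.0, 1.0, 1.0), (1, -1, 1))
        assert not verify_loop_certificate(cycle_network, cert)

    def test_chain_columns_are_independent(self, chain_network):
        cert = LoopCertificate((0, 1), (1.0, 0.5), (1, 1))
        assert not verify_loop_certificate(chain_network, cert)

    def test_nonpositive_gamma_rejected_at_construction(self):
        with pytest.raises(Exception):
            LoopCertificate((0, 1), (1.0, 0.0), (1, 1))


class TestFindLoop:
    def test_planted_three_cycle(self, cycle_network):
        cert = find_loop(cycle_network, forward(3), [0, 1, 2], k_max=6)
        assert cert is not None and set(cert.reactions) == {0, 1, 2}
        assert cert.gamma == pytest.approx((1.0, 1.0, 1.0))
        assert max(cert.gamma) == 1.0

    def test_chain_members_excluded(self):
        net = generate_network(FixtureSpec(M=8, N=6, density=0.4, seed=2))
        sigma, _ = plant_feasible_directions(net, 0.5, 0)
        net, sigma, planted = plant_loop(net, sigma, 3)
        cands = list(planted.reactions) + [0, 1]  # loop plus two feasible reactions
        cert = find_loop(net, sigma, cands, k_max=6)
        assert set(cert.reactions) == set(planted.reactions)

    def test_acyclic_candidates_give_none(self, chain_network):
        assert find_loop(chain_network, forward(2), [0, 1], k_max=4) is None

    def test_visit_count_shortcut(self, cycle_network):
        cert = find_loop(cycle_network, forward(3), [0, 1, 2], k_max=6,
                         counts={0: 7, 1: 7, 2: 7})
        assert cert is not None and cert.gamma == pytest.approx((1.0, 1.0, 1.0))

    def test_budget_error_is_distinct_from_none(self):
        net = generate_network(FixtureSpec(M=12, N=14, density=0.4, seed=5))
        sigma, _ = plant_feasible_directions(net, 0.5, 1)
        with pytest.raises(BudgetExceededError):
            find_loop(net, sigma, list(range(14)), k_max=8, budget=10)

    def test_minimality_against_brute_force(self):
        """The returned loop has the smallest member count: verified by
        checking no strictly smaller subset admits a certificate."""
        from itertools import combinations
        rng = np.random.default_rng(0)
        for _ in range(20):
            net = generate_network(FixtureSpec(M=6, N=8, density=0.35,
                                               seed=int(rng.integers(2**31))))
            sigma = DirectionAssignment(rng.choice([-1, 1], size=8))
            cands = list(range(8))
            try:
                cert = find_loop(net, sigma, cands, k_max=8)
            except BudgetExceededError:
                continue
            if cert is None:
                continue
            k = len(cert.reactions)
            for smaller in range(2, k):
                for sub in combinations(cands, smaller):
                    sub_cert = find_loop(net, sigma, list(sub), k_max=smaller)
                    assert sub_cert is None


class TestLPOracle:
    def test_chain_feasible_with_strict_witness(self, chain_network):
        res = lp_feasibility_oracle(chain_network, forward(2))
        assert res.status == "FEASIBLE"
        dg = chain_network.S.T @ res.mu.mu
        assert np.all(dg < 0)

    def test_cycle_infeasible_with_verified_certificate(self, cycle_network):
        res = lp_feasibility_oracle(cycle_network, forward(3))
        assert res.status == "INFEASIBLE"
        assert verify_loop_certificate(cycle_network, res.certificate)

    def test_completeness_at_small_scale(self):
        """find_loop over all constrained reactions (k_max = N) certifies
        infeasibility exactly when the LP oracle does."""
        rng = np.random.default_rng(3)
        n_checked = 0
        for _ in range(200):
            net = generate_network(FixtureSpec(M=int(rng.integers(4, 9)),
                                               N=int(rng.integers(5, 12)),
                                               density=0.35,
                                               seed=int(rng.integers(2**31))))
            sigma = DirectionAssignment(rng.choice([-1, 1], size=net.N))
            oracle = lp_feasibility_oracle(net, sigma)
            try:
                cert = find_loop(net, sigma, list(range(net.N)), k_max=net.N)
            except BudgetExceededError:
                continue
            n_checked += 1
            if oracle.status == "INFEASIBLE":
                assert cert is not None and verify_loop_certificate(net, cert)
            else:
                assert cert is None
        assert n_checked >= 150


class TestRemoveLoop:
    def test_flips_exactly_one_reversible_member(self):
        sigma = DirectionAssignment([1, 1, 1])
        cert = LoopCertificate((0, 1, 2), (1.0, 1.0, 1.0), (1, 1, 1))
        reversible = np.array([False, True, True])
        out = remove_loop(sigma, cert, reversible, np.random.default_rng(0))
        diff = np.flatnonzero(out.sigma != sigma.sigma)
        assert diff.size == 1 and diff[0] in (1, 2)

    def test_uniform_choice_frequency(self):
        sigma = DirectionAssignment([1, 1, 1])
        cert = LoopCertificate((0, 1, 2), (1.0, 1.0, 1.0), (1, 1, 1))
        reversible = np.array([False, True, True])
        hits = 0
        for seed in range(2000):
            out = remove_loop(sigma, cert, reversible, np.random.default_rng(seed))
            if out.sigma[1] != 1:
                hits += 1
        assert abs(hits / 2000 - 0.5) < 0.05  # binomial 95% band

    def test_all_irreversible_raises_with_certificate(self):
        sigma = DirectionAssignment([1, 1])
        cert = LoopCertificate((0, 1), (1.0, 1.0), (1, 1))
        with pytest.raises(UnrepairableLoopError) as exc:
            remove_loop(sigma, cert, np.array([False, False]), 0)
        assert exc.value.certificate is cert


class TestCorrectDirections:
    CFG = SolverConfig(max_iters=4000, window=1500)

    def test_single_planted_loop_unique_repair(self):
        net = generate_network(FixtureSpec(M=8, N=10, density=0.3, seed=4))
        sigma, _ = plant_feasible_directions(net, 0.5, 7)
        net, sigma0, _ = plant_loop(net, sigma, 3,
                                    reversible_pattern=[True, False, False])
        res = correct_directions(net, sigma0, config=self.CFG, seed=1)
        diff = np.flatnonzero(res.sigma.sigma != sigma0.sigma)
        assert diff.size == 1 and net.reversible[diff[0]]
        assert lp_feasibility_oracle(net, res.sigma).status == "FEASIBLE"
        assert certified_feasibility(net, res.sigma, res.mu, self.CFG.eps)

    def test_already_feasible_returns_input(self):
        net = generate_network(FixtureSpec(M=8, N=10, density=0.3, seed=9))
        sigma, _ = plant_feasible_directions(net, 0.5, 2)
        res = correct_directions(net, sigma, config=self.CFG, seed=0)
        assert res.certificates == []
        assert np.array_equal(res.sigma.sigma, sigma.sigma)

    def test_two_disjoint_planted_loops(self):
        net = generate_network(FixtureSpec(M=8, N=10, density=0.3, seed=12))
        sigma, _ = plant_feasible_directions(net, 0.5, 3)
        net, sigma, _ = plant_loop(net, sigma, 3, tag=0)
        net, sigma, _ = plant_loop(net, sigma, 4, tag=1)
        res = correct_directions(net, sigma, config=self.CFG, seed=5)
        assert len(res.certificates) == 2
        assert lp_feasibility_oracle(net, res.sigma).status == "FEASIBLE"

    def test_irreversible_directions_never_flipped(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            net = generate_network(FixtureSpec(M=8, N=10, density=0.3,
                                               seed=int(rng.integers(2**31))))
            sigma, _ = plant_feasible_directions(net, 0.5, rng)
            net, sigma0, _ = plant_loop(net, sigma, 3, tag=0)
            res = correct_directions(net, sigma0, config=self.CFG,
                                     seed=int(rng.integers(2**31)))
            irrev = ~net.reversible
            assert np.array_equal(res.sigma.sigma[irrev], sigma0.sigma[irrev])


class TestCatalogue:
    CFG = SolverConfig(max_iters=4000, window=1500)

    def test_loop_free_network_clean_catalogue(self):
        net = generate_network(FixtureSpec(M=8, N=10, density=0.3,
                                           reversible_fraction=0.0, seed=21))
        sigma, _ = plant_feasible_directions(net, 0.5, 3)
        # with no reversible reactions every draw equals the planted one
        draws = [sigma.copy() for _ in range(20)]
        cat = catalogue_loops(net, draws, self.CFG, seed=0)
        assert cat.entries == [] and cat.feasible_fraction == 1.0

    def test_conditional_loop_and_dedup(self):
        """A loop whose trigger is one reversible member sampled backward
        appears in about half the draws but is catalogued once."""
        from thermoflux import ReactionNetwork
        net = generate_network(FixtureSpec(M=8, N=10, density=0.3,
                                           reversible_fraction=0.0, seed=22))
        sigma, _ = plant_feasible_directions(net, 0.5, 3)
        # re-orient columns so the annotated forward direction is the planted
        # feasible one (random draws keep irreversible reactions forward)
        net = ReactionNetwork(net.metabolite_ids, net.reaction_ids,
                              net.S * sigma.sigma, net.reversible)
        sigma = DirectionAssignment(np.ones(net.N, dtype=int))
        net, sigma, planted = plant_loop(net, sigma, 3,
                                         reversible_pattern=[True, False, False])
        rng = np.random.default_rng(0)
        draws = [random_direction_assignment(net, rng) for _ in range(60)]
        cat = catalogue_loops(net, draws, self.CFG, seed=1)
        assert len(cat.entries) == 1
        entry = cat.entries[0]
        assert set(entry.certificate.reactions) == set(planted.reactions)
        assert abs(cat.feasible_fraction - 0.5) < 0.2
        assert entry.occurrences == sum(s == "REPAIRED" for s in cat.statuses)

    def test_canonical_key_ignores_inversion_and_scale(self):
        a = LoopCertificate((3, 5), (1.0, 0.5), (1, -1))
        b = LoopCertificate((5, 3), (0.25, 0.5), (1, -1))
        assert a.canonical_key() == b.canonical_key()
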