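"""Unit and property tests for the sequence simulator."""

import itertools

import numpy as np
import pytest

from phylosector import io as psio
from phylosector import seqsim as sim


class TestEffectVector:
    def test_default_draw_shapes_and_sector_contrast(self):
        ev = sim.make_effect_vector(seed=0)
        assert ev.L == 200 and ev.L_S == 20
        assert np.array_equal(ev.sector_indices, np.arange(20))
        mask = ev.sector_mask
        assert np.abs(ev.D[mask]).mean() > np.abs(ev.D[~mask]).mean()

    def test_no_sector_zero_background_is_all_zero(self):
        ev = sim.make_effect_vector(L=10, L_S=0, bg_mean=0.0, bg_sd=0.0, seed=1)
        assert np.all(ev.D == 0.0)

    def test_flip_fraction_negates_leading_half_of_sector(self):
        base = sim.make_effect_vector(seed=3)
        flipped = sim.make_effect_vector(flip_fraction=0.5, seed=3)
        assert np.allclose(flipped.D[:10], -base.D[:10])
        assert np.allclose(flipped.D[10:], base.D[10:])
        assert (flipped.D[:10] < 0).all()

    def test_deterministic_given_seed(self):
        a = sim.make_effect_vector(seed=11)
        b = sim.make_effect_vector(seed=11)
        assert np.array_equal(a.D, b.D)

    @pytest.mark.parametrize(
        "kwargs", [dict(L=5, L_S=6), dict(sector_sd=-1.0), dict(flip_fraction=2.0)]
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            sim.make_effect_vector(**kwargs)


class TestHamiltonian:
    def test_direct_arithmetic(self):
        params = sim.SelectionParams(kappa=2.0, tau_star=0.0)
        assert sim.hamiltonian([1, 1], np.array([1.0, 1.0]), params) == pytest.approx(4.0)

    def test_zero_at_favoured_trait_and_neutral(self):
        D = np.array([2.0, 1.0, 1.0])
        seq = np.array([1, 1, 1])  # tau = 4
        assert sim.hamiltonian(seq, D, sim.SelectionParams(3.0, 4.0)) == 0.0
        assert sim.hamiltonian(seq, D, sim.SelectionParams(0.0, -7.0)) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            sim.hamiltonian([1, 1, 1], np.array([1.0, 1.0]), sim.SelectionParams(1.0, 0.0))


class TestMetropolisStep:
    def test_downhill_always_accepted(self, rng):
        D = np.array([1.0, 1.0])
        params = sim.SelectionParams(kappa=50.0, tau_star=0.0)
        # tau = 2, any flip moves tau to 0 = tau*: dH < 0
        for _ in range(20):
            _, accepted = sim.metropolis_step(np.array([1, 1], np.int8), D, params, rng)
            assert accepted

    def test_neutral_accepts_everything(self, rng):
        params = sim.SelectionParams(kappa=0.0, tau_star=0.0)
        seq = np.array([1, -1, 1, -1], np.int8)
        for _ in range(20):
            out, accepted = sim.metropolis_step(seq, np.ones(4), params, rng)
            assert accepted
            assert np.sum(out != seq) == 1

    def test_uphill_acceptance_rate_matches_boltzmann(self, rng):
        # at tau = tau*, a flip at site i costs dH = 2 kappa D_i^2
        D = np.array([1.0, 1.0])
        params = sim.SelectionParams(kappa=0.5, tau_star=0.0)
        seq = np.array([1, -1], np.int8)  # tau = 0
        n = 4000
        acc = sum(sim.metropolis_step(seq, D, params, rng)[1] for _ in range(n))
        expected = np.exp(-2 * params.kappa)  # = exp(-1)
        assert acc / n == pytest.approx(expected, abs=4 * np.sqrt(expected / n))


class TestEquilibriumSampling:
    def test_exact_enumeration_oracle_small_L(self):
        """MCMC agrees with exact sums over all 2^L states.

        Stopping a Metropolis run at a fixed number of *acceptances*
        samples the jump chain, whose stationary law weights each state by
        its Boltzmann probability times its total acceptance probability;
        the exact jump-chain expectation is the oracle here, and it stays
        within a few percent of the plain Boltzmann value.
        """
        L = 10
        rng = np.random.default_rng(5)
        D = rng.normal(1.0, 0.5, size=L)
        params = sim.SelectionParams(kappa=0.8, tau_star=2.0)
        states = np.array(list(itertools.product([-1, 1], repeat=L)))
        taus = states @ D
        boltz = np.exp(-0.5 * params.kappa * (taus - params.tau_star) ** 2)
        boltz /= boltz.sum()
        accept = np.zeros(states.shape[0])
        for i in range(L):
            flipped = taus - 2 * D[i] * states[:, i]
            dH = 0.5 * params.kappa * (
                (flipped - params.tau_star) ** 2 - (taus - params.tau_star) ** 2
            )
            accept += np.minimum(1.0, np.exp(-dH)) / L
        jump = boltz * accept
        jump /= jump.sum()
        exact_tau = float(jump @ taus)
        exact_mag = states.T @ jump
        n = 8000
        msa = sim.sample_equilibrium_msa(n, D, params, n_accepted=150, seed=6)
        got_tau = (msa.sequences @ D).mean()
        se = (msa.sequences @ D).std() / np.sqrt(n)
        assert got_tau == pytest.approx(exact_tau, abs=4 * se)
        assert np.abs(msa.sequences.mean(axis=0) - exact_mag).max() < 4 / np.sqrt(n)
        # the protocol's bias relative to plain Boltzmann sampling is small
        assert abs(exact_tau - float(boltz @ taus)) < 0.05 * abs(float(boltz @ taus))

    def test_trait_distribution_centred_and_tightens_with_kappa(
        self, reference_effects, reference_params
    ):
        msa = sim.sample_equilibrium_msa(2000, reference_effects, reference_params, seed=8)
        taus = msa.sequences @ reference_effects.D
        assert abs(taus.mean() - reference_params.tau_star) < 10.0
        strong = sim.SelectionParams(4 * reference_params.kappa, reference_params.tau_star)
        taus2 = (
            sim.sample_equilibrium_msa(2000, reference_effects, strong, seed=9).sequences
            @ reference_effects.D
        )
        assert taus2.std() < taus.std()
        assert abs(taus2.mean() - reference_params.tau_star) < abs(taus.mean() - reference_params.tau_star)

    def test_neutral_magnetization_bound(self):
        D = np.ones(50)
        msa = sim.sample_equilibrium_msa(
            500, D, sim.SelectionParams(0.0, 0.0), n_accepted=500, seed=10
        )
        assert np.abs(msa.sequences.mean(axis=0)).max() < 3 / np.sqrt(500)

    def test_zero_acceptances_returns_initial_sequence(self):
        D = np.ones(20)
        params = sim.SelectionParams(1.0, 0.0)
        a = sim.sample_equilibrium_sequence(D, params, n_accepted=0, seed=13)
        b = np.random.default_rng(13).choice(np.array([-1, 1], np.int8), size=20)
        assert np.array_equal(a, b)

    def test_seed_determinism(self, small_effects, small_params):
        a = sim.sample_equilibrium_msa(10, small_effects, small_params, seed=14)
        b = sim.sample_equilibrium_msa(10, small_effects, small_params, seed=14)
        assert np.array_equal(a.sequences, b.sequences)

    def test_unreachable_trait_warns(self):
        D = np.ones(5)
        with pytest.warns(UserWarning, match="tau"):
            sim.sample_equilibrium_sequence(D, sim.SelectionParams(0.1, 50.0), 10, seed=15)

    def test_stall_error_under_frozen_selection(self):
        D = np.array([1.0, 1.0])
        params = sim.SelectionParams(kappa=500.0, tau_star=0.0)
        anc = np.array([1, -1], np.int8)  # tau = tau*, any flip dH = 1000
        with pytest.raises(sim.StallError):
            sim.evolve_on_binary_tree(anc, mu=1, n=1, effects=D, params=params,
                                      seed=16, stall_cap=2000)


@pytest.fixture(scope="module")
def record(small_effects, small_params):
    return sim.evolve_on_binary_tree(
        None, mu=4, n=5, effects=small_effects, params=small_params, seed=21
    )


class TestBinaryTree:

    def test_leaf_count_is_two_to_the_n(self, record):
        assert record.leaf_msa.M == 2**5

    def test_hamming_bounds_from_mutation_counts(self, record):
        mu, n = 4, 5
        leaves = record.leaf_msa.sequences
        sib = (leaves[0] != leaves[1]).sum()  # first two leaves are siblings
        assert sib <= 2 * mu
        for a, b in [(0, 10), (3, 31), (7, 20)]:
            assert (leaves[a] != leaves[b]).sum() <= 2 * mu * n

    def test_mu_zero_leaves_identical_with_sentinel_G(self, small_effects, small_params):
        rec = sim.evolve_on_binary_tree(
            None, mu=0, n=3, effects=small_effects, params=small_params, seed=22
        )
        assert (rec.leaf_msa.sequences == rec.root).all()
        assert (rec.G == rec.g_sentinel).all()

    def test_leaves_replayable_from_mutation_logs(self, record):
        for leaf in record.leaf_indices:
            seq = record.root.copy()
            path = []
            k = int(leaf)
            while k > 0:
                path.append(k)
                k = (k - 1) // 2
            for node in reversed(path):
                for site in record.mutation_log[node]:
                    seq[site] = -seq[site]
            assert np.array_equal(seq, record.node_sequences[leaf])

    def test_G_consistency_with_shallower_nodes(self, record):
        root = record.root
        for site in range(root.size):
            g = record.G[site]
            shallow = record.node_depths < g
            assert (record.node_sequences[shallow, site] == root[site]).all()

    def test_bit_identical_given_seed(self, small_effects, small_params):
        a = sim.evolve_on_binary_tree(None, 3, 4, small_effects, small_params, seed=23)
        b = sim.evolve_on_binary_tree(None, 3, 4, small_effects, small_params, seed=23)
        assert np.array_equal(a.node_sequences, b.node_sequences)
        assert np.array_equal(a.G, b.G)


class TestNewickTree:
    def test_zero_length_star_tree_copies_ancestor(self, small_effects, small_params):
        anc = np.ones(small_effects.L, np.int8)
        rec = sim.evolve_on_newick_tree(
            anc, "(a:0,b:0,c:0);", 5.0, small_effects, small_params, seed=31
        )
        assert (rec.leaf_msa.sequences == anc).all()

    def test_long_branches_decorrelate_to_equilibrium(self, small_effects, small_params):
        rec = sim.evolve_on_newick_tree(
            None, "(a:1,b:1);", 5000.0, small_effects, small_params, seed=32
        )
        eq = sim.sample_equilibrium_msa(400, small_effects, small_params, seed=33)
        d_tree = sim.mean_pairwise_hamming(rec.leaf_msa)
        d_eq = sim.mean_pairwise_hamming(eq)
        # one pair vs the equilibrium ensemble: generous tolerance
        assert d_tree == pytest.approx(d_eq, abs=0.12)

    def test_matches_binary_tree_statistics(self, small_effects, small_params):
        """Perfect binary topology as newick with Poisson(mu) branch counts
        reproduces the fixed-mu simulator's diversity up to jitter."""
        def nwk(d):
            return f"({nwk(d-1)},{nwk(d-1)}):1" if d else "x:1"

        mu, n = 6, 5
        rec_fixed = sim.evolve_on_binary_tree(
            None, mu=mu, n=n, effects=small_effects, params=small_params, seed=34
        )
        hs = []
        for s in range(3):
            rec_nwk = sim.evolve_on_newick_tree(
                None, nwk(n) + ";", float(mu), small_effects, small_params, seed=35 + s
            )
            assert rec_nwk.leaf_msa.M == 2**n
            hs.append(sim.mean_pairwise_hamming(rec_nwk.leaf_msa))
        assert np.mean(hs) == pytest.approx(
            sim.mean_pairwise_hamming(rec_fixed.leaf_msa), rel=0.25
        )

    def test_reports_mean_mutations_per_lineage(self, small_effects, small_params):
        rec = sim.evolve_on_newick_tree(
            None, "((a:1,b:1):1,(c:1,d:1):1);", 10.0, small_effects, small_params, seed=36
        )
        assert rec.mean_mutations_per_lineage == pytest.approx(20.0, rel=0.5)

    def test_malformed_newick_and_missing_lengths(self, small_effects, small_params):
        with pytest.raises(Exception):
            sim.evolve_on_newick_tree(None, "((a:1,b:1", 1.0, small_effects, small_params)
        with pytest.raises(ValueError, match="branch length"):
            sim.evolve_on_newick_tree(None, "(a:1,b);", 1.0, small_effects, small_params, seed=37)


class TestHamming:
    def test_identical_rows_give_zero(self):
        msa = sim.BinaryMSA(np.ones((4, 8), np.int8))
        assert sim.mean_pairwise_hamming(msa) == 0.0

    def test_hand_computed_example(self):
        msa = np.array([[1, 1, 1, 1], [1, 1, -1, -1], [-1, -1, -1, -1]], np.int8)
        # pair distances: 1/2, 1, 1/2
        assert sim.mean_pairwise_hamming(msa) == pytest.approx(2 / 3)

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            sim.mean_pairwise_hamming(np.ones((1, 5), np.int8))


class TestIO:
    def test_fasta_roundtrip(self, tmp_path, small_effects, small_params):
        msa = sim.sample_equilibrium_msa(6, small_effects, small_params, 50, seed=41)
        psio.write_binary_fasta(msa, tmp_path / "m.fasta")
        back, ids = psio.read_binary_fasta(tmp_path / "m.fasta")
        assert np.array_equal(back.sequences, msa.sequences)
        assert ids == [f"seq{m}" for m in range(6)]

    def test_csv_roundtrip(self, tmp_path):
        msa = sim.BinaryMSA(np.array([[1, -1], [-1, -1]], np.int8))
        psio.write_binary_csv(msa, tmp_path / "m.csv")
        assert np.array_equal(psio.read_binary_csv(tmp_path / "m.csv").sequences, msa.sequences)

    def test_record_serialization_layout(self, tmp_path, small_effects, small_params):
        rec = sim.evolve_on_binary_tree(None, 2, 3, small_effects, small_params, seed=42)
        rec.to_dir(tmp_path / "rec")
        for name in ("tree.nwk", "leaves.fasta", "internal_nodes.fasta", "G.csv", "mutation_log.csv"):
            assert (tmp_path / "rec" / name).exists()
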