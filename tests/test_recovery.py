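"""Self-consistent configuration recovery."""

import itertools

import numpy as np
import pytest

from sqd_binder import (
    InitializationError,
    NoiseModel,
    OccupationEstimate,
    RecoveryConfig,
    SampleSet,
    apply_lucj,
    build_subspace,
    casci_energy,
    corrupt,
    init_occupations,
    lucj_from_ccsd,
    lucj_mask,
    make_batches,
    recover_configuration,
    recover_samples,
    recovery_loop,
    sample_state,
)
from sqd_binder._bits import pack, popcount, unpack
from sqd_binder.determinant_ci import CIVector, DeterminantSubspace


class TestInitOccupations:
    def test_reference_shots(self):
        s = SampleSet(4, {pack(0b0011, 0b0011, 4): 50})
        est = init_occupations(s, 2, 2)
        assert np.array_equal(est.n, [1, 1, 0, 0, 1, 1, 0, 0])

    def test_two_configurations_average(self):
        s = SampleSet(2, {pack(0b01, 0b01, 2): 10, pack(0b10, 0b10, 2): 10})
        est = init_occupations(s, 1, 1)
        assert np.abs(est.n - 0.5).max() < 1e-14

    def test_no_correct_configuration(self):
        s = SampleSet(2, {pack(0b11, 0b01, 2): 5})
        with pytest.raises(InitializationError):
            init_occupations(s, 1, 1)

    def test_matches_conditional_enumeration(self):
        """Exact conditional expectation of each bit given correct particle
        number, from exhaustive enumeration of flip masks at M=3."""
        m, eps, shots = 3, 0.1, 200_000
        cfg = pack(0b011, 0b100, m)
        weights = {}
        for flips in itertools.product((0, 1), repeat=2 * m):
            mask = sum(bit << i for i, bit in enumerate(flips))
            new = cfg ^ mask
            a, b = unpack(new, m)
            if popcount(a) == 2 and popcount(b) == 1:
                k = sum(flips)
                weights[new] = weights.get(new, 0.0) + eps**k * (1 - eps) ** (
                    2 * m - k
                )
        total = sum(weights.values())
        exact = np.zeros(2 * m)
        for new, w in weights.items():
            exact += (w / total) * np.array(
                [(new >> i) & 1 for i in range(2 * m)], dtype=float
            )
        corrupted = corrupt(SampleSet(m, {cfg: shots}), NoiseModel(eps, seed=4))
        est = init_occupations(corrupted, 2, 1)
        n_kept = sum(
            c
            for k, c in corrupted.counts.items()
            if popcount(unpack(k, m)[0]) == 2 and popcount(unpack(k, m)[1]) == 1
        )
        sigma = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / n_kept)
        assert np.all(np.abs(est.n - exact) < 3 * sigma + 1e-3)


class TestRecoverConfiguration:
    def test_correct_configuration_unchanged(self):
        n = OccupationEstimate(np.full(8, 0.5))
        cfg = pack(0b0101, 0b0011, 4)
        rng = np.random.default_rng(0)
        assert recover_configuration(cfg, n, 2, 2, rng) == cfg

    def test_degenerate_weights_deterministic(self):
        # M=2, N_alpha=1, empty alpha sector, n_alpha = (1, 0)
        n = OccupationEstimate(np.array([1.0, 0.0, 0.5, 0.5]))
        cfg = pack(0b00, 0b01, 2)
        rng = np.random.default_rng(0)
        out = recover_configuration(cfg, n, 1, 1, rng)
        assert unpack(out, 2)[0] == 0b01

    def test_insertion_frequencies_proportional_to_occupations(self):
        probs = np.array([0.6, 0.3, 0.1])
        n = OccupationEstimate(np.concatenate([probs, [1, 1, 1]]))
        rng = np.random.default_rng(42)
        cfg = pack(0b000, 0b111, 3)  # alpha deficit of one electron
        hits = np.zeros(3)
        trials = 100_000
        for _ in range(trials):
            out = recover_configuration(cfg, n, 1, 3, rng)
            hits[int(np.log2(unpack(out, 3)[0]))] += 1
        freq = hits / trials
        sigma = np.sqrt(probs * (1 - probs) / trials)
        assert np.all(np.abs(freq - probs) < 3 * sigma)

    def test_zero_probability_fallback_uniform(self):
        # surplus electron but 1 - n = 0 everywhere: uniform removal
        n = OccupationEstimate(np.array([1.0, 1.0, 0.5, 0.5]))
        rng = np.random.default_rng(1)
        out = recover_configuration(pack(0b11, 0b01, 2), n, 1, 1, rng)
        assert popcount(unpack(out, 2)[0]) == 1

    def test_all_outputs_have_exact_particle_numbers(self):
        rng = np.random.default_rng(3)
        n = OccupationEstimate(rng.random(8))
        for cfg in rng.integers(0, 1 << 8, size=200):
            out = recover_configuration(int(cfg), n, 2, 2, rng)
            a, b = unpack(out, 4)
            assert popcount(a) == 2 and popcount(b) == 2


class TestBatches:
    def test_single_batch_of_single_configuration(self):
        pool = SampleSet(2, {pack(0b01, 0b01, 2): 100})
        rng = np.random.default_rng(0)
        (batch,) = make_batches(pool, 1, 100, rng)
        assert batch.counts == pool.counts

    def test_seeded_batches_reproducible(self):
        pool = SampleSet(2, {pack(0b01, 0b01, 2): 60, pack(0b10, 0b10, 2): 40})
        a = make_batches(pool, 3, 50, np.random.default_rng(7))
        b = make_batches(pool, 3, 50, np.random.default_rng(7))
        assert [x.counts for x in a] == [y.counts for y in b]
        assert all(x.shots == 50 for x in a)


class TestBuildSubspace:
    def test_cartesian_product_dimension(self):
        batch = SampleSet(
            3, {pack(0b011, 0b011, 3): 1, pack(0b101, 0b110, 3): 1}
        )
        S = build_subspace(batch, 2, 2)
        assert S.dimension == 4

    def test_single_configuration(self):
        S = build_subspace(SampleSet(3, {pack(0b011, 0b101, 3): 5}), 2, 2)
        assert S.dimension == 1

    def test_wrong_particle_number_rejected(self):
        batch = SampleSet(3, {pack(0b111, 0b011, 3): 1})
        with pytest.raises(ValueError):
            build_subspace(batch, 2, 2)


class TestRecoveryLoop:
    def _toy(self):
        from sqd_binder import random_hamiltonian

        ham = random_hamiltonian(4, 2, 2, seed=7, scale=0.5)
        rng = np.random.default_rng(42)
        t2 = 0.5 * rng.normal(size=(2, 2, 2, 2))
        t2 = t2 + t2.transpose(1, 0, 3, 2)
        ansatz = lucj_from_ccsd(t2, lucj_mask(4, "line_heavyhex"))
        return ham, ansatz

    def test_noiseless_full_support_reaches_casci_at_first_iteration(self):
        ham, ansatz = self._toy()
        psi = apply_lucj(ansatz, 4, 2, 2)
        raw = sample_state(psi, 10_000, seed=9)
        cfg = RecoveryConfig(
            k=2, batch_size=8_000, iterations=3, seed=5, compute_variance=False
        )
        result = recovery_loop(ham, raw, cfg)
        exact = casci_energy(ham, compute_variance=False).energy
        assert result.iterations[0].e_min == pytest.approx(exact, abs=1e-8)

    def test_batch_count_and_minimum_contract(self):
        ham, ansatz = self._toy()
        psi = apply_lucj(ansatz, 4, 2, 2)
        raw = corrupt(sample_state(psi, 4_000, seed=9), NoiseModel(0.02, 3))
        cfg = RecoveryConfig(
            k=3, batch_size=1_000, iterations=2, seed=5,
            energy_tol=0.0, compute_variance=False,
        )
        result = recovery_loop(ham, raw, cfg)
        for rec in result.iterations:
            assert len(rec.results) == 3
            assert rec.e_min == min(r.energy for r in rec.results)
            assert rec.e_min == rec.results[rec.best_batch].energy

    def test_variational_safety(self):
        ham, ansatz = self._toy()
        psi = apply_lucj(ansatz, 4, 2, 2)
        raw = corrupt(sample_state(psi, 4_000, seed=9), NoiseModel(0.05, 3))
        cfg = RecoveryConfig(
            k=3, batch_size=500, iterations=4, seed=5,
            energy_tol=0.0, compute_variance=False,
        )
        result = recovery_loop(ham, raw, cfg)
        exact = casci_energy(ham, compute_variance=False).energy
        for e in result.energy_history:
            assert e >= exact - 1e-10

    def test_larger_batches_do_not_worsen_energy(self):
        ham, ansatz = self._toy()
        psi = apply_lucj(ansatz, 4, 2, 2)
        finals = {size: [] for size in (200, 2_000)}
        for s in range(5):
            raw = corrupt(
                sample_state(psi, 4_000, seed=20 + s), NoiseModel(0.02, 30 + s)
            )
            for size in finals:
                cfg = RecoveryConfig(
                    k=3, batch_size=size, iterations=4, seed=40 + s,
                    compute_variance=False,
                )
                finals[size].append(recovery_loop(ham, raw, cfg).energy)
        assert np.median(finals[2_000]) <= np.median(finals[200]) + 1e-8


def test_recover_samples_is_identity_on_noiseless_sets():
    rng = np.random.default_rng(2)
    t2 = 0.4 * rng.normal(size=(2, 2, 2, 2))
    t2 = t2 + t2.transpose(1, 0, 3, 2)
    psi = apply_lucj(lucj_from_ccsd(t2, lucj_mask(4, "line_heavyhex")), 4, 2, 2)
    raw = sample_state(psi, 3_000, seed=6)
    est = init_occupations(raw, 2, 2)
    out = recover_samples(raw, est, 2, 2, np.random.default_rng(0))
    assert out.counts == raw.counts


def test_recovered_pool_has_only_correct_particle_numbers():
    rng = np.random.default_rng(2)
    t2 = 0.4 * rng.normal(size=(2, 2, 2, 2))
    t2 = t2 + t2.transpose(1, 0, 3, 2)
    psi = apply_lucj(lucj_from_ccsd(t2, lucj_mask(4, "line_heavyhex")), 4, 2, 2)
    raw = corrupt(sample_state(psi, 3_000, seed=6), NoiseModel(0.05, 7))
    est = init_occupations(raw, 2, 2)
    out = recover_samples(raw, est, 2, 2, np.random.default_rng(0))
    assert out.shots == raw.shots
    for cfg in out.counts:
        a, b = unpack(cfg, 4)
        assert popcount(a) == 2 and popcount(b) == 2
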