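import numpy as np
import pytest

import chromstate as cs
from chromstate.hmm_segmentation import _em, _init_model, sample_sequence
from conftest import enumerate_loglik, random_hmm


class TestEmissionProb:
    def test_half_half(self):
        assert cs.emission_prob([0.5, 0.5], [1, 0]) == pytest.approx(0.25)

    def test_product(self):
        assert cs.emission_prob([0.8, 0.2], [1, 1]) == pytest.approx(0.16)

    def test_degenerate_certain_emission(self):
        assert cs.emission_prob([1.0, 0.5], [0, 1]) == 0.0

    def test_invalid_obs(self):
        with pytest.raises(ValueError):
            cs.emission_prob([0.5], [2])


class TestForward:
    def test_two_step_hand_computed(self, toy_model):
        # sum over the 4 paths of pi * E * A * E = 0.322
        ll = cs.forward_loglik(toy_model, np.array([[1], [1]]))
        assert np.exp(ll) == pytest.approx(0.322, abs=1e-12)

    def test_single_step(self):
        m = cs.HMMModel(2, ["m0"], np.array([1.0, 0.0]),
                        np.array([[0.5, 0.5], [0.5, 0.5]]),
                        np.array([[0.8], [0.3]]))
        assert np.exp(cs.forward_loglik(m, np.array([[1]]))) == (
            pytest.approx(0.8)
        )

    def test_zero_probability_sequence(self):
        m = cs.HMMModel(2, ["m0"], np.array([1.0, 0.0]),
                        np.array([[1.0, 0.0], [0.0, 1.0]]),
                        np.array([[1.0], [1.0]]))
        assert cs.forward_loglik(m, np.array([[0]])) == -np.inf

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            K = int(rng.integers(2, 4))
            M = int(rng.integers(1, 4))
            T = int(rng.integers(1, 9))
            model = random_hmm(rng, K, M)
            obs = rng.integers(0, 2, size=(T, M)).astype(np.uint8)
            assert cs.forward_loglik(model, obs) == pytest.approx(
                enumerate_loglik(model, obs), abs=1e-10
            )


class TestLearn:
    def test_monotone_loglik_and_determinism(self, small_study, small_config):
        marks = [m for m in small_config.marks if m != "IgG"]
        ct = small_config.cell_types[0]
        binary = cs.binarize(
            {m: small_study.tracks[ct][m] for m in marks},
            control=small_study.tracks[ct]["IgG"], cell_type=ct, marks=marks,
        )
        m1 = cs.learn_model(binary, K=4, seed=5, n_restarts=2, max_iter=30)
        trace = np.array(m1.loglik_trace)
        assert (np.diff(trace) >= -1e-8).all()
        m2 = cs.learn_model(binary, K=4, seed=5, n_restarts=2, max_iter=30)
        assert np.array_equal(m1.emissionprob, m2.emissionprob)
        assert np.array_equal(m1.transmat, m2.transmat)

    def test_row_stochastic_after_learning(self, small_study, small_config):
        marks = [m for m in small_config.marks if m != "IgG"]
        ct = small_config.cell_types[0]
        binary = cs.binarize(
            {m: small_study.tracks[ct][m] for m in marks},
            control=small_study.tracks[ct]["IgG"], cell_type=ct, marks=marks,
        )
        model = cs.learn_model(binary, K=3, seed=1, n_restarts=1, max_iter=15)
        assert np.allclose(model.transmat.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(model.startprob.sum(), 1.0, atol=1e-9)

    def test_k_below_two_rejected(self, small_study, small_config):
        marks = [m for m in small_config.marks if m != "IgG"]
        ct = small_config.cell_types[0]
        binary = cs.binarize(
            {m: small_study.tracks[ct][m] for m in marks},
            cell_type=ct, marks=marks,
        )
        with pytest.raises(ValueError):
            cs.learn_model(binary, K=1)

    def test_reindexed_by_k4me3_emission(self, small_study, small_config):
        marks = [m for m in small_config.marks if m != "IgG"]
        ct = small_config.cell_types[0]
        binary = cs.binarize(
            {m: small_study.tracks[ct][m] for m in marks}, cell_type=ct,
            marks=marks,
        )
        model = cs.learn_model(binary, K=4, seed=2, n_restarts=1, max_iter=20)
        k4 = model.emissionprob[:, marks.index("H3K4me3")]
        assert (np.diff(k4) <= 1e-12).all()

    def test_parameter_recovery_three_states(self):
        truth = cs.HMMModel(
            3,
            ["H3K4me3", "H3K27ac"],
            np.array([1 / 3] * 3),
            np.array([[0.95, 0.03, 0.02],
                      [0.04, 0.92, 0.04],
                      [0.02, 0.03, 0.95]]),
            np.array([[0.9, 0.8], [0.85, 0.05], [0.02, 0.03]]),
        )
        _, obs = sample_sequence(truth, 20_000, seed=4)
        grid = cs.BinGrid(200, {"chr1": 200 * len(obs)})
        binary = cs.BinaryMatrix(grid=grid, marks=truth.marks,
                                 calls={"chr1": obs})
        model = cs.learn_model(binary, K=3, seed=0, n_restarts=2)
        # truth is already in descending-K4me3 order, as is the learned model
        assert np.abs(model.emissionprob - truth.emissionprob).max() < 0.05


class TestDecode:
    def test_deterministic_emissions(self):
        m = cs.HMMModel(2, ["m0"], np.array([0.5, 0.5]),
                        np.array([[0.9, 0.1], [0.1, 0.9]]),
                        np.array([[1.0], [0.0]]))
        grid = cs.BinGrid(200, {"chr1": 800})
        binary = cs.BinaryMatrix(
            grid=grid, marks=["m0"],
            calls={"chr1": np.array([[1], [1], [0], [0]], dtype=np.uint8)},
        )
        for mode in ("posterior", "viterbi"):
            seg = cs.decode(m, binary, mode=mode)
            assert list(seg.state_path["chr1"]) == [1, 1, 2, 2]
            assert [(iv.start, iv.end, s) for iv, s in seg.segments] == [
                (0, 400, 1), (400, 800, 2),
            ]

    def test_posterior_rows_sum_to_one(self, toy_model):
        grid = cs.BinGrid(200, {"chr1": 1200})
        rng = np.random.default_rng(0)
        binary = cs.BinaryMatrix(
            grid=grid, marks=["H3K4me3"],
            calls={"chr1": rng.integers(0, 2, size=(6, 1)).astype(np.uint8)},
        )
        seg = cs.decode(toy_model, binary, mode="posterior")
        assert np.allclose(seg.posterior["chr1"].sum(axis=1), 1.0, atol=1e-9)

    def test_viterbi_beats_random_paths(self):
        rng = np.random.default_rng(9)
        model = random_hmm(rng, 3, 2)
        model = cs.HMMModel(3, model.marks, model.startprob,
                            model.transmat, model.emissionprob)
        _, obs = sample_sequence(model, 60, seed=2)
        grid = cs.BinGrid(200, {"chr1": 200 * 60})
        binary = cs.BinaryMatrix(grid=grid, marks=model.marks,
                                 calls={"chr1": obs})
        seg = cs.decode(model, binary, mode="viterbi")
        vit = seg.state_path["chr1"] - 1

        def path_ll(path):
            with np.errstate(divide="ignore"):
                ll = np.log(model.startprob[path[0]])
                ll += sum(
                    np.log(model.transmat[path[t - 1], path[t]])
                    for t in range(1, len(path))
                )
                for t in range(len(path)):
                    ll += np.log(
                        cs.emission_prob(model.emissionprob[path[t]], obs[t])
                    )
            return ll

        best = path_ll(vit)
        for _ in range(300):
            rand = rng.integers(0, 3, size=60)
            assert path_ll(rand) <= best + 1e-9

    def test_segments_tile_genome(self, small_study, small_config):
        marks = [m for m in small_config.marks if m != "IgG"]
        ct = small_config.cell_types[0]
        binary = cs.binarize(
            {m: small_study.tracks[ct][m] for m in marks}, cell_type=ct,
            marks=marks,
        )
        model = cs.learn_model(binary, K=3, seed=0, n_restarts=1, max_iter=10)
        seg = cs.decode(model, binary)
        total = sum(iv.length for iv, _ in seg.segments)
        assert total == sum(small_study.grid.chrom_lengths.values())
        for (a, sa), (b, sb) in zip(seg.segments, seg.segments[1:]):
            if a.chrom == b.chrom:
                assert a.end == b.start and sa != sb

    def test_mark_order_mismatch_rejected(self, toy_model):
        grid = cs.BinGrid(200, {"chr1": 400})
        binary = cs.BinaryMatrix(
            grid=grid, marks=["other"],
            calls={"chr1": np.zeros((2, 1), dtype=np.uint8)},
        )
        with pytest.raises(ValueError, match="mark"):
            cs.decode(toy_model, binary)


class TestModelIO:
    def test_round_trip(self, toy_model, tmp_path):
        path = tmp_path / "model.tsv"
        cs.write_model(toy_model, path)
        back = cs.read_model(path)
        assert back.marks == toy_model.marks
        assert np.allclose(back.transmat, toy_model.transmat)
        assert np.allclose(back.emissionprob, toy_model.emissionprob)


def test_em_monotone_over_random_starts(small_study, small_config):
    """EM log-likelihood never decreases, whatever the start point."""
    marks = [m for m in small_config.marks if m != "IgG"]
    ct = small_config.cell_types[0]
    binary = cs.binarize(
        {m: small_study.tracks[ct][m] for m in marks}, cell_type=ct,
        marks=marks,
    )
    seqs = [np.asarray(s, dtype=float) for s in binary.sequences()]
    freq = np.concatenate(seqs).mean(axis=0)
    for seed in range(8):
        rng = np.random.default_rng(seed)
        model = _init_model(marks, 4, np.clip(freq, 0.01, 0.99), rng)
        fitted = _em(model, seqs, max_iter=8, rel_tol=0.0)
        trace = np.array(fitted.loglik_trace)
        assert (np.diff(trace) >= -1e-8).all()
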