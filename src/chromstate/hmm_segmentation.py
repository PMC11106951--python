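"""Multivariate Bernoulli-emission hidden Markov model over binarized bins.

Each genomic bin carries a binary vector of mark calls; hidden chromatin
states emit marks independently with state-specific probabilities
``E[k, m] = P(mark m = 1 | state k)``. Parameters are learned by Baum-Welch
EM on per-chromosome sequences (no transitions across chromosome ends) and
bins are assigned states by posterior argmax (default) or Viterbi. Learned
states are re-indexed 1..K by descending H3K4me3 emission (ties broken by
H3K27ac) so that states 1/2 are the promoter-proximal ("TSS") states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import BinGrid, GenomicInterval
from .signal_norm import BinaryMatrix

PROB_FLOOR = 1e-6


@dataclass
class HMMModel:
    """Initial / transition / Bernoulli-emission parameters for K states."""

    n_states: int
    marks: list[str]
    startprob: np.ndarray  # (K,)
    transmat: np.ndarray  # (K, K) row-stochastic
    emissionprob: np.ndarray  # (K, M) in [0, 1]
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.emissionprob = np.asarray(self.emissionprob, dtype=float)
        self.validate()

    def validate(self) -> None:
        K, M = self.n_states, len(self.marks)
        if self.startprob.shape != (K,) or self.transmat.shape != (K, K):
            raise ValueError("parameter shape mismatch")
        if self.emissionprob.shape != (K, M):
            raise ValueError("emission shape mismatch")
        if abs(self.startprob.sum() - 1.0) > 1e-9:
            raise ValueError("initial probabilities must sum to 1")
        if np.abs(self.transmat.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if ((self.emissionprob < 0) | (self.emissionprob > 1)).any():
            raise ValueError("emission probabilities must lie in [0, 1]")


@dataclass
class Segmentation:
    """Decoded per-bin states merged into maximal same-state segments.

    ``segments`` are (interval, state) with 1-based states; ``state_path``
    keeps the raw per-bin assignment per chromosome. Adjacent segments have
    different states and jointly tile every binned position.
    """

    grid: BinGrid
    segments: list[tuple[GenomicInterval, int]]
    state_path: dict[str, np.ndarray]
    posterior: dict[str, np.ndarray] | None = None
    cell_type: str = ""


def emission_prob(e_row: np.ndarray, obs: np.ndarray) -> float:
    """P(obs | state) = prod_m E[m]^obs[m] (1-E[m])^(1-obs[m])."""
    e_row = np.asarray(e_row, dtype=float)
    obs = np.asarray(obs)
    if e_row.shape != obs.shape:
        raise ValueError("emission row and observation lengths differ")
    if not np.isin(obs, (0, 1)).all():
        raise ValueError("observations must be 0/1")
    with np.errstate(divide="ignore"):
        logp = np.where(obs == 1, np.log(e_row), np.log1p(-e_row))
    total = logp.sum()
    return float(np.exp(total)) if np.isfinite(total) else 0.0


def _emission_matrix(model_E: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """B[t, k] = P(obs_t | state k) for a (T, M) binary sequence."""
    E = np.clip(np.asarray(model_E, dtype=float), 0.0, 1.0)
    obs = np.asarray(obs, dtype=float)
    with np.errstate(divide="ignore"):
        # clamp -inf to a huge finite negative so 0 * log(0) stays 0 in the
        # matmul; exp underflows to an exact 0 probability either way
        logE = np.maximum(np.log(E), -1e30)
        log1mE = np.maximum(np.log1p(-E), -1e30)
    logB = obs @ logE.T + (1.0 - obs) @ log1mE.T
    return np.exp(logB)


def _check_obs(obs: np.ndarray, n_marks: int) -> np.ndarray:
    obs = np.asarray(obs)
    if obs.ndim != 2 or obs.shape[1] != n_marks:
        raise ValueError("observation matrix must be (T, n_marks)")
    if not np.isin(obs, (0, 1)).all():
        raise ValueError("observations must be 0/1")
    return obs


def _scaled_forward(model: HMMModel, B: np.ndarray):
    """Scaled forward pass; returns (alpha_hat, scale c, loglik)."""
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = model.startprob * B[0]
    c[0] = a.sum()
    if c[0] == 0.0:
        return None, None, -np.inf
    alpha[0] = a / c[0]
    A = model.transmat
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        if c[t] == 0.0:
            return None, None, -np.inf
        alpha[t] = a / c[t]
    return alpha, c, float(np.log(c).sum())


def _scaled_backward(model: HMMModel, B: np.ndarray, c: np.ndarray) -> np.ndarray:
    T, K = B.shape
    beta = np.empty((T, K))
    beta[-1] = 1.0
    A = model.transmat
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


def forward_loglik(model: HMMModel, obs_seq: np.ndarray) -> float:
    """log P(obs_seq | model); -inf for a zero-probability sequence."""
    obs = _check_obs(obs_seq, len(model.marks))
    B = _emission_matrix(model.emissionprob, obs)
    _, _, ll = _scaled_forward(model, B)
    return ll


def _init_model(
    marks: list[str], K: int, mark_freq: np.ndarray, rng: np.random.Generator
) -> HMMModel:
    """Jittered-frequency emissions, sticky transitions, uniform start."""
    M = len(marks)
    E = np.clip(
        mark_freq[None, :] + rng.uniform(-0.1, 0.1, size=(K, M)), 0.01, 0.99
    )
    A = np.full((K, K), 0.1 / (K - 1))
    np.fill_diagonal(A, 0.9)
    pi = np.full(K, 1.0 / K)
    return HMMModel(K, list(marks), pi, A, E)


def _floor_normalize(rows: np.ndarray, floor: float = PROB_FLOOR) -> np.ndarray:
    rows = np.maximum(rows, floor)
    return rows / rows.sum(axis=-1, keepdims=True)


def learn_model(
    binary: BinaryMatrix | list[BinaryMatrix],
    K: int = 10,
    seed: int = 0,
    max_iter: int = 200,
    rel_tol: float = 1e-4,
    n_restarts: int = 3,
) -> HMMModel:
    """Baum-Welch EM over per-chromosome sequences; best of ``n_restarts``.

    Accepts one BinaryMatrix or a list (e.g. both cell types concatenated as
    extra sequences sharing one model). Log-likelihood is checked to be
    non-decreasing every iteration; emission/transition floors of 1e-6 avoid
    absorbing zeros. Returned states are re-indexed by descending H3K4me3
    emission (ties by H3K27ac).
    """
    if K < 2:
        raise ValueError("need at least 2 states")
    mats = binary if isinstance(binary, list) else [binary]
    marks = mats[0].marks
    for m in mats[1:]:
        if m.marks != marks:
            raise ValueError("mark order differs between binary matrices")
    seqs = [np.asarray(s, dtype=float) for m in mats for s in m.sequences()]
    allobs = np.concatenate(seqs, axis=0)
    if len(np.unique(allobs, axis=0)) < min(K, 2):
        import warnings

        warnings.warn("degenerate input: fewer distinct observation rows than states")
    mark_freq = np.clip(allobs.mean(axis=0), 0.01, 0.99)

    rng = np.random.default_rng(seed)
    best: HMMModel | None = None
    for _ in range(max(1, n_restarts)):
        model = _init_model(marks, K, mark_freq, rng)
        model = _em(model, seqs, max_iter, rel_tol)
        if best is None or model.loglik_trace[-1] > best.loglik_trace[-1]:
            best = model
    assert best is not None
    return _reindex_states(best)


def _em(model: HMMModel, seqs: list[np.ndarray], max_iter: int,
        rel_tol: float) -> HMMModel:
    prev_ll = -np.inf
    trace: list[float] = []
    for _ in range(max_iter):
        pi_acc = np.zeros(model.n_states)
        xi_acc = np.zeros_like(model.transmat)
        e_num = np.zeros_like(model.emissionprob)
        e_den = np.zeros(model.n_states)
        ll = 0.0
        for obs in seqs:
            B = _emission_matrix(model.emissionprob, obs)
            alpha, c, seq_ll = _scaled_forward(model, B)
            if not np.isfinite(seq_ll):
                raise FloatingPointError("zero-probability sequence during EM")
            beta = _scaled_backward(model, B, c)
            gamma = alpha * beta  # rows sum to 1 under this scaling
            ll += seq_ll
            pi_acc += gamma[0]
            if len(obs) > 1:
                weighted = (B[1:] * beta[1:]) / c[1:, None]
                xi_acc += model.transmat * (alpha[:-1].T @ weighted)
            e_num += gamma.T @ obs
            e_den += gamma.sum(axis=0)
        trace.append(ll)
        if ll < prev_ll - 1e-8:
            raise AssertionError(
                f"EM log-likelihood decreased: {prev_ll} -> {ll}"
            )
        model = HMMModel(
            model.n_states,
            model.marks,
            _floor_normalize(pi_acc),
            _floor_normalize(xi_acc),
            np.clip(e_num / np.maximum(e_den[:, None], 1e-300),
                    PROB_FLOOR, 1 - PROB_FLOOR),
            loglik_trace=trace,
        )
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= rel_tol * abs(prev_ll):
            break
        prev_ll = ll
    model.loglik_trace = trace
    return model


def _reindex_states(model: HMMModel) -> HMMModel:
    primary = model.marks.index("H3K4me3") if "H3K4me3" in model.marks else 0
    secondary = (
        model.marks.index("H3K27ac")
        if "H3K27ac" in model.marks
        else min(1, len(model.marks) - 1)
    )
    order = np.lexsort(
        (-model.emissionprob[:, secondary], -model.emissionprob[:, primary])
    )
    return HMMModel(
        model.n_states,
        model.marks,
        model.startprob[order],
        model.transmat[np.ix_(order, order)],
        model.emissionprob[order],
        loglik_trace=model.loglik_trace,
    )


def decode(
    model: HMMModel, binary: BinaryMatrix, mode: str = "posterior"
) -> Segmentation:
    """Assign a state to every bin and merge runs into segments.

    ``posterior`` (default) takes the argmax of per-bin posteriors from the
    forward-backward pass; ``viterbi`` takes the jointly most probable path.
    States in the result are 1-based.
    """
    if binary.marks != model.marks:
        raise ValueError("mark order of model and binary matrix differ")
    if mode not in ("posterior", "viterbi"):
        raise ValueError(f"unknown decode mode {mode!r}")
    grid = binary.grid
    state_path: dict[str, np.ndarray] = {}
    posterior: dict[str, np.ndarray] = {}
    for chrom in grid.chroms:
        obs = np.asarray(binary.calls[chrom], dtype=float)
        B = _emission_matrix(model.emissionprob, obs)
        if mode == "posterior":
            alpha, c, ll = _scaled_forward(model, B)
            if not np.isfinite(ll):
                raise ValueError(f"{chrom}: zero-probability sequence")
            beta = _scaled_backward(model, B, c)
            gamma = alpha * beta
            posterior[chrom] = gamma
            state_path[chrom] = gamma.argmax(axis=1) + 1
        else:
            state_path[chrom] = _viterbi(model, B) + 1
    segments = _merge_segments(grid, state_path)
    return Segmentation(
        grid=grid,
        segments=segments,
        state_path=state_path,
        posterior=posterior if mode == "posterior" else None,
        cell_type=binary.cell_type,
    )


def _viterbi(model: HMMModel, B: np.ndarray) -> np.ndarray:
    T, K = B.shape
    with np.errstate(divide="ignore"):
        logA = np.log(model.transmat)
        logB = np.log(B)
        logpi = np.log(model.startprob)
    delta = logpi + logB[0]
    back = np.empty((T, K), dtype=np.int32)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _merge_segments(
    grid: BinGrid, state_path: dict[str, np.ndarray]
) -> list[tuple[GenomicInterval, int]]:
    segments: list[tuple[GenomicInterval, int]] = []
    bs = grid.bin_size
    for chrom in grid.chroms:
        path = state_path[chrom]
        chrom_len = grid.chrom_lengths[chrom]
        boundaries = np.flatnonzero(np.diff(path)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(path)]))
        for s, e in zip(starts, ends):
            segments.append(
                (
                    GenomicInterval(chrom, int(s) * bs, min(int(e) * bs, chrom_len)),
                    int(path[s]),
                )
            )
    return segments


def sample_sequence(
    model: HMMModel, T: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (states 0-based, observations) of length T from the model."""
    rng = seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed)
    )
    K, M = model.n_states, len(model.marks)
    states = np.empty(T, dtype=np.int64)
    states[0] = rng.choice(K, p=model.startprob)
    for t in range(1, T):
        states[t] = rng.choice(K, p=model.transmat[states[t - 1]])
    obs = (rng.random((T, M)) < model.emissionprob[states]).astype(np.uint8)
    return states, obs


# ---------------------------------------------------------------------------
# Model text serialization (TSV blocks: pi, transitions, emissions)
# ---------------------------------------------------------------------------

def write_model(model: HMMModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#states\t{model.n_states}\n")
        fh.write("#marks\t" + "\t".join(model.marks) + "\n")
        fh.write("#initial\n")
        fh.write("\t".join(f"{v:.10g}" for v in model.startprob) + "\n")
        fh.write("#transitions\n")
        for row in model.transmat:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")
        fh.write("#emissions\n")
        for row in model.emissionprob:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_model(path: str | Path) -> HMMModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    K = int(lines[0].split("\t")[1])
    marks = lines[1].split("\t")[1:]
    idx = lines.index("#initial")
    pi = np.array([float(v) for v in lines[idx + 1].split("\t")])
    tidx = lines.index("#transitions")
    A = np.array(
        [[float(v) for v in lines[tidx + 1 + k].split("\t")] for k in range(K)]
    )
    eidx = lines.index("#emissions")
    E = np.array(
        [[float(v) for v in lines[eidx + 1 + k].split("\t")] for k in range(K)]
    )
    return HMMModel(K, marks, pi, A, E)
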