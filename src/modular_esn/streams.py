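"""Synthetic input generators for every experiment.

Three kinds of input drive the simulations: i.i.d. Bernoulli binary streams
for the memory-capacity task, one-hot 4x5 binary sequences with a separate
cue channel for the recall task, and constant drive signals for the
spreading experiments.  All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BinaryStream",
    "SequenceSet",
    "RecallEpisode",
    "binomial_stream",
    "one_hot_sequence_set",
    "assemble_recall_episode",
    "constant_drive",
]

N_CHANNELS = 4
SEQ_LENGTH = 5
N_UNIQUE_SEQUENCES = N_CHANNELS**SEQ_LENGTH  # 1024 one-hot 4x5 sequences


@dataclass(frozen=True)
class BinaryStream:
    """An i.i.d. Bernoulli(p) stream of 0s and 1s."""

    values: np.ndarray
    p: float
    seed: int

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": np.arange(len(self.values)), "u": self.values})


@dataclass(frozen=True)
class SequenceSet:
    """Distinct one-hot 4x5 binary sequences.

    ``sequences`` has shape (n, 4, 5): at each of the 5 time steps exactly
    one of the 4 channels is active, so each column sums to 1.
    """

    sequences: np.ndarray
    seed: int

    def __len__(self) -> int:
        return self.sequences.shape[0]


@dataclass(frozen=True)
class RecallEpisode:
    """One recall trial: sequence, delay, cue, decision.

    ``inputs`` has 5 channels (4 data + 1 cue) and ``5 + delta_t + 2``
    columns: the sequence occupies the first 5 steps, then ``delta_t``
    all-zero distractor steps, then the cue (channel 5 set to 1.0 for one
    step), then one all-zero decision step at which the readout is
    evaluated.  ``target`` is the flattened 20-bit sequence.
    """

    inputs: np.ndarray
    target: np.ndarray
    cue_step: int
    decision_step: int

    @property
    def n_steps(self) -> int:
        return self.inputs.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.inputs.T, columns=[f"ch{j}" for j in range(self.inputs.shape[0])])
        df.insert(0, "t", np.arange(self.n_steps))
        return df


def binomial_stream(T: int, p: float = 0.5, seed: int = 0) -> BinaryStream:
    """Length-``T`` i.i.d. Bernoulli(``p``) stream of 0s and 1s."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    values = (rng.random(T) < p).astype(np.float64)
    return BinaryStream(values=values, p=p, seed=seed)


def one_hot_sequence_set(n: int, seed: int = 0) -> SequenceSet:
    """Sample ``n`` distinct one-hot 4x5 sequences uniformly without replacement.

    There are 4^5 = 1024 such sequences; each is encoded by its base-4 code
    (the active channel at each of the 5 steps), and ``n`` codes are drawn
    without replacement so the set is duplicate-free.
    """
    if not 1 <= n <= N_UNIQUE_SEQUENCES:
        raise ValueError(f"n must lie in [1, {N_UNIQUE_SEQUENCES}], got {n}")
    rng = np.random.default_rng(seed)
    codes = rng.choice(N_UNIQUE_SEQUENCES, size=n, replace=False)
    sequences = np.zeros((n, N_CHANNELS, SEQ_LENGTH), dtype=np.float64)
    for idx, code in enumerate(codes):
        for t in range(SEQ_LENGTH):
            sequences[idx, code % N_CHANNELS, t] = 1.0
            code //= N_CHANNELS
    return SequenceSet(sequences=sequences, seed=seed)


def assemble_recall_episode(seq: np.ndarray, delta_t: int) -> RecallEpisode:
    """Lay out one recall episode around a 4x5 sequence.

    Steps (1-based): 1-5 present the sequence on channels 1-4; steps
    ``6 .. 5 + delta_t`` are the all-zero distractor; step ``5 + delta_t + 1``
    raises the cue channel to 1.0; the following step is the decision step
    (all channels zero) at which the readout is read once.
    """
    seq = np.asarray(seq, dtype=np.float64)
    if seq.shape != (N_CHANNELS, SEQ_LENGTH):
        raise ValueError(f"expected a {N_CHANNELS}x{SEQ_LENGTH} sequence, got shape {seq.shape}")
    if delta_t < 0:
        raise ValueError(f"delta_t must be >= 0, got {delta_t}")
    n_steps = SEQ_LENGTH + delta_t + 2
    inputs = np.zeros((N_CHANNELS + 1, n_steps), dtype=np.float64)
    inputs[:N_CHANNELS, :SEQ_LENGTH] = seq
    cue_step = SEQ_LENGTH + delta_t  # 0-based column index
    inputs[N_CHANNELS, cue_step] = 1.0
    return RecallEpisode(
        inputs=inputs,
        target=seq.ravel().copy(),
        cue_step=cue_step,
        decision_step=cue_step + 1,
    )


def constant_drive(value: float, k_in: int, T_max: int) -> np.ndarray:
    """A ``k_in x T_max`` input matrix holding ``value`` on every channel."""
    if T_max < 1:
        raise ValueError(f"T_max must be >= 1, got {T_max}")
    return np.full((k_in, T_max), float(value))
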