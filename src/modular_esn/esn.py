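"""Echo state network core: dynamics, activation, readout training.

The reservoir follows standard discrete-time ESN dynamics without feedback
or time constants,

    x(t+1) = f(W x(t) + W_in u(t+1)),
    y(t)   = g(W_out [x(t) : u(t)]),

where ``f`` is the neuron activation, ``g`` the readout rule and
``[a : b]`` denotes vector concatenation.  The default activation is a
general sigmoid

    f(z) = a / (b + exp(-gain * (z - c))) - d

with ``(a, b, c, gain, d) = (1, 1, 1, 10, 0)``: a steep, threshold-like
response centered at ``z = 1`` that makes the spreading dynamics a complex
contagion — a neuron fires only when several presynaptic neurons are active
in unison.  ``linear`` and ``tanh`` presets give the classic ESN regimes
used as controls.

Only the readout weights are trained, by ordinary least squares against the
history of reservoir states: ``W_out = Y_target X^+`` with ``X^+`` the
Moore-Penrose pseudoinverse of the stacked ``[x(t) : u(t)]`` design matrix.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "ActivationParams",
    "InputProjection",
    "Reservoir",
    "Trajectory",
    "Readout",
    "activation",
    "build_input_weights",
    "step_state",
    "run_reservoir",
    "train_readout",
    "readout_output",
    "save_reservoir",
    "load_reservoir",
]


@dataclass(frozen=True)
class ActivationParams:
    """Neuron activation function.

    ``name = "threshold"`` (the default) is the general sigmoid with
    parameters ``a = b = c = 1``, ``gain = 10``, ``d = 0``; ``"linear"``
    is the identity; ``"tanh"`` the hyperbolic tangent.  Arbitrary sigmoid
    shapes can be built with ``name = "sigmoid"`` and explicit parameters.
    """

    name: str = "threshold"
    a: float = 1.0
    b: float = 1.0
    c: float = 1.0
    gain: float = 10.0
    d: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ("threshold", "sigmoid", "linear", "tanh"):
            raise ValueError(f"unknown activation preset {self.name!r}")
        if self.b <= 0:
            raise ValueError("sigmoid parameter b must be positive")
        if self.name == "threshold" and (
            (self.a, self.b, self.c, self.gain, self.d) != (1.0, 1.0, 1.0, 10.0, 0.0)
        ):
            raise ValueError(
                "the 'threshold' preset fixes (a, b, c, gain, d) = (1, 1, 1, 10, 0); "
                "use name='sigmoid' for other shapes"
            )

    @classmethod
    def threshold(cls) -> "ActivationParams":
        return cls(name="threshold")

    @classmethod
    def linear(cls) -> "ActivationParams":
        return cls(name="linear")

    @classmethod
    def tanh(cls) -> "ActivationParams":
        return cls(name="tanh")

    @property
    def range(self) -> tuple[float, float]:
        """Closed output range of the activation (infinite for linear)."""
        if self.name in ("threshold", "sigmoid"):
            return (-self.d, self.a / self.b - self.d)
        if self.name == "tanh":
            return (-1.0, 1.0)
        return (-np.inf, np.inf)

    def __call__(self, z):
        return activation(z, self)


def activation(z, params: ActivationParams):
    """Apply the activation elementwise.

    For the sigmoid presets this is ``a / (b + exp(-gain * (z - c))) - d``,
    monotone non-decreasing for positive gain and saturating at
    ``a / b - d`` (z -> +inf) and ``-d`` (z -> -inf).
    """
    z = np.asarray(z, dtype=np.float64)
    if params.name == "linear":
        out = z.copy()
    elif params.name == "tanh":
        out = np.tanh(z)
    else:
        with np.errstate(over="ignore"):
            out = params.a / (params.b + np.exp(-params.gain * (z - params.c))) - params.d
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class InputProjection:
    """How input channels connect into the reservoir.

    Each input dimension is injected into an independent uniformly random
    subset of ``round(r_sig * N)`` neurons, with weights drawn uniform on
    ``[iw_low, iw_high]`` (constant when the bounds coincide) and scaled by
    ``input_gain``.
    """

    r_sig: float
    input_gain: float = 1.0
    iw_low: float = -0.2
    iw_high: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.r_sig <= 1.0:
            raise ValueError(f"r_sig must lie in (0, 1], got {self.r_sig}")
        if self.input_gain <= 0:
            raise ValueError("input_gain must be positive")
        if self.iw_low > self.iw_high:
            raise ValueError("iw_low must be <= iw_high")


def build_input_weights(n_nodes: int, k_in: int, proj: InputProjection) -> np.ndarray:
    """Build the dense ``N x k_in`` input weight matrix.

    Exactly ``round(r_sig * N)`` entries per column are nonzero, at rows
    chosen uniformly without replacement, independently per column.
    Deterministic given ``proj.seed``.
    """
    n_receiving = int(round(proj.r_sig * n_nodes))
    if n_receiving < 1:
        raise ValueError(
            f"r_sig = {proj.r_sig} selects zero of {n_nodes} neurons; no neuron would receive input"
        )
    rng = np.random.default_rng(proj.seed)
    W_in = np.zeros((n_nodes, k_in), dtype=np.float64)
    for j in range(k_in):
        rows = rng.choice(n_nodes, size=n_receiving, replace=False)
        if proj.iw_low == proj.iw_high:
            w = np.full(n_receiving, proj.iw_low)
        else:
            w = rng.uniform(proj.iw_low, proj.iw_high, size=n_receiving)
        W_in[rows, j] = w * proj.input_gain
    return W_in


@dataclass
class Reservoir:
    """A fixed recurrent network: weights, input projection and activation.

    ``W[i, j]`` is the weight of the directed edge from presynaptic ``j``
    to postsynaptic ``i``; ``W_in`` maps the ``k_in`` input channels onto
    the neurons.  ``membership`` carries the community labels of the
    generating graph when there is one.
    """

    W: sparse.csr_array
    W_in: np.ndarray
    activation: ActivationParams = field(default_factory=ActivationParams.threshold)
    membership: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if self.W_in.shape[0] != self.W.shape[0]:
            raise ValueError(
                f"W and W_in row counts disagree: {self.W.shape[0]} vs {self.W_in.shape[0]}"
            )

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def k_in(self) -> int:
        return self.W_in.shape[1]


@dataclass(frozen=True)
class Trajectory:
    """State history ``X`` (N x T) aligned with its inputs ``U`` (k_in x T).

    Column ``t`` of ``X`` is the state x(t+1) reached in response to input
    column ``t`` of ``U`` (u(t+1)); the initial state x(0) is not stored.
    """

    X: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape[1] != self.U.shape[1]:
            raise ValueError("X and U must have the same number of columns")

    @property
    def n_steps(self) -> int:
        return self.X.shape[1]

    def design_matrix(self) -> np.ndarray:
        """The (N + k_in) x T stacked regression design ``[x(t) : u(t)]``."""
        return np.vstack([self.X, self.U])


def step_state(x: np.ndarray, u_next: np.ndarray, res: Reservoir) -> np.ndarray:
    """One update ``f(W x + W_in u)``.

    ``x`` may be a single state ``(N,)`` or a batch ``(N, B)`` of states
    evolving under a matching batch of inputs; batches are independent
    columns (no interaction), which is how episode sets are run efficiently.
    """
    x = np.asarray(x, dtype=np.float64)
    u_next = np.asarray(u_next, dtype=np.float64)
    if x.shape[0] != res.n_nodes or u_next.shape[0] != res.k_in:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[0]} rows, u has {u_next.shape[0]}; "
            f"reservoir expects {res.n_nodes} and {res.k_in}"
        )
    if x.ndim != u_next.ndim or (x.ndim == 2 and x.shape[1] != u_next.shape[1]):
        raise ValueError("x and u_next batch shapes disagree")
    z = res.W @ x + res.W_in @ u_next
    return activation(z, res.activation)


def run_reservoir(x0: np.ndarray | None, inputs: np.ndarray, res: Reservoir) -> Trajectory:
    """Drive the reservoir with ``inputs`` (k_in x T) from ``x0`` (default 0).

    Purely deterministic given the weights and inputs; T = 0 yields an
    empty trajectory.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
    if inputs.shape[0] != res.k_in:
        raise ValueError(f"inputs have {inputs.shape[0]} channels, reservoir expects {res.k_in}")
    n, T = res.n_nodes, inputs.shape[1]
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=np.float64).copy()
    X = np.empty((n, T), dtype=np.float64)
    for t in range(T):
        x = step_state(x, inputs[:, t], res)
        X[:, t] = x
    return Trajectory(X=X, U=inputs)


@dataclass(frozen=True)
class Readout:
    """Trained linear readout, optionally followed by the step rule.

    ``W_out`` has shape ``l x (N + k_in)``; the output is
    ``z = W_out [x : u]`` passed through the step function
    ``g(z) = 1 if z > 0.5 else 0`` in ``"step"`` mode, or returned as-is in
    ``"identity"`` mode.  The boundary ``z = 0.5`` maps to 0.
    """

    W_out: np.ndarray
    mode: str = "identity"

    def __post_init__(self) -> None:
        if self.mode not in ("identity", "step"):
            raise ValueError(f"readout mode must be 'identity' or 'step', got {self.mode!r}")


def train_readout(traj: Trajectory, targets: np.ndarray, mode: str = "identity") -> Readout:
    """Least-squares readout training against the trajectory history.

    Solves ``min ||W_out D - targets||_F`` with ``D`` the stacked
    ``[x(t) : u(t)]`` design; for rank-deficient designs the minimum-norm
    solution is returned (pseudoinverse contract).  No regularization.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    if targets.shape[1] != traj.n_steps:
        raise ValueError(
            f"targets have {targets.shape[1]} columns but trajectory has {traj.n_steps}"
        )
    D = traj.design_matrix()
    sol, *_ = np.linalg.lstsq(D.T, targets.T, rcond=None)
    return Readout(W_out=sol.T, mode=mode)


def readout_output(x: np.ndarray, u: np.ndarray, ro: Readout) -> np.ndarray:
    """Evaluate the readout on one state (or a batch of state columns)."""
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    u = np.atleast_1d(np.asarray(u, dtype=np.float64))
    stacked = np.concatenate([x, u], axis=0)
    if stacked.shape[0] != ro.W_out.shape[1]:
        raise ValueError(
            f"state+input dimension {stacked.shape[0]} does not match readout "
            f"width {ro.W_out.shape[1]}"
        )
    z = ro.W_out @ stacked
    if ro.mode == "step":
        return (z > 0.5).astype(np.float64)
    return z


# -- serialization ----------------------------------------------------------

def save_reservoir(directory, res: Reservoir) -> None:
    """Save a reservoir to a directory (weights TSV, input TSV, JSON header).

    Weights are written with 17 significant digits so the round trip is
    bit-exact.
    """
    os.makedirs(directory, exist_ok=True)
    coo = res.W.tocoo()
    with open(os.path.join(directory, "weights.tsv"), "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{j}\t{i}\t{w:.17g}\n")
    with open(os.path.join(directory, "input_weights.tsv"), "w") as fh:
        fh.write("node\tchannel\tweight\n")
        rows, cols = np.nonzero(res.W_in)
        for i, j in zip(rows, cols):
            fh.write(f"{i}\t{j}\t{res.W_in[i, j]:.17g}\n")
    header = {
        "n_nodes": res.n_nodes,
        "k_in": res.k_in,
        "activation": {
            "name": res.activation.name,
            "a": res.activation.a,
            "b": res.activation.b,
            "c": res.activation.c,
            "gain": res.activation.gain,
            "d": res.activation.d,
        },
        "membership": None if res.membership is None else [int(m) for m in res.membership],
    }
    with open(os.path.join(directory, "reservoir.json"), "w") as fh:
        json.dump(header, fh, indent=1)


def load_reservoir(directory) -> Reservoir:
    """Load a reservoir saved by :func:`save_reservoir`."""
    with open(os.path.join(directory, "reservoir.json")) as fh:
        header = json.load(fh)
    n, k_in = header["n_nodes"], header["k_in"]
    rows, cols, data = [], [], []
    with open(os.path.join(directory, "weights.tsv")) as fh:
        next(fh)
        for line in fh:
            j, i, w = line.split("\t")
            rows.append(int(i))
            cols.append(int(j))
            data.append(float(w))
    W = sparse.csr_array((data, (rows, cols)), shape=(n, n))
    W_in = np.zeros((n, k_in))
    with open(os.path.join(directory, "input_weights.tsv")) as fh:
        next(fh)
        for line in fh:
            i, j, w = line.split("\t")
            W_in[int(i), int(j)] = float(w)
    act = ActivationParams(**header["activation"])
    membership = header["membership"]
    return Reservoir(
        W=W,
        W_in=W_in,
        activation=act,
        membership=None if membership is None else np.asarray(membership),
    )
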