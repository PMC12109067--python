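"""Four-layer dendritic ganglion network (a sigma-pi architecture).

Per receptive field the 24 binary horizontal-cell features x_i pass through:

  synapse   s_ijm = sigmoid((w_ijm * x_i - q_ijm) / d_ijm)
  branch    b_jm  = prod_i s_ijm                      (multiplicative dendrite)
  membrane  u_m   = sum_j v_jm * b_jm
  soma      o_m   = sigmoid(lambda_m * (u_m - theta_m))

One shared parameter set is applied at every receptive field of the image and
the per-field soma outputs are sum-pooled into the global direction-response
vector.  Because each synapse after training sits in one of four regimes --
excitatory, inhibitory, constant-1 (pass-through) or constant-0 (pruned, it
silences its branch) -- learning effectively rewires which inputs each
dendrite listens to.

For binary inputs every synapse takes only two values, sigmoid(-q/d) and
sigmoid((w-q)/d), which lets the branch products be evaluated as a single
log-space matrix product over all receptive fields at once.  The general
per-field path is retained for real-valued inputs and as a cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .hc_frontend import HCFeatureField, feature_matrix

__all__ = [
    "ModelParams", "ForwardTrace", "sigmoid", "log_sigmoid",
    "synapse_forward", "branch_forward", "membrane_forward", "soma_forward",
    "forward_image", "predict", "predict_batch", "classify_synapse_state",
    "save_checkpoint", "load_checkpoint",
]

N_INPUTS = 24
N_OUTPUTS = 8


def sigmoid(z: np.ndarray | float) -> np.ndarray:
    """Overflow-guarded logistic (dtype-preserving for float inputs)."""
    z = np.asarray(z)
    if z.dtype not in (np.float32, np.float64):
        z = z.astype(np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def log_sigmoid(z: np.ndarray) -> np.ndarray:
    """log(sigmoid(z)) computed stably."""
    return -np.logaddexp(0.0, -np.asarray(z, dtype=np.float64))


@dataclass
class ModelParams:
    """All parameters of the dendritic network.

    ``w`` and ``q`` (shape I x J x M) are learnable; the synapse distance
    ``d`` is fixed at 1 (any constant d is absorbed into w and q), the branch
    weights ``v`` (J x M) are fixed at 1/J so the membrane potential stays in
    (0, 1) regardless of the branch count, and the soma slope/threshold
    default to lambda=10, theta=0.5 so a single fully active branch centers
    the soma at its threshold.
    """

    w: np.ndarray
    q: np.ndarray
    v: np.ndarray
    lam: np.ndarray
    theta: np.ndarray
    d: float = 1.0
    theta_h: int = 3

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        self.q = np.asarray(self.q, dtype=np.float64)
        if self.w.shape != self.q.shape or self.w.ndim != 3:
            raise ValueError("w and q must both have shape (I, J, M)")
        i, j, m = self.w.shape
        self.v = np.asarray(self.v, dtype=np.float64).reshape(j, m)
        self.lam = np.asarray(self.lam, dtype=np.float64).reshape(m)
        self.theta = np.asarray(self.theta, dtype=np.float64).reshape(m)
        if np.any(self.lam <= 0):
            raise ValueError("soma slope lambda must be positive")
        if self.d <= 0:
            raise ValueError("synapse distance d must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.w.shape

    @property
    def n_branches(self) -> int:
        return self.w.shape[1]

    @classmethod
    def init_random(
        cls,
        n_branches: int,
        rng: np.random.Generator | int | None = None,
        n_inputs: int = N_INPUTS,
        n_outputs: int = N_OUTPUTS,
        lam: float = 10.0,
        theta: float = 0.5,
        v_mode: str = "mean",
        theta_h: int = 3,
        w_range: tuple[float, float] = (-1.0, 1.0),
        q_range: tuple[float, float] = (-4.0, -2.0),
        output_symmetric: bool = True,
    ) -> "ModelParams":
        """Random initialization in the permissive (unpruned) regime.

        Weights draw from ``w_range`` and biases from ``q_range``; the
        default bias range puts every synapse near the constant-1
        (pass-through) state, so branch products start well away from zero
        and gradients can flow -- learning then carves excitatory,
        inhibitory and pruned (constant-0) synapses out of this permissive
        start, mirroring developmental synaptic pruning.  A mid-range bias
        init collapses the 24-factor products to ~1e-8 and freezes learning.

        With ``output_symmetric`` (default) the same random draw is shared
        by all eight direction outputs, so the untrained network responds
        identically to every direction and starts exactly at the uniform
        predictor; per-output asymmetries then grow only from the label
        signal.  Set False for fully independent draws.

        ``v_mode='mean'`` sets v = 1/J; ``'one'`` sets v = 1.
        """
        if n_branches < 1:
            raise ValueError("branch count must be >= 1")
        rng = np.random.default_rng(rng)
        v_val = 1.0 / n_branches if v_mode == "mean" else 1.0
        if output_symmetric:
            w0 = rng.uniform(*w_range, size=(n_inputs, n_branches, 1))
            q0 = rng.uniform(*q_range, size=(n_inputs, n_branches, 1))
            w = np.repeat(w0, n_outputs, axis=2)
            q = np.repeat(q0, n_outputs, axis=2)
        else:
            shape = (n_inputs, n_branches, n_outputs)
            w = rng.uniform(*w_range, size=shape)
            q = rng.uniform(*q_range, size=shape)
        return cls(
            w=w, q=q,
            v=np.full((n_branches, n_outputs), v_val),
            lam=np.full(n_outputs, lam),
            theta=np.full(n_outputs, theta),
            theta_h=theta_h,
        )

    def copy(self) -> "ModelParams":
        return ModelParams(self.w.copy(), self.q.copy(), self.v.copy(),
                           self.lam.copy(), self.theta.copy(),
                           d=self.d, theta_h=self.theta_h)


@dataclass
class ForwardTrace:
    """Per-field intermediates of one image, retained for the backward pass.

    ``S`` (fields x I x J x M) is stored only when the forward pass ran the
    general real-input path; on the binary fast path it is reconstructable
    from ``X`` and the two synapse values and left as None.
    """

    X: np.ndarray                 # (F, I) inputs per receptive field
    B: np.ndarray                 # (F, J, M) branch outputs
    U: np.ndarray                 # (F, M) membrane outputs
    O_field: np.ndarray           # (F, M) per-field soma outputs
    O_pooled: np.ndarray          # (M,) sum-pooled response vector
    binary: bool = True
    S: np.ndarray | None = None

    @property
    def n_fields(self) -> int:
        return self.X.shape[0]


# ---------------------------------------------------------------------------
# Layerwise operations (single receptive field)
# ---------------------------------------------------------------------------

def synapse_forward(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """Synaptic outputs s_ijm for one receptive field, shape (I, J, M)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != params.shape[0]:
        raise ValueError("input length does not match parameter shape")
    z = (params.w * x[:, None, None] - params.q) / params.d
    return sigmoid(z)


def branch_forward(S: np.ndarray) -> np.ndarray:
    """Branch outputs b_jm = prod_i s_ijm, shape (J, M).

    Evaluated in log space when the product is long, to preserve precision;
    identical to the plain product within 1e-12 relative.
    """
    S = np.asarray(S, dtype=np.float64)
    if S.shape[0] * S.shape[1] * S.shape[2] > 4096:
        return np.exp(np.sum(np.log(S), axis=0))
    return np.prod(S, axis=0)


def membrane_forward(B: np.ndarray, params: ModelParams) -> np.ndarray:
    """Membrane potentials u_m = sum_j v_jm b_jm, shape (M,)."""
    return np.sum(params.v * B, axis=0)


def soma_forward(U: np.ndarray, params: ModelParams) -> np.ndarray:
    """Soma outputs o_m = sigmoid(lambda_m (u_m - theta_m))."""
    return sigmoid(params.lam * (np.asarray(U, dtype=np.float64) - params.theta))


# ---------------------------------------------------------------------------
# Whole-image forward pass
# ---------------------------------------------------------------------------

def _binary_tables(params: ModelParams):
    """Per-parameter synapse values for x=0 and x=1 (binary-input regime)."""
    z0 = -params.q / params.d
    z1 = (params.w - params.q) / params.d
    return z0, z1


def _forward_stack_binary(X: np.ndarray, params: ModelParams,
                          dtype=np.float64):
    """Vectorized forward over a stack of receptive fields.

    X: (F, I) binary.  Returns (B, U, O) with shapes (F,J,M), (F,M), (F,M).
    log b[f,j,m] = sum_i log s0[i,j,m] + sum_i x[f,i] (log s1 - log s0)[i,j,m]

    ``dtype=float32`` roughly halves time and memory; the training loop uses
    it (accuracy is gradient-noise dominated), while the public forward pass
    stays in float64.
    """
    i, j, m = params.shape
    z0, z1 = _binary_tables(params)
    ls0 = log_sigmoid(z0)
    ls1 = log_sigmoid(z1)
    base = ls0.sum(axis=0).reshape(1, j * m).astype(dtype)
    delta = (ls1 - ls0).reshape(i, j * m).astype(dtype)
    logB = base + X.astype(dtype) @ delta
    B = np.exp(logB).reshape(-1, j, m)
    U = np.einsum("fjm,jm->fm", B, params.v.astype(dtype))
    O = sigmoid(params.lam.astype(dtype) * (U - params.theta.astype(dtype)))
    return B, U, O


def _forward_stack_general(X: np.ndarray, params: ModelParams):
    """Reference path for arbitrary real inputs; also returns S."""
    z = (params.w[None] * X[:, :, None, None].astype(np.float64)
         - params.q[None]) / params.d
    S = sigmoid(z)                               # (F, I, J, M)
    B = np.exp(np.sum(log_sigmoid(z), axis=1))   # (F, J, M)
    U = np.einsum("fjm,jm->fm", B, params.v)
    O = sigmoid(params.lam * (U - params.theta))
    return S, B, U, O


def forward_image(field: HCFeatureField | np.ndarray, params: ModelParams) -> ForwardTrace:
    """Run the network at every receptive field and sum-pool the soma outputs.

    ``field`` may be an :class:`HCFeatureField` or a pre-flattened (F, I)
    input matrix.  Binary inputs take the fast log-space path.
    """
    X = feature_matrix(field) if isinstance(field, HCFeatureField) else np.asarray(field)
    if X.ndim != 2 or X.shape[1] != params.shape[0]:
        raise ValueError("input matrix must be (n_fields, I)")
    binary = bool(np.isin(X, (0, 1)).all())
    if binary:
        B, U, O = _forward_stack_binary(X, params)
        S = None
    else:
        S, B, U, O = _forward_stack_general(X, params)
    return ForwardTrace(X=X, B=B, U=U, O_field=O, O_pooled=O.sum(axis=0),
                        binary=binary, S=S)


def predict(O_pooled: np.ndarray) -> int:
    """Direction code (1..8) of the maximal pooled response; ties -> lowest code."""
    return int(np.argmax(O_pooled)) + 1


def predict_batch(X_stack: np.ndarray, params: ModelParams,
                  chunk: int = 128, dtype=np.float64) -> np.ndarray:
    """Predicted direction codes for a stack of images.

    X_stack: (N, F, I) binary feature matrices (one per image).
    ``dtype=float32`` speeds up monitoring loops; the default keeps full
    precision for reported predictions.
    """
    n, f, i = X_stack.shape
    codes = np.empty(n, dtype=np.int64)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        flat = X_stack[lo:hi].reshape(-1, i)
        _, _, O = _forward_stack_binary(flat, params, dtype=dtype)
        pooled = O.reshape(hi - lo, f, -1).sum(axis=1, dtype=np.float64)
        codes[lo:hi] = np.argmax(pooled, axis=1) + 1
    return codes


def classify_synapse_state(w: float, q: float, d: float = 1.0) -> str:
    """Functional regime of one synapse under binary inputs.

    s0 = sigmoid(-q/d) is the response to x=0, s1 = sigmoid((w-q)/d) to x=1.
    constant_1: both above 0.5 (pass-through); constant_0: both below 0.5
    (pruned -- the branch is silenced); excitatory: s1 above, s0 below;
    inhibitory: s0 above, s1 below.
    """
    s0 = float(sigmoid(-q / d))
    s1 = float(sigmoid((w - q) / d))
    if min(s0, s1) > 0.5:
        return "constant_1"
    if max(s0, s1) < 0.5:
        return "constant_0"
    if s1 >= s0:
        return "excitatory"
    return "inhibitory"


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(params: ModelParams, path: str | Path,
                    extra: dict | None = None) -> Path:
    """Write parameters to a single NPZ archive with a versioned JSON header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    i, j, m = params.shape
    header = {
        "version": CHECKPOINT_VERSION,
        "I": i, "J": j, "M": m,
        "d": params.d, "theta_h": params.theta_h,
        "extra": extra or {},
    }
    np.savez_compressed(
        path, w=params.w, q=params.q, v=params.v, lam=params.lam,
        theta=params.theta,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
    )
    return path


def load_checkpoint(path: str | Path) -> tuple[ModelParams, dict]:
    """Load a checkpoint; returns (params, header)."""
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["header"]).decode())
        params = ModelParams(
            w=data["w"], q=data["q"], v=data["v"], lam=data["lam"],
            theta=data["theta"], d=float(header["d"]),
            theta_h=int(header["theta_h"]),
        )
    return params, header
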