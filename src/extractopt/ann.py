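"""Feed-forward MLP trained by Levenberg-Marquardt, for RSM comparison.

The network is the classic one-hidden-layer regression MLP: tangent-
sigmoid hidden units, linear outputs, inputs and targets min-max
normalized to [-1, 1]. Default topology is 3-6-4 (three extraction
factors in, four assay responses out, six hidden neurons).

Training is full-batch Levenberg-Marquardt on the summed squared error
over all outputs: steps dw = -(J'J + mu*I)^-1 J'e with the damping mu
decreased after an accepted step and increased after a rejected one,
plus early stopping on a held-out validation subset (training stops
after ``max_val_fail`` consecutive epochs without a new validation
best, and the best-validation weights are returned). The Jacobian is
analytic; everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design import DesignMatrix

__all__ = [
    "MLPModel",
    "TrainConfig",
    "TrainingHistory",
    "split_dataset",
    "forward",
    "train_mlp",
    "train_best_of",
    "predict_mlp",
    "tansig",
]


def tansig(z: np.ndarray) -> np.ndarray:
    """Hyperbolic-tangent sigmoid, 2/(1+exp(-2z)) - 1 == tanh(z)."""
    return np.tanh(z)


@dataclass
class TrainConfig:
    hidden: int = 6
    max_epochs: int = 1000
    mu0: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 10.0
    mu_max: float = 1e10
    max_val_fail: int = 6
    grad_tol: float = 1e-10
    seed: int = 0
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    init: str = "nguyen-widrow"  # or "uniform" (U(-0.5, 0.5))

    def __post_init__(self) -> None:
        if not 1 <= self.hidden <= 15:
            raise ValueError("hidden layer size must be in 1..15")
        if self.mu0 <= 0:
            raise ValueError("mu0 must be > 0")
        if self.init not in ("nguyen-widrow", "uniform"):
            raise ValueError("init must be 'nguyen-widrow' or 'uniform'")
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("split fractions must be >= 0 and sum to 1")


@dataclass
class MLPModel:
    """Weights plus the input/output normalization that makes them usable."""

    W1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (n_out, hidden)
    b2: np.ndarray  # (n_out,)
    x_min: np.ndarray
    x_max: np.ndarray
    y_min: np.ndarray
    y_max: np.ndarray

    @property
    def n_in(self) -> int:
        return self.W1.shape[1]

    @property
    def n_out(self) -> int:
        return self.W2.shape[0]

    @property
    def hidden(self) -> int:
        return self.W1.shape[0]

    def normalize_x(self, X: np.ndarray) -> np.ndarray:
        rng = np.where(self.x_max > self.x_min, self.x_max - self.x_min, 1.0)
        return 2.0 * (X - self.x_min) / rng - 1.0

    def normalize_y(self, Y: np.ndarray) -> np.ndarray:
        rng = np.where(self.y_max > self.y_min, self.y_max - self.y_min, 1.0)
        return 2.0 * (Y - self.y_min) / rng - 1.0

    def denormalize_y(self, Yn: np.ndarray) -> np.ndarray:
        rng = np.where(self.y_max > self.y_min, self.y_max - self.y_min, 1.0)
        return (Yn + 1.0) / 2.0 * rng + self.y_min

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k).tolist()
            for k in ("W1", "b1", "W2", "b2", "x_min", "x_max", "y_min", "y_max")
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    train_sse: list[float] = field(default_factory=list)
    val_sse: list[float] = field(default_factory=list)
    mu: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_reason: str = ""


class TrainingFailure(RuntimeError):
    """The damped normal equations could not be solved at any damping."""


def split_dataset(
    n: int, fractions=(0.70, 0.15, 0.15), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint train/validation/test index sets covering range(n).

    Validation and test sizes are round(n * fraction); the remainder
    goes to training. The shuffle is seeded and reproducible.
    """
    f = np.asarray(fractions, dtype=float)
    if n < 3:
        raise ValueError("need n >= 3 to split")
    if np.any(f < 0) or not np.isclose(f.sum(), 1.0):
        raise ValueError("fractions must be >= 0 and sum to 1")
    n_val = int(round(n * f[1]))
    n_test = int(round(n * f[2]))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("empty training set")
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def forward(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """De-normalized network outputs for natural-unit inputs (rows)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_in:
        raise ValueError(f"input dimension {X.shape[1]} != {model.n_in}")
    Xn = model.normalize_x(X)
    A = tansig(Xn @ model.W1.T + model.b1)
    Yn = A @ model.W2.T + model.b2
    return model.denormalize_y(Yn)


predict_mlp = forward


def _pack(W1, b1, W2, b2):
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(theta, h, ni, no):
    i = 0
    W1 = theta[i : i + h * ni].reshape(h, ni); i += h * ni
    b1 = theta[i : i + h]; i += h
    W2 = theta[i : i + no * h].reshape(no, h); i += no * h
    b2 = theta[i : i + no]
    return W1, b1, W2, b2


def _residual_and_jacobian(theta, Xn, Tn, h):
    """Residuals e = y - t (stacked over outputs) and the analytic Jacobian."""
    n, ni = Xn.shape
    no = Tn.shape[1]
    W1, b1, W2, b2 = _unpack(theta, h, ni, no)
    Z = Xn @ W1.T + b1
    A = np.tanh(Z)  # (n, h)
    Y = A @ W2.T + b2
    E = Y - Tn  # (n, no)
    dA = 1.0 - A**2  # tanh'
    P = theta.size
    J = np.empty((n * no, P))
    # column blocks ordered as in _pack
    for o in range(no):
        rows = slice(o * n, (o + 1) * n)
        # dW1[hid, i] = W2[o, hid] * dA[:, hid] * Xn[:, i]
        g = W2[o] * dA  # (n, h)
        J[rows, : h * ni] = (g[:, :, None] * Xn[:, None, :]).reshape(n, h * ni)
        J[rows, h * ni : h * ni + h] = g
        W2block = np.zeros((n, no * h))
        W2block[:, o * h : (o + 1) * h] = A
        J[rows, h * ni + h : h * ni + h + no * h] = W2block
        b2block = np.zeros((n, no))
        b2block[:, o] = 1.0
        J[rows, h * ni + h + no * h :] = b2block
    return E.T.ravel(), J


def _init_theta(rng, h, ni, no, scheme):
    """Seeded initial weights.

    "nguyen-widrow" spreads the hidden-unit active regions evenly over
    the normalized [-1, 1] input cube (the standard initialization for
    tanh layers and the one the classic neural-network toolboxes use);
    "uniform" draws everything from U(-0.5, 0.5).
    """
    if scheme == "uniform":
        return rng.uniform(-0.5, 0.5, size=h * ni + h + no * h + no)
    W1 = rng.uniform(-1.0, 1.0, (h, ni))
    W1 /= np.linalg.norm(W1, axis=1, keepdims=True)
    mag = 0.7 * h ** (1.0 / ni)
    W1 *= mag
    b1 = mag * np.linspace(-1.0, 1.0, h) * np.sign(W1[:, 0])
    W2 = rng.uniform(-0.5, 0.5, (no, h))
    b2 = rng.uniform(-0.5, 0.5, no)
    return _pack(W1, b1, W2, b2)


def _sse(theta, Xn, Tn, h):
    n, ni = Xn.shape
    W1, b1, W2, b2 = _unpack(theta, h, ni, Tn.shape[1])
    Y = np.tanh(Xn @ W1.T + b1) @ W2.T + b2
    return float(np.sum((Y - Tn) ** 2))


def train_mlp(
    design: DesignMatrix | np.ndarray,
    responses,
    config: TrainConfig | None = None,
) -> tuple[MLPModel, TrainingHistory]:
    """Train one network from one seeded initialization.

    ``design`` may be a DesignMatrix (natural units are used) or a raw
    input array; ``responses`` a ResponseTable or target array.
    """
    config = config or TrainConfig()
    X = design.natural if isinstance(design, DesignMatrix) else np.asarray(design, float)
    T = np.asarray(getattr(responses, "values", responses), dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    n, ni = X.shape
    no = T.shape[1]
    h = config.hidden

    model = MLPModel(
        W1=np.zeros((h, ni)), b1=np.zeros(h), W2=np.zeros((no, h)), b2=np.zeros(no),
        x_min=X.min(axis=0), x_max=X.max(axis=0),
        y_min=T.min(axis=0), y_max=T.max(axis=0),
    )
    Xn = model.normalize_x(X)
    Tn = model.normalize_y(T)

    tr, va, te = split_dataset(n, config.fractions, config.seed)
    if len(tr) < 2:
        raise ValueError("need at least 2 training points")

    rng = np.random.default_rng(config.seed)
    theta = _init_theta(rng, h, ni, no, config.init)

    mu = config.mu0
    sse_tr = _sse(theta, Xn[tr], Tn[tr], h)
    best_val = _sse(theta, Xn[va], Tn[va], h) if len(va) else np.inf
    best_theta = theta.copy()
    best_epoch = 0
    val_fail = 0
    hist = TrainingHistory()
    stop = "max_epochs"

    for epoch in range(1, config.max_epochs + 1):
        e, J = _residual_and_jacobian(theta, Xn[tr], Tn[tr], h)
        g = J.T @ e
        if np.max(np.abs(g)) < config.grad_tol:
            stop = "gradient"
            break
        H = J.T @ J
        accepted = False
        while mu <= config.mu_max:
            try:
                step = np.linalg.solve(H + mu * np.eye(H.shape[0]), -g)
            except np.linalg.LinAlgError as err:  # pragma: no cover
                raise TrainingFailure("damped normal equations singular") from err
            cand = theta + step
            sse_new = _sse(cand, Xn[tr], Tn[tr], h)
            if sse_new < sse_tr:
                theta, sse_tr = cand, sse_new
                mu = max(mu / config.mu_decrease, 1e-20)
                accepted = True
                break
            mu *= config.mu_increase
        if not accepted:
            stop = "mu_max"
            break

        val = _sse(theta, Xn[va], Tn[va], h) if len(va) else np.inf
        hist.epochs.append(epoch)
        hist.train_sse.append(sse_tr)
        hist.val_sse.append(val)
        hist.mu.append(mu)
        if len(va):
            if val < best_val:
                best_val, best_theta, best_epoch, val_fail = val, theta.copy(), epoch, 0
            else:
                val_fail += 1
                if val_fail >= config.max_val_fail:
                    stop = "validation"
                    break
        else:
            best_theta, best_epoch = theta.copy(), epoch

    hist.best_epoch = best_epoch
    hist.stop_reason = stop
    model.W1, model.b1, model.W2, model.b2 = _unpack(best_theta, h, ni, no)
    return model, hist


def train_best_of(
    design,
    responses,
    config: TrainConfig | None = None,
    n_restarts: int = 20,
) -> tuple[MLPModel, TrainingHistory, list[TrainingHistory]]:
    """Restart training from ``n_restarts`` seeds; keep the best-validation run.

    Seeds are config.seed, config.seed+1, ...; each restart reshuffles
    the data split and the weight initialization. Selection is by final
    validation SSE (ties go to the earlier seed).
    """
    config = config or TrainConfig()
    best = None
    histories = []
    for i in range(n_restarts):
        cfg = replace(config, seed=config.seed + i)
        model, hist = train_mlp(design, responses, cfg)
        X = design.natural if isinstance(design, DesignMatrix) else np.asarray(design, float)
        T = np.asarray(getattr(responses, "values", responses), dtype=float)
        _, va, _ = split_dataset(X.shape[0], cfg.fractions, cfg.seed)
        val = float(np.sum((forward(model, X[va]) - T[va]) ** 2)) if len(va) else np.inf
        histories.append(hist)
        if best is None or val < best[0]:
            best = (val, model, hist)
    return best[1], best[2], histories
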