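"""Physics-informed neural-network solver for the QSSA-reduced system.

A small feed-forward network maps scaled time ``tau = t / t_max`` in [0, 1]
to the nine slow amounts (vein, artery, seven tissues), normalized by the
injected dose so that a sigmoid output layer can represent them.  Training
minimizes the physics loss

    L(theta) = sum_batch || dNN/dt - f(NN) ||^2  +  || NN(0) - y_ic ||^2

where the time derivative is a first-order finite difference
``(NN(tau + eps) - NN(tau)) / eps`` rescaled by ``t_max``, and
``f(N_nss) = A_nn N_nss + A_ns N_ss`` with the quasi-steady amounts
``N_ss`` re-solved from the algebraic block at every iteration — the
elimination is interleaved with the parameter updates exactly as in the
QSSA training loop, rather than baked into a pre-reduced matrix.

The network is an input layer on scalar scaled time, two tanh hidden
layers and a 9-unit sigmoid output; optimization is Adam on a
full-collocation batch.  Everything is plain numpy with hand-written
backpropagation — the model is tiny and needs no autograd framework.
Training the *full* stiff system this way fails (the sub-second binding
transients are unrepresentable on the scaled-time grid), so the trainer
refuses anything but a reduced system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .qssa import ReducedSystem
from .solve import SolverConfig, Trajectory, integrate


@dataclass
class PinnConfig:
    """Architecture, collocation and optimization settings."""

    hidden: int = 64           # units per hidden layer
    n_collocation: int = 512   # equally spaced points in scaled time [0, 1]
    t_max: float = 1.0e3       # time-scale factor, s
    epsilon: float | None = None   # FD step in scaled time; default: grid spacing
    epochs: int = 30_000
    lr: float = 1.0e-3
    lr_decay: float = 0.1      # lr is multiplied by this over the full run
    ic_weight: float = 10.0    # weight of the initial-condition loss term
    tol: float = 1.0e-8        # stop when loss drops below this
    patience: int = 8_000      # epochs without best-loss improvement
    seed: int = 0

    def __post_init__(self):
        for f_ in ("hidden", "n_collocation", "epochs"):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be positive")
        for f_ in ("t_max", "lr", "tol", "ic_weight"):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be > 0")
        if self.epsilon is None:
            # one collocation-grid spacing: the finite difference then spans
            # the gap between nodes, so no inter-node behaviour is invisible
            # to the residual
            self.epsilon = 1.0 / self.n_collocation
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


class MLP:
    """Tiny time -> 9-amounts network: two tanh hidden layers, sigmoid out.

    The first layer is initialized multi-scale: unit input weights are
    log-spread over ~1..500 with transition centers spread over [0, 1], so
    the network can represent both the seconds-scale redistribution
    transient and the hours-scale drainage from the start of training
    (a plain small-weight initialization cannot reach the fast modes and
    training stalls on them).  Deeper layers use Glorot initialization.
    """

    #: log10 range of first-layer unit timescales
    SCALE_DECADES = 2.7

    def __init__(self, hidden: int, n_out: int, seed: int):
        rng = np.random.default_rng(seed)

        def glorot(n_in, n_o):
            s = np.sqrt(6.0 / (n_in + n_o))
            return rng.uniform(-s, s, size=(n_in, n_o))

        scales = 10.0 ** rng.uniform(0.0, self.SCALE_DECADES, hidden)
        scales *= rng.choice([-1.0, 1.0], hidden)
        centers = rng.uniform(0.0, 1.0, hidden)
        self.params = {
            "W1": scales.reshape(1, hidden), "b1": -scales * centers,
            "W2": glorot(hidden, hidden), "b2": np.zeros(hidden),
            "W3": glorot(hidden, n_out), "b3": np.zeros(n_out),
        }

    def forward(self, t: np.ndarray):
        """Outputs (n, n_out) plus the cache needed for backprop."""
        t = np.atleast_1d(t).reshape(-1, 1)
        p = self.params
        A1 = np.tanh(t @ p["W1"] + p["b1"])
        A2 = np.tanh(A1 @ p["W2"] + p["b2"])
        Y = 1.0 / (1.0 + np.exp(-(A2 @ p["W3"] + p["b3"])))
        return Y, (t, A1, A2, Y)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.forward(t)[0]

    def backward(self, cache, G: np.ndarray, grads: dict) -> None:
        """Accumulate dLoss/dparams given dLoss/doutput ``G``."""
        t, A1, A2, Y = cache
        p = self.params
        dZ3 = G * Y * (1.0 - Y)
        grads["W3"] += A2.T @ dZ3
        grads["b3"] += dZ3.sum(axis=0)
        dA2 = dZ3 @ p["W3"].T
        dZ2 = dA2 * (1.0 - A2**2)
        grads["W2"] += A1.T @ dZ2
        grads["b2"] += dZ2.sum(axis=0)
        dA1 = dZ2 @ p["W2"].T
        dZ1 = dA1 * (1.0 - A1**2)
        grads["W1"] += t.T @ dZ1
        grads["b1"] += dZ1.sum(axis=0)

    def zero_grads(self) -> dict:
        return {k: np.zeros_like(v) for k, v in self.params.items()}


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _slow_rhs(reduced: ReducedSystem, Y: np.ndarray) -> np.ndarray:
    """f(N_nss) with the quasi-steady block solved at this call.

    ``Y`` is (n, 9) in dose units; returns (n, 9) in dose units per second.
    """
    p = reduced.partition
    N_ss = np.linalg.solve(p.A_ss, -p.A_sn @ Y.T)    # g(N_nss, N_ss) = 0
    return (p.A_nn @ Y.T + p.A_ns @ N_ss).T


def pinn_loss(
    net: MLP,
    t_batch: np.ndarray,
    reduced: ReducedSystem,
    y_ic: np.ndarray,
    cfg: PinnConfig,
    return_grads: bool = False,
):
    """Physics loss: batch-mean squared ODE residual plus weighted squared
    IC error.

    ``t_batch`` is in scaled time (a subset of [0, 1]); ``y_ic`` is the
    dose-normalized initial amount vector.  The residual is formed in
    scaled-time units — the right-hand side is multiplied by ``t_max`` and
    compared against the finite-difference derivative ``dNN/dtau`` — which
    is algebraically the same equation as in physical time but keeps the
    loss surface O(1) and trainable.  The mean over the batch (rather than
    the raw sum) and the IC weight are conditioning choices; they rescale
    the objective without changing its minimizer.
    """
    t_batch = np.asarray(t_batch, dtype=float)
    if t_batch.min() < 0 or t_batch.max() > 1:
        raise ValueError("t_batch must lie in scaled time [0, 1]")
    eps = cfg.epsilon
    n = len(t_batch)

    Y1, cache1 = net.forward(t_batch)
    Y2, cache2 = net.forward(t_batch + eps)
    dYdtau = (Y2 - Y1) / eps
    F = _slow_rhs(reduced, Y1) * cfg.t_max     # rhs in scaled time
    R = dYdtau - F

    Y0, cache0 = net.forward(np.array([0.0]))
    ic_err = Y0[0] - y_ic

    loss = float(np.sum(R**2) / n + cfg.ic_weight * np.sum(ic_err**2))
    if not return_grads:
        return loss

    grads = net.zero_grads()
    G2 = 2.0 * R / eps / n
    # dL/dY1 through both the finite difference and f(Y1); the algebraic
    # solve makes f linear with matrix A_nn + A_ns (-A_ss^-1 A_sn)
    p = reduced.partition
    M_scaled = (p.A_nn + p.A_ns @ np.linalg.solve(p.A_ss, -p.A_sn)) * cfg.t_max
    G1 = -G2 - (2.0 / n) * R @ M_scaled
    net.backward(cache2, G2, grads)
    net.backward(cache1, G1, grads)
    net.backward(cache0, 2.0 * cfg.ic_weight * ic_err[None, :], grads)
    return loss, grads


@dataclass
class PinnResult:
    """Trained network, its predicted trajectory and the loss history."""

    trajectory: Trajectory
    loss_history: np.ndarray
    net: MLP
    config: PinnConfig
    converged: bool

    def summary(self) -> str:
        h = self.loss_history
        return "\n".join(
            [
                "PINN training summary",
                "---------------------",
                f"epochs run:     {len(h)}",
                f"final loss:     {h[-1]:.4e}",
                f"best loss:      {h.min():.4e}",
                f"converged:      {self.converged} (tol={self.config.tol:g})",
                f"collocation:    {self.config.n_collocation} points, "
                f"t_max={self.config.t_max:g} s",
            ]
        )


def train_pinn(reduced: ReducedSystem, cfg: PinnConfig | None = None) -> PinnResult:
    """Train the network to satisfy the reduced ODE system.

    Each iteration solves the quasi-steady block for the current network
    output, evaluates the physics loss, and updates the parameters (Adam);
    it stops at ``tol``, at ``epochs``, or early with a warning if the best
    loss has not improved for ``patience`` epochs (best-so-far parameters
    are restored).  Deterministic for a fixed config seed.
    """
    if not isinstance(reduced, ReducedSystem):
        raise TypeError(
            "the neural solver only supports the QSSA-reduced system; the full "
            "stiff system's fast binding transients are unrepresentable on the "
            "scaled-time grid and training fails — reduce with qssa_reduce first"
        )
    cfg = cfg or PinnConfig()
    dose = float(reduced.y0.sum())
    if dose <= 0:
        raise ValueError("reduced system has no injected dose")
    y_ic = reduced.y0 / dose

    t_batch = np.linspace(0.0, 1.0, cfg.n_collocation)
    net = MLP(cfg.hidden, len(reduced.labels), cfg.seed)
    opt = _Adam(net.params, cfg.lr)

    history = np.empty(cfg.epochs)
    best_loss = np.inf
    best_params = {k: v.copy() for k, v in net.params.items()}
    best_epoch = 0
    n_run = cfg.epochs
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr * cfg.lr_decay ** (epoch / cfg.epochs)
        loss, grads = pinn_loss(net, t_batch, reduced, y_ic, cfg, return_grads=True)
        history[epoch] = loss
        if loss < best_loss:
            best_loss = loss
            best_params = {k: v.copy() for k, v in net.params.items()}
            best_epoch = epoch
        if loss <= cfg.tol:
            n_run = epoch + 1
            break
        if epoch - best_epoch >= cfg.patience:
            warnings.warn(
                f"loss plateaued for {cfg.patience} epochs; stopping early at "
                f"epoch {epoch} with best loss {best_loss:.3e}"
            )
            n_run = epoch + 1
            break
        opt.step(net.params, grads)
    net.params = best_params

    Y = net(t_batch) * dose
    traj = Trajectory(
        t=t_batch * cfg.t_max,
        Y=Y.T,
        degraded=np.zeros_like(t_batch),
        labels=list(reduced.labels),
        volumes=np.asarray(reduced.volumes, dtype=float),
        meta={
            "method": "pinn",
            "epochs": n_run,
            "best_loss": best_loss,
            "seed": cfg.seed,
            "model": reduced.name,
            "note": "degraded mass not tracked by the neural solution",
        },
    )
    return PinnResult(
        trajectory=traj,
        loss_history=history[:n_run],
        net=net,
        config=cfg,
        converged=best_loss <= cfg.tol,
    )


def reference_solution(reduced: ReducedSystem, cfg: PinnConfig) -> Trajectory:
    """Conventional nonstiff integration on the PINN collocation grid."""
    t = np.linspace(0.0, 1.0, cfg.n_collocation) * cfg.t_max
    return integrate(
        reduced,
        SolverConfig(method="RK45", t_span=(0.0, cfg.t_max), t_eval=t,
                     rtol=1e-8),
    )


def relative_l2(pred: Trajectory, ref: Trajectory) -> float:
    """|| pred - ref ||_F / || ref ||_F over all states on the common grid."""
    Yr = np.vstack([np.interp(pred.t, ref.t, row) for row in ref.Y])
    return float(np.linalg.norm(pred.Y - Yr) / np.linalg.norm(Yr))
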