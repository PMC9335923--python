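"""Quasi-steady-state reduction of the temporal models.

The stiffness of the full systems comes from the separation between fast
processes (vascular washout, endothelial binding/unbinding, order seconds)
and slow ones (tissue uptake and degradation, order hours).  The QSSA
treats every vascular and endothelial state as instantaneously equilibrated:
with the linear system partitioned into quasi-steady amounts ``N_ss``
(organ vascular + endothelial states) and dynamic amounts ``N_nss`` (vein,
artery and the organ tissues),

    d N_nss / dt = A_nn N_nss + A_ns N_ss
    0            = A_sn N_nss + A_ss N_ss     (quasi-steady condition)

so ``N_ss = -A_ss^{-1} A_sn N_nss`` and the dynamics close on the 9 slow
states with the effective matrix ``M = A_nn - A_ns A_ss^{-1} A_sn``.
Because the system is linear the elimination is exact at every instant —
solving the algebraic block per step and pre-reducing the matrix are the
same operation; the per-step route is kept for the neural-network solver,
which interleaves the algebraic solve with training.

For the unbranched 7-organ model the algebraic block has 14 equations
(7 vascular + 7 endothelial); for the branched model it has 64 per organ
(32 vascular + 32 endothelial generations), 448 in all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compartmental import ODESystem
from .solve import SolverConfig, Trajectory, integrate

#: relative residual bound for the algebraic solve
RESIDUAL_TOL = 1e-10


class QssaError(ValueError):
    pass


@dataclass
class QssaPartition:
    """Index bookkeeping and operators of the quasi-steady subsystem."""

    ss_labels: list[str]
    nss_labels: list[str]
    A_ss: np.ndarray        # quasi-steady block (G matrix)
    A_sn: np.ndarray        # dynamic -> quasi-steady coupling
    A_ns: np.ndarray        # quasi-steady -> dynamic coupling
    A_nn: np.ndarray
    S: np.ndarray           # N_ss = S @ N_nss, i.e. -A_ss^{-1} A_sn

    @property
    def n_ss(self) -> int:
        return len(self.ss_labels)

    @property
    def n_nss(self) -> int:
        return len(self.nss_labels)

    def solve_ss(self, n_nss: np.ndarray) -> np.ndarray:
        """Solve g(N_nss, N_ss) = 0 for the quasi-steady amounts."""
        return np.linalg.solve(self.A_ss, -self.A_sn @ n_nss)

    def residual(self, n_nss: np.ndarray, n_ss: np.ndarray) -> float:
        """||A_sn N_nss + A_ss N_ss|| — zero for the exact algebraic solve."""
        return float(np.linalg.norm(self.A_sn @ n_nss + self.A_ss @ n_ss))


@dataclass
class ReducedSystem:
    """9-state dynamic system produced by the QSSA (vein, artery, tissues).

    Satisfies the same contract as :class:`~nanopbpk.compartmental.ODESystem`
    (``A``, ``deg_rates``, ``y0``, ``labels``, ``volumes``) so it can be fed
    to :func:`~nanopbpk.solve.integrate` directly.  ``deg_rates`` includes
    the degradation flux routed through the eliminated quasi-steady states,
    evaluated on their algebraic values.
    """

    name: str
    labels: list[str]
    A: np.ndarray
    deg_rates: np.ndarray
    volumes: np.ndarray
    y0: np.ndarray
    partition: QssaPartition
    meta: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def rhs(self, t, y):
        return self.A @ y

    def reconstruct_ss(self, n_nss: np.ndarray) -> np.ndarray:
        """Quasi-steady vascular/endothelial amounts for given slow amounts."""
        return self.partition.S @ n_nss


def _is_fast_label(label: str) -> bool:
    return "_bl" in label or "_EC" in label


def qssa_reduce(system: ODESystem) -> tuple[ReducedSystem, QssaPartition]:
    """Partition a full system and eliminate the quasi-steady block.

    Raises :class:`QssaError` if the quasi-steady operator is singular —
    this happens only if some organ has no escape path (K_off, K_up, K_deg
    and washout all zero), and the error names the offending block.
    """
    labels = list(system.labels)
    ss_idx = [i for i, l in enumerate(labels) if _is_fast_label(l)]
    nss_idx = [i for i, l in enumerate(labels) if not _is_fast_label(l)]
    if not ss_idx:
        raise QssaError("system has no vascular/endothelial states to eliminate")

    A = system.A
    A_ss = A[np.ix_(ss_idx, ss_idx)]
    A_sn = A[np.ix_(ss_idx, nss_idx)]
    A_ns = A[np.ix_(nss_idx, ss_idx)]
    A_nn = A[np.ix_(nss_idx, nss_idx)]
    try:
        S = np.linalg.solve(A_ss, -A_sn)
    except np.linalg.LinAlgError as err:
        # locate a structurally singular organ block for the error message
        diag = np.abs(np.diag(A_ss))
        worst = labels[ss_idx[int(np.argmin(diag))]]
        raise QssaError(
            f"quasi-steady operator is singular (no escape path near state "
            f"{worst!r})"
        ) from err

    partition = QssaPartition(
        ss_labels=[labels[i] for i in ss_idx],
        nss_labels=[labels[i] for i in nss_idx],
        A_ss=A_ss, A_sn=A_sn, A_ns=A_ns, A_nn=A_nn, S=S,
    )
    M = A_nn + A_ns @ S
    deg = system.deg_rates[nss_idx] + system.deg_rates[ss_idx] @ S
    reduced = ReducedSystem(
        name=f"{system.name}_qssa",
        labels=partition.nss_labels,
        A=M,
        deg_rates=deg,
        volumes=system.volumes[nss_idx],
        y0=system.y0[nss_idx],
        partition=partition,
        meta={**system.meta, "reduced_from": system.name,
              "n_ss": partition.n_ss, "n_nss": partition.n_nss},
    )
    if np.any(system.y0[ss_idx] != 0):
        raise QssaError(
            "initial condition places mass in a quasi-steady state; the QSSA "
            "requires the bolus to start in a dynamic compartment"
        )
    return reduced, partition


def solve_qssa(reduced: ReducedSystem, cfg: SolverConfig | None = None) -> Trajectory:
    """Integrate the reduced system with a nonstiff explicit method.

    The algebraic residual of the reconstruction is checked on the returned
    grid; it is exact (machine precision) because the elimination is linear.
    """
    cfg = cfg or SolverConfig(method="RK45")
    traj = integrate(reduced, cfg)
    # audit the quasi-steady reconstruction on a few grid points
    p = reduced.partition
    for j in range(0, traj.Y.shape[1], max(1, traj.Y.shape[1] // 8)):
        n_nss = traj.Y[:, j]
        n_ss = reduced.reconstruct_ss(n_nss)
        scale = np.linalg.norm(n_nss) or 1.0
        if p.residual(n_nss, n_ss) > RESIDUAL_TOL * scale:
            raise QssaError("quasi-steady residual exceeded tolerance")
    return traj


def tissue_comparison(full: Trajectory, reduced: Trajectory,
                      organs, t_window=(1e2, 1e4), n_points: int = 200) -> float:
    """Relative L2 distance between full and reduced tissue trajectories.

    Both trajectories are interpolated onto a uniform ``n_points`` grid over
    ``t_window`` (so the metric does not depend on either solver's output
    grid); the norm is over all listed organs jointly, normalized by the
    full-model norm.
    """
    t0 = max(t_window[0], full.t[0], reduced.t[0])
    t1 = min(t_window[1], full.t[-1], reduced.t[-1])
    t = np.linspace(t0, t1, n_points)
    diffs, refs = [], []
    for organ in organs:
        y_full = np.interp(t, full.t, full.amount(f"{organ}_T"))
        y_red = np.interp(t, reduced.t, reduced.amount(f"{organ}_T"))
        diffs.append(y_red - y_full)
        refs.append(y_full)
    diff = np.concatenate(diffs)
    ref = np.concatenate(refs)
    return float(np.linalg.norm(diff) / np.linalg.norm(ref))
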