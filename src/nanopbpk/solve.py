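"""Integration of the assembled linear PBPK systems.

All models in this package are linear, autonomous ODE systems
``dN/dt = A N`` on molar amounts, augmented with one auxiliary cumulative
state tracking degraded mass (``d(deg)/dt = sum_i K_deg,i N_i``).  Because
total mass (states + degraded) is a *linear* invariant of the augmented
system, any consistent ODE method preserves it up to roundoff and Newton
tolerance, which is what the mass-conservation audit checks.

Two solution routes are provided:

* ``solve_ivp`` methods (default ``BDF`` — the systems are stiff, with
  binding/unbinding and vascular washout on the scale of seconds against
  uptake and degradation on the scale of hours), and
* an exact matrix-exponential propagator (``method="expm"``), stepping
  ``y_{k+1} = e^{A dt} y_k`` on a uniform grid.  For a linear system this is
  exact to machine precision and serves as the independent cross-check for
  the adaptive solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

#: eigenvalues smaller than this fraction of |lambda|_max are treated as the
#: conserved (zero) modes of a closed system and excluded from the stiffness
#: ratio
ZERO_MODE_FLOOR = 1e-12

STIFF_METHODS = {"BDF", "Radau", "LSODA"}
NONSTIFF_METHODS = {"RK45", "RK23", "DOP853"}


class SolverError(RuntimeError):
    pass


@dataclass
class SolverConfig:
    """Integration contract: method, horizon, grid and tolerances."""

    method: str = "BDF"
    t_span: tuple[float, float] = (0.0, 1.0e4)   # seconds
    n_points: int = 201
    dt: float | None = None      # fixed step (expm / max_step compatibility mode)
    rtol: float = 1.0e-8
    atol: float | None = None    # default: 1e-14 * max|y0|
    seed: int = 0
    t_eval: Sequence[float] | None = None

    def __post_init__(self):
        if self.t_span[1] <= self.t_span[0]:
            raise ValueError("t_span must be increasing")
        if self.rtol <= 0:
            raise ValueError("rtol must be > 0")

    def grid(self) -> np.ndarray:
        if self.t_eval is not None:
            t = np.asarray(self.t_eval, dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError("t_eval must be strictly increasing")
            return t
        if self.dt is not None:
            n = int(round((self.t_span[1] - self.t_span[0]) / self.dt))
            return self.t_span[0] + self.dt * np.arange(n + 1)
        return np.linspace(self.t_span[0], self.t_span[1], self.n_points)


@dataclass
class Trajectory:
    """Time-resolved amounts per compartment plus cumulative degraded mass."""

    t: np.ndarray                  # (nt,), seconds
    Y: np.ndarray                  # (n_states, nt), mol
    degraded: np.ndarray           # (nt,), mol
    labels: list[str]
    volumes: np.ndarray            # (n_states,), litres
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    # -- accessors --------------------------------------------------------

    def amount(self, label: str) -> np.ndarray:
        return self.Y[self._index[label]]

    def concentration(self, label: str) -> np.ndarray:
        i = self._index[label]
        return self.Y[i] / self.volumes[i]

    def select(self, labels: Sequence[str]) -> np.ndarray:
        return self.Y[[self._index[l] for l in labels]]

    def total_mass(self) -> np.ndarray:
        """Sum of all compartment amounts plus cumulative degraded mass."""
        return self.Y.sum(axis=0) + self.degraded

    def conservation_drift(self) -> float:
        """max |M(t) - M(0)| / M(0) over the trajectory."""
        m = self.total_mass()
        return float(np.max(np.abs(m - m[0])) / m[0])

    def at_time(self, t_query: float) -> np.ndarray:
        """Linearly interpolated amounts at one time point."""
        return np.array([np.interp(t_query, self.t, row) for row in self.Y])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time, compartment, amount, concentration."""
        records = []
        for i, lab in enumerate(self.labels):
            records.append(
                pd.DataFrame(
                    {
                        "time_s": self.t,
                        "compartment": lab,
                        "amount_mol": self.Y[i],
                        "concentration_M": self.Y[i] / self.volumes[i],
                    }
                )
            )
        records.append(
            pd.DataFrame(
                {
                    "time_s": self.t,
                    "compartment": "degraded",
                    "amount_mol": self.degraded,
                    "concentration_M": np.nan,
                }
            )
        )
        return pd.concat(records, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, labels: Sequence[str] | None = None, ax=None,
             normalize: bool = True, logx: bool = False):
        """Plot amount time courses (dose-normalized by default).

        ``labels`` defaults to every tissue state plus vein and artery.
        Returns the matplotlib axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if labels is None:
            labels = [l for l in self.labels
                      if l.endswith("_T") or l in ("vein", "artery")]
        scale = self.total_mass()[0] if normalize else 1.0
        for lab in labels:
            ax.plot(self.t, self.amount(lab) / scale, label=lab)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("dose fraction" if normalize else "amount (mol)")
        if logx:
            ax.set_xscale("log")
        ax.legend(fontsize="small", ncol=2)
        return ax

    def summary(self) -> str:
        lines = [
            "Trajectory summary",
            "------------------",
            f"states:              {len(self.labels)}",
            f"time span:           [{self.t[0]:g}, {self.t[-1]:g}] s "
            f"({len(self.t)} points)",
            f"solver:              {self.meta.get('method', '?')} "
            f"(rtol={self.meta.get('rtol', '?')})",
            f"injected dose:       {self.total_mass()[0]:.6g} mol",
            f"degraded at t_end:   {self.degraded[-1]:.6g} mol",
            f"conservation drift:  {self.conservation_drift():.3e}",
        ]
        return "\n".join(lines)


def _augmented_matrix(system) -> np.ndarray:
    """Rate matrix with the cumulative-degraded row appended."""
    n = system.A.shape[0]
    J = np.zeros((n + 1, n + 1))
    J[:n, :n] = system.A
    J[n, :n] = system.deg_rates
    return J


def integrate(system, cfg: SolverConfig | None = None) -> Trajectory:
    """Integrate an assembled system and attach the conservation audit.

    Parameters
    ----------
    system
        Any object with ``A`` (rate matrix on amounts), ``deg_rates``,
        ``y0``, ``labels`` and ``volumes`` — the compartmental, branched and
        QSSA-reduced systems all satisfy this contract.
    cfg
        Solver configuration; default is adaptive implicit (``BDF``) over
        ``[0, 1e4]`` s.
    """
    cfg = cfg or SolverConfig()
    J = _augmented_matrix(system)
    y0 = np.append(system.y0, 0.0)
    t_grid = cfg.grid()
    atol = cfg.atol if cfg.atol is not None else 1e-14 * np.max(np.abs(y0))

    if cfg.method == "expm":
        dts = np.diff(t_grid)
        Y = np.empty((len(y0), len(t_grid)))
        Y[:, 0] = y0
        props: dict[float, np.ndarray] = {}
        y = y0
        for i, dt in enumerate(dts):
            key = round(float(dt), 12)
            if key not in props:
                props[key] = expm(J * dt)
            y = props[key] @ y
            Y[:, i + 1] = y
    else:
        kwargs = {}
        if cfg.method in STIFF_METHODS:
            kwargs["jac"] = J
        if cfg.dt is not None:
            kwargs["max_step"] = cfg.dt
        sol = solve_ivp(
            lambda t, y: J @ y,
            (t_grid[0], t_grid[-1]),
            y0,
            method=cfg.method,
            t_eval=t_grid,
            rtol=cfg.rtol,
            atol=atol,
            **kwargs,
        )
        if not sol.success:
            ratio = stiffness_ratio(system)
            raise SolverError(
                f"{cfg.method} failed: {sol.message} (stiffness ratio {ratio:.3g}; "
                "consider an implicit method)"
            )
        Y = sol.y

    meta = {
        "method": cfg.method,
        "rtol": cfg.rtol,
        "atol": atol,
        "seed": cfg.seed,
        "model": getattr(system, "name", "unknown"),
    }
    return Trajectory(
        t=t_grid,
        Y=Y[:-1],
        degraded=Y[-1],
        labels=list(system.labels),
        volumes=np.asarray(system.volumes, dtype=float),
        meta=meta,
    )


def stiffness_ratio(system_or_matrix, floor: float = ZERO_MODE_FLOOR) -> float:
    """``|lambda|_max / |lambda|_min`` of the rate matrix.

    Eigenvalues with magnitude below ``floor * |lambda|_max`` are excluded:
    a closed system has an exact zero mode (mass conservation) that would
    make the ratio infinite.
    """
    A = system_or_matrix if isinstance(system_or_matrix, np.ndarray) else system_or_matrix.A
    lam = np.linalg.eigvals(A)
    mags = np.abs(lam)
    lam_max = mags.max()
    if lam_max == 0:
        raise ValueError("all eigenvalues are zero; stiffness ratio undefined")
    retained = mags[mags > floor * lam_max]
    return float(lam_max / retained.min())
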