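"""Shared toy objects for the neural-solver tests."""

import numpy as np

from nanopbpk.nn_solver import MLP
from nanopbpk.qssa import QssaPartition, ReducedSystem


def static_reduced_system(n: int = 3) -> ReducedSystem:
    """Toy reduced system with zero dynamics (dy/dt = 0)."""
    part = QssaPartition(
        ss_labels=["s"], nss_labels=[f"x{i}_T" for i in range(n)],
        A_ss=-np.eye(1), A_sn=np.zeros((1, n)), A_ns=np.zeros((n, 1)),
        A_nn=np.zeros((n, n)), S=np.zeros((1, n)),
    )
    return ReducedSystem(
        name="static", labels=part.nss_labels, A=np.zeros((n, n)),
        deg_rates=np.zeros(n), volumes=np.ones(n),
        y0=np.full(n, 1.0 / n), partition=part,
    )


class ConstantNet(MLP):
    """Network whose output is a constant vector (for loss anatomy tests)."""

    def __init__(self, value):
        self.value = np.asarray(value, dtype=float)
        self.params = {}

    def forward(self, t):
        t = np.atleast_1d(t).reshape(-1, 1)
        Y = np.tile(self.value, (len(t), 1))
        return Y, None
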