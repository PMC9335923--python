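"""Lumped temporal compartmental models A and B.

Each organ is split into vascular (bl), endothelial-bound (EC) and tissue
(T) sub-compartments; organs are connected through venous and arterial
compartments by blood flow.  States are molar *amounts*; first-order
exchange between sub-compartments uses the rates K_on, K_off, K_up, K_NS
and K_deg, and inter-compartment transport uses flows Q (L/min) acting on
concentrations (amount / compartment volume).

Model A (5 organs — lung, heart, kidney, liver, spleen; 17 ODEs) wires all
organs in parallel between artery and vein.  Model B (7 organs, adding gut
and 'other'; 23 ODEs) separates the pulmonary circulation (vein -> heart ->
lung -> heart -> artery at full cardiac output), routes splenic and gut
outflow through the liver (hepatic flow Q_hep = Q_liver + Q_spleen + Q_gut)
and perfuses the heart itself through a coronary branch.

Every equation is generated from the flow topology under strict node-wise
flow balance (sum of inflows equals sum of outflows at every vascular
node), which is the structural condition for the zero-slope total-mass
audit to hold; assembly fails loudly on any imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import MODEL_A_ORGANS, MODEL_B_ORGANS, PhysiologyTable
from .solve import SolverConfig, Trajectory, integrate

#: tolerance for node-wise flow balance and column-sum mass closure
_BALANCE_TOL = 1e-9


class AssemblyError(ValueError):
    pass


@dataclass
class ODESystem:
    """Assembled linear state-space ``dN/dt = A N`` on molar amounts.

    ``deg_rates`` drives the auxiliary cumulative-degraded state; the
    augmented system conserves total mass exactly (every column of ``A``
    sums to minus that state's degradation rate).
    """

    name: str
    labels: list[str]
    A: np.ndarray                 # (n, n), 1/s
    deg_rates: np.ndarray         # (n,), 1/s
    volumes: np.ndarray           # (n,), L
    y0: np.ndarray                # (n,), mol
    edges: list[tuple[str, str, float]] = field(default_factory=list)  # flows, L/min
    organs: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def rhs(self, t, y):
        return self.A @ y

    def topology_frame(self):
        """Flow topology as a tidy edge list (source, target, Q in L/min)."""
        import pandas as pd

        return pd.DataFrame(self.edges, columns=["source", "target",
                                                 "Q_L_per_min"])

    def topology_to_csv(self, path) -> None:
        self.topology_frame().to_csv(path, index=False)

    def validate(self) -> None:
        self._check_flow_balance()
        self._check_mass_closure()

    def _check_flow_balance(self) -> None:
        inflow: dict[str, float] = {}
        outflow: dict[str, float] = {}
        for u, v, q in self.edges:
            outflow[u] = outflow.get(u, 0.0) + q
            inflow[v] = inflow.get(v, 0.0) + q
        for node in set(inflow) | set(outflow):
            qin, qout = inflow.get(node, 0.0), outflow.get(node, 0.0)
            if abs(qin - qout) > _BALANCE_TOL * max(qin, qout, 1e-300):
                raise AssemblyError(
                    f"flow imbalance at node {node!r}: inflow {qin:g} L/min, "
                    f"outflow {qout:g} L/min"
                )

    def _check_mass_closure(self) -> None:
        resid = self.A.sum(axis=0) + self.deg_rates
        worst = np.argmax(np.abs(resid))
        scale = np.max(np.abs(self.A)) or 1.0
        if np.abs(resid[worst]) > _BALANCE_TOL * scale:
            raise AssemblyError(
                f"mass closure violated in column {self.labels[worst]!r}: "
                f"residual {resid[worst]:g} 1/s"
            )


class _Builder:
    """Accumulates flow edges and kinetic terms into a rate matrix."""

    def __init__(self, name: str, labels: list[str], volumes: np.ndarray):
        self.name = name
        self.labels = labels
        self.idx = {lab: i for i, lab in enumerate(labels)}
        self.volumes = volumes
        n = len(labels)
        self.A = np.zeros((n, n))
        self.deg = np.zeros(n)
        self.edges: list[tuple[str, str, float]] = []

    def flow(self, u: str, v: str, q_L_per_min: float) -> None:
        """Transport edge u -> v carrying q (L/min) of u's concentration."""
        if q_L_per_min < 0:
            raise AssemblyError(f"negative flow on edge {u} -> {v}")
        iu, iv = self.idx[u], self.idx[v]
        rate = q_L_per_min / 60.0 / self.volumes[iu]   # 1/s
        self.A[iv, iu] += rate
        self.A[iu, iu] -= rate
        self.edges.append((u, v, q_L_per_min))

    def first_order(self, src: str, dst: str | None, k: float) -> None:
        """First-order transfer src -> dst (dst=None: degradation sink)."""
        i = self.idx[src]
        self.A[i, i] -= k
        if dst is None:
            self.deg[i] += k
        else:
            self.A[self.idx[dst], i] += k


def _organ_kinetics(b: _Builder, organ, bl: str, ec: str, tis: str) -> None:
    """Binding, uptake and degradation pathways within one organ."""
    b.first_order(bl, ec, organ.K_on)
    b.first_order(ec, bl, organ.K_off)
    b.first_order(ec, tis, organ.K_up)
    b.first_order(bl, tis, organ.K_NS)
    b.first_order(bl, None, organ.K_deg)
    b.first_order(ec, None, organ.K_deg)
    b.first_order(tis, None, organ.K_deg)


def _finish(b: _Builder, phys: PhysiologyTable, organs) -> ODESystem:
    sysm = phys.systemic
    b.first_order("vein", None, sysm.K_deg_vein)
    b.first_order("artery", None, sysm.K_deg_art)
    y0 = np.zeros(len(b.labels))
    y0[b.idx["vein"]] = sysm.dose
    system = ODESystem(
        name=b.name,
        labels=b.labels,
        A=b.A,
        deg_rates=b.deg,
        volumes=b.volumes,
        y0=y0,
        edges=b.edges,
        organs=tuple(organs),
        meta={"dose": sysm.dose},
    )
    system.validate()
    return system


def build_model_a(phys: PhysiologyTable) -> ODESystem:
    """Model A: 5 organs in parallel between artery and vein (17 ODEs)."""
    if set(phys.organ_names) != set(MODEL_A_ORGANS):
        raise AssemblyError(
            f"model A needs exactly the organs {sorted(MODEL_A_ORGANS)}, "
            f"got {sorted(phys.organ_names)}"
        )
    organs = [phys.organs[n] for n in MODEL_A_ORGANS]
    labels = ["vein", "artery"]
    volumes = [phys.systemic.V_vein, phys.systemic.V_art]
    for o in organs:
        labels += [f"{o.name}_bl", f"{o.name}_EC", f"{o.name}_T"]
        volumes += [o.V_bl, o.V_EC, o.V_T]
    b = _Builder("model_a", labels, np.array(volumes))

    q_total = sum(o.Q for o in organs)
    b.flow("vein", "artery", q_total)
    for o in organs:
        b.flow("artery", f"{o.name}_bl", o.Q)
        b.flow(f"{o.name}_bl", "vein", o.Q)
        _organ_kinetics(b, o, f"{o.name}_bl", f"{o.name}_EC", f"{o.name}_T")
    return _finish(b, phys, MODEL_A_ORGANS)


def model_b_flows(phys: PhysiologyTable) -> dict[str, float]:
    """Derived flows of the model-B wiring (L/min).

    Cardiac output is the sum of the systemic organ flows (heart coronary,
    kidney, liver hepatic-arterial, spleen, gut, other); the lung is
    perfused in series at full cardiac output, and hepatic outflow is
    Q_hep = Q_liver + Q_spleen + Q_gut.
    """
    o = phys.organs
    co = sum(o[n].Q for n in ("heart", "kidney", "liver", "spleen", "gut", "other"))
    return {
        "cardiac_output": co,
        "Q_hep": o["liver"].Q + o["spleen"].Q + o["gut"].Q,
    }


def build_model_b(phys: PhysiologyTable, other_to_liver: bool = False) -> ODESystem:
    """Model B: 7 organs, pulmonary loop and hepatic coupling (23 ODEs).

    ``other_to_liver`` switches the 'other' compartment's venous return to
    drain through the liver instead of directly to the vein (default: direct
    to vein, matching the model-B wiring diagram).
    """
    if set(phys.organ_names) != set(MODEL_B_ORGANS):
        raise AssemblyError(
            f"model B needs exactly the organs {sorted(MODEL_B_ORGANS)}, "
            f"got {sorted(phys.organ_names)}"
        )
    og = phys.organs
    labels = ["vein", "artery"]
    volumes = [phys.systemic.V_vein, phys.systemic.V_art]
    for n in MODEL_B_ORGANS:
        o = og[n]
        labels += [f"{n}_bl", f"{n}_EC", f"{n}_T"]
        volumes += [o.V_bl, o.V_EC, o.V_T]
    b = _Builder("model_b", labels, np.array(volumes))

    flows = model_b_flows(phys)
    co = flows["cardiac_output"]
    q_hep = flows["Q_hep"]

    # pulmonary loop: vein -> heart -> lung -> heart -> artery, at full CO
    b.flow("vein", "heart_bl", co)
    b.flow("heart_bl", "lung_bl", co)
    b.flow("lung_bl", "heart_bl", co)
    b.flow("heart_bl", "artery", co)
    # coronary perfusion of the heart tissue itself
    b.flow("artery", "heart_bl", og["heart"].Q)
    b.flow("heart_bl", "vein", og["heart"].Q)
    # systemic organs
    b.flow("artery", "kidney_bl", og["kidney"].Q)
    b.flow("kidney_bl", "vein", og["kidney"].Q)
    b.flow("artery", "liver_bl", og["liver"].Q)
    b.flow("artery", "spleen_bl", og["spleen"].Q)
    b.flow("spleen_bl", "liver_bl", og["spleen"].Q)
    b.flow("artery", "gut_bl", og["gut"].Q)
    b.flow("gut_bl", "liver_bl", og["gut"].Q)
    b.flow("artery", "other_bl", og["other"].Q)
    if other_to_liver:
        b.flow("other_bl", "liver_bl", og["other"].Q)
        b.flow("liver_bl", "vein", q_hep + og["other"].Q)
    else:
        b.flow("other_bl", "vein", og["other"].Q)
        b.flow("liver_bl", "vein", q_hep)

    for n in MODEL_B_ORGANS:
        _organ_kinetics(b, og[n], f"{n}_bl", f"{n}_EC", f"{n}_T")
    return _finish(b, phys, MODEL_B_ORGANS)


# -- degradation / conservation bookkeeping -------------------------------

def degraded_mass(traj: Trajectory) -> np.ndarray:
    """Cumulative degraded amount Mol_deg(t) (mol), from the auxiliary state."""
    return traj.degraded


def degraded_mass_riemann(traj: Trajectory, system: ODESystem) -> np.ndarray:
    """Riemann-sum variant of Mol_deg(t): sum_t sum_i K_deg,i N_i(t) dt.

    Left-endpoint quadrature of the degradation flux on the trajectory
    grid; agrees with the integrated auxiliary state to O(dt) and serves as
    a fidelity check on the bookkeeping.
    """
    flux = system.deg_rates @ traj.Y          # (nt,), mol/s
    dt = np.diff(traj.t)
    out = np.zeros_like(traj.t)
    out[1:] = np.cumsum(flux[:-1] * dt)
    return out


def total_mass(traj: Trajectory) -> np.ndarray:
    """Mol_total(t): all compartment amounts plus cumulative degraded mass."""
    return traj.total_mass()


# -- statsmodels-style front doors ---------------------------------------

class CompartmentalModel:
    """Temporal PBPK model; ``solve()`` returns a :class:`Trajectory`."""

    _builder = None
    _organ_set: tuple[str, ...] = ()

    def __init__(self, phys: PhysiologyTable, **build_kwargs):
        if set(phys.organ_names) - set(self._organ_set):
            phys = phys.subset(self._organ_set)
        self.phys = phys
        self.system = type(self)._builder(phys, **build_kwargs)

    @classmethod
    def from_config(cls, path, **build_kwargs):
        from .params import load_physiology

        return cls(load_physiology(path), **build_kwargs)

    def solve(self, cfg: SolverConfig | None = None) -> Trajectory:
        return integrate(self.system, cfg)


class CompartmentalModelA(CompartmentalModel):
    _builder = staticmethod(build_model_a)
    _organ_set = MODEL_A_ORGANS


class CompartmentalModelB(CompartmentalModel):
    _builder = staticmethod(build_model_b)
    _organ_set = MODEL_B_ORGANS
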