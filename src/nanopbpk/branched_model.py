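"""Generation-resolved branched compartmental model.

The model-B wiring with every organ's vascular compartment replaced by a
serial chain of branching-element generations.  Each generation ``n`` of an
organ carries a vascular state and an endothelial state; the organ keeps a
single tissue state fed by uptake summed over all generations.  With the
default murine tree (16 bifurcations, 32 generations) and 7 organs this is

    2 (vein, artery) + 32*7 (vascular) + 32*7 (endothelial) + 7 (tissue)
    = 457 dynamical states.

Each organ's vasculature is represented by one branching element: the
per-generation storage volumes are those of a *single* element, and every
first-order rate constant acting on vascular/endothelial states is
multiplied by the organ's element count ``phi`` (the per-generation
equations carry ``phi`` on every kinetic term).  The effective washout
rate is therefore ``Q / V_element`` — ``phi``-fold faster than the lumped
model for organs with ``phi > 1`` — which is what makes tissue onset
quicker in well-vascularized organs and slower where ``phi < 1``.  The
endothelial-layer volume of one element (``V_EC / phi``) is allocated
across generations proportionally to generation surface area.  Tissue
degradation is not ``phi``-scaled (the tissue compartment is the whole
organ, not a tiled element).

``volume_scaling="organ"`` switches to a volume-preserving variant
(per-generation volumes ``phi * V_gen``, unscaled rates) whose total
vascular volume matches the organ's ``V_bl``; collapsing the tree to a
single generation under this scaling reproduces the lumped model B
state-for-state, which is used as a consistency check.

The full organ flow passes through every generation of the chain — what
splits at a bifurcation is the per-branch flow ``Q/N^n``, so amount flux
is conserved across generation boundaries.
"""

from __future__ import annotations

import numpy as np

from .compartmental import AssemblyError, ODESystem, _Builder, model_b_flows
from .params import MODEL_B_ORGANS, PhysiologyTable
from .solve import SolverConfig, Trajectory, integrate
from .vascular_tree import VascularTree, attach_phi, build_tree


def branched_labels(organs, n_gen: int) -> tuple[list[str], list[str]]:
    labels = ["vein", "artery"]
    for name in organs:
        labels += [f"{name}_bl_{n}" for n in range(1, n_gen + 1)]
        labels += [f"{name}_EC_{n}" for n in range(1, n_gen + 1)]
        labels.append(f"{name}_T")
    return labels


def build_branched(
    phys: PhysiologyTable,
    tree: VascularTree | None = None,
    expected_generations: int | None = None,
    other_to_liver: bool = False,
    volume_scaling: str = "element",
) -> ODESystem:
    """Assemble the branched system in the model-B wiring.

    ``expected_generations`` (if given) asserts the tree size; the default
    murine tree has 32 generations and yields the 457-state system.

    ``volume_scaling`` selects ``"element"`` (default: single-element
    storage volumes, phi-scaled vascular/endothelial kinetics, per the
    per-generation equations) or ``"organ"`` (volume-preserving: storage
    ``phi * V_gen`` with unscaled rates).  Under ``"organ"`` scaling a
    degenerate single-generation tree collapses the model exactly onto the
    lumped model B, which is used as a consistency check.
    """
    if volume_scaling not in ("element", "organ"):
        raise ValueError(f"unknown volume_scaling {volume_scaling!r}")
    if set(phys.organ_names) != set(MODEL_B_ORGANS):
        raise AssemblyError(
            f"branched model needs exactly the organs {sorted(MODEL_B_ORGANS)}"
        )
    tree = tree or build_tree(**(phys.tree_config or {}))
    n_gen = tree.n_generations
    if expected_generations is not None and n_gen != expected_generations:
        raise AssemblyError(
            f"tree has {n_gen} generations, expected {expected_generations}"
        )
    phys = attach_phi(phys, tree)
    og = phys.organs

    gen_vol = tree.generation_volumes_litres()          # (n_gen,), per element
    gen_area = tree.generation_areas()
    area_frac = gen_area / gen_area.sum()

    labels = branched_labels(MODEL_B_ORGANS, n_gen)
    volumes = [phys.systemic.V_vein, phys.systemic.V_art]
    for name in MODEL_B_ORGANS:
        o = og[name]
        if volume_scaling == "element":
            volumes += list(gen_vol)                    # one element's vasculature
            volumes += list(o.V_EC / o.phi * area_frac)  # one element's EC layer
        else:
            volumes += list(o.phi * gen_vol)            # whole-organ vasculature
            volumes += list(o.V_EC * area_frac)
        volumes.append(o.V_T)
    b = _Builder("branched", labels, np.array(volumes))

    flows = model_b_flows(phys)
    co = flows["cardiac_output"]
    q_hep = flows["Q_hep"]

    def first(name):
        return f"{name}_bl_1"

    def last(name):
        return f"{name}_bl_{n_gen}"

    # serial chains: full organ flow passes through every generation
    chain_flow = {
        "lung": co,
        "heart": 2 * co + og["heart"].Q,
        "kidney": og["kidney"].Q,
        "liver": q_hep + (og["other"].Q if other_to_liver else 0.0),
        "spleen": og["spleen"].Q,
        "gut": og["gut"].Q,
        "other": og["other"].Q,
    }
    for name in MODEL_B_ORGANS:
        for n in range(1, n_gen):
            b.flow(f"{name}_bl_{n}", f"{name}_bl_{n + 1}", chain_flow[name])

    # macro wiring (model B): pulmonary loop, coronary branch, hepatic coupling
    b.flow("vein", first("heart"), co)
    b.flow(last("heart"), first("lung"), co)
    b.flow(last("lung"), first("heart"), co)
    b.flow(last("heart"), "artery", co)
    b.flow("artery", first("heart"), og["heart"].Q)
    b.flow(last("heart"), "vein", og["heart"].Q)
    b.flow("artery", first("kidney"), og["kidney"].Q)
    b.flow(last("kidney"), "vein", og["kidney"].Q)
    b.flow("artery", first("liver"), og["liver"].Q)
    b.flow("artery", first("spleen"), og["spleen"].Q)
    b.flow(last("spleen"), first("liver"), og["spleen"].Q)
    b.flow("artery", first("gut"), og["gut"].Q)
    b.flow(last("gut"), first("liver"), og["gut"].Q)
    b.flow("artery", first("other"), og["other"].Q)
    if other_to_liver:
        b.flow(last("other"), first("liver"), og["other"].Q)
        b.flow(last("liver"), "vein", q_hep + og["other"].Q)
    else:
        b.flow(last("other"), "vein", og["other"].Q)
        b.flow(last("liver"), "vein", q_hep)

    # per-generation kinetics; tissue collects uptake from every generation.
    # Under element scaling every vascular/EC kinetic term carries phi;
    # tissue degradation stays unscaled (whole-organ compartment).
    for name in MODEL_B_ORGANS:
        o = og[name]
        scale = o.phi if volume_scaling == "element" else 1.0
        tis = f"{name}_T"
        for n in range(1, n_gen + 1):
            bl, ec = f"{name}_bl_{n}", f"{name}_EC_{n}"
            b.first_order(bl, ec, scale * o.K_on)
            b.first_order(ec, bl, scale * o.K_off)
            b.first_order(ec, tis, scale * o.K_up)
            b.first_order(bl, tis, scale * o.K_NS)
            b.first_order(bl, None, scale * o.K_deg)
            b.first_order(ec, None, scale * o.K_deg)
        b.first_order(tis, None, o.K_deg)

    sysm = phys.systemic
    b.first_order("vein", None, sysm.K_deg_vein)
    b.first_order("artery", None, sysm.K_deg_art)
    y0 = np.zeros(len(labels))
    y0[b.idx["vein"]] = sysm.dose
    system = ODESystem(
        name="branched",
        labels=labels,
        A=b.A,
        deg_rates=b.deg,
        volumes=b.volumes,
        y0=y0,
        edges=b.edges,
        organs=tuple(MODEL_B_ORGANS),
        meta={
            "dose": sysm.dose,
            "n_generations": n_gen,
            "phi": {n: og[n].phi for n in MODEL_B_ORGANS},
            "diameter_nm": phys.np_spec.diameter,
            "volume_scaling": volume_scaling,
        },
    )
    system.validate()
    return system


def tissue_labels(organs=MODEL_B_ORGANS) -> list[str]:
    return [f"{n}_T" for n in organs]


def biodistribution_vs_size(
    diameters_nm,
    phys: PhysiologyTable,
    tree: VascularTree | None = None,
    t_eval: float = 300.0,
    cfg: SolverConfig | None = None,
):
    """Per-organ tissue dose fraction at ``t_eval`` for each NP diameter.

    Builds and integrates the branched system once per diameter (K_on and
    K_off re-derived from the Stokes-Einstein / log(K_EC) relations) and
    reports tissue amounts normalized by the injected dose.

    Returns a pandas DataFrame indexed by diameter with one column per organ.
    """
    import pandas as pd

    tree = tree or build_tree(**(phys.tree_config or {}))
    cfg = cfg or SolverConfig(t_span=(0.0, max(t_eval, 1.0)), n_points=101)
    rows = []
    for d in diameters_nm:
        table = phys.with_nanoparticle(d)
        system = build_branched(table, tree)
        traj = integrate(system, cfg)
        amounts = traj.at_time(t_eval)
        idx = {lab: i for i, lab in enumerate(traj.labels)}
        dose = phys.systemic.dose
        rows.append(
            {name: amounts[idx[f"{name}_T"]] / dose for name in MODEL_B_ORGANS}
        )
    out = pd.DataFrame(rows, index=pd.Index(diameters_nm, name="diameter_nm"))
    return out


class BranchedModel:
    """Branched PBPK model; ``solve()`` returns a :class:`Trajectory`."""

    def __init__(
        self,
        phys: PhysiologyTable,
        tree: VascularTree | None = None,
        diameter_nm: float | None = None,
        **build_kwargs,
    ):
        if diameter_nm is not None:
            phys = phys.with_nanoparticle(diameter_nm)
        self.phys = phys
        self.tree = tree or build_tree(**(phys.tree_config or {}))
        self.system = build_branched(phys, self.tree, **build_kwargs)

    @classmethod
    def from_config(cls, path, **kwargs):
        from .params import load_physiology

        return cls(load_physiology(path), **kwargs)

    def solve(self, cfg: SolverConfig | None = None) -> Trajectory:
        return integrate(self.system, cfg)
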