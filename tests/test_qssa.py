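"""QSSA reduction: partition sizes, exactness of the algebraic solve,
fidelity to the full model, stiffness reduction."""

import numpy as np
import pytest

from nanopbpk.compartmental import ODESystem, build_model_b
from nanopbpk.qssa import (
    QssaError,
    qssa_reduce,
    solve_qssa,
    tissue_comparison,
)
from nanopbpk.solve import SolverConfig, integrate, stiffness_ratio


@pytest.fixture(scope="module")
def reduced_b(system_b):
    return qssa_reduce(system_b)


class TestPartition:
    def test_model_b_partition_sizes(self, reduced_b):
        reduced, part = reduced_b
        assert reduced.n_states == 9
        assert part.n_ss == 14  # 7 vascular + 7 endothelial
        assert set(reduced.labels) == {"vein", "artery"} | {
            f"{o}_T" for o in
            ("lung", "heart", "kidney", "liver", "spleen", "gut", "other")
        }

    def test_branched_partition_sizes(self, system_branched):
        reduced, part = qssa_reduce(system_branched)
        assert reduced.n_states == 9
        assert part.n_ss == 64 * 7

    def test_zero_binding_gives_zero_ec_quasi_steady(self, murine):
        table = murine.replace_rates(
            {n: {"K_on": 0.0, "K_off": 0.0} for n in murine.organ_names}
        )
        reduced, part = qssa_reduce(build_model_b(table))
        n_ss = reduced.reconstruct_ss(reduced.y0)
        ec = [i for i, l in enumerate(part.ss_labels) if "_EC" in l]
        assert np.allclose(n_ss[ec], 0.0)

    def test_singular_block_named(self, murine):
        # an organ with no escape path from the endothelial state at all
        table = murine.replace_rates(
            {"spleen": {"K_off": 0.0, "K_up": 0.0, "K_deg": 0.0}}
        )
        with pytest.raises(QssaError, match="spleen"):
            qssa_reduce(build_model_b(table))

    def test_mass_in_fast_state_rejected(self, system_b):
        bad = ODESystem(
            name="bad", labels=list(system_b.labels), A=system_b.A,
            deg_rates=system_b.deg_rates, volumes=system_b.volumes,
            y0=np.roll(system_b.y0, 2),  # dose lands in lung_bl
            edges=system_b.edges, organs=system_b.organs,
        )
        with pytest.raises(QssaError, match="quasi-steady state"):
            qssa_reduce(bad)


class TestAlgebraicSolve:
    def test_residual_machine_precision(self, reduced_b):
        reduced, part = reduced_b
        rng = np.random.default_rng(0)
        for _ in range(5):
            n_nss = rng.uniform(0, 1, reduced.n_states)
            n_ss = part.solve_ss(n_nss)
            assert part.residual(n_nss, n_ss) < 1e-10 * np.linalg.norm(n_nss)
            assert np.allclose(n_ss, reduced.reconstruct_ss(n_nss))

    def test_toy_fast_slow_closed_form(self):
        # textbook linear fast-slow chain: slow source s feeds a fast
        # intermediate c (rates a in, b out with b >> a); QSSA gives
        # c = (a/b) s and an effective slow decay ds/dt = -a s with the
        # product routed onward at rate b c.
        a_rate, b_rate = 1.0e-3, 10.0
        A = np.array(
            [
                [-a_rate, 0.0, 0.0],
                [a_rate, -b_rate, 0.0],
                [0.0, b_rate, 0.0],
            ]
        )
        system = ODESystem(
            name="toy", labels=["vein", "x_bl", "x_T"], A=A,
            deg_rates=np.zeros(3), volumes=np.ones(3),
            y0=np.array([1.0, 0.0, 0.0]), edges=[],
        )
        reduced, part = qssa_reduce(system)
        assert part.ss_labels == ["x_bl"]
        traj = solve_qssa(reduced, SolverConfig(method="RK45",
                                                t_span=(0.0, 4000.0),
                                                rtol=1e-10))
        s = traj.amount("vein")
        prod = traj.amount("x_T")
        assert np.allclose(s, np.exp(-a_rate * traj.t), rtol=1e-6, atol=1e-9)
        assert np.allclose(prod, 1.0 - np.exp(-a_rate * traj.t),
                           rtol=1e-5, atol=1e-8)
        # quasi-steady intermediate value
        c = reduced.reconstruct_ss(np.array([s[-1], prod[-1]]))
        assert c[0] == pytest.approx(a_rate / b_rate * s[-1], rel=1e-9)


class TestFidelity:
    def test_reduced_tissue_tracks_full_model(self, traj_b, reduced_b, murine):
        reduced, _ = reduced_b
        r_traj = solve_qssa(reduced, SolverConfig(method="RK45",
                                                  t_span=(0.0, 1.0e4)))
        err = tissue_comparison(traj_b, r_traj, murine.organ_names)
        assert err <= 0.2

    def test_reduced_system_less_stiff(self, system_b, reduced_b):
        reduced, _ = reduced_b
        assert stiffness_ratio(reduced) < stiffness_ratio(system_b)

    def test_capacity_limit(self, murine):
        # the QSSA error is controlled by the mass capacity of the
        # eliminated compartments: shrinking the vascular and endothelial
        # volumes shrinks the tissue-trajectory error
        from dataclasses import replace

        from nanopbpk.params import PhysiologyTable

        def qssa_error(table):
            system = build_model_b(table)
            grid = np.linspace(0.0, 1.0e4, 201)
            full = integrate(system, SolverConfig(t_eval=grid))
            reduced, _ = qssa_reduce(system)
            r_traj = solve_qssa(reduced, SolverConfig(method="RK45",
                                                      t_eval=grid))
            return tissue_comparison(full, r_traj, murine.organ_names)

        organs = {
            n: replace(o, V_bl=o.V_bl / 10.0, V_EC=o.V_EC / 10.0)
            for n, o in murine.organs.items()
        }
        systemic = replace(murine.systemic)
        systemic.V_total = (systemic.V_vein + systemic.V_art
                            + sum(o.V_bl for o in organs.values()))
        shrunk = PhysiologyTable(organs, systemic, murine.np_spec,
                                 murine.kec, murine.steady_state,
                                 murine.tree_config)
        assert qssa_error(shrunk) < qssa_error(murine)

    def test_branched_reduction_beats_unbranched_reduction(
        self, system_b, traj_b, system_branched, traj_branched, murine
    ):
        # the branched model drains its (phi-scaled) vascular/endothelial
        # pools faster, so its quasi-steady elimination loses less mass:
        # relative L2 of tissue curves is smaller than for the lumped model
        red_b, _ = qssa_reduce(system_b)
        err_b = tissue_comparison(
            traj_b,
            solve_qssa(red_b, SolverConfig(method="RK45", t_span=(0.0, 1e4))),
            murine.organ_names,
        )
        red_br, _ = qssa_reduce(system_branched)
        err_br = tissue_comparison(
            traj_branched,
            solve_qssa(red_br, SolverConfig(method="RK45", t_span=(0.0, 1e4))),
            murine.organ_names,
        )
        assert err_br < err_b

    def test_faster_escape_reduces_error(self, murine):
        # weaker endothelial retention (larger K_off) leaves less mass in
        # the eliminated states and improves the reduction
        def qssa_error(table):
            system = build_model_b(table)
            grid = np.linspace(0.0, 1.0e4, 201)
            full = integrate(system, SolverConfig(t_eval=grid))
            reduced, _ = qssa_reduce(system)
            r_traj = solve_qssa(reduced, SolverConfig(method="RK45",
                                                      t_eval=grid))
            return tissue_comparison(full, r_traj, murine.organ_names)

        weaker = murine.replace_rates(
            {n: {"K_off": murine.organs[n].K_off * 30.0}
             for n in murine.organ_names}
        )
        assert qssa_error(weaker) < qssa_error(murine)
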