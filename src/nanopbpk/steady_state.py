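"""Steady-state %ID/g biodistribution model.

Predicts percent injected dose per gram of tissue from endothelial and
macrophage association constants at short observation times (before
substantial internalization).  Two variants are provided:

* ``original`` — specific (receptor-mediated) adhesion only, with the
  non-specific coefficient entering multiplicatively in the leading term;
* ``modified`` — non-specific transport through the intercellular cleft
  enters additively, which is the variant validated against murine data.

The printed source expressions lost their fraction bars in typesetting; the
dimensional reconstruction implemented here divides each bracketed
association term by (cell diameter x injected concentration), so that

    %ID/g (modified) = { kappa_p + phi_EC K_EC L_EC,b / (D_EC C_out) }
                         * L_cap / L_EC,b
                     + { phi_M K_M L_M,b / (D_M C_out) } * L_cap / L_M,b

with an endothelial term scaled by the capillary cell-free layer relative
to the EC binding distance and an analogous macrophage term.  The assembled
expression is exposed verbatim in this docstring for audit; the ambiguous
grouping of the original variant's leading term is behind the ``grouping``
switch.  The macrophage term uses the macrophage concentration ``phi_M``
(the printed form repeats phi_EC, a suspected typo).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .params import ValidationError

MEMBRANE_CONDITIONS = (
    "flat",
    "membrane",
    "membrane_macrophages",
    "membrane_active_macrophages",
)
ANTIBODY_DENSITIES = (41, 100, 162)


@dataclass
class SteadyStateParams:
    """Inputs of the steady-state %ID/g expression (one organ, one condition)."""

    kappa_p: float     # non-specific binding coefficient
    K_EC: float        # NP-endothelial association constant
    K_M: float         # NP-macrophage association constant
    D_EC: float        # endothelial cell diameter, m
    D_M: float         # macrophage diameter, m
    phi_EC: float      # endothelial cell concentration in target tissue
    phi_M: float       # macrophage concentration in target tissue
    L_EC_b: float      # binding-competent distance from EC receptor, m
    L_M_b: float       # binding-competent distance from macrophage receptor, m
    C_out: float       # injected NP concentration
    L_cap: float       # capillary cell-free layer, m

    def validate(self) -> None:
        for f in ("D_EC", "D_M", "L_EC_b", "L_M_b", "L_cap", "C_out"):
            if getattr(self, f) <= 0:
                raise ValidationError(
                    f"steady-state parameter {f} must be > 0 "
                    f"(got {getattr(self, f)}); the %ID/g expression divides by it"
                )
        for f in ("kappa_p", "K_EC", "K_M", "phi_EC", "phi_M"):
            if getattr(self, f) < 0:
                raise ValidationError(f"steady-state parameter {f} must be >= 0")


def percent_idg(
    params: SteadyStateParams,
    variant: str = "modified",
    grouping: str = "normalized",
) -> float:
    """Steady-state percent injected dose per gram for one organ.

    ``variant`` selects the original (multiplicative kappa_p) or modified
    (additive kappa_p) model.  ``grouping`` resolves the rendering
    ambiguity of the original variant's leading term: ``"normalized"``
    (default) divides it by (D_EC * C_out) like every other association
    term; ``"literal"`` keeps the printed product ``kappa_p K_EC C_out``.
    """
    params.validate()
    p = params
    ec_assoc = p.phi_EC * p.K_EC * p.L_EC_b / (p.D_EC * p.C_out)
    if variant == "modified":
        ec_bracket = p.kappa_p + ec_assoc
    elif variant == "original":
        if grouping == "normalized":
            ec_bracket = p.kappa_p * p.K_EC / (p.D_EC * p.C_out) + ec_assoc
        elif grouping == "literal":
            ec_bracket = p.kappa_p * p.K_EC * p.C_out + ec_assoc
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
    else:
        raise ValueError(f"unknown variant {variant!r}")
    ec_term = ec_bracket * p.L_cap / p.L_EC_b
    m_term = (p.phi_M * p.K_M * p.L_M_b / (p.D_M * p.C_out)) * p.L_cap / p.L_M_b
    return float(ec_term + m_term)


def macrophage_term(params: SteadyStateParams) -> float:
    """The macrophage contribution alone (zero when phi_M or K_M is zero)."""
    p = params
    p.validate()
    return float((p.phi_M * p.K_M * p.L_M_b / (p.D_M * p.C_out)) * p.L_cap / p.L_M_b)


class SteadyStateModel:
    """%ID/g over organs x membrane conditions x antibody densities.

    Built from the ``steady_state`` block of a parameter file (see the
    shipped murine fixture): global geometry (cell diameters, binding
    distances, cell-free layer, injected concentration, kappa_p) plus a
    per-condition table of association-constant overrides per organ at a
    reference antibody density.  K_EC scales with surface antibody count as
    ``(n / n_ref) ** antibody_exponent``.
    """

    def __init__(self, config: dict):
        if not config:
            raise ValidationError("no steady_state configuration supplied")
        self.config = config
        for f in ("kappa_p", "phi_EC", "D_EC", "D_M", "L_EC_b", "L_M_b",
                  "L_cap", "C_out", "conditions"):
            if f not in config:
                raise ValidationError(f"steady_state.{f} is missing")
        self.n_ref = config.get("antibody_reference", 100)
        self.gamma = config.get("antibody_exponent", 1.0)

    @classmethod
    def from_physiology(cls, phys) -> "SteadyStateModel":
        return cls(phys.steady_state)

    def params_for(
        self, organ: str, condition: str, n_antibodies: float
    ) -> SteadyStateParams:
        c = self.config
        try:
            cond = c["conditions"][condition]
        except KeyError:
            raise ValidationError(f"no override block for condition {condition!r}")
        kec_table = cond.get("K_EC", {})
        if organ not in kec_table:
            raise ValidationError(
                f"missing K_EC override for condition {condition!r}, organ {organ!r}"
            )
        scale = (n_antibodies / self.n_ref) ** self.gamma
        km = cond.get("K_M", 0.0)
        km_val = km.get(organ) if isinstance(km, dict) else km
        if km_val is None:
            raise ValidationError(
                f"missing K_M override for condition {condition!r}, organ {organ!r}"
            )
        return SteadyStateParams(
            kappa_p=c["kappa_p"],
            K_EC=kec_table[organ] * scale,
            K_M=km_val * scale,
            D_EC=c["D_EC"],
            D_M=c["D_M"],
            phi_EC=c["phi_EC"],
            phi_M=cond.get("phi_M", 0.0),
            L_EC_b=c["L_EC_b"],
            L_M_b=c["L_M_b"],
            C_out=c["C_out"],
            L_cap=c["L_cap"],
        )

    def percent_idg(self, organ: str, condition: str, n_antibodies: float,
                    variant: str = "modified", **kw) -> float:
        return percent_idg(self.params_for(organ, condition, n_antibodies),
                           variant=variant, **kw)

    def condition_table(
        self,
        organs=None,
        conditions=MEMBRANE_CONDITIONS,
        densities=ANTIBODY_DENSITIES,
        variant: str = "modified",
    ) -> "SteadyStateResult":
        organs = organs or sorted(
            next(iter(self.config["conditions"].values()))["K_EC"]
        )
        rows = []
        for organ in organs:
            for cond in conditions:
                for n in densities:
                    rows.append(
                        {
                            "organ": organ,
                            "condition": cond,
                            "n_antibodies": n,
                            "percent_idg": self.percent_idg(
                                organ, cond, n, variant=variant
                            ),
                        }
                    )
        return SteadyStateResult(pd.DataFrame(rows), variant)


def membrane_condition_table(model: SteadyStateModel, organs=None, **kw) -> pd.DataFrame:
    """Functional wrapper around :meth:`SteadyStateModel.condition_table`."""
    return model.condition_table(organs=organs, **kw).table


@dataclass
class SteadyStateResult:
    table: pd.DataFrame
    variant: str

    def pivot(self) -> pd.DataFrame:
        return self.table.pivot_table(
            index="organ", columns=["condition", "n_antibodies"],
            values="percent_idg",
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> str:
        lines = [
            f"Steady-state %ID/g ({self.variant} variant)",
            "-" * 44,
            self.pivot().round(3).to_string(),
        ]
        return "\n".join(lines)


def temporal_percent_idg(traj, phys, t_seconds: float = 1800.0) -> pd.Series:
    """%ID/g implied by a temporal trajectory at ``t_seconds``.

    Counts endothelial-bound plus internalized tissue content (the
    quantities the steady-state model predicts at short times), normalized
    by the injected dose and organ weight.  Used to check that the
    steady-state model approximates the temporal model at the ~30 min
    scale.
    """
    amounts = traj.at_time(t_seconds)
    idx = {lab: i for i, lab in enumerate(traj.labels)}
    dose = phys.systemic.dose
    out = {}
    for name, organ in phys.organs.items():
        bound = sum(
            amounts[i]
            for lab, i in idx.items()
            if lab.startswith(f"{name}_EC") or lab == f"{name}_T"
        )
        out[name] = 100.0 * bound / dose / organ.weight
    return pd.Series(out, name="percent_idg")
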