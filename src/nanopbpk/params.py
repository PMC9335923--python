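"""Physiological and nanoparticle parameters.

Loads per-organ physiology (flows, vascular/endothelial/tissue volumes, rate
constants) and nanoparticle properties from a YAML/JSON config, derives the
quantities the models need, and validates the stated invariants:

* the endothelial-layer volume ``V_EC = phi_EC * V_T * l_NC_b / D_EC``,
* venous/arterial blood volumes from total-blood-volume closure
  ``V_total = V_art + V_vein + sum(V_bl)`` with ``V_vein = V_art``,
* size-dependent binding kinetics ``K_on = D / l^2`` with the Stokes-Einstein
  diffusivity ``D = kB*T / (6 pi eta r)`` and
  ``K_off = K_on / log(K_EC)``, where ``log(K_EC)`` is linear in particle
  diameter (slope-point form anchored at a reference diameter).

All quantities are kept in SI-based model units internally: seconds, litres,
moles, metres; organ flows are stored as given (L/min) and converted to L/s
where rate matrices are assembled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

#: Boltzmann constant (J/K)
KB = 1.380649e-23

MODEL_A_ORGANS = ("lung", "heart", "kidney", "liver", "spleen")
MODEL_B_ORGANS = ("lung", "heart", "kidney", "liver", "spleen", "gut", "other")

_REQUIRED_UNITS = {
    "Q": "L/min",
    "V": "L",
    "K": "1/s",
    "weight": "g",
}


class ValidationError(ValueError):
    """A parameter file violated an invariant; the message names the field."""


@dataclass
class OrganParams:
    """Physiology and kinetics of a single organ compartment."""

    name: str
    Q: float          # blood flow, L/min
    V_bl: float       # vascular volume, L
    V_T: float        # tissue volume, L
    V_EC: float       # endothelial-layer volume, L
    weight: float     # organ wet weight, g
    K_on: float       # NP-receptor binding rate, 1/s
    K_off: float      # unbinding rate, 1/s
    K_up: float       # transcytotic uptake rate, 1/s
    K_NS: float       # non-specific uptake rate, 1/s
    K_deg: float      # degradation rate, 1/s
    phi: float | None = None   # branching-element count (branched model only)

    def validate(self) -> None:
        for f in ("V_bl", "V_T", "V_EC", "weight"):
            if getattr(self, f) <= 0:
                raise ValidationError(f"{self.name}.{f} must be > 0, got {getattr(self, f)}")
        if self.Q < 0:
            raise ValidationError(f"{self.name}.Q must be >= 0, got {self.Q}")
        for f in ("K_on", "K_off", "K_up", "K_NS", "K_deg"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{self.name}.{f} must be >= 0, got {getattr(self, f)}")
        if self.phi is not None and self.phi <= 0:
            raise ValidationError(f"{self.name}.phi must be > 0, got {self.phi}")


@dataclass
class SystemicParams:
    """Vein/artery volumes, degradation rates and the injected dose."""

    V_total: float      # total blood volume, L
    V_vein: float       # venous blood volume, L
    V_art: float        # arterial blood volume, L
    K_deg_vein: float   # 1/s
    K_deg_art: float    # 1/s
    dose: float         # injected amount, mol

    def validate(self, sum_V_bl: float) -> None:
        if self.V_vein <= 0 or self.V_art <= 0:
            raise ValidationError(
                f"V_vein/V_art must be > 0 (got {self.V_vein}, {self.V_art}); "
                f"check V_total against the summed organ vascular volumes"
            )
        if not math.isclose(self.V_vein, self.V_art, rel_tol=1e-9):
            raise ValidationError("V_vein must equal V_art")
        closure = self.V_art + self.V_vein + sum_V_bl
        if not math.isclose(closure, self.V_total, rel_tol=1e-6):
            raise ValidationError(
                f"V_total closure violated: V_art + V_vein + sum(V_bl) = {closure:g} "
                f"!= V_total = {self.V_total:g}"
            )
        for f in ("K_deg_vein", "K_deg_art"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be >= 0")
        if self.dose <= 0:
            raise ValidationError("dose must be > 0")


@dataclass
class NanoparticleSpec:
    """Nanoparticle size and the physical constants behind its diffusivity."""

    diameter: float           # nm
    n_antibodies: int = 100
    T: float = 310.0          # K
    eta: float = 1.2e-3       # Pa.s (murine plasma)
    l_glyco: float = 5.0e-7   # glycocalyx thickness, m
    kB: float = KB

    def validate(self) -> None:
        for f in ("diameter", "T", "eta", "l_glyco"):
            if getattr(self, f) <= 0:
                raise ValidationError(f"nanoparticle.{f} must be > 0")


@dataclass
class KecRelation:
    """log(K_EC) as a linear function of particle diameter (slope-point form)."""

    slope: float               # d log(K_EC) / d diameter, 1/nm
    anchor_diameter: float     # nm
    anchor_logKec: float
    log_base: float = 10.0
    per_organ_anchor: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.anchor_diameter <= 0:
            raise ValidationError("kec_relation.anchor_diameter must be > 0")
        if self.log_base <= 1:
            raise ValidationError("kec_relation.log_base must be > 1")

    def log_kec(self, diameter_nm: float, organ: str | None = None) -> float:
        anchor = self.per_organ_anchor.get(organ, self.anchor_logKec)
        return anchor + self.slope * (diameter_nm - self.anchor_diameter)


def stokes_einstein_diffusivity(np_spec: NanoparticleSpec) -> float:
    """Diffusion coefficient D = kB*T / (6 pi eta r), m^2/s (r = diameter/2)."""
    np_spec.validate()
    r = np_spec.diameter * 1e-9 / 2.0
    return np_spec.kB * np_spec.T / (6.0 * math.pi * np_spec.eta * r)


def size_dependent_kinetics(
    np_spec: NanoparticleSpec, rel: KecRelation, organ: str | None = None
) -> tuple[float, float, float]:
    """Diameter-dependent (K_on, K_off, log K_EC) for one organ.

    K_on is diffusion-limited through the glycocalyx, ``K_on = D / l^2``;
    K_off follows from the crowding-corrected equilibrium constant,
    ``K_off = K_on / log(K_EC)``.

    Raises
    ------
    ValidationError
        If the linear relation extrapolates to ``log(K_EC) <= 0`` — the
        off-rate is undefined there and the relation is out of its validity
        range.
    """
    rel.validate()
    D = stokes_einstein_diffusivity(np_spec)
    k_on = D / np_spec.l_glyco**2
    log_kec = rel.log_kec(np_spec.diameter, organ)
    if log_kec <= 0:
        raise ValidationError(
            f"log(K_EC) = {log_kec:g} <= 0 at diameter {np_spec.diameter:g} nm"
            f"{' for ' + organ if organ else ''}: the linear log(K_EC)-diameter "
            "relation was extrapolated outside its validity range"
        )
    return k_on, k_on / log_kec, log_kec


def derive_endothelial_volume(
    phi_EC: float, D_EC: float, V_T: float, l_NC_b: float
) -> float:
    """Endothelial-layer volume from the two-step area chain.

    The endothelial area per organ follows from ``l_EC^2 = phi_EC * V_T / D_EC``
    and the layer volume is that area times the receptor-layer height,
    ``V_EC = l_EC^2 * l_NC_b``.  With ``V_T`` in litres and the lengths in
    metres the result is in litres (the length units cancel).

    ``phi_EC = 0`` is allowed and yields ``V_EC = 0`` (no endothelial layer).
    """
    if phi_EC < 0:
        raise ValidationError("phi_EC must be >= 0")
    for name, v in (("D_EC", D_EC), ("V_T", V_T), ("l_NC_b", l_NC_b)):
        if v <= 0:
            raise ValidationError(f"{name} must be > 0, got {v}")
    area = phi_EC * V_T / D_EC
    return area * l_NC_b


class PhysiologyTable:
    """Validated per-organ physiology plus systemic/nanoparticle parameters."""

    def __init__(
        self,
        organs: dict[str, OrganParams],
        systemic: SystemicParams,
        np_spec: NanoparticleSpec,
        kec: KecRelation,
        steady_state: dict | None = None,
        tree_config: dict | None = None,
    ):
        self.organs = organs
        self.systemic = systemic
        self.np_spec = np_spec
        self.kec = kec
        self.steady_state = steady_state or {}
        self.tree_config = tree_config or {}
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_config(cls, config: Mapping) -> "PhysiologyTable":
        units = config.get("units")
        if not units:
            raise ValidationError("config must declare a 'units' block")
        for key, expected in _REQUIRED_UNITS.items():
            if units.get(key) != expected:
                raise ValidationError(
                    f"units.{key} must be declared as '{expected}', got {units.get(key)!r}"
                )

        endo = config.get("endothelium", {})
        for f in ("phi_EC", "D_EC", "l_NC_b"):
            if f not in endo:
                raise ValidationError(f"endothelium.{f} is missing")

        np_cfg = dict(config.get("nanoparticle", {}))
        np_spec = NanoparticleSpec(**np_cfg)
        kec_cfg = dict(config.get("kec_relation", {}))
        kec = KecRelation(**kec_cfg)

        organ_cfg = config.get("organs")
        if not organ_cfg:
            raise ValidationError("config declares no organs")
        organs: dict[str, OrganParams] = {}
        for name, oc in organ_cfg.items():
            missing = {"Q", "V_bl", "V_T", "weight", "K_NS", "K_up", "K_deg"} - set(oc)
            if missing:
                raise ValidationError(f"organ {name} is missing fields: {sorted(missing)}")
            V_EC = oc.get(
                "V_EC",
                derive_endothelial_volume(
                    endo["phi_EC"], endo["D_EC"], oc["V_T"], endo["l_NC_b"]
                ),
            )
            k_on, k_off, _ = size_dependent_kinetics(np_spec, kec, name)
            organs[name] = OrganParams(
                name=name,
                Q=oc["Q"],
                V_bl=oc["V_bl"],
                V_T=oc["V_T"],
                V_EC=V_EC,
                weight=oc["weight"],
                K_on=oc.get("K_on", k_on),
                K_off=oc.get("K_off", k_off),
                K_up=oc["K_up"],
                K_NS=oc["K_NS"],
                K_deg=oc["K_deg"],
            )

        sys_cfg = config.get("systemic")
        if not sys_cfg:
            raise ValidationError("config must declare a 'systemic' block")
        sum_V_bl = sum(o.V_bl for o in organs.values())
        if "V_vein" in sys_cfg:
            V_vein = sys_cfg["V_vein"]
            V_art = sys_cfg.get("V_art", V_vein)
            V_total = sys_cfg.get("V_total", V_vein + V_art + sum_V_bl)
        else:
            if "V_total" not in sys_cfg:
                raise ValidationError("systemic block needs V_total (or V_vein/V_art)")
            V_total = sys_cfg["V_total"]
            V_vein = V_art = (V_total - sum_V_bl) / 2.0
        systemic = SystemicParams(
            V_total=V_total,
            V_vein=V_vein,
            V_art=V_art,
            K_deg_vein=sys_cfg.get("K_deg_vein", 0.0),
            K_deg_art=sys_cfg.get("K_deg_art", 0.0),
            dose=sys_cfg.get("dose", 1.0),
        )
        return cls(
            organs,
            systemic,
            np_spec,
            kec,
            steady_state=config.get("steady_state"),
            tree_config=config.get("vascular_tree"),
        )

    def validate(self) -> None:
        for organ in self.organs.values():
            organ.validate()
        self.np_spec.validate()
        self.kec.validate()
        self.systemic.validate(sum(o.V_bl for o in self.organs.values()))

    # -- derived views ----------------------------------------------------

    @property
    def organ_names(self) -> tuple[str, ...]:
        return tuple(self.organs)

    def subset(self, names) -> "PhysiologyTable":
        """A new table restricted to ``names`` (V_total re-closed to match)."""
        organs = {}
        for n in names:
            if n not in self.organs:
                raise ValidationError(f"organ {n!r} not in table")
            organs[n] = replace(self.organs[n])
        sum_V_bl = sum(o.V_bl for o in organs.values())
        systemic = replace(
            self.systemic,
            V_total=self.systemic.V_vein + self.systemic.V_art + sum_V_bl,
        )
        return PhysiologyTable(
            organs, systemic, self.np_spec, self.kec,
            steady_state=self.steady_state, tree_config=self.tree_config,
        )

    def with_nanoparticle(self, diameter_nm: float) -> "PhysiologyTable":
        """A new table with K_on/K_off re-derived for a different NP size."""
        np_spec = replace(self.np_spec, diameter=diameter_nm)
        organs = {}
        for name, o in self.organs.items():
            k_on, k_off, _ = size_dependent_kinetics(np_spec, self.kec, name)
            organs[name] = replace(o, K_on=k_on, K_off=k_off)
        return PhysiologyTable(
            organs, replace(self.systemic), np_spec, self.kec,
            steady_state=self.steady_state, tree_config=self.tree_config,
        )

    def updated(self, organ: str, **rates) -> "PhysiologyTable":
        """A new table with rate constants of one organ replaced."""
        if organ not in self.organs:
            raise ValidationError(f"organ {organ!r} not in table")
        organs = {n: (replace(o, **rates) if n == organ else replace(o))
                  for n, o in self.organs.items()}
        return PhysiologyTable(
            organs, replace(self.systemic), self.np_spec, self.kec,
            steady_state=self.steady_state, tree_config=self.tree_config,
        )

    def replace_rates(self, per_organ: Mapping[str, Mapping[str, float]]) -> "PhysiologyTable":
        """A new table with several organs' rate constants replaced at once."""
        unknown = set(per_organ) - set(self.organs)
        if unknown:
            raise ValidationError(f"organs not in table: {sorted(unknown)}")
        organs = {
            n: (replace(o, **per_organ[n]) if n in per_organ else replace(o))
            for n, o in self.organs.items()
        }
        return PhysiologyTable(
            organs, replace(self.systemic), self.np_spec, self.kec,
            steady_state=self.steady_state, tree_config=self.tree_config,
        )

    def to_frame(self) -> pd.DataFrame:
        """Organ x parameter table of the derived values."""
        rows = []
        for o in self.organs.values():
            rows.append(
                {
                    "organ": o.name, "Q_L_per_min": o.Q, "V_bl_L": o.V_bl,
                    "V_EC_L": o.V_EC, "V_T_L": o.V_T, "weight_g": o.weight,
                    "K_on_per_s": o.K_on, "K_off_per_s": o.K_off,
                    "K_up_per_s": o.K_up, "K_NS_per_s": o.K_NS,
                    "K_deg_per_s": o.K_deg, "phi": o.phi,
                }
            )
        return pd.DataFrame(rows).set_index("organ")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def load_physiology(path) -> PhysiologyTable:
    """Load and validate a YAML or JSON parameter file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    config = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PhysiologyTable.from_config(config)


def default_murine_table() -> PhysiologyTable:
    """The shipped murine fixture parameter set."""
    return load_physiology(Path(__file__).parent / "data" / "murine.yaml")
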