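"""Experimental-data ingestion, unit conversion and NRMSD validation.

Experimental biodistribution studies report percent of injected dose per
gram of tissue (%ID/g) at a handful of sampling times; the models predict
whole-organ content.  This module converts between the two
(%ID/t = %ID/g x organ weight), holds tidy tables of experimental time
points, and scores a model trajectory against them with the normalized
root-mean-square deviation

    NRMSD = sqrt( mean_k (model(t_k) - exp_k)^2 ) / norm

where the model curve is linearly interpolated at the experimental times.
The normalization constant defaults to the mean of the experimental values
(dividing by their range or maximum is available via ``normalization``);
with mean normalization the score is invariant to a common rescaling of
model and data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solve import Trajectory

_COLUMNS = ["organ", "time_min", "value", "unit", "source"]
_UNITS = {"%ID/g", "%ID/t"}


@dataclass
class BiodistributionTable:
    """Tidy rows of (organ, time [min], value, unit, source label)."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = set(_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"biodistribution table missing columns {sorted(missing)}")
        bad_units = set(self.table["unit"]) - _UNITS
        if bad_units:
            raise ValueError(f"unknown units {sorted(bad_units)}; expected {_UNITS}")
        if (self.table["time_min"] < 0).any():
            raise ValueError("negative time in biodistribution table")
        if (self.table["value"] < 0).any():
            raise ValueError("negative value in biodistribution table")

    @classmethod
    def from_records(cls, records) -> "BiodistributionTable":
        return cls(pd.DataFrame(records, columns=_COLUMNS))

    @classmethod
    def read_csv(cls, path) -> "BiodistributionTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def organ(self, name: str, unit: str | None = None) -> pd.DataFrame:
        sub = self.table[self.table["organ"] == name]
        if unit is not None:
            sub = sub[sub["unit"] == unit]
        return sub.sort_values("time_min")

    def in_idt(self, organ_weights: dict[str, float]) -> "BiodistributionTable":
        """All rows converted to %ID/t using the supplied organ weights (g)."""
        rows = []
        for _, r in self.table.iterrows():
            if r["unit"] == "%ID/t":
                rows.append(dict(r))
            else:
                if r["organ"] not in organ_weights:
                    raise KeyError(f"no organ weight for {r['organ']!r}")
                rows.append(
                    {
                        **dict(r),
                        "value": idg_to_idt(r["value"], organ_weights[r["organ"]]),
                        "unit": "%ID/t",
                    }
                )
        return BiodistributionTable(pd.DataFrame(rows, columns=_COLUMNS))


def idg_to_idt(value_idg: float, organ_weight_g: float) -> float:
    """%ID/t = %ID/g x organ weight (g)."""
    if organ_weight_g <= 0:
        raise ValueError(f"organ weight must be > 0, got {organ_weight_g}")
    return value_idg * organ_weight_g


def model_idt_curve(traj: Trajectory, phys, organ: str) -> tuple[np.ndarray, np.ndarray]:
    """(time [min], %ID/t) for one organ's tissue + endothelial content."""
    dose = phys.systemic.dose
    content = np.zeros_like(traj.t)
    for lab in traj.labels:
        if lab == f"{organ}_T" or lab.startswith(f"{organ}_EC"):
            content = content + traj.amount(lab)
    return traj.t / 60.0, 100.0 * content / dose


def nrmsd(
    model_t_min: np.ndarray,
    model_values: np.ndarray,
    exp: BiodistributionTable,
    organ: str,
    unit: str = "%ID/t",
    normalization: str = "mean",
) -> float:
    """NRMSD between a model curve and experimental points for one organ.

    The model curve is interpolated linearly at the experimental times;
    ``normalization`` divides the RMSD by the ``"mean"`` (default),
    ``"range"`` or ``"max"`` of the experimental values.
    """
    pts = exp.organ(organ, unit)
    if len(pts) == 0:
        raise ValueError(f"no experimental {unit} points for organ {organ!r}")
    t_exp = pts["time_min"].to_numpy(dtype=float)
    v_exp = pts["value"].to_numpy(dtype=float)
    if t_exp.min() < model_t_min.min() - 1e-9 or t_exp.max() > model_t_min.max() + 1e-9:
        raise ValueError(
            f"experimental times [{t_exp.min():g}, {t_exp.max():g}] min fall "
            f"outside the model curve [{model_t_min.min():g}, "
            f"{model_t_min.max():g}] min"
        )
    v_mod = np.interp(t_exp, model_t_min, model_values)
    rmsd = float(np.sqrt(np.mean((v_mod - v_exp) ** 2)))
    if normalization == "mean":
        norm = float(np.mean(v_exp))
    elif normalization == "range":
        norm = float(np.ptp(v_exp))
    elif normalization == "max":
        norm = float(np.max(v_exp))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if norm == 0:
        raise ValueError("normalization constant is zero")
    return rmsd / norm


def validate_trajectory(
    traj: Trajectory, phys, exp: BiodistributionTable, organs=None,
    normalization: str = "mean",
) -> pd.DataFrame:
    """NRMSD per organ for a model trajectory against an experimental table."""
    organs = organs or sorted(set(exp.table["organ"]) & set(phys.organs))
    weights = {n: o.weight for n, o in phys.organs.items()}
    exp_idt = exp.in_idt(weights)
    rows = []
    for organ in organs:
        t_min, v = model_idt_curve(traj, phys, organ)
        rows.append(
            {
                "organ": organ,
                "nrmsd": nrmsd(t_min, v, exp_idt, organ, normalization=normalization),
                "n_points": len(exp_idt.organ(organ, "%ID/t")),
            }
        )
    return pd.DataFrame(rows).set_index("organ")
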