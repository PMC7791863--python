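"""Closed-form grazing, stoichiometry, qPCR and polyphosphate calculators.

Clearance and ingestion rates follow the classical bottle-experiment
formulation: with prey concentration declining exponentially under
constant filtering, the clearance rate per grazer is

    F = ln(Ct' / Ct) * V / (n * t)

where Ct' and Ct are the end-point prey concentrations in the grazer-free
control and the experimental bottle, V the culture volume, n the number
of grazers and t the incubation period. Ingestion is I = F * [C] with [C]
the prey concentration in the experimental bottle averaged over the
incubation. All calculators are pure functions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

ATOMIC_MASS = {"C": 12.011, "N": 14.007, "P": 30.974}


@dataclass
class GrazingObservation:
    """One bottle-pair observation from a grazing experiment.

    ``c_control_end`` (Ct', cells/mL) and ``c_exp_end`` (Ct, cells/mL) are
    end-point prey concentrations in the grazer-free and experimental
    bottles; ``volume`` in mL, ``duration`` in days; ``mean_prey_conc``
    ([C], cells/mL) is the time-averaged prey concentration in the
    experimental bottle.
    """

    c_control_end: float
    c_exp_end: float
    volume: float
    n_grazers: int
    duration: float
    mean_prey_conc: float | None = None

    def __post_init__(self) -> None:
        for name in ("c_control_end", "c_exp_end", "volume", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_grazers <= 0:
            raise ValueError("n_grazers must be strictly positive")
        if self.mean_prey_conc is not None and self.mean_prey_conc <= 0:
            raise ValueError("mean_prey_conc must be strictly positive")


@dataclass
class QpcrQuartet:
    """The four cycle-threshold values entering a 2^-ddCt calculation."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_treated",
            "ct_reference_treated",
            "ct_target_control",
            "ct_reference_control",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def clearance_rate(
    obs: GrazingObservation, volume_unit_out: Literal["mL", "uL"] = "uL"
) -> float:
    """Clearance rate F = ln(Ct'/Ct) * V / (n t), per grazer per day.

    Computed in the unit of ``volume`` (mL) and converted on request;
    the conventional reporting unit here is uL per individual per day.
    Negative values (prey net growth in the experimental bottle) are
    returned as-is with a warning, since truncation would bias means.
    """
    f_ml = math.log(obs.c_control_end / obs.c_exp_end) * obs.volume / (
        obs.n_grazers * obs.duration
    )
    if f_ml < 0:
        warnings.warn(
            "negative clearance rate: prey outgrew the control in the "
            "experimental bottle",
            stacklevel=2,
        )
    if volume_unit_out == "mL":
        return f_ml
    if volume_unit_out in ("uL", "µL"):
        return f_ml * 1000.0
    raise ValueError(f"unknown volume unit {volume_unit_out!r}")


def ingestion_rate(clearance_ml: float, mean_prey_conc: float) -> float:
    """Ingestion rate I = F * [C], cells per grazer per day.

    ``clearance_ml`` must be in mL per individual per day so units cancel
    against the cells/mL prey concentration.
    """
    if not math.isfinite(clearance_ml):
        raise ValueError("clearance rate must be finite")
    if mean_prey_conc <= 0:
        raise ValueError("mean prey concentration must be strictly positive")
    return clearance_ml * mean_prey_conc


def mean_prey_concentration(
    c_start: float, c_end: float, method: Literal["arithmetic", "log_mean"] = "log_mean"
) -> float:
    """Time-averaged prey concentration over the incubation.

    The log mean (c_start - c_end) / ln(c_start / c_end) is the exact time
    average under exponential decline and is the default; the arithmetic
    mean is available for comparison. Both reduce to the common value when
    the concentrations are equal.
    """
    if c_start <= 0 or c_end <= 0:
        raise ValueError("concentrations must be strictly positive")
    if method == "arithmetic":
        return (c_start + c_end) / 2.0
    if method == "log_mean":
        if c_start == c_end:
            return c_start
        return (c_start - c_end) / math.log(c_start / c_end)
    raise ValueError(f"unknown method {method!r}")


def molar_ratio(
    mass_a: float,
    mass_b: float,
    element_a: Literal["C", "N", "P"],
    element_b: Literal["C", "N", "P"],
) -> float:
    """Molar ratio of two elemental masses given in the same mass unit."""
    if mass_a <= 0 or mass_b <= 0:
        raise ValueError("masses entering a ratio must be strictly positive")
    return (mass_a / ATOMIC_MASS[element_a]) / (mass_b / ATOMIC_MASS[element_b])


def ddct_fold_change(q: QpcrQuartet) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control;
    returns 2 to the power -ddCt.
    """
    d_treated = q.ct_target_treated - q.ct_reference_treated
    d_control = q.ct_target_control - q.ct_reference_control
    return 2.0 ** (-(d_treated - d_control))


def polyp_specific_fluorescence(rfu: float, protein_mg: float) -> float:
    """Polyphosphate signal normalised to total cellular protein (r.f.u./mg)."""
    if protein_mg <= 0:
        raise ValueError("protein mass must be strictly positive")
    if rfu < 0:
        raise ValueError("fluorescence must be non-negative")
    return rfu / protein_mg
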