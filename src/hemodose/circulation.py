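"""Whole-body blood circulation as flow-weighted parallel compartments.

The circulating blood pool is split into named compartments, each holding a
blood volume V_o (mL) and receiving a blood flow Q_o (mL/min). Blood
"particles" visit compartments with probability proportional to Q_o and stay
for the mean transit time V_o / Q_o, which makes the long-run occupancy of a
compartment proportional to its blood volume — the stationary behaviour the
ICRP reference-person flow model implies. A "residual body" compartment
absorbs whatever volume and flow the named organs do not claim, so that the
compartment sums close exactly on the sex-specific totals (male: 5.3 L blood,
6.5 L/min cardiac output; female: 3.9 L, 5.9 L/min).

The per-compartment volume/flow fractions shipped in ``data/`` are an
adaptation of ICRP Publication 89 reference values to this parallel topology
(conduit vessels and lungs carry the full cardiac output in series in the
real circulation; here their flow fractions are scaled so a parallel model
reproduces sensible transit times). The table is user-replaceable: pass any
CSV with the same header to :func:`build_reference_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Compartment",
    "CirculationModel",
    "REFERENCE_TOTALS",
    "STANDARD_COMPARTMENTS",
    "RESIDUAL_NAME",
    "build_reference_model",
    "mean_transit_time",
    "steady_state_occupancy",
    "validate",
    "load_parameter_table",
]

#: Sex-specific reference totals: (total blood volume [L], cardiac output [L/min]).
REFERENCE_TOTALS = {"male": (5.3, 6.5), "female": (3.9, 5.9)}

RESIDUAL_NAME = "residual_body"

#: Anatomical structures tracked for head-and-neck blood dose estimation.
STANDARD_COMPARTMENTS = (
    "aorta",
    "bone",
    "brain",
    "bronchi",
    "fat",
    "large_arteries",
    "large_veins",
    "lungs",
    "lymph_nodes",
    "skeletal_muscles",
    "skin",
    "stomach",
    "esophagus",
    "superior_vena_cava",
    "thyroid",
    RESIDUAL_NAME,
)

#: Relative tolerance for the conservation invariants.
_CONSERVATION_RTOL = 1e-3


@dataclass
class Compartment:
    """One blood pool with its volume, perfusing flow and in-field flag."""

    name: str
    blood_volume: float  # mL
    blood_flow: float  # mL/min
    in_field: bool = True


@dataclass
class CirculationModel:
    """Parallel-compartment circulation with sex-specific totals."""

    sex: str
    compartments: list[Compartment] = field(default_factory=list)
    total_blood_volume: float = 0.0  # L
    cardiac_output: float = 0.0  # L/min

    def compartment(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compartments]


def mean_transit_time(c: Compartment) -> float:
    """Mean residence time of blood in a compartment, in seconds (60·V/Q)."""
    if c.blood_flow <= 0:
        raise ValidationError(f"compartment {c.name!r} has non-positive blood flow")
    return 60.0 * c.blood_volume / c.blood_flow


def steady_state_occupancy(m: CirculationModel) -> dict[str, float]:
    """Stationary probability of residing in each compartment (V_o / V_total)."""
    problems = validate(m)
    if problems:
        raise ValidationError("; ".join(problems))
    total_ml = m.total_blood_volume * 1000.0
    return {c.name: c.blood_volume / total_ml for c in m.compartments}


def validate(m: CirculationModel) -> list[str]:
    """Return a list of invariant violations (empty iff the model is valid)."""
    out: list[str] = []
    seen: set[str] = set()
    for c in m.compartments:
        if c.name in seen:
            out.append(f"duplicate compartment name {c.name!r}")
        seen.add(c.name)
        if c.blood_volume <= 0:
            out.append(f"compartment {c.name!r}: blood_volume must be > 0")
        if c.blood_flow <= 0:
            out.append(f"compartment {c.name!r}: blood_flow must be > 0")
    v_sum = sum(c.blood_volume for c in m.compartments)
    q_sum = sum(c.blood_flow for c in m.compartments)
    v_tot = m.total_blood_volume * 1000.0
    q_tot = m.cardiac_output * 1000.0
    if v_tot <= 0 or abs(v_sum - v_tot) > _CONSERVATION_RTOL * v_tot:
        out.append(
            f"blood volume not conserved: compartments sum to {v_sum:.1f} mL, "
            f"total is {v_tot:.1f} mL"
        )
    if q_tot <= 0 or abs(q_sum - q_tot) > _CONSERVATION_RTOL * q_tot:
        out.append(
            f"blood flow not conserved: compartments sum to {q_sum:.1f} mL/min, "
            f"cardiac output is {q_tot:.1f} mL/min"
        )
    return out


def load_parameter_table(source: str | Path | pd.DataFrame | None = None,
                         sex: str = "male") -> pd.DataFrame:
    """Load a compartment parameter table.

    The table must have columns ``compartment, volume_fraction, flow_fraction,
    in_field`` with fractions relative to the sex-specific totals. With
    ``source=None`` the packaged reference table for ``sex`` is used.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    elif source is None:
        ref = resources.files("hemodose.data") / f"icrp89_{sex}.csv"
        with resources.as_file(ref) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(source)
    required = {"compartment", "volume_fraction", "flow_fraction", "in_field"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"parameter table missing columns: {sorted(missing)}")
    return df


def build_reference_model(
    sex: str,
    parameter_table: str | Path | pd.DataFrame | None = None,
    required_compartments: Sequence[str] | None = None,
) -> CirculationModel:
    """Build a circulation model with sex-specific reference totals.

    Parameters
    ----------
    sex:
        ``"male"`` (5.3 L, 6.5 L/min) or ``"female"`` (3.9 L, 5.9 L/min).
    parameter_table:
        CSV path or DataFrame with per-compartment volume/flow fractions.
        ``None`` loads the packaged reference table, in which case the full
        standard compartment list is required.
    required_compartments:
        Names that must be present in the table (besides the residual body,
        which is synthesized if absent). Defaults to
        :data:`STANDARD_COMPARTMENTS` when the packaged table is used, and to
        no requirement for user-supplied tables.
    """
    if sex not in REFERENCE_TOTALS:
        raise ConfigurationError(f"unknown sex {sex!r}; expected 'male' or 'female'")
    if required_compartments is None and parameter_table is None:
        required_compartments = [n for n in STANDARD_COMPARTMENTS if n != RESIDUAL_NAME]

    df = load_parameter_table(parameter_table, sex=sex)
    names = list(df["compartment"])
    if len(set(names)) != len(names):
        raise ValidationError("duplicate compartment names in parameter table")
    if required_compartments:
        missing = [n for n in required_compartments if n not in names]
        if missing:
            raise ConfigurationError(
                f"parameter table is missing compartment(s): {', '.join(missing)}"
            )

    v_total_l, q_total_lmin = REFERENCE_TOTALS[sex]
    v_total, q_total = v_total_l * 1000.0, q_total_lmin * 1000.0

    # Residual closure: the residual body absorbs the unclaimed remainder so
    # that both conservation sums close exactly. Any fractions listed for it
    # in the table are recomputed.
    named = df[df["compartment"] != RESIDUAL_NAME]
    v_frac_sum = float(named["volume_fraction"].sum())
    q_frac_sum = float(named["flow_fraction"].sum())
    tol = 1e-9
    if v_frac_sum > 1 + tol or q_frac_sum > 1 + tol:
        raise ValidationError(
            f"compartment fractions exceed totals before residual closure "
            f"(volume {v_frac_sum:.4f}, flow {q_frac_sum:.4f})"
        )

    compartments = [
        Compartment(
            name=str(row.compartment),
            blood_volume=float(row.volume_fraction) * v_total,
            blood_flow=float(row.flow_fraction) * q_total,
            in_field=bool(row.in_field),
        )
        for row in named.itertuples()
    ]
    v_res = (1.0 - v_frac_sum) * v_total
    q_res = (1.0 - q_frac_sum) * q_total
    if v_res > tol * v_total or q_res > tol * q_total:
        if v_res <= 0 or q_res <= 0:
            raise ValidationError(
                "residual closure impossible: one of volume/flow is fully "
                "claimed while the other is not"
            )
        res_in_field = True
        if RESIDUAL_NAME in set(df["compartment"]):
            res_in_field = bool(
                df.loc[df["compartment"] == RESIDUAL_NAME, "in_field"].iloc[0]
            )
        compartments.append(
            Compartment(RESIDUAL_NAME, v_res, q_res, in_field=res_in_field)
        )

    model = CirculationModel(
        sex=sex,
        compartments=compartments,
        total_blood_volume=v_total_l,
        cardiac_output=q_total_lmin,
    )
    problems = validate(model)
    if problems:
        raise ValidationError("; ".join(problems))
    return model
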