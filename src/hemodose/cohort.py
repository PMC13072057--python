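"""Synthetic head-and-neck plan cohort with the study's comparison structure.

Real treatment plans come out of a commercial optimizer and are not
reproducible here; what the downstream analysis consumes is only their
dose-level signature, which this module emulates directly at the DVH level:

* a 20-patient cohort (15 male / 5 female) with 60 Gy / 52 Gy prescriptions
  to PTV1 / PTV2 in 33 fractions;
* six plan conditions per patient — {IMRT, IMPT} x {Conv, BVS-90%, BVS-80%};
* organ-class dose priors (lognormal course mean doses: conduit vessels high,
  near-field neck organs moderate, low-dose-bath tissues low, distal organs
  lowest) shaped into smooth logistic survival curves;
* proton plans shrink the out-of-field low-dose bath by a configurable
  factor while vessel doses, driven by target proximity, stay put;
* vessel-sparing conditions rescale the large-artery/large-vein (and other
  conduit vessel) DVH dose axes so the vessel mean dose is exactly 90% / 80%
  of the same patient's conventional plan, with a small localized
  redistribution (brain/brainstem hot-spot up, esophagus mean down);
* one optional outlier whose vessels overlap the target: vessel doses near
  prescription scale and essentially no vessel-sparing headroom.

Schedules follow the delivery parameters of the emulated study: IMRT 9
fields x 40 s, IMPT 4 fields x 30 s, 33 fractions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .circulation import STANDARD_COMPARTMENTS, RESIDUAL_NAME
from .dvh import DEFAULT_BIN_WIDTH, CumulativeDVH, read_dvh_csv, write_dvh_csv
from .errors import ConfigurationError, IntegrityError
from .simulator import BeamSchedule

__all__ = [
    "CohortConfig",
    "PlanCondition",
    "MODALITIES",
    "CONSTRAINT_LEVELS",
    "generate_cohort",
    "generate_overlap_outlier",
    "emit_cohort",
    "load_cohort",
]

MODALITIES = ("IMRT", "IMPT")
CONSTRAINT_LEVELS = ("conv", "bvs90", "bvs80")

PRESCRIPTIONS = {"PTV1": 60.0, "PTV2": 52.0}
N_FRACTIONS = 33
SCHEDULES = {
    "IMRT": dict(n_fields=9, field_beam_on=40.0),
    "IMPT": dict(n_fields=4, field_beam_on=30.0),
}

#: Conduit vessels whose mean dose the BVS constraint controls.
VESSEL_ORGANS = ("aorta", "large_arteries", "large_veins", "superior_vena_cava")
#: Near-field neck structures.
NECK_ORGANS = ("thyroid", "lymph_nodes", "esophagus")
#: Low-dose bath tissues (large volumes, low dose).
BATH_ORGANS = ("bone", "skeletal_muscles", "skin", "brain", RESIDUAL_NAME)
#: Distal thoracic/abdominal organs.
DISTAL_ORGANS = ("lungs", "stomach", "bronchi", "fat")

#: Lognormal priors for course mean dose (Gy): (median, sigma of log).
DOSE_PRIORS = {
    "vessel": (5.5, 0.35),
    "neck": (3.0, 0.40),
    "bath": (0.7, 0.30),
    "distal": (0.3, 0.40),
}

#: Relative width of the logistic organ survival curves (s / mean).
ORGAN_SHAPE_WIDTH = 0.6


def _organ_class(name: str) -> str:
    if name in VESSEL_ORGANS:
        return "vessel"
    if name in NECK_ORGANS:
        return "neck"
    if name in BATH_ORGANS:
        return "bath"
    if name in DISTAL_ORGANS:
        return "distal"
    raise ConfigurationError(f"organ {name!r} has no dose-prior class")


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort; defaults are the emulated study design."""

    n_patients: int = 20
    male_fraction: float = 15 / 20
    seed: int = 0
    vessel_scaling: dict = field(
        default_factory=lambda: {"conv": 1.0, "bvs90": 0.9, "bvs80": 0.8}
    )
    impt_low_dose_factor: float = 0.55  # multiplier on non-vessel organ doses
    brain_dmax_increase: tuple = (0.01, 0.03)  # BVS hot-spot redistribution
    esophagus_dmean_decrease: tuple = (0.05, 0.10)  # concurrent esophagus gain
    include_overlap_outlier: bool = True
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not (0 <= self.male_fraction <= 1):
            raise ConfigurationError("male_fraction must be a probability")
        for k, v in self.vessel_scaling.items():
            if not (0 < v <= 1):
                raise ConfigurationError(f"vessel scaling {k}={v} not in (0, 1]")
        if not (0 < self.impt_low_dose_factor <= 1):
            raise ConfigurationError("impt_low_dose_factor must be in (0, 1]")
        for lo, hi in (self.brain_dmax_increase, self.esophagus_dmean_decrease):
            if not (0 <= lo <= hi < 1):
                raise ConfigurationError("redistribution effect bounds invalid")


@dataclass
class PlanCondition:
    """One patient-plan: organ DVHs, targets, schedule and labels."""

    patient_id: str
    sex: str
    modality: str
    constraint_level: str
    organ_dvhs: dict[str, CumulativeDVH]
    ptv_dvhs: dict[str, CumulativeDVH]
    ptv_volumes: dict[str, float]  # cm^3
    isodose95_volumes: dict[str, float]  # cm^3
    schedule: BeamSchedule
    is_outlier: bool = False

    @property
    def condition(self) -> str:
        return f"{self.modality}_{self.constraint_level}"


# ---------------------------------------------------------------------- #
# curve builders


def _organ_survival_dvh(mean: float, rel_width: float, bin_width: float) -> CumulativeDVH:
    """Logistic survival curve with (approximately) the requested mean dose.

    S(d) = L(d) / L(0) with L logistic around mu and scale rel_width*mu;
    mu is calibrated numerically so the trapezoidal mean equals ``mean``.
    """
    def survival_for(mu: float):
        s0 = rel_width * mu
        def s(d):
            base = 1.0 / (1.0 + np.exp((d - mu) / s0))
            return base / (1.0 / (1.0 + np.exp(-mu / s0)))
        return s

    mu = mean
    for _ in range(4):  # fixed-point calibration of the curve mean
        s = survival_for(mu)
        grid_max = mu * (1 + 10 * rel_width)
        fine = np.linspace(0, grid_max, 4001)
        m_actual = np.trapezoid(np.clip(s(fine), 0, 1), fine)
        mu *= mean / m_actual
    s = survival_for(mu)
    return CumulativeDVH.from_survival(s, mu * (1 + 10 * rel_width), bin_width)


def _ptv_survival_dvh(rx: float, hi_target: float, bin_width: float) -> CumulativeDVH:
    """Piecewise-linear target DVH hitting a requested homogeneity index.

    The hot shoulder is kept inside the +1% objective (D0.1% < 1.01 Rx);
    the cold shoulder is widened to realize HI = D5%/D95% above 1.02, the
    regime head-and-neck plans actually occupy.
    """
    e = 0.006  # D5% at Rx*(1+e)
    c = 1.0 - (1.0 + e) / hi_target  # D95% at Rx*(1-c)
    h = e + 0.003  # D0.1% at Rx*(1+h) < 1.01 Rx
    b = c + 0.01  # D98% shoulder slightly below D95%
    knots_d = np.array([0.0, rx * (1 - b - 0.02), rx * (1 - b), rx * (1 - c),
                        rx * (1 + e), rx * (1 + h), rx * (1 + h) + 2 * bin_width])
    knots_s = np.array([1.0, 1.0, 0.98, 0.95, 0.05, 0.001, 0.0])

    def s(d):
        return np.interp(d, knots_d, knots_s)

    return CumulativeDVH.from_survival(s, knots_d[-1], bin_width)


# ---------------------------------------------------------------------- #
# generation


def _draw_patient_baseline(rng: np.random.Generator, cfg: CohortConfig,
                           outlier: bool) -> dict[str, float]:
    """Course mean dose per organ for the patient's IMRT-Conv plan."""
    means = {}
    for organ in STANDARD_COMPARTMENTS:
        med, sig = DOSE_PRIORS[_organ_class(organ)]
        means[organ] = float(np.exp(np.log(med) + sig * rng.standard_normal()))
    if outlier:
        # vessels overlap the target: vessel dose near prescription scale
        for organ in VESSEL_ORGANS:
            means[organ] = float(rng.uniform(50.0, 58.0))
    return means


def _make_conditions(patient_id: str, sex: str, baseline: dict[str, float],
                     rng: np.random.Generator, cfg: CohortConfig,
                     outlier: bool) -> list[PlanCondition]:
    bw = cfg.bin_width
    # per-patient plan-quality randomness, shared across conditions with
    # small per-condition jitter
    hi_center = {ptv: rng.uniform(1.03, 1.08) for ptv in PRESCRIPTIONS}
    ptv_volumes = {"PTV1": float(rng.lognormal(np.log(150.0), 0.4)),
                   "PTV2": float(rng.lognormal(np.log(350.0), 0.3))}
    brain_up = rng.uniform(*cfg.brain_dmax_increase)
    eso_down = rng.uniform(*cfg.esophagus_dmean_decrease)

    conditions = []
    for modality in MODALITIES:
        # modality baseline: protons shrink the low-dose bath
        organ_means = dict(baseline)
        if modality == "IMPT":
            for organ in organ_means:
                if organ not in VESSEL_ORGANS:
                    organ_means[organ] *= cfg.impt_low_dose_factor
        conv_dvhs = {
            organ: _organ_survival_dvh(m, ORGAN_SHAPE_WIDTH, bw)
            for organ, m in organ_means.items()
        }
        for level in CONSTRAINT_LEVELS:
            f = cfg.vessel_scaling[level]
            if outlier:
                # vessels inside the target leave almost no sparing headroom:
                # the optimizer cannot pull dose off vessels that sit in the
                # PTV, so the achieved scaling is capped near unity
                # (conv -> 1.0, bvs90 -> 0.995, bvs80 -> 0.99).
                f = 1.0 - 0.05 * (1.0 - f)
            dvhs = {}
            for organ, d in conv_dvhs.items():
                if organ in VESSEL_ORGANS and f < 1.0:
                    dvhs[organ] = d.scale_dose(f)
                elif organ == "brain" and level != "conv":
                    scale = 1.0 + brain_up * (1.0 if level == "bvs80" else 0.5)
                    dvhs[organ] = d.scale_dose(scale)
                elif organ == "esophagus" and level != "conv":
                    scale = 1.0 - eso_down * (1.0 if level == "bvs80" else 0.5)
                    dvhs[organ] = d.scale_dose(scale)
                else:
                    dvhs[organ] = CumulativeDVH(d.dose_gy.copy(),
                                                d.volume_fraction.copy())
            ptv_dvhs = {}
            iso95 = {}
            for ptv, rx in PRESCRIPTIONS.items():
                hi = float(np.clip(hi_center[ptv] + rng.uniform(-0.008, 0.008),
                                   1.022, 1.095))
                ptv_dvhs[ptv] = _ptv_survival_dvh(rx, hi, bw)
                iso95[ptv] = ptv_volumes[ptv] * float(rng.uniform(0.965, 0.995))
            sched = BeamSchedule(modality=modality, n_fractions=N_FRACTIONS,
                                 **SCHEDULES[modality])
            conditions.append(PlanCondition(
                patient_id=patient_id, sex=sex, modality=modality,
                constraint_level=level, organ_dvhs=dvhs, ptv_dvhs=ptv_dvhs,
                ptv_volumes=dict(ptv_volumes), isodose95_volumes=iso95,
                schedule=sched, is_outlier=outlier,
            ))
    return conditions


def generate_cohort(cfg: CohortConfig | None = None) -> list[PlanCondition]:
    """Generate the full synthetic cohort (n_patients x 6 plan conditions).

    Deterministic for a fixed seed. If ``include_overlap_outlier`` is set,
    the last patient is the vessel-target-overlap case.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n_male = int(round(cfg.male_fraction * cfg.n_patients))
    sexes = np.array(["male"] * n_male + ["female"] * (cfg.n_patients - n_male))
    rng.shuffle(sexes)
    plans: list[PlanCondition] = []
    for i in range(cfg.n_patients):
        outlier = cfg.include_overlap_outlier and i == cfg.n_patients - 1
        pid = f"P{i + 1:03d}"
        baseline = _draw_patient_baseline(rng, cfg, outlier)
        plans.extend(_make_conditions(pid, str(sexes[i]), baseline, rng, cfg, outlier))
    return plans


def generate_overlap_outlier(cfg: CohortConfig | None = None,
                             patient_id: str = "P999",
                             sex: str = "male",
                             rng: np.random.Generator | None = None
                             ) -> list[PlanCondition]:
    """Generate the six plan conditions of a vessel-target-overlap patient.

    The outlier's conduit vessels sit inside the high-dose region, so its
    vessel mean dose is near prescription scale in every condition and the
    vessel-sparing constraint changes it by < 2%.
    """
    cfg = cfg or CohortConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    baseline = _draw_patient_baseline(rng, cfg, outlier=True)
    return _make_conditions(patient_id, sex, baseline, rng, cfg, outlier=True)


# ---------------------------------------------------------------------- #
# serialization: cohort/<patient>/<modality>_<level>/{dvh.csv,ptv.csv} + manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def emit_cohort(plans: list[PlanCondition], path: str | Path) -> Path:
    """Serialize a cohort to a directory tree with an integrity manifest."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in plans:
        d = root / p.patient_id / p.condition
        d.mkdir(parents=True, exist_ok=True)
        write_dvh_csv(p.organ_dvhs, d / "dvh.csv")
        write_dvh_csv(p.ptv_dvhs, d / "ptv.csv")
        entries.append({
            "patient_id": p.patient_id,
            "sex": p.sex,
            "modality": p.modality,
            "constraint_level": p.constraint_level,
            "is_outlier": p.is_outlier,
            "ptv_volumes": p.ptv_volumes,
            "isodose95_volumes": p.isodose95_volumes,
            "schedule": {
                "modality": p.schedule.modality,
                "n_fields": p.schedule.n_fields,
                "field_beam_on": p.schedule.field_beam_on,
                "n_fractions": p.schedule.n_fractions,
                "inter_field_gap": p.schedule.inter_field_gap,
            },
            "files": {
                "dvh.csv": _sha256(d / "dvh.csv"),
                "ptv.csv": _sha256(d / "ptv.csv"),
            },
        })
    manifest = {"n_plan_conditions": len(plans), "plans": entries}
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root


def load_cohort(path: str | Path) -> list[PlanCondition]:
    """Load a serialized cohort, verifying file hashes against the manifest."""
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise IntegrityError(f"no manifest.json under {root}")
    manifest = json.loads(manifest_path.read_text())
    plans = []
    for entry in manifest["plans"]:
        d = root / entry["patient_id"] / f"{entry['modality']}_{entry['constraint_level']}"
        for fname, want in entry["files"].items():
            fpath = d / fname
            if not fpath.exists() or _sha256(fpath) != want:
                raise IntegrityError(
                    f"cohort file corrupt or missing: {entry['patient_id']} "
                    f"{entry['modality']}_{entry['constraint_level']}/{fname}"
                )
        sched = BeamSchedule(**entry["schedule"])
        plans.append(PlanCondition(
            patient_id=entry["patient_id"], sex=entry["sex"],
            modality=entry["modality"], constraint_level=entry["constraint_level"],
            organ_dvhs=read_dvh_csv(d / "dvh.csv"),
            ptv_dvhs=read_dvh_csv(d / "ptv.csv"),
            ptv_volumes=entry["ptv_volumes"],
            isodose95_volumes=entry["isodose95_volumes"],
            schedule=sched, is_outlier=entry["is_outlier"],
        ))
    if len(plans) != manifest["n_plan_conditions"]:
        raise IntegrityError("manifest plan count does not match entries")
    return plans
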