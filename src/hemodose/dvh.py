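"""Cumulative dose-volume histograms and the scalar metrics built on them.

A cumulative DVH is the survival function of dose over a structure's volume:
``volume_fraction[i]`` is the fraction of the volume receiving at least
``dose_gy[i]``. All plan evaluation in this package reduces to a handful of
scalar functionals of that curve:

* ``Dn%`` — the minimum dose received by the most-irradiated n% of the
  volume, i.e. the (linearly interpolated) inverse of the survival curve,
  with ties resolved toward the lower dose;
* ``VxGy`` — the volume fraction receiving at least x Gy;
* ``Dmean`` — the integral of the survival curve (trapezoidal);
* ``HI = D5% / D95%`` — target dose homogeneity (1 = perfectly uniform);
* ``CI`` — 95%-isodose volume over PTV volume, reported in percent.

DVHs live on a uniform dose grid starting at 0 Gy (default bin 0.01 Gy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, UndefinedMetricError, ValidationError

__all__ = [
    "CumulativeDVH",
    "PlanQuality",
    "read_dvh_csv",
    "write_dvh_csv",
    "d_at_volume",
    "v_at_dose",
    "mean_dose",
    "max_dose",
    "homogeneity_index",
    "conformity_index",
]

DEFAULT_BIN_WIDTH = 0.01  # Gy
_MAX_DOSE_TOL = 1e-9


@dataclass
class CumulativeDVH:
    """Cumulative DVH on a uniform dose grid starting at 0 Gy."""

    dose_gy: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        d, v = self.dose_gy, self.volume_fraction
        if d.ndim != 1 or d.shape != v.shape or d.size < 2:
            raise ValidationError("dose grid and volume fractions must be 1-D, equal length >= 2")
        if d[0] != 0.0:
            raise ValidationError("dose grid must start at 0 Gy")
        if np.any(np.diff(d) <= 0):
            raise ValidationError("dose grid must be strictly increasing")
        if abs(v[0] - 1.0) > 1e-9:
            raise ValidationError("volume fraction at 0 Gy must be 1")
        if np.any(np.diff(v) > 1e-12):
            raise ValidationError("volume fractions must be monotone non-increasing")
        if v[-1] < -1e-12:
            raise ValidationError("volume fractions must be non-negative")

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def delta(cls, dose: float, bin_width: float = DEFAULT_BIN_WIDTH) -> "CumulativeDVH":
        """Uniform-dose DVH: the whole volume receives exactly ``dose``."""
        if dose < 0:
            raise DomainError("dose must be non-negative")
        grid = _uniform_grid(dose + bin_width, bin_width)
        frac = np.where(grid <= dose + _MAX_DOSE_TOL, 1.0, 0.0)
        return cls(grid, frac)

    @classmethod
    def from_survival(cls, survival, max_dose_gy: float,
                      bin_width: float = DEFAULT_BIN_WIDTH) -> "CumulativeDVH":
        """Tabulate an analytic survival function ``S(d)`` on a uniform grid.

        The curve is clipped to [0, 1], forced to 1 at d=0 and made monotone.
        """
        grid = _uniform_grid(max_dose_gy, bin_width)
        frac = np.clip(np.asarray(survival(grid), dtype=float), 0.0, 1.0)
        frac[0] = 1.0
        frac = np.minimum.accumulate(frac)
        return cls(grid, frac)

    @classmethod
    def from_doses(cls, doses: np.ndarray,
                   bin_width: float = DEFAULT_BIN_WIDTH) -> "CumulativeDVH":
        """Empirical survival curve of a sample of per-particle doses."""
        doses = np.asarray(doses, dtype=float)
        if doses.size == 0:
            raise DomainError("cannot build a DVH from an empty dose vector")
        if np.any(doses < 0):
            raise DomainError("doses must be non-negative")
        grid = _uniform_grid(float(doses.max()) + bin_width, bin_width)
        srt = np.sort(doses)
        # fraction of doses >= each grid point
        frac = 1.0 - np.searchsorted(srt, grid, side="left") / doses.size
        frac[0] = 1.0
        return cls(grid, frac)

    # ------------------------------------------------------------------ #
    # transforms

    def scale_dose(self, alpha: float) -> "CumulativeDVH":
        """Scale the dose axis by ``alpha`` (grid stays uniform; bin scales)."""
        if alpha <= 0:
            raise DomainError("dose-axis scale factor must be positive")
        return CumulativeDVH(self.dose_gy * alpha, self.volume_fraction.copy())

    @property
    def bin_width(self) -> float:
        return float(self.dose_gy[1] - self.dose_gy[0])

    # ------------------------------------------------------------------ #
    # metrics (methods delegate to the module-level functions)

    def d_at_volume(self, n: float) -> float:
        return d_at_volume(self, n)

    def v_at_dose(self, x: float) -> float:
        return v_at_dose(self, x)

    def mean_dose(self) -> float:
        return mean_dose(self)

    def max_dose(self) -> float:
        return max_dose(self)

    def inverse_survival(self, u: np.ndarray) -> np.ndarray:
        """Vectorized inverse of the survival curve (dose at volume fraction u).

        Equivalent to ``d_at_volume(100*u)`` elementwise; used for
        inverse-CDF sampling of organ doses.
        """
        u = np.asarray(u, dtype=float)
        s_rev = self.volume_fraction[::-1]
        d_rev = self.dose_gy[::-1]
        # np.interp needs non-decreasing x; duplicates (flat survival
        # segments) are measure-zero for continuous u.
        return np.interp(u, s_rev, d_rev, left=d_rev[0], right=d_rev[-1])


@dataclass
class PlanQuality:
    """HI / CI pair for one planning target volume."""

    structure: str
    hi: float
    ci_percent: float


def _uniform_grid(max_dose: float, bin_width: float) -> np.ndarray:
    if bin_width <= 0:
        raise DomainError("bin width must be positive")
    n = max(int(np.ceil(max_dose / bin_width)), 1)
    return np.arange(n + 1) * bin_width


# ---------------------------------------------------------------------- #
# scalar metrics


def d_at_volume(dvh: CumulativeDVH, n: float) -> float:
    """Dn%: largest dose received by at least n% of the volume (interpolated)."""
    if not (0 < n <= 100):
        raise DomainError(f"n must be in (0, 100], got {n}")
    v = n / 100.0
    s, d = dvh.volume_fraction, dvh.dose_gy
    idx = np.nonzero(s >= v)[0]
    if idx.size == 0:  # only possible for v == 1 with s[0] slightly < 1
        return 0.0
    i = int(idx[-1])
    if s[i] == v:
        # flat run at exactly v: the largest qualifying dose is the run's end
        return float(d[i])
    if i == s.size - 1:
        return float(d[-1])
    # linear interpolation across the crossing
    return float(d[i] + (d[i + 1] - d[i]) * (s[i] - v) / (s[i] - s[i + 1]))


def v_at_dose(dvh: CumulativeDVH, x: float) -> float:
    """VxGy: interpolated volume fraction receiving at least ``x`` Gy."""
    if x < 0:
        raise DomainError(f"dose must be non-negative, got {x}")
    return float(np.interp(x, dvh.dose_gy, dvh.volume_fraction,
                           left=1.0, right=dvh.volume_fraction[-1]))


def mean_dose(dvh: CumulativeDVH) -> float:
    """Mean dose: trapezoidal integral of the survival curve over dose."""
    return float(np.trapezoid(dvh.volume_fraction, dvh.dose_gy))


def max_dose(dvh: CumulativeDVH) -> float:
    """Highest grid dose still covering a non-negligible volume fraction."""
    idx = np.nonzero(dvh.volume_fraction > _MAX_DOSE_TOL)[0]
    return float(dvh.dose_gy[int(idx[-1])]) if idx.size else 0.0


def homogeneity_index(dvh: CumulativeDVH) -> float:
    """HI = D5% / D95%; 1 means perfectly uniform target dose."""
    d95 = d_at_volume(dvh, 95)
    if d95 <= 0:
        raise UndefinedMetricError("HI undefined: D95% is zero")
    return d_at_volume(dvh, 5) / d95


def conformity_index(volume_95_isodose: float, ptv_volume: float) -> float:
    """CI in percent: 100 x (tissue volume inside 95% isodose) / (PTV volume)."""
    if volume_95_isodose <= 0 or ptv_volume <= 0:
        raise DomainError("volumes must be positive")
    return 100.0 * volume_95_isodose / ptv_volume


# ---------------------------------------------------------------------- #
# CSV I/O — dialect: header `organ,dose_gy,volume_fraction`


def write_dvh_csv(dvhs: dict[str, CumulativeDVH], path: str | Path) -> None:
    """Write a map organ -> DVH as a long-format CSV (full float precision)."""
    frames = [
        pd.DataFrame(
            {"organ": name, "dose_gy": d.dose_gy, "volume_fraction": d.volume_fraction}
        )
        for name, d in dvhs.items()
    ]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["organ", "dose_gy", "volume_fraction"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_dvh_csv(path: str | Path) -> dict[str, CumulativeDVH]:
    """Read a map organ -> DVH, rejecting invariant violations with row numbers."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse DVH CSV {path}: {exc}") from exc
    expected = ["organ", "dose_gy", "volume_fraction"]
    if list(df.columns[:3]) != expected:
        raise FormatError(
            f"{path}: expected header {expected}, found {list(df.columns)}"
        )
    out: dict[str, CumulativeDVH] = {}
    for organ, grp in df.groupby("organ", sort=False):
        rows = grp.index.to_numpy()
        frac = grp["volume_fraction"].to_numpy(dtype=float)
        rising = np.nonzero(np.diff(frac) > 1e-12)[0]
        if rising.size:
            row = int(rows[rising[0] + 1]) + 2  # 1-based, plus header line
            raise FormatError(
                f"{path}: volume_fraction rises at row {row} (organ {organ!r})"
            )
        try:
            out[str(organ)] = CumulativeDVH(grp["dose_gy"].to_numpy(dtype=float), frac)
        except ValidationError as exc:
            raise FormatError(f"{path}: organ {organ!r}: {exc}") from exc
    return out
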