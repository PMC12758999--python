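"""OSL dosimeter calibration and count-to-dose conversion.

An optically stimulated luminescence (OSL) chip reports a photon count that
is, to good approximation, proportional to absorbed dose.  Each imaging or
treatment modality (planning CT, CBCT, megavoltage RT) gets its own
calibration curve built from replicate readings at known delivered doses; the
calibration factor is the mean of the per-point dose/count ratios, with the
spread of those ratios carried as the factor's relative uncertainty.  A
slope-through-origin alternative is available for comparison with graphical
calibration curves.

Converted doses are corrected multiplicatively for beam quality, linearity,
incidence angle and signal fading, and a measurement uncertainty budget can
be combined either in quadrature or by Monte-Carlo propagation of the
multiplicative error model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .units import DoseValue

Modality = Literal["planning_ct", "cbct", "rt"]
MODALITIES = ("planning_ct", "cbct", "rt")

#: Reader sensitivity floor: readings below this are indistinguishable from zero.
READER_SENSITIVITY = DoseValue(0.7, "mGy")


class ReplicateStats(NamedTuple):
    mean: float
    sd: float
    cv: float


@dataclass(frozen=True)
class CalibrationPoint:
    """Replicate-summarised counts at one known delivered dose."""

    delivered_dose: DoseValue
    count_mean: float
    count_sd: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not (self.count_mean > 0):
            raise ValidationError("count_mean must be positive")
        if self.count_sd < 0:
            raise ValidationError("count_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if not (0 <= self.cv < 1):
            raise ValidationError(f"replicate CV {self.cv:.3f} outside [0, 1)")

    @property
    def cv(self) -> float:
        return self.count_sd / self.count_mean

    @property
    def ratio_cgy_per_count(self) -> float:
        return self.delivered_dose.cgy / self.count_mean


@dataclass(frozen=True)
class CorrectionFactors:
    """Multiplicative dose corrections; 1.0 means no correction."""

    beam_quality: float = 1.0
    linearity: float = 1.0
    angle: float = 1.0
    fading: float = 1.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not (v > 0):
                raise ValidationError(f"correction factor {name} must be positive")

    @property
    def product(self) -> float:
        return self.beam_quality * self.linearity * self.angle * self.fading


@dataclass(frozen=True)
class CalibrationCurve:
    modality: str
    factor_cgy_per_count: float
    corrections: CorrectionFactors = field(default_factory=CorrectionFactors)
    factor_uncertainty: float = 0.0  # relative sd of the per-point ratios
    points: tuple[CalibrationPoint, ...] = ()

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}; expected {MODALITIES}")
        if not (self.factor_cgy_per_count > 0):
            raise ValidationError("calibration factor must be positive")
        if self.factor_uncertainty < 0:
            raise ValidationError("factor uncertainty must be nonnegative")

    @property
    def inverse_counts_per_cgy(self) -> float:
        return 1.0 / self.factor_cgy_per_count

    def to_json(self, path: str | Path) -> None:
        payload = {
            "modality": self.modality,
            "factor_cgy_per_count": self.factor_cgy_per_count,
            "inverse_counts_per_cgy": self.inverse_counts_per_cgy,
            "corrections": asdict(self.corrections),
            "factor_uncertainty": self.factor_uncertainty,
            "points": [
                {
                    "delivered_dose_cgy": p.delivered_dose.cgy,
                    "count_mean": p.count_mean,
                    "count_sd": p.count_sd,
                    "n_replicates": p.n_replicates,
                }
                for p in self.points
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        d = json.loads(Path(path).read_text())
        return cls(
            modality=d["modality"],
            factor_cgy_per_count=d["factor_cgy_per_count"],
            corrections=CorrectionFactors(**d.get("corrections", {})),
            factor_uncertainty=d.get("factor_uncertainty", 0.0),
            points=tuple(
                CalibrationPoint(
                    DoseValue(p["delivered_dose_cgy"], "cGy"),
                    p["count_mean"],
                    p.get("count_sd", 0.0),
                    p.get("n_replicates", 1),
                )
                for p in d.get("points", ())
            ),
        )


@dataclass(frozen=True)
class OSLReading:
    """One raw reader output, optionally background-corrected."""

    raw_counts: float
    background_counts: float = 0.0
    modality: str = "planning_ct"
    dosimeter_id: str = ""

    def __post_init__(self) -> None:
        if self.background_counts < 0 or self.raw_counts < self.background_counts:
            raise ValidationError("need raw_counts >= background_counts >= 0")

    @property
    def net_counts(self) -> float:
        return self.raw_counts - self.background_counts


@dataclass(frozen=True)
class UncertaintyBudget:
    components: tuple[tuple[str, float], ...]
    method: str
    combined_relative_sd: float

    def as_frame(self) -> pd.DataFrame:
        rows = list(self.components) + [("combined", self.combined_relative_sd)]
        return pd.DataFrame(rows, columns=["component", "relative_sd"])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------
def replicate_stats(counts: Sequence[float]) -> ReplicateStats:
    """Mean, sample SD (n-1 denominator; 0 for a single value) and CV of replicates."""
    if len(counts) == 0:
        raise ValidationError("need at least one replicate count")
    arr = np.asarray(counts, dtype=float)
    if np.any(arr <= 0):
        raise ValidationError("replicate counts must be positive")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return ReplicateStats(mean, sd, sd / mean)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV = sd / mean for already-summarised replicate statistics."""
    if mean <= 0:
        raise ValidationError("mean must be positive")
    if sd < 0:
        raise ValidationError("sd must be nonnegative")
    return sd / mean


def build_calibration(
    points: Sequence[CalibrationPoint],
    modality: str,
    corrections: CorrectionFactors | None = None,
    method: Literal["ratio_mean", "slope_origin"] = "ratio_mean",
) -> CalibrationCurve:
    """Build a modality calibration curve from dose/count points.

    ``ratio_mean`` (default) averages the per-point dose/count ratios;
    ``slope_origin`` is the least-squares slope of dose on counts through the
    origin, which weights high-count points more heavily.
    """
    if len(points) == 0:
        raise ValidationError("need at least one calibration point")
    if any(p.delivered_dose.cgy <= 0 for p in points):
        raise ValidationError("calibration doses must be positive")
    ratios = np.array([p.ratio_cgy_per_count for p in points])
    if method == "ratio_mean":
        factor = float(ratios.mean())
        rel_u = float(ratios.std(ddof=1) / factor) if len(points) > 1 else 0.0
    elif method == "slope_origin":
        c = np.array([p.count_mean for p in points])
        d = np.array([p.delivered_dose.cgy for p in points])
        factor = float(np.dot(c, d) / np.dot(c, c))
        rel_u = float(ratios.std(ddof=1) / factor) if len(points) > 1 else 0.0
    else:
        raise ConfigurationError(f"unknown calibration method {method!r}")
    return CalibrationCurve(
        modality=modality,
        factor_cgy_per_count=factor,
        corrections=corrections or CorrectionFactors(),
        factor_uncertainty=rel_u,
        points=tuple(points),
    )


def counts_to_dose(reading: OSLReading, curve: CalibrationCurve) -> DoseValue:
    """Convert a background-corrected reading to absorbed dose (cGy).

    dose = (raw - background) * factor * beam_quality * linearity * angle * fading
    """
    if reading.modality != curve.modality:
        raise ConfigurationError(
            f"reading modality {reading.modality!r} does not match "
            f"curve modality {curve.modality!r}"
        )
    dose_cgy = reading.net_counts * curve.factor_cgy_per_count * curve.corrections.product
    return DoseValue(dose_cgy, "cGy")


def dose_to_counts(dose: DoseValue, curve: CalibrationCurve) -> float:
    """Expected net counts for a given absorbed dose (inverse of counts_to_dose)."""
    return dose.cgy / (curve.factor_cgy_per_count * curve.corrections.product)


def propagate_uncertainty(
    components: Sequence[tuple[str, float]],
    method: Literal["quadrature", "monte_carlo"] = "quadrature",
    n_draws: int = 100_000,
    seed: int = 20260102,
) -> UncertaintyBudget:
    """Combine independent relative uncertainties of a multiplicative model.

    ``quadrature``: sqrt(sum s_k**2) — exact for small relative SDs.
    ``monte_carlo``: empirical relative SD of the product of independently
    perturbed factors (1 + eps_k), eps_k ~ N(0, s_k), over a seeded run;
    robust to larger components where the linearised quadrature rule starts
    to bias low.
    """
    comps = tuple((str(name), float(s)) for name, s in components)
    if any(s < 0 for _, s in comps):
        raise ValidationError("relative uncertainties must be nonnegative")
    if method == "quadrature":
        combined = math.sqrt(sum(s * s for _, s in comps))
    elif method == "monte_carlo":
        if len(comps) == 1:
            combined = comps[0][1]  # single factor: relative sd is exact
        else:
            rng = np.random.default_rng(seed)
            product = np.ones(int(n_draws))
            for _, s in comps:
                product *= 1.0 + rng.normal(0.0, s, size=int(n_draws))
            combined = float(product.std(ddof=1) / product.mean())
    else:
        raise ConfigurationError(f"unknown uncertainty method {method!r}")
    return UncertaintyBudget(comps, method, combined)


def zero_check(
    readings: Iterable[OSLReading],
    threshold_counts: float | None = None,
    curve: CalibrationCurve | None = None,
) -> list[bool]:
    """Verify bleaching: True means the residual signal is at or below threshold.

    The default threshold is the reader sensitivity (0.7 mGy) expressed in
    counts through the active calibration curve; the boundary is inclusive
    (a reading exactly at threshold passes).
    """
    if threshold_counts is None:
        if curve is None:
            raise ConfigurationError(
                "zero_check needs an explicit threshold_counts or a curve to "
                "convert the reader sensitivity into counts"
            )
        threshold_counts = dose_to_counts(READER_SENSITIVITY, curve)
    if not (threshold_counts > 0):
        raise ValidationError("threshold_counts must be positive")
    return [r.net_counts <= threshold_counts for r in readings]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
def read_calibration_csv(path: str | Path) -> dict[str, list[CalibrationPoint]]:
    """Read points from ``modality,delivered_dose_cgy,count_mean,count_sd,n_replicates``."""
    df = pd.read_csv(path)
    required = {"modality", "delivered_dose_cgy", "count_mean"}
    if not required.issubset(df.columns):
        raise ValidationError(f"calibration CSV must have columns {sorted(required)}")
    out: dict[str, list[CalibrationPoint]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.modality), []).append(
            CalibrationPoint(
                DoseValue(float(row.delivered_dose_cgy), "cGy"),
                float(row.count_mean),
                float(getattr(row, "count_sd", 0.0) or 0.0),
                int(getattr(row, "n_replicates", 1) or 1),
            )
        )
    return out


def read_readings_csv(path: str | Path) -> list[OSLReading]:
    """Read readings from ``dosimeter_id,modality,raw_counts,background_counts``."""
    df = pd.read_csv(path)
    required = {"dosimeter_id", "modality", "raw_counts"}
    if not required.issubset(df.columns):
        raise ValidationError(f"readings CSV must have columns {sorted(required)}")
    return [
        OSLReading(
            raw_counts=float(row.raw_counts),
            background_counts=float(getattr(row, "background_counts", 0.0) or 0.0),
            modality=str(row.modality),
            dosimeter_id=str(row.dosimeter_id),
        )
        for row in df.itertuples(index=False)
    ]
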