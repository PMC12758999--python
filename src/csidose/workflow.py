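"""Per-organ dose ledger across the radiotherapy pathway.

A pediatric craniospinal course exposes every organ three ways: once at the
planning CT, once per CBCT positioning scan (typically daily, ~15 over the
course), and during treatment delivery itself.  This module accumulates the
imaging part organ by organ, expresses it relative to the prescription
(craniospinal dose, and total with posterior-fossa boost), and tabulates
per-technique plan EUD/NTCP matrices so that delivery techniques can be
compared side by side.

Per-acquisition CBCT uncertainties are treated as independent and combined
in quadrature (scaling with sqrt(n), not n).  All report-time rounding —
imaging totals to whole mGy, percents to two decimals — happens only in the
rendering helpers; full precision is kept internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .radiobiology import EUDResult, NTCPResult, OrganNTCPParams, PlanMetrics, compute_ntcp
from .units import DoseValue, as_dose

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrganImagingDose:
    """Measured absorbed dose to one organ: one planning CT + one CBCT acquisition."""

    organ: str
    ct_dose: DoseValue
    cbct_dose_per_acq: DoseValue
    ct_uncertainty: DoseValue = DoseValue(0.0, "mGy")
    cbct_uncertainty: DoseValue = DoseValue(0.0, "mGy")
    n_osl_positions: int = 1

    def __post_init__(self) -> None:
        if self.n_osl_positions < 1:
            raise ValidationError("n_osl_positions must be >= 1")


@dataclass(frozen=True)
class Prescription:
    """Prescribed therapeutic dose: craniospinal course plus tumour-bed boost."""

    craniospinal_dose: DoseValue = DoseValue(36.0, "Gy")
    craniospinal_fractions: int = 20
    boost_dose: DoseValue = DoseValue(18.0, "Gy")
    boost_fractions: int = 10

    def __post_init__(self) -> None:
        if self.craniospinal_dose.gy <= 0 or self.boost_dose.gy < 0:
            raise ValidationError("prescription doses must be positive")
        if self.craniospinal_fractions < 1 or self.boost_fractions < 0:
            raise ValidationError("fraction counts must be positive")

    @property
    def total_with_boost(self) -> DoseValue:
        return DoseValue(self.craniospinal_dose.gy + self.boost_dose.gy, "Gy")


@dataclass(frozen=True)
class WorkflowExposure:
    """One organ's row in the pathway ledger (imaging totals and relative shares)."""

    organ: str
    imaging_total: DoseValue
    imaging_uncertainty: DoseValue
    cbct_only_total: DoseValue
    n_cbct: int
    relative_to_prescription: float  # percent of the craniospinal prescription
    relative_to_total_with_boost: float  # percent of prescription + boost
    plan_doses: Mapping[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------
def cumulative_imaging_dose(
    organ_dose: OrganImagingDose, n_cbct: int, include_ct: bool = True
) -> tuple[DoseValue, DoseValue]:
    """Total imaging dose (and its uncertainty) for one organ.

    total = [CT] + n * CBCT-per-acquisition; the CBCT repeats are independent
    acquisitions, so their uncertainties add in quadrature:
    u = sqrt(u_ct**2 + n * u_cbct**2).
    """
    if n_cbct < 0:
        raise ValidationError("n_cbct must be nonnegative")
    ct = organ_dose.ct_dose.mgy if include_ct else 0.0
    u_ct = organ_dose.ct_uncertainty.mgy if include_ct else 0.0
    total = ct + n_cbct * organ_dose.cbct_dose_per_acq.mgy
    u = math.sqrt(u_ct**2 + n_cbct * organ_dose.cbct_uncertainty.mgy ** 2)
    return DoseValue(total, "mGy"), DoseValue(u, "mGy")


def relative_dose(dose: DoseValue | float, reference: DoseValue | float) -> float:
    """Percent share of *dose* relative to *reference* after exact unit reconciliation."""
    dose = as_dose(dose, "Gy")
    ref = as_dose(reference, "Gy")
    if ref.gy <= 0:
        raise ValidationError("reference dose must be positive")
    return 100.0 * dose.gy / ref.gy


def build_exposure_report(
    table: Sequence[OrganImagingDose],
    prescription: Prescription,
    n_cbct: int,
    plans: Mapping[str, Mapping[str, object]] | None = None,
) -> list[WorkflowExposure]:
    """One ledger row per organ: imaging totals plus percent-of-prescription columns.

    ``plans`` optionally maps technique -> organ -> PlanMetrics/EUDResult; organs
    missing from a plan get an explicit None cell, never a zero.
    """
    seen: set[str] = set()
    rows: list[WorkflowExposure] = []
    plans = plans or {}
    for od in table:
        if od.organ in seen:
            raise ValidationError(f"duplicate organ {od.organ!r} in dose table")
        seen.add(od.organ)
        total, u = cumulative_imaging_dose(od, n_cbct, include_ct=True)
        cbct_only, _ = cumulative_imaging_dose(od, n_cbct, include_ct=False)
        rows.append(
            WorkflowExposure(
                organ=od.organ,
                imaging_total=total,
                imaging_uncertainty=u,
                cbct_only_total=cbct_only,
                n_cbct=n_cbct,
                relative_to_prescription=relative_dose(total, prescription.craniospinal_dose),
                relative_to_total_with_boost=relative_dose(total, prescription.total_with_boost),
                plan_doses={t: per_organ.get(od.organ) for t, per_organ in plans.items()},
            )
        )
    return rows


def exposure_aggregate(rows: Sequence[WorkflowExposure]) -> dict[str, object]:
    """Min/max summary across organs (CBCT-only totals and percent shares)."""
    if not rows:
        raise ValidationError("empty exposure report")
    by_cbct = sorted(rows, key=lambda r: r.cbct_only_total.mgy)
    by_pct = sorted(rows, key=lambda r: r.relative_to_prescription)
    return {
        "min_cbct_only_organ": by_cbct[0].organ,
        "min_cbct_only_mgy": by_cbct[0].cbct_only_total.mgy,
        "max_cbct_only_organ": by_cbct[-1].organ,
        "max_cbct_only_mgy": by_cbct[-1].cbct_only_total.mgy,
        "min_percent_of_prescription": by_pct[0].relative_to_prescription,
        "max_percent_of_prescription": by_pct[-1].relative_to_prescription,
        "max_percent_organ": by_pct[-1].organ,
    }


def exposure_frame(rows: Sequence[WorkflowExposure], rounded: bool = False) -> pd.DataFrame:
    """Tabular view of the ledger; ``rounded`` applies report-time rounding
    (whole mGy, two-decimal percents) and logs each rounding applied."""
    recs = []
    for r in rows:
        rec = {
            "organ": r.organ,
            "imaging_total_mgy": r.imaging_total.mgy,
            "imaging_uncertainty_mgy": r.imaging_uncertainty.mgy,
            "cbct_only_total_mgy": r.cbct_only_total.mgy,
            "n_cbct": r.n_cbct,
            "pct_of_prescription": r.relative_to_prescription,
            "pct_of_total_with_boost": r.relative_to_total_with_boost,
        }
        recs.append(rec)
    df = pd.DataFrame(recs)
    if rounded:
        for col in ("imaging_total_mgy", "imaging_uncertainty_mgy", "cbct_only_total_mgy"):
            df[col] = df[col].round(0)
        for col in ("pct_of_prescription", "pct_of_total_with_boost"):
            df[col] = df[col].round(2)
        logger.info("report rounding applied: mGy columns to integers, percents to 2 decimals")
    return df


# ---------------------------------------------------------------------------
# technique comparison
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class TechniqueComparison:
    """Organ x technique EUD and NTCP matrices with deltas vs a reference technique."""

    eud_gy: pd.DataFrame  # index organ, columns technique
    ntcp_pct: pd.DataFrame
    reference: str
    delta_eud_gy: pd.DataFrame  # technique minus reference
    ratio_eud: pd.DataFrame
    missing: tuple[tuple[str, str], ...] = ()  # (organ, technique) cells with no data

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: ``organ,technique,metric,value``."""
        frames = []
        for metric, df in (("eud_gy", self.eud_gy), ("ntcp_pct", self.ntcp_pct)):
            long = df.reset_index().melt(id_vars="organ", var_name="technique", value_name="value")
            long["metric"] = metric
            frames.append(long[["organ", "technique", "metric", "value"]])
        return pd.concat(frames, ignore_index=True)


def compare_techniques(
    plans: Mapping[str, Mapping[str, DoseValue | float | EUDResult]],
    params: Mapping[str, OrganNTCPParams],
    reference: str | None = None,
) -> TechniqueComparison:
    """Build EUD (Gy) and NTCP (%) matrices across treatment techniques.

    ``plans`` maps technique -> organ -> EUD; organs without NTCP parameters
    get NaN in the NTCP matrix, and organs absent from a technique are
    reported in ``missing`` and rendered as NaN, never silently zeroed.
    """
    if not plans:
        raise ValidationError("need at least one technique to compare")
    techniques = list(plans)
    reference = reference or techniques[0]
    if reference not in plans:
        raise ValidationError(f"reference technique {reference!r} not among {techniques}")
    organs: list[str] = []
    for per_organ in plans.values():
        for o in per_organ:
            if o not in organs:
                organs.append(o)
    eud = pd.DataFrame(index=pd.Index(organs, name="organ"), columns=techniques, dtype=float)
    ntcp = eud.copy()
    missing: list[tuple[str, str]] = []
    for t in techniques:
        for o in organs:
            val = plans[t].get(o)
            if val is None:
                missing.append((o, t))
                continue
            if isinstance(val, EUDResult):
                e = val.eud.gy
            else:
                e = as_dose(val, "Gy").gy
            eud.loc[o, t] = e
            if o in params:
                ntcp.loc[o, t] = compute_ntcp(DoseValue(e, "Gy"), params[o]).percent
    if missing:
        logger.warning("missing EUD cells (organ, technique): %s", missing)
    delta = eud.sub(eud[reference], axis=0)
    ratio = eud.div(eud[reference], axis=0)
    return TechniqueComparison(eud, ntcp, reference, delta, ratio, tuple(missing))


def ntcp_from_plans(
    plans: Mapping[str, Mapping[str, DoseValue | float | EUDResult]],
    params: Mapping[str, OrganNTCPParams],
) -> dict[str, dict[str, NTCPResult]]:
    """Full NTCP results (not just the matrix) per technique and organ."""
    out: dict[str, dict[str, NTCPResult]] = {}
    for t, per_organ in plans.items():
        out[t] = {}
        for o, val in per_organ.items():
            if o not in params or val is None:
                continue
            e = val.eud if isinstance(val, EUDResult) else as_dose(val, "Gy")
            out[t][o] = compute_ntcp(e, params[o])
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------
def read_organ_dose_csv(path: str | Path) -> list[OrganImagingDose]:
    """Read ``organ,n_osl,ct_dose_mgy,ct_u_mgy,cbct_dose_mgy,cbct_u_mgy``."""
    df = pd.read_csv(path)
    required = {"organ", "ct_dose_mgy", "cbct_dose_mgy"}
    if not required.issubset(df.columns):
        raise ValidationError(f"organ dose CSV must have columns {sorted(required)}")
    rows = [
        OrganImagingDose(
            organ=str(r.organ),
            ct_dose=DoseValue(float(r.ct_dose_mgy), "mGy"),
            cbct_dose_per_acq=DoseValue(float(r.cbct_dose_mgy), "mGy"),
            ct_uncertainty=DoseValue(float(getattr(r, "ct_u_mgy", 0.0) or 0.0), "mGy"),
            cbct_uncertainty=DoseValue(float(getattr(r, "cbct_u_mgy", 0.0) or 0.0), "mGy"),
            n_osl_positions=int(getattr(r, "n_osl", 1) or 1),
        )
        for r in df.itertuples(index=False)
    ]
    if len({r.organ for r in rows}) != len(rows):
        raise ValidationError("duplicate organ labels in dose table")
    return rows


def write_organ_dose_csv(rows: Sequence[OrganImagingDose], path: str | Path) -> None:
    pd.DataFrame(
        {
            "organ": [r.organ for r in rows],
            "n_osl": [r.n_osl_positions for r in rows],
            "ct_dose_mgy": [r.ct_dose.mgy for r in rows],
            "ct_u_mgy": [r.ct_uncertainty.mgy for r in rows],
            "cbct_dose_mgy": [r.cbct_dose_per_acq.mgy for r in rows],
            "cbct_u_mgy": [r.cbct_uncertainty.mgy for r in rows],
        }
    ).to_csv(path, index=False)


def reference_imaging_doses() -> list[OrganImagingDose]:
    """The bundled phantom-measured organ dose table (planning CT + single CBCT)."""
    from importlib.resources import files

    with files("csidose").joinpath("data/imaging_organ_doses.csv").open("r") as fh:  # type: ignore[union-attr]
        import io

        return read_organ_dose_csv(io.StringIO(fh.read()))
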