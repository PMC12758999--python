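"""Dose-volume histograms, equivalent uniform dose and NTCP.

The biological core of the package.  A heterogeneous organ dose distribution,
summarised as a dose-volume histogram (DVH), is reduced to a single
generalised-mean dose following Niemierko:

    EUD = (sum_i v_i * D_i ** a) ** (1 / a)

where ``v_i`` is the fractional organ volume in dose bin ``D_i`` and ``a`` is
a tissue-specific volume-effect exponent (a = 1: parallel organ, mean dose;
a >> 1: serial organ, maximum-dose driven).  The complication probability is
the logistic sigmoid in log dose

    NTCP = 1 / (1 + (D50 / EUD) ** (4 * gamma50))

with ``D50`` the tolerance dose for a 50% complication rate and ``gamma50``
the normalised slope at that point.  ``fit_ntcp_params`` inverts the sigmoid
from observed (EUD, NTCP) pairs — exactly for two pairs, by logit-scale least
squares otherwise — which is how published NTCP figures can be checked for
self-consistency when the underlying (D50, gamma50) are not reported.

Internally every dose is carried in Gy; the I/O helpers convert on ingest.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, InconsistencyError, ValidationError
from .units import DoseValue, as_dose

logger = logging.getLogger(__name__)

DVHForm = Literal["differential", "cumulative"]

_NORM_TOL = 1e-9


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class DVH:
    """Per-organ dose-volume histogram.

    ``differential`` form: ``volume[i]`` is the fractional organ volume whose
    dose falls in the bin centred at ``dose_gy[i]``; fractions sum to 1.
    ``cumulative`` form: ``volume[i]`` is the fractional volume receiving at
    least ``dose_gy[i]``; non-increasing, starting at 1.
    Bin doses are strictly increasing in both forms.
    """

    organ: str
    dose_gy: np.ndarray
    volume: np.ndarray
    form: DVHForm = "differential"

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_gy, dtype=float)
        v = np.asarray(self.volume, dtype=float)
        object.__setattr__(self, "dose_gy", d)
        object.__setattr__(self, "volume", v)
        if d.ndim != 1 or v.shape != d.shape or d.size == 0:
            raise ValidationError("DVH needs matching 1-D, non-empty dose and volume arrays")
        if np.any(d < 0):
            raise ValidationError("DVH bin doses must be nonnegative")
        if np.any(np.diff(d) <= 0):
            raise ValidationError("DVH bin doses must be strictly increasing")
        if np.any(v < -_NORM_TOL) or np.any(v > 1 + _NORM_TOL):
            raise ValidationError("DVH volume fractions must lie in [0, 1]")
        if self.form == "differential":
            total = float(v.sum())
            if abs(total - 1.0) > _NORM_TOL:
                raise ValidationError(
                    f"differential DVH volume fractions must sum to 1 (got {total!r})"
                )
        elif self.form == "cumulative":
            if np.any(np.diff(v) > _NORM_TOL):
                raise ValidationError("cumulative DVH volume must be non-increasing in dose")
            if abs(float(v[0]) - 1.0) > _NORM_TOL:
                raise ValidationError("cumulative DVH must start at volume fraction 1")
        else:
            raise ValidationError(f"unknown DVH form {self.form!r}")

    @classmethod
    def from_bins(
        cls,
        organ: str,
        bins: Iterable[tuple[float, float]],
        form: DVHForm = "differential",
        unit: str = "Gy",
    ) -> "DVH":
        """Build from (dose, volume_fraction) pairs; doses interpreted in *unit*."""
        doses, vols = zip(*bins)
        dose_gy = [as_dose(d, unit).gy if not isinstance(d, DoseValue) else d.gy for d in doses]
        return cls(organ, np.asarray(dose_gy), np.asarray(vols, dtype=float), form)


@dataclass(frozen=True)
class OrganNTCPParams:
    """Radiobiological parameter triple (a, D50, gamma50) for one organ/endpoint."""

    organ: str
    a: float
    d50: DoseValue
    gamma50: float
    endpoint: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValidationError("volume-effect exponent a must be nonzero")
        if not (self.d50.gy > 0):
            raise ValidationError("D50 must be positive")
        if not (self.gamma50 > 0):
            raise ValidationError("gamma50 must be positive")


@dataclass(frozen=True)
class EUDResult:
    organ: str
    eud: DoseValue
    a_used: float


@dataclass(frozen=True)
class NTCPResult:
    organ: str
    ntcp: float
    eud: DoseValue
    params_used: OrganNTCPParams

    @property
    def percent(self) -> float:
        return 100.0 * self.ntcp


@dataclass(frozen=True)
class PlanMetrics:
    """Summary plan-quality metrics for one organ: Dmax, Dmean and Vx columns."""

    organ: str
    dmax: DoseValue
    dmean: DoseValue
    vx: Mapping[float, float] = field(default_factory=dict)  # threshold Gy -> % volume


# ---------------------------------------------------------------------------
# DVH manipulation
# ---------------------------------------------------------------------------
def convert_dvh(dvh: DVH, target_form: DVHForm) -> DVH:
    """Convert between differential and cumulative forms on shared bin doses.

    Cumulative volume at bin i is the differential volume at or above bin i,
    so the conversion is an exclusive suffix sum / first difference and is
    lossless: a round trip reproduces the input to floating-point accuracy.
    """
    if target_form not in ("differential", "cumulative"):
        raise ValidationError(f"unknown DVH form {target_form!r}")
    if dvh.form == target_form:
        return dvh
    if target_form == "cumulative":
        cum = np.cumsum(dvh.volume[::-1])[::-1]
        return DVH(dvh.organ, dvh.dose_gy, cum, "cumulative")
    diff = np.empty_like(dvh.volume)
    diff[:-1] = dvh.volume[:-1] - dvh.volume[1:]
    diff[-1] = dvh.volume[-1]
    # clip -0.0 / tiny negatives from cancellation before revalidation
    diff[np.abs(diff) < _NORM_TOL] = np.abs(diff[np.abs(diff) < _NORM_TOL])
    return DVH(dvh.organ, dvh.dose_gy, diff, "differential")


def compute_eud(dvh: DVH, a: float) -> EUDResult:
    """Generalised-mean (Niemierko) equivalent uniform dose of a DVH.

    Accepts either DVH form (cumulative input is converted first).  For
    ``a = 1`` this is exactly the mean dose; the result always lies between
    the lowest and highest occupied dose bin.
    """
    if a == 0:
        raise ValidationError("EUD exponent a must be nonzero (a=0 is undefined)")
    diff = convert_dvh(dvh, "differential")
    occupied = diff.volume > 0
    d, v = diff.dose_gy[occupied], diff.volume[occupied]
    if a < 0 and np.any(d == 0):
        raise DomainError(
            "EUD with a < 0 diverges on zero-dose bins: D**a is unbounded at D=0; "
            "strip or floor zero-dose volume first"
        )
    if a == 1:
        eud = float(np.dot(v, d))
    else:
        with np.errstate(over="raise"):
            eud = float(np.dot(v, np.power(d, a)) ** (1.0 / a))
    return EUDResult(dvh.organ, DoseValue(eud, "Gy"), a)


def compute_ntcp(
    eud: DoseValue | float | EUDResult, params: OrganNTCPParams
) -> NTCPResult:
    """Sigmoid complication probability at a given equivalent uniform dose.

    ``NTCP = 1 / (1 + (D50/EUD)**(4*gamma50))``; strictly increasing in EUD,
    exactly 0.5 at EUD = D50.  A zero EUD returns the limit value 0.
    """
    if isinstance(eud, EUDResult):
        eud = eud.eud
    eud = as_dose(eud, "Gy")
    e, d50 = eud.gy, params.d50.gy
    if e == 0.0:
        logger.info("NTCP at zero EUD for %s: returning limit value 0", params.organ)
        ntcp = 0.0
    else:
        # evaluate on the log scale to avoid overflow at extreme dose ratios
        t = 4.0 * params.gamma50 * (math.log(d50) - math.log(e))
        ntcp = 1.0 / (1.0 + math.exp(t)) if t < 700 else 0.0
    return NTCPResult(params.organ, ntcp, eud, params)


def fit_ntcp_params(
    pairs: Sequence[tuple[DoseValue | float, float]],
    organ: str = "",
    a: float = 1.0,
    endpoint: str = "",
) -> OrganNTCPParams:
    """Recover (D50, gamma50) from observed (EUD, NTCP) pairs.

    On the logit scale the sigmoid is linear in log dose:
    ``log((1-N)/N) = 4*gamma50*(log D50 - log EUD)``.  Two pairs give the
    closed-form solution; more pairs are fitted by ordinary least squares on
    that scale.  Back-substitution into :func:`compute_ntcp` reproduces the
    inputs exactly for two pairs.

    The volume-effect exponent ``a`` is not identifiable from (EUD, NTCP)
    pairs and is passed through to the returned parameter set.
    """
    if len(pairs) < 2:
        raise ValidationError("need at least two (EUD, NTCP) pairs")
    euds = np.array([as_dose(e, "Gy").gy for e, _ in pairs])
    ntcps = np.array([float(n) for _, n in pairs])
    if np.any(euds <= 0):
        raise ValidationError("EUDs must be positive to fit the sigmoid")
    if np.any((ntcps <= 0) | (ntcps >= 1)):
        raise DomainError("NTCP values must lie strictly in (0, 1) to be logit-invertible")
    for i in range(len(euds)):
        for j in range(i + 1, len(euds)):
            if euds[i] == euds[j] and ntcps[i] != ntcps[j]:
                raise InconsistencyError(
                    f"identical EUD {euds[i]} Gy mapped to different NTCPs "
                    f"{ntcps[i]} and {ntcps[j]}"
                )
    x = np.log(euds)
    y = np.log((1.0 - ntcps) / ntcps)  # = 4*g*(log d50) - 4*g*x
    if len(pairs) == 2:
        if x[0] == x[1]:
            raise ValidationError("two-point fit needs distinct EUDs")
        slope = (y[1] - y[0]) / (x[1] - x[0])
    else:
        slope, _ = np.polyfit(x, y, 1)
    if slope >= 0:
        raise InconsistencyError("NTCP must increase with EUD; fitted slope is not negative")
    gamma50 = -slope / 4.0
    midpoint = np.isclose(ntcps, 0.5)
    if midpoint.any():
        # a pair at NTCP = 0.5 pins D50 exactly to its EUD
        d50 = float(euds[np.argmax(midpoint)])
    elif len(pairs) == 2:
        d50 = float(np.exp(x[0] + y[0] / (4.0 * gamma50)))
    else:
        intercept = float(np.polyfit(x, y, 1)[1])
        d50 = float(np.exp(intercept / (4.0 * gamma50)))
    return OrganNTCPParams(organ, a, DoseValue(d50, "Gy"), float(gamma50), endpoint,
                           source="fitted from (EUD, NTCP) pairs")


def dvh_metrics(
    dvh: DVH, thresholds: Sequence[DoseValue | float] = ()
) -> PlanMetrics:
    """Dmax, Dmean and Vx plan metrics of a DVH (either form).

    Dmax is the highest dose bin with nonzero volume, Dmean the
    volume-weighted mean, and Vx the percent of organ volume receiving at
    least the threshold dose (inclusive at the boundary).
    """
    diff = convert_dvh(dvh, "differential")
    occupied = diff.volume > 0
    if not occupied.any():
        raise ValidationError("DVH has no occupied bins")
    dmax = float(diff.dose_gy[occupied][-1])
    dmean = float(np.dot(diff.volume, diff.dose_gy))
    vx = {}
    for t in thresholds:
        t_gy = as_dose(t, "Gy").gy
        vx[t_gy] = 100.0 * float(diff.volume[diff.dose_gy >= t_gy].sum())
    return PlanMetrics(dvh.organ, DoseValue(dmax, "Gy"), DoseValue(dmean, "Gy"), vx)


def eqd2_transform(
    dvh: DVH, alpha_beta: DoseValue | float, n_fractions: int
) -> DVH:
    """Linear-quadratic equieffective dose in 2 Gy fractions, bin by bin.

    Each bin dose D (delivered in ``n_fractions`` equal fractions) becomes
    ``D * (D/n + ab) / (2 + ab)``; volume fractions are untouched.  Off by
    default in the pipeline — apply only when plans with different
    fractionation must be compared on a common scale.
    """
    ab = as_dose(alpha_beta, "Gy").gy
    if ab <= 0:
        raise ValidationError("alpha/beta ratio must be positive")
    if n_fractions < 1:
        raise ValidationError("n_fractions must be >= 1")
    diff = convert_dvh(dvh, "differential")
    d = diff.dose_gy
    eqd2 = d * (d / n_fractions + ab) / (2.0 + ab)
    if np.any(np.diff(eqd2) <= 0):  # cannot happen for ab > 0, d increasing
        raise ValidationError("EQD2 transform broke bin ordering")
    out = DVH(diff.organ, eqd2, diff.volume, "differential")
    return convert_dvh(out, dvh.form)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------
def read_dvh_csv(path: str | Path) -> dict[str, DVH]:
    """Read DVHs from the CSV dialect ``organ,dose_gy,volume_fraction,form``.

    One file may hold several organs; each organ's rows must share one form.
    """
    df = pd.read_csv(path)
    required = {"organ", "dose_gy", "volume_fraction", "form"}
    if not required.issubset(df.columns):
        raise ValidationError(f"DVH CSV must have columns {sorted(required)}")
    out: dict[str, DVH] = {}
    for organ, grp in df.groupby("organ", sort=False):
        forms = grp["form"].unique()
        if len(forms) != 1:
            raise ValidationError(f"organ {organ!r} mixes DVH forms {list(forms)}")
        grp = grp.sort_values("dose_gy")
        out[str(organ)] = DVH(
            str(organ),
            grp["dose_gy"].to_numpy(float),
            grp["volume_fraction"].to_numpy(float),
            str(forms[0]),  # type: ignore[arg-type]
        )
    if not out:
        raise ValidationError("DVH CSV contains no rows")
    return out


def write_dvh_csv(dvhs: Iterable[DVH], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "organ": d.organ,
                "dose_gy": d.dose_gy,
                "volume_fraction": d.volume,
                "form": d.form,
            }
        )
        for d in dvhs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_organ_params(path: str | Path) -> dict[str, OrganNTCPParams]:
    """Load per-organ (a, D50, gamma50) parameters from a YAML or JSON list.

    Each entry: ``{organ, a, d50_gy, gamma50, endpoint, source}``.
    """
    text = Path(path).read_text()
    entries = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(entries, list):
        raise ValidationError("organ parameter file must contain a list of entries")
    out: dict[str, OrganNTCPParams] = {}
    for e in entries:
        organ = str(e["organ"])
        if organ in out:
            raise ValidationError(f"duplicate organ {organ!r} in parameter file")
        out[organ] = OrganNTCPParams(
            organ=organ,
            a=float(e["a"]),
            d50=DoseValue(float(e["d50_gy"]), "Gy"),
            gamma50=float(e["gamma50"]),
            endpoint=str(e.get("endpoint", "")),
            source=str(e.get("source", "")),
        )
    return out


def default_organ_params() -> dict[str, OrganNTCPParams]:
    """Bundled literature parameter set (see ``data/ntcp_params.yaml``)."""
    from importlib.resources import files

    return load_organ_params(files("csidose").joinpath("data/ntcp_params.yaml"))  # type: ignore[arg-type]
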