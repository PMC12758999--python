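"""End-to-end run: calibration -> dose accounting -> EUD/NTCP -> comparison.

`run_full_pipeline` takes a single YAML-serialisable configuration pointing
at the input files, executes every stage of the analysis, and writes a
report bundle (CSV + JSON) plus a manifest that records all inputs (with
SHA-256 digests), parameters and the seed, so a run can be reproduced from
the manifest alone.  On any stage failure the partially written bundle is
removed: outputs are staged in a temporary directory and moved into place
only after every stage succeeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .calibration import build_calibration, read_calibration_csv
from .errors import CsidoseError, ValidationError
from .radiobiology import (
    compute_eud,
    default_organ_params,
    eqd2_transform,
    load_organ_params,
    read_dvh_csv,
)
from .units import DoseValue
from .workflow import (
    Prescription,
    build_exposure_report,
    compare_techniques,
    exposure_aggregate,
    exposure_frame,
    read_organ_dose_csv,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full analysis run (YAML-loadable)."""

    organ_dose_csv: str
    dvh_csvs: Mapping[str, str] = field(default_factory=dict)  # technique -> path
    calibration_csv: str | None = None
    params_file: str | None = None
    output_dir: str = "csidose_out"
    n_cbct: int = 15
    craniospinal_gy: float = 36.0
    craniospinal_fractions: int = 20
    boost_gy: float = 18.0
    boost_fractions: int = 10
    reference_technique: str | None = None
    apply_eqd2: bool = False
    alpha_beta_gy: float = 3.0
    seed: int = 20260102

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError("run config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.n_cbct < 0:
            raise ValidationError("n_cbct must be nonnegative")
        for label, p in self.input_paths().items():
            if not Path(p).exists():
                raise ValidationError(f"{label} input not found: {p}")

    def input_paths(self) -> dict[str, str]:
        paths = {"organ_dose_csv": self.organ_dose_csv}
        if self.calibration_csv:
            paths["calibration_csv"] = self.calibration_csv
        if self.params_file:
            paths["params_file"] = self.params_file
        for tech, p in self.dvh_csvs.items():
            paths[f"dvh:{tech}"] = p
        return paths

    def prescription(self) -> Prescription:
        return Prescription(
            DoseValue(self.craniospinal_gy, "Gy"),
            self.craniospinal_fractions,
            DoseValue(self.boost_gy, "Gy"),
            self.boost_fractions,
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every analysis stage and write the report bundle.

    Returns a mapping of artefact name to written path.  Raises (and leaves
    no partial bundle behind) if any stage fails.
    """
    config.validate()
    outdir = Path(config.output_dir)
    staging = Path(tempfile.mkdtemp(prefix="csidose_stage_"))
    try:
        written = _run_stages(config, staging)
        outdir.mkdir(parents=True, exist_ok=True)
        final: dict[str, Path] = {}
        for name, p in written.items():
            dest = outdir / p.name
            shutil.move(str(p), dest)
            final[name] = dest
        return final
    finally:
        shutil.rmtree(staging, ignore_errors=True)


def _run_stages(config: RunConfig, staging: Path) -> dict[str, Path]:
    written: dict[str, Path] = {}

    # stage 1: calibration (optional — only when raw calibration points are supplied)
    curves = {}
    if config.calibration_csv:
        try:
            for modality, points in read_calibration_csv(config.calibration_csv).items():
                curves[modality] = build_calibration(points, modality)
        except CsidoseError as e:
            raise ValidationError(f"[calibration] {e}") from e
        p = staging / "calibration_curves.json"
        p.write_text(
            json.dumps(
                {
                    m: {
                        "factor_cgy_per_count": c.factor_cgy_per_count,
                        "inverse_counts_per_cgy": c.inverse_counts_per_cgy,
                        "factor_uncertainty": c.factor_uncertainty,
                        "n_points": len(c.points),
                    }
                    for m, c in curves.items()
                },
                indent=2,
            )
            + "\n"
        )
        written["calibration"] = p

    # stage 2: imaging-dose accounting
    try:
        organ_doses = read_organ_dose_csv(config.organ_dose_csv)
        prescription = config.prescription()
        rows = build_exposure_report(organ_doses, prescription, config.n_cbct)
        aggregate = exposure_aggregate(rows)
    except CsidoseError as e:
        raise ValidationError(f"[accounting] {e}") from e
    p = staging / "exposure_report.csv"
    exposure_frame(rows).to_csv(p, index=False)
    written["exposure_report"] = p
    p = staging / "exposure_report_rounded.csv"
    exposure_frame(rows, rounded=True).to_csv(p, index=False)
    written["exposure_report_rounded"] = p
    p = staging / "exposure_aggregate.json"
    p.write_text(json.dumps(aggregate, indent=2) + "\n")
    written["exposure_aggregate"] = p

    # stage 3: EUD/NTCP per technique
    params = (
        load_organ_params(config.params_file) if config.params_file else default_organ_params()
    )
    if config.dvh_csvs:
        try:
            plans = {}
            for tech, dvh_path in config.dvh_csvs.items():
                dvhs = read_dvh_csv(dvh_path)
                per_organ = {}
                for organ, dvh in dvhs.items():
                    if config.apply_eqd2:
                        n = config.craniospinal_fractions
                        dvh = eqd2_transform(dvh, DoseValue(config.alpha_beta_gy, "Gy"), n)
                    a = params[organ].a if organ in params else 1.0
                    per_organ[organ] = compute_eud(dvh, a)
                plans[tech] = per_organ
            comparison = compare_techniques(plans, params, config.reference_technique)
        except CsidoseError as e:
            raise ValidationError(f"[radiobiology] {e}") from e
        for name, df in (
            ("eud_matrix", comparison.eud_gy),
            ("ntcp_matrix", comparison.ntcp_pct),
            ("delta_eud_matrix", comparison.delta_eud_gy),
        ):
            p = staging / f"{name}.csv"
            df.to_csv(p)
            written[name] = p
        p = staging / "comparison_long.csv"
        comparison.to_long_frame().to_csv(p, index=False)
        written["comparison_long"] = p

    # stage 4: manifest
    manifest = {
        "package": "csidose",
        "version": __version__,
        "seed": config.seed,
        "n_cbct": config.n_cbct,
        "prescription": {
            "craniospinal_gy": config.craniospinal_gy,
            "craniospinal_fractions": config.craniospinal_fractions,
            "boost_gy": config.boost_gy,
            "boost_fractions": config.boost_fractions,
        },
        "apply_eqd2": config.apply_eqd2,
        "reference_technique": config.reference_technique,
        "params_provenance": {
            organ: pr.source for organ, pr in sorted(params.items())
        },
        "inputs": {
            label: {"path": str(path), "sha256": _sha256(path)}
            for label, path in config.input_paths().items()
        },
        "outputs": sorted(p.name for p in written.values()),
    }
    p = staging / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest"] = p
    return written
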