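"""End-to-end simulated replication of the phantom delineation study.

The simulated protocol mirrors the physical one, per participant and
phantom:

1. **Experiment registration** — the six anterior anatomical landmarks
   are digitized in tracker space with EMTS noise and registered to their
   CT positions; FRE is recorded, and TRE is evaluated at the (held-out)
   fiducial markers.
2. The planned sutures are mapped through that *imperfect* alignment:
   the participant sees — and traces — what the misaligned overlay
   shows.  This is the causal chain from registration error to
   delineation error.
3. **Delineation** — a drawn suture is simulated from each displayed
   suture with correlated tangent-plane noise.
4. **Evaluation registration** — the fiducials are digitized with OTS
   noise and registered back to CT; its FRE is recorded.
5. The drawn curves are digitized (OTS point noise) and mapped into CT
   space through the evaluation alignment.
6. Each digitized curve is scored against its planned suture with the
   delineation distance d = S_A / D_L.

The whole run is a pure function of the configuration and the master
seed; per-participant/stage sub-seeds are derived through
``numpy.random.SeedSequence`` so records do not depend on execution
order.  Grouped summaries report mean and sample sd (n-1) of d per
phantom x {coronal, virtual (pooled), lambdoid, all}.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .delineation import DEFAULT_STEP_MM, DelineationError, delineation_distance
from .errors import DegenerateInputError, InvalidParameterError, NoOverlapError
from .mesh import Polyline3D
from .phantom import (
    DELINEATED_SUTURES,
    NoiseSpec,
    PhantomSpec,
    make_phantom,
    simulate_drawn_suture,
)
from .registration import (
    LabeledPointSet,
    register_paired_points,
    target_registration_error,
)

__all__ = [
    "StudyConfig",
    "DelineationRecord",
    "RegistrationRecord",
    "StudyReport",
    "run_simulated_study",
    "summarize_report",
    "summarize_registrations",
    "write_study_report",
    "read_records_csv",
]

logger = logging.getLogger("cranionav.study")

#: stage codes for sub-seed derivation (fixed: part of the reproducibility contract)
_STAGES = {"experiment_reg": 0, "delineation": 1, "evaluation_reg": 2, "digitization": 3}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one simulated study run.

    Defaults reproduce the published protocol scale: 12 participants, two
    phantoms (10- and 8-fiducial layouts), five delineated sutures each
    (sagittal excluded — it is visualized for midline guidance only),
    0.25 mm resampling.
    """

    phantoms: tuple[PhantomSpec, ...] = (
        PhantomSpec(name="SK1", n_fiducials=10),
        PhantomSpec(name="SK2", n_fiducials=8, axes_mm=(65.0, 52.0, 47.0)),
    )
    participants: int = 12
    sutures_to_delineate: tuple[str, ...] = DELINEATED_SUTURES
    emts_sigma: float = 0.35
    ots_sigma: float = 0.4
    delineation_sigma: float = 1.5
    delineation_correlation_length: float = 20.0
    systematic_offset: float = 0.0
    step: float = DEFAULT_STEP_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.participants < 1:
            raise InvalidParameterError("participants must be >= 1")
        if not self.step > 0:
            raise InvalidParameterError("step must be > 0")
        if not 1 <= len(self.phantoms) <= 2:
            raise InvalidParameterError("1 or 2 phantom specs required")
        if min(self.emts_sigma, self.ots_sigma, self.delineation_sigma) < 0:
            raise InvalidParameterError("sigmas must be >= 0")

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(
            digitization_sigma=self.ots_sigma,
            delineation_sigma=self.delineation_sigma,
            delineation_correlation_length=self.delineation_correlation_length,
            systematic_offset=self.systematic_offset,
        )


@dataclass(frozen=True)
class DelineationRecord:
    """One delineated suture: who, where, what, and how far off."""

    participant: int
    phantom: str
    suture: str
    drawn_curve: Polyline3D
    error: DelineationError


@dataclass(frozen=True)
class RegistrationRecord:
    """Per participant x phantom registration errors (mm)."""

    participant: int
    phantom: str
    emts_fre: float
    emts_tre: float
    ots_fre: float


@dataclass(frozen=True)
class StudyReport:
    """Everything a simulated study produced."""

    config: StudyConfig
    records: list[DelineationRecord]
    registrations: list[RegistrationRecord]
    missing: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def error_table(self) -> pd.DataFrame:
        return summarize_report(self.records)

    @property
    def registration_table(self) -> pd.DataFrame:
        return summarize_registrations(self.registrations)

    def records_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant": r.participant,
                "phantom": r.phantom,
                "suture": r.suture,
                "S_A_mm2": r.error.spanned_area,
                "D_L_mm": r.error.overlap_length,
                "d_mm": r.error.distance,
                "overlap_fraction": r.error.overlap_fraction,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "participant",
                "phantom",
                "suture",
                "S_A_mm2",
                "D_L_mm",
                "d_mm",
                "overlap_fraction",
            ],
        )


def _stage_rng(master: int, phantom_index: int, participant: int, stage: str):
    seq = np.random.SeedSequence(
        [int(master), int(phantom_index), int(participant), _STAGES[stage]]
    )
    return np.random.default_rng(seq)


def _perturb(rng, points: LabeledPointSet, sigma: float) -> LabeledPointSet:
    noise = rng.normal(0.0, sigma, size=points.positions.shape)
    return LabeledPointSet(points.labels, points.positions + noise)


def run_simulated_study(config: StudyConfig) -> StudyReport:
    """Run the full simulated protocol; pure function of the config."""
    records: list[DelineationRecord] = []
    registrations: list[RegistrationRecord] = []
    missing: list[tuple[int, str, str]] = []
    noise = config.noise_spec()

    for k, spec in enumerate(config.phantoms):
        phantom_seed = int(
            np.random.SeedSequence([config.seed, k, 10_000]).generate_state(1)[0]
            % (2**31)
        )
        phantom = make_phantom(spec, seed=phantom_seed)
        for s in config.sutures_to_delineate:
            if s not in phantom.sutures:
                raise InvalidParameterError(f"unknown suture label {s!r}")
        pose = phantom.patient_sensor_pose  # CT -> tracker (world) truth
        world_surface = phantom.surface.transformed(pose)
        world_landmarks = phantom.anatomical_landmarks.transformed(pose)
        world_fiducials = phantom.fiducials.transformed(pose)
        logger.info(
            "phantom %s: %d triangles, %d fiducials, seed %d",
            spec.name,
            phantom.surface.n_triangles,
            len(phantom.fiducials),
            phantom_seed,
        )

        for p in range(config.participants):
            # 1. experiment registration (EMTS): CT -> world estimate
            rng = _stage_rng(config.seed, k, p, "experiment_reg")
            measured_lm = _perturb(rng, world_landmarks, config.emts_sigma)
            exp_reg = register_paired_points(phantom.anatomical_landmarks, measured_lm)
            tre = target_registration_error(
                exp_reg.transform, phantom.fiducials, world_fiducials
            )

            # 4. evaluation registration (OTS): world -> CT estimate
            rng = _stage_rng(config.seed, k, p, "evaluation_reg")
            measured_fid = _perturb(rng, world_fiducials, config.ots_sigma)
            eval_reg = register_paired_points(measured_fid, phantom.fiducials)

            registrations.append(
                RegistrationRecord(
                    participant=p,
                    phantom=spec.name,
                    emts_fre=exp_reg.fre,
                    emts_tre=tre.tre,
                    ots_fre=eval_reg.fre,
                )
            )

            delin_rng = _stage_rng(config.seed, k, p, "delineation")
            digit_rng = _stage_rng(config.seed, k, p, "digitization")
            for suture in config.sutures_to_delineate:
                planned = phantom.sutures[suture]
                # 2. the participant sees the plan through the imperfect alignment
                displayed = planned.transformed(exp_reg.transform)
                # 3. human tracing on the physical (world) surface
                draw_seed = int(delin_rng.integers(2**31))
                drawn_world = simulate_drawn_suture(
                    world_surface, displayed, noise, seed=draw_seed, step=config.step
                )
                # 5. digitize the drawn curve and map it into CT space
                digitized = drawn_world.points + digit_rng.normal(
                    0.0, config.ots_sigma, size=drawn_world.points.shape
                )
                drawn_ct = Polyline3D(
                    eval_reg.transform.apply(digitized), label=suture
                )
                # 6. score against the plan on the CT surface
                try:
                    err = delineation_distance(
                        phantom.surface, planned, drawn_ct, step=config.step
                    )
                except NoOverlapError as exc:
                    warnings.warn(
                        f"no usable overlap for participant {p}, phantom "
                        f"{spec.name}, suture {suture}: {exc}",
                        stacklevel=2,
                    )
                    missing.append((p, spec.name, suture))
                    continue
                records.append(
                    DelineationRecord(
                        participant=p,
                        phantom=spec.name,
                        suture=suture,
                        drawn_curve=drawn_ct,
                        error=err,
                    )
                )
            logger.debug("participant %d on %s done", p, spec.name)

    logger.info(
        "study complete: %d records, %d missing, seed %d",
        len(records),
        len(missing),
        config.seed,
    )
    return StudyReport(
        config=config, records=records, registrations=registrations, missing=missing
    )


def _suture_class(label: str) -> str:
    return "virtual" if label.startswith("virtual") else label


def summarize_report(records: list[DelineationRecord]) -> pd.DataFrame:
    """Mean and sample sd (n-1) of d per phantom x suture class.

    Virtual sutures are pooled into one ``virtual`` class and an ``all``
    row aggregates every delineated suture of the phantom.  A group with
    a single record reports sd = 0 and ``sd_defined = False``.
    """
    if not records:
        raise DegenerateInputError("no records to summarize")
    df = pd.DataFrame(
        {
            "phantom": [r.phantom for r in records],
            "cls": [_suture_class(r.suture) for r in records],
            "d": [r.error.distance for r in records],
        }
    )
    rows = []
    order = ["coronal", "virtual", "lambdoid", "all"]
    for phantom, sub in df.groupby("phantom", sort=True):
        for cls in order:
            vals = sub["d"].to_numpy() if cls == "all" else sub.loc[sub.cls == cls, "d"].to_numpy()
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "phantom": phantom,
                    "suture_class": cls,
                    "n": len(vals),
                    "mean_mm": float(np.mean(vals)),
                    "sd_mm": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "sd_defined": len(vals) > 1,
                }
            )
    return pd.DataFrame(rows)


def summarize_registrations(registrations: list[RegistrationRecord]) -> pd.DataFrame:
    """Per-phantom mean +/- sd of EMTS FRE, EMTS TRE and OTS FRE (mm)."""
    if not registrations:
        raise DegenerateInputError("no registration records")
    df = pd.DataFrame(
        {
            "phantom": [r.phantom for r in registrations],
            "emts_fre": [r.emts_fre for r in registrations],
            "emts_tre": [r.emts_tre for r in registrations],
            "ots_fre": [r.ots_fre for r in registrations],
        }
    )
    rows = []
    for phantom, sub in df.groupby("phantom", sort=True):
        row = {"phantom": phantom, "n": len(sub)}
        for col in ("emts_fre", "emts_tre", "ots_fre"):
            v = sub[col].to_numpy()
            row[f"{col}_mean_mm"] = float(np.mean(v))
            row[f"{col}_sd_mm"] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def write_study_report(report: StudyReport, directory: str | Path) -> dict[str, Path]:
    """Write records, summaries and a run manifest to ``directory``.

    Files: ``records.csv`` (one row per delineated suture),
    ``summary_delineation.csv``, ``summary_registration.csv`` and
    ``manifest.json`` (config, master seed, package version, missing
    records).  Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": directory / "records.csv",
        "summary_delineation": directory / "summary_delineation.csv",
        "summary_registration": directory / "summary_registration.csv",
        "manifest": directory / "manifest.json",
    }
    report.records_frame().to_csv(paths["records"], index=False)
    report.error_table.to_csv(paths["summary_delineation"], index=False)
    report.registration_table.to_csv(paths["summary_registration"], index=False)
    cfg = report.config
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "participants": cfg.participants,
        "phantoms": [
            {
                "name": s.name,
                "axes_mm": list(s.axes_mm),
                "n_fiducials": s.n_fiducials,
                "tessellation": s.tessellation,
            }
            for s in cfg.phantoms
        ],
        "sutures_to_delineate": list(cfg.sutures_to_delineate),
        "emts_sigma": cfg.emts_sigma,
        "ots_sigma": cfg.ots_sigma,
        "delineation_sigma": cfg.delineation_sigma,
        "delineation_correlation_length": cfg.delineation_correlation_length,
        "systematic_offset": cfg.systematic_offset,
        "step": cfg.step,
        "n_records": len(report.records),
        "missing_records": [list(m) for m in report.missing],
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths


def read_records_csv(path: str | Path) -> pd.DataFrame:
    """Read a ``records.csv`` written by :func:`write_study_report`."""
    df = pd.read_csv(path)
    expected = {"participant", "phantom", "suture", "S_A_mm2", "D_L_mm", "d_mm"}
    if not expected.issubset(df.columns):
        raise DegenerateInputError(f"not a records file: {sorted(df.columns)}")
    return df
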