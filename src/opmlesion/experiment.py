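"""Factorial experiment orchestration.

Runs the full study: synthetic cohort x source scenario x inversion
method x sensor-error condition.  Data are always simulated with the
TRUE forward model; position, orientation and rigid-rotation errors
distort the forward model used for inversion only, while gain errors
multiply the simulated data.  One position/orientation/rotation
realisation is shared by all lesions at a given error level; gain
realisations are drawn per lesion.

Every cell's random numbers derive from the master seed and the cell's
coordinates, so any output row can be regenerated in isolation and the
zero-error column is bit-identical to a no-error run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortConfig, generate_cohort, make_head
from .evaluation import is_correct_peak, nearest_alternative_distances
from .forward import (
    ConductorModel,
    LeadField,
    brain_shell,
    normal_oriented_sources,
    single_shell_leadfield,
)
from .inversion import (
    compare_lesion_models,
    ebb_invert,
    peak_location,
    preprocess,
)
from .sensors import (
    build_array,
    draw_gains,
    perturb_orientations,
    perturb_positions,
    rigid_rotate,
)
from .simulate import SourceScenario, apply_gains, scenario_vertices, simulate

__all__ = [
    "ErrorCondition",
    "ExperimentConfig",
    "run_experiment",
    "default_error_conditions",
    "flexible_combo_condition",
    "preset_well_separated_flexible",
    "preset_nearby_rigid",
]

logger = logging.getLogger("opmlesion")

# the published error-level grids, one error source at a time
POSITION_GRID_MM = (0.0, 2.0, 4.0, 5.0, 6.0, 8.0, 10.0)
ORIENTATION_GRID_DEG = (0.0, 5.0, 10.0, 15.0, 20.0)
GAIN_GRID = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05)
RIGID_GRID_DEG = (0.0, 5.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class ErrorCondition:
    """One sensor-error condition (usually a single non-zero source)."""

    label: str
    position_sd: float = 0.0  # mm
    orientation_sd: float = 0.0  # degrees
    gain_sd: float = 0.0  # fraction of unity gain
    rigid_deg: float = 0.0  # degrees

    @property
    def distorts_forward(self) -> bool:
        return (
            self.position_sd > 0 or self.orientation_sd > 0 or self.rigid_deg > 0
        )


def default_error_conditions() -> tuple:
    """The published one-at-a-time error grids plus the shared zero level."""
    out = [ErrorCondition("none")]
    out += [
        ErrorCondition(f"position_{v:g}mm", position_sd=v)
        for v in POSITION_GRID_MM
        if v > 0
    ]
    out += [
        ErrorCondition(f"orientation_{v:g}deg", orientation_sd=v)
        for v in ORIENTATION_GRID_DEG
        if v > 0
    ]
    out += [
        ErrorCondition(f"gain_{100 * v:g}pct", gain_sd=v) for v in GAIN_GRID if v > 0
    ]
    out += [
        ErrorCondition(f"rigid_{v:g}deg", rigid_deg=v)
        for v in RIGID_GRID_DEG
        if v > 0
    ]
    return tuple(out)


def flexible_combo_condition() -> ErrorCondition:
    """Combined flexible-array errors: 5 mm, 10 degrees, 5% gain."""
    return ErrorCondition(
        "flexible_combo", position_sd=5.0, orientation_sd=10.0, gain_sd=0.05
    )


def preset_well_separated_flexible(
    seed: int, n_patients: int = 40
) -> "ExperimentConfig":
    """Headline condition A: every candidate pair > 4 cm apart, combined
    flexible errors (5 mm / 10 deg / 5%), loose MSP, COM scenario."""
    return ExperimentConfig(
        n_patients=n_patients,
        cohort=CohortConfig(separation=(42.0, None), k_range=(2, 4)),
        conditions=(flexible_combo_condition(),),
        methods=("loose",),
        seed=seed,
    )


def preset_nearby_rigid(seed: int, n_patients: int = 40) -> "ExperimentConfig":
    """Headline condition B: nearest alternative < 2 cm, 20-degree rigid
    helmet rotation, loose MSP, COM scenario.

    Lesion areas are reduced relative to the default range so that
    disjoint patches with centres under 2 cm apart remain packable.
    """
    return ExperimentConfig(
        n_patients=n_patients,
        cohort=CohortConfig(
            area_range=(150.0, 400.0), separation=(14.0, 19.0), k_range=(2, 4)
        ),
        conditions=(ErrorCondition("rigid_20deg", rigid_deg=20.0),),
        methods=("loose",),
        seed=seed,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    n_patients: int = 10
    cohort: CohortConfig = field(default_factory=CohortConfig)
    head_order: int = 4
    cortex_radius: float = 70.0
    bumpiness: float = 0.1
    scalp_radius: float = 92.0
    spacing: float = 32.0
    offset: float = 8.7
    shell_order: int = 10
    shell_margin: float = 6.0
    scenarios: tuple = (SourceScenario.COM,)
    methods: tuple = ("ebb", "loose", "restricted")
    conditions: tuple = (ErrorCondition("none"),)
    snr_db: float = -20.0
    rate: float = 1000.0
    loose_k: int = 100
    seed: int = 0

    _KNOWN = None

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        for key in d:
            if key not in known:
                raise ValueError(f"unknown config field: {key}")
        if "cohort" in d:
            d["cohort"] = CohortConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d["cohort"].items()
                }
            )
        if "scenarios" in d:
            d["scenarios"] = tuple(SourceScenario(s) for s in d["scenarios"])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        if "conditions" in d:
            d["conditions"] = tuple(
                c if isinstance(c, ErrorCondition) else ErrorCondition(**c)
                for c in d["conditions"]
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_json(self) -> str:
        d = asdict(self)
        d["scenarios"] = [SourceScenario(s).value for s in self.scenarios]
        return json.dumps(d, indent=1, default=str)


def _seed(master: int, *key) -> int:
    """Deterministic per-cell seed below 2^31."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, *map(int, key)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _distorted_leadfield(array, cond, sources, shell, seed):
    a = array
    if cond.position_sd > 0:
        a = perturb_positions(a, cond.position_sd, seed=_seed(seed, 11))
    if cond.orientation_sd > 0:
        a = perturb_orientations(a, cond.orientation_sd, seed=_seed(seed, 12))
    if cond.rigid_deg > 0:
        a = rigid_rotate(a, cond.rigid_deg, seed=_seed(seed, 13))
    return single_shell_leadfield(a, sources, shell)


def run_experiment(config: ExperimentConfig, cohort: Cohort = None) -> pd.DataFrame:
    """Run the full factorial study and return one row per
    (lesion, scenario, method, error condition)."""
    t0 = time.time()
    master = config.seed
    head = (
        cohort.head
        if cohort is not None
        else make_head(
            order=config.head_order,
            cortex_radius=config.cortex_radius,
            bumpiness=config.bumpiness,
            scalp_radius=config.scalp_radius,
            seed=_seed(master, 1),
        )
    )
    if cohort is None:
        cohort = generate_cohort(
            head, config.n_patients, config.cohort, seed=_seed(master, 2)
        )
    array = build_array(
        head.scalp, config.spacing, offset=config.offset, seed=_seed(master, 3)
    )
    sources = normal_oriented_sources(head.cortex)
    shell = ConductorModel(
        kind="shell",
        mesh=brain_shell(head, margin=config.shell_margin),
        order=config.shell_order,
    )
    L_true = single_shell_leadfield(array, sources, shell)
    logger.info(
        "setup: %d patients, %d lesions, %d channels, %d sources (%.1fs)",
        cohort.n_patients,
        cohort.n_lesions,
        L_true.n_channels,
        L_true.n_sources,
        time.time() - t0,
    )

    # forward models per condition (shared across lesions)
    lf_inv = {}
    for ci, cond in enumerate(config.conditions):
        if cond.distorts_forward:
            t = time.time()
            lf_inv[ci] = _distorted_leadfield(
                array, cond, sources, shell, _seed(master, 4, ci)
            )
            logger.info(
                "condition %s: distorted forward model (%.1fs)",
                cond.label,
                time.time() - t,
            )
        else:
            lf_inv[ci] = L_true

    rows = []
    cortex = head.cortex
    for pi, patient in enumerate(cohort.patients):
        nearest_alt = nearest_alternative_distances(patient)
        means = np.array([les.mean_position for les in patient.lesions])
        for li, lesion in enumerate(patient.lesions):
            others = np.delete(means, li, axis=0)
            for scenario in config.scenarios:
                active = scenario_vertices(
                    lesion, scenario, seed=_seed(master, 5, pi, li)
                )
                rec0 = simulate(
                    L_true,
                    active,
                    rate=config.rate,
                    snr_db=config.snr_db,
                    seed=_seed(master, 6, pi, li, list(config.scenarios).index(scenario)),
                    true_lesion=lesion.label,
                    scenario=scenario,
                )
                Y_clean = preprocess(rec0)
                for ci, cond in enumerate(config.conditions):
                    if cond.gain_sd > 0:
                        gains = draw_gains(
                            rec0.n_channels,
                            cond.gain_sd,
                            seed=_seed(master, 7, ci, pi, li),
                        )
                        Y = preprocess(apply_gains(rec0, gains))
                    else:
                        Y = Y_clean
                    L_inv = lf_inv[ci]
                    for method in config.methods:
                        base = {
                            "patient": patient.id,
                            "lesion": lesion.label,
                            "scenario": SourceScenario(scenario).value,
                            "method": method,
                            "condition": cond.label,
                            "position_sd": cond.position_sd,
                            "orientation_sd": cond.orientation_sd,
                            "gain_sd": cond.gain_sd,
                            "rigid_deg": cond.rigid_deg,
                            "nearest_alt_mm": float(nearest_alt[li]),
                        }
                        try:
                            rows.append(
                                base
                                | _run_cell(
                                    Y,
                                    L_inv,
                                    patient,
                                    lesion,
                                    method,
                                    means[li],
                                    others,
                                    cortex,
                                    config.loose_k,
                                )
                            )
                        except Exception as exc:  # graceful degradation
                            logger.warning(
                                "cell failed (%s / %s / %s / %s): %s",
                                patient.id,
                                lesion.label,
                                method,
                                cond.label,
                                exc,
                            )
                            rows.append(
                                base
                                | {
                                    "correct": np.nan,
                                    "delta_f": np.nan,
                                    "peak_dist_mm": np.nan,
                                    "error": str(exc),
                                }
                            )
        logger.info("patient %s done (%.1fs elapsed)", patient.id, time.time() - t0)
    df = pd.DataFrame(rows)
    df.attrs["config"] = config.to_json()
    return df


def _run_cell(Y, L_inv, patient, lesion, method, true_mean, others, cortex, loose_k):
    if method == "ebb":
        res = ebb_invert(Y, L_inv)
        peak = cortex.vertices[peak_location(res)]
        return {
            "correct": is_correct_peak(peak, true_mean, others),
            "delta_f": np.nan,
            "peak_dist_mm": float(np.linalg.norm(peak - true_mean)),
        }
    cmp = compare_lesion_models(
        Y,
        L_inv,
        patient,
        method=method,
        true_lesion=lesion.label,
        k=loose_k,
    )
    delta_f = cmp.delta_f
    if method == "restricted":
        return {
            "correct": bool(delta_f is not None and delta_f > 0),
            "delta_f": delta_f,
            "peak_dist_mm": np.nan,
        }
    # loose: take the winning solution's peak and apply the distance rule
    win = cmp.winner
    if win is None:
        return {"correct": False, "delta_f": delta_f, "peak_dist_mm": np.nan}
    peak = cortex.vertices[peak_location(cmp.results[win])]
    return {
        "correct": is_correct_peak(peak, true_mean, others),
        "delta_f": delta_f,
        "peak_dist_mm": float(np.linalg.norm(peak - true_mean)),
    }
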