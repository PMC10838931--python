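"""Sensor-level trial simulation for the four lesion source scenarios.

A trial is 1 s long.  The source waveform is a single cosine cycle of
200 ms (5 Hz) centred in the trial, zero elsewhere.  Activity is placed
according to one of four scenarios describing where in a lesion the
epileptiform current might originate: its centre of mass, the whole
lesion, its whole boundary, or a single boundary vertex.  All active
dipoles share the waveform with identical unit moments; white Gaussian
channel noise is scaled to a fixed sensor SNR (default -20 dB), so
absolute dipole moment is irrelevant and lesion size/depth do not alter
the sensor-level SNR by design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import h5py
import numpy as np

from .forward import LeadField
from .geometry import VertexPatch

__all__ = [
    "SourceScenario",
    "SimulatedRecording",
    "scenario_vertices",
    "waveform",
    "simulate",
    "apply_gains",
]


class SourceScenario(str, Enum):
    COM = "com"
    WHOLE_LESION = "whole_lesion"
    WHOLE_EDGE = "whole_edge"
    PIECE_OF_EDGE = "piece_of_edge"


@dataclass(frozen=True)
class SimulatedRecording:
    """One simulated OP-MEG trial (n_channels x n_samples, fT)."""

    data: np.ndarray
    rate: float  # Hz
    channel_names: tuple
    true_lesion: str
    scenario: SourceScenario
    active_vertices: np.ndarray
    snr_db: float
    seed: int
    gain_seed: int = None

    def __post_init__(self):
        d = np.asarray(self.data, dtype=np.float64)
        if not np.all(np.isfinite(d)):
            raise ValueError("recording contains non-finite values")
        if d.shape[0] != len(self.channel_names):
            raise ValueError("data rows must match channel count")
        object.__setattr__(self, "data", d)
        object.__setattr__(
            self, "active_vertices", np.asarray(self.active_vertices, dtype=np.int64)
        )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data)
            fh.attrs.update(
                {
                    "rate": self.rate,
                    "true_lesion": self.true_lesion,
                    "scenario": self.scenario.value,
                    "snr_db": self.snr_db,
                    "seed": self.seed,
                    "gain_seed": -1 if self.gain_seed is None else self.gain_seed,
                }
            )
            fh.create_dataset("active_vertices", data=self.active_vertices)
            fh.create_dataset(
                "channel_names",
                data=np.array(self.channel_names, dtype=h5py.string_dtype()),
            )

    @classmethod
    def load(cls, path) -> "SimulatedRecording":
        with h5py.File(path, "r") as fh:
            gs = int(fh.attrs["gain_seed"])
            return cls(
                data=fh["data"][()],
                rate=float(fh.attrs["rate"]),
                channel_names=tuple(
                    n.decode() if isinstance(n, bytes) else str(n)
                    for n in fh["channel_names"][()]
                ),
                true_lesion=str(fh.attrs["true_lesion"]),
                scenario=SourceScenario(str(fh.attrs["scenario"])),
                active_vertices=fh["active_vertices"][()],
                snr_db=float(fh.attrs["snr_db"]),
                seed=int(fh.attrs["seed"]),
                gain_seed=None if gs < 0 else gs,
            )


def scenario_vertices(
    lesion: VertexPatch, scenario: SourceScenario, seed: int = 0
) -> np.ndarray:
    """Active vertex set of a lesion under a source scenario."""
    scenario = SourceScenario(scenario)
    if len(lesion) == 1:
        return lesion.indices.copy()
    boundary = lesion.boundary_vertices
    if boundary.size == 0:
        raise ValueError("lesion covers the whole mesh: boundary scenarios undefined")
    if scenario is SourceScenario.COM:
        return np.array([lesion.com_vertex])
    if scenario is SourceScenario.WHOLE_LESION:
        return lesion.indices.copy()
    if scenario is SourceScenario.WHOLE_EDGE:
        return boundary
    rng = np.random.default_rng(seed)
    return np.array([boundary[rng.integers(len(boundary))]])


def waveform(rate: float = 1000.0) -> np.ndarray:
    """Single 200 ms cosine cycle centred in a 1 s trial.

    s(t) = cos(2 pi 5 Hz (t - 0.5 s)) for t in [0.4, 0.6] s, zero
    elsewhere; peak 1 at trial centre.  ``rate`` must be at least
    512 Hz so the 0-256 Hz analysis band is representable.
    """
    if rate < 512:
        raise ValueError("sampling rate must be >= 512 Hz")
    n = int(round(rate))
    t = np.arange(n) / rate
    s = np.cos(2.0 * np.pi * 5.0 * (t - 0.5))
    s[(t < 0.4) | (t > 0.6)] = 0.0
    return s


def simulate(
    lead_field: LeadField,
    active: np.ndarray,
    rate: float = 1000.0,
    snr_db: float = -20.0,
    seed: int = 0,
    true_lesion: str = "",
    scenario: SourceScenario = SourceScenario.COM,
) -> SimulatedRecording:
    """Project unit dipoles at ``active`` vertices through the lead field
    and add white channel noise at the requested sensor SNR.

    The noise SD sigma satisfies
    20 log10(rms(noiseless) / sigma) = ``snr_db`` with the rms taken
    over all channels and samples of the noiseless data.
    """
    active = np.asarray(active, dtype=np.int64)
    if active.min() < 0 or active.max() >= lead_field.n_sources:
        raise ValueError("active vertices outside the lead-field source space")
    topo = lead_field.matrix[:, active].sum(axis=1)  # identical unit moments
    if np.allclose(topo, 0.0):
        raise ValueError("all active sources are magnetically silent")
    s = waveform(rate)
    clean = np.outer(topo, s)
    rms = np.sqrt(np.mean(clean**2))
    sigma = rms * 10.0 ** (-snr_db / 20.0)
    rng = np.random.default_rng(seed)
    data = clean + rng.normal(0.0, sigma, size=clean.shape)
    return SimulatedRecording(
        data=data,
        rate=rate,
        channel_names=lead_field.channel_names,
        true_lesion=true_lesion,
        scenario=SourceScenario(scenario),
        active_vertices=active,
        snr_db=snr_db,
        seed=seed,
    )


def apply_gains(
    recording: SimulatedRecording, gains: np.ndarray, gain_seed: int = None
) -> SimulatedRecording:
    """Multiply each channel by its gain factor (rows scale exactly)."""
    gains = np.asarray(gains, dtype=np.float64)
    if gains.shape != (recording.n_channels,):
        raise ValueError("gain vector length must equal channel count")
    return replace(
        recording, data=recording.data * gains[:, None], gain_seed=gain_seed
    )
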