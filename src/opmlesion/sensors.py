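"""Dual-axis OPM sensor arrays and their error models.

Each sensor sits a fixed stand-off above the scalp (default 8.7 mm, the
distance from scalp to vapour-cell centre for a typical wearable OPM)
and carries an orthonormal triad: one radial axis along the local scalp
normal and two tangential axes.  Two channels are recorded per sensor:
the radial axis and one seeded, arbitrarily rotated tangential axis.

Four error classes mimic imperfect knowledge of a wearable array:

* flexible position errors - i.i.d. Gaussian displacement per sensor;
* flexible orientation errors - independent random-axis rotation of each
  sensor triad with Gaussian-magnitude angle;
* per-channel gain errors - multiplicative factors 1 + eps,
  eps ~ N(0, sd^2), independent across channels;
* rigid rotation - the whole helmet rotated about a seeded random axis
  through the head origin (a co-registration-type error).

All operators at magnitude zero are exact identities, so the error-free
baseline is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import TriangleMesh

__all__ = [
    "SensorArray",
    "build_array",
    "perturb_positions",
    "perturb_orientations",
    "rigid_rotate",
    "draw_gains",
]


@dataclass(frozen=True)
class SensorArray:
    """OPM sites with orthonormal triads and a dual-axis channel table.

    ``positions``: (n_sensors, 3) mm.  ``triads``: (n_sensors, 3, 3),
    rows = (radial, tangential-1, tangential-2) unit vectors.
    ``tangent_angles``: the per-sensor angle (radians) of the measured
    tangential channel within the tangent plane.
    """

    positions: np.ndarray
    triads: np.ndarray
    tangent_angles: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=np.float64)
        t = np.asarray(self.triads, dtype=np.float64)
        a = np.asarray(self.tangent_angles, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != 3 or t.shape != (len(p), 3, 3):
            raise ValueError("inconsistent sensor geometry")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "triads", t)
        object.__setattr__(self, "tangent_angles", a)

    @property
    def n_sensors(self) -> int:
        return len(self.positions)

    @property
    def n_channels(self) -> int:
        return 2 * self.n_sensors

    @property
    def channel_positions(self) -> np.ndarray:
        """(n_channels, 3): radial and tangential channel are colocated."""
        return np.repeat(self.positions, 2, axis=0)

    @property
    def channel_orientations(self) -> np.ndarray:
        """(n_channels, 3) unit sensitive-axis vectors, channel order
        (sensor0-radial, sensor0-tangential, sensor1-radial, ...)."""
        rad = self.triads[:, 0, :]
        tan = (
            np.cos(self.tangent_angles)[:, None] * self.triads[:, 1, :]
            + np.sin(self.tangent_angles)[:, None] * self.triads[:, 2, :]
        )
        out = np.empty((self.n_channels, 3))
        out[0::2] = rad
        out[1::2] = tan
        return out

    @property
    def channel_names(self) -> list:
        names = []
        for i in range(self.n_sensors):
            names += [f"S{i:03d}-RAD", f"S{i:03d}-TAN"]
        return names

    def channel_table(self) -> pd.DataFrame:
        pos = self.channel_positions
        ori = self.channel_orientations
        return pd.DataFrame(
            {
                "name": self.channel_names,
                "sensor": np.repeat(np.arange(self.n_sensors), 2),
                "axis": ["radial", "tangential"] * self.n_sensors,
                "x": pos[:, 0],
                "y": pos[:, 1],
                "z": pos[:, 2],
                "ox": ori[:, 0],
                "oy": ori[:, 1],
                "oz": ori[:, 2],
            }
        )


def _orthonormal_triad(normals: np.ndarray) -> np.ndarray:
    """Complete unit normals into right-handed orthonormal triads."""
    n = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(n), 1))
    swap = np.abs(n[:, 2]) > 0.9
    ref[swap] = [1.0, 0.0, 0.0]
    t1 = np.cross(ref, n)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(n, t1)
    return np.stack([n, t1, t2], axis=1)


def build_array(
    scalp: TriangleMesh,
    spacing: float,
    offset: float = 8.7,
    seed: int = 0,
) -> SensorArray:
    """Pack dual-axis OPMs uniformly on the scalp at a target spacing.

    Sites come from seeded farthest-point sampling over the scalp
    vertices; points are added while the largest coverage gap exceeds
    0.75 x ``spacing``, which makes the mean nearest-neighbour distance
    land near ``spacing`` (on an adult-sized surface, 32 mm / 64 mm
    spacing yield sensor counts close to the published dense and sparse
    OPM layouts).  The count scales with spacing^-2.  Each site is
    lifted ``offset`` mm along the local outward normal.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    rng = np.random.default_rng(seed)
    pts = scalp.vertices
    start = int(rng.integers(len(pts)))
    chosen = [start]
    dmin = np.linalg.norm(pts - pts[start], axis=1)
    while True:
        nxt = int(np.argmax(dmin))
        if dmin[nxt] < 0.75 * spacing:
            break
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(pts - pts[nxt], axis=1))
    if len(chosen) < 4:
        raise ValueError("spacing too large for this scalp: fewer than 4 sensors")
    chosen = np.array(chosen)
    normals = scalp.vertex_normals[chosen]
    positions = pts[chosen] + offset * normals
    triads = _orthonormal_triad(normals)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=len(chosen))
    return SensorArray(positions=positions, triads=triads, tangent_angles=angles)


def perturb_positions(array: SensorArray, sd: float, seed: int = 0) -> SensorArray:
    """Displace each sensor by i.i.d. N(0, sd^2) per Cartesian component (mm)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return array
    rng = np.random.default_rng(seed)
    delta = rng.normal(0.0, sd, size=array.positions.shape)
    return replace(array, positions=array.positions + delta)


def perturb_orientations(array: SensorArray, sd: float, seed: int = 0) -> SensorArray:
    """Rotate each triad independently: uniform random axis, angle |N(0, sd^2)|
    (degrees).  Positions are untouched; triads stay orthonormal."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return array
    rng = np.random.default_rng(seed)
    n = array.n_sensors
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = np.abs(rng.normal(0.0, np.deg2rad(sd), size=n))
    rot = Rotation.from_rotvec(axes * angles[:, None]).as_matrix()
    # rows of the triad are vectors: v' = R v  ->  triad' = triad @ R.T
    new_triads = np.einsum("nij,nkj->nki", rot, array.triads)
    return replace(array, triads=new_triads)


def rigid_rotate(
    array: SensorArray, angle: float, seed: int = 0, axis=None
) -> SensorArray:
    """Rotate the whole array as one body about a random axis through the
    head origin by ``angle`` degrees (helmet co-registration error)."""
    if angle < 0:
        raise ValueError("angle must be non-negative")
    if angle == 0:
        return array
    if axis is None:
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(axis * np.deg2rad(angle)).as_matrix()
    return replace(
        array,
        positions=array.positions @ rot.T,
        triads=np.einsum("ij,nkj->nki", rot, array.triads),
    )


def draw_gains(n_channels: int, sd: float, seed: int = 0) -> np.ndarray:
    """Per-channel multiplicative gain factors 1 + eps, eps ~ N(0, sd^2).

    ``sd`` is a fraction of unity gain (e.g. 0.05 for the 5% level);
    at sd = 0 the gains are exactly one.
    """
    if not 0.0 <= sd <= 0.2:
        raise ValueError("sd must be in [0, 0.2]")
    if sd == 0:
        return np.ones(n_channels)
    rng = np.random.default_rng(seed)
    return 1.0 + rng.normal(0.0, sd, size=n_channels)
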