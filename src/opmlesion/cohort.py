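"""Synthetic heads and patient cohorts.

Real lesion-candidate maps (machine-detected focal cortical dysplasias
mapped to a template cortical surface) are access-restricted, so this
module generates statistically matched stand-ins: a smooth non-spherical
"cortex" inside a spherical scalp, and patients carrying 2-14 disjoint
geodesic-disk lesion patches whose count distribution has median 2.
Separation between candidate sites is a first-class control because it
is the main driver of discriminability downstream.

Everything is reproducible from a single integer seed through
:class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

from .geometry import TriangleMesh, VertexPatch, geodesic_disk, make_icosphere

__all__ = [
    "SyntheticHead",
    "Patient",
    "Cohort",
    "CohortConfig",
    "make_head",
    "sample_lesion_count",
    "generate_patient",
    "generate_cohort",
]


@dataclass(frozen=True)
class SyntheticHead:
    """Cortex (bumpy sphere, mean radius ~70 mm) inside a spherical scalp."""

    cortex: TriangleMesh
    scalp: TriangleMesh

    def min_clearance(self) -> float:
        rc = np.linalg.norm(self.cortex.vertices, axis=1).max()
        rs = np.linalg.norm(self.scalp.vertices, axis=1).min()
        return float(rs - rc)


@dataclass(frozen=True)
class Patient:
    id: str
    lesions: tuple  # tuple[VertexPatch, ...]

    @property
    def k(self) -> int:
        return len(self.lesions)

    def com_positions(self) -> np.ndarray:
        mesh = self.lesions[0].mesh
        return np.array([mesh.vertices[p.com_vertex] for p in self.lesions])


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for a synthetic cohort.

    ``area_range`` is the uniform lesion-area window in mm^2;
    ``separation`` = (minimum pairwise COM distance, maximum
    nearest-alternative COM distance or None) in mm; ``k_range``
    truncates the lesion-count distribution; ``count_p`` is the success
    parameter of the shifted-geometric count distribution
    P(k) = p (1-p)^(k-2) on {2, ..., 14} (p = 0.6 gives median 2).
    """

    area_range: tuple = (200.0, 1000.0)
    separation: tuple = (30.0, None)
    k_range: tuple = (2, 14)
    count_p: float = 0.6
    max_retries: int = 400


@dataclass(frozen=True)
class Cohort:
    head: SyntheticHead
    patients: tuple
    config: CohortConfig
    seed: int

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_lesions(self) -> int:
        return sum(p.k for p in self.patients)

    def manifest(self) -> dict:
        return {
            "seed": int(self.seed),
            "n_patients": self.n_patients,
            "n_lesions": self.n_lesions,
            "config": {
                "area_range": list(self.config.area_range),
                "separation": [
                    self.config.separation[0],
                    self.config.separation[1],
                ],
                "k_range": list(self.config.k_range),
                "count_p": self.config.count_p,
            },
            "patients": [
                {
                    "id": p.id,
                    "k": p.k,
                    "lesions": [
                        {
                            "label": les.label,
                            "n_vertices": int(len(les)),
                            "com_vertex": int(les.com_vertex),
                        }
                        for les in p.lesions
                    ],
                }
                for p in self.patients
            ],
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


# ---------------------------------------------------------------------


def _random_harmonic_field(directions: np.ndarray, rng, lmax: int = 4) -> np.ndarray:
    """Smooth random scalar field on the unit sphere, max |f| = 1.

    A seeded random combination of real spherical harmonics with
    1 <= l <= lmax, i.e. band-limited, so the resulting surface stays
    smooth and star-shaped.
    """
    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1, 1))
    phi = np.arctan2(y, x)
    f = np.zeros(len(directions))
    for ell in range(1, lmax + 1):
        for m in range(-ell, ell + 1):
            c = rng.standard_normal() / (1.0 + ell)
            ylm = sph_harm_y(ell, abs(m), theta, phi)
            if m > 0:
                val = np.sqrt(2.0) * (-1) ** m * ylm.real
            elif m < 0:
                val = np.sqrt(2.0) * (-1) ** m * ylm.imag
            else:
                val = ylm.real
            f += c * val
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def make_head(
    order: int = 4,
    cortex_radius: float = 70.0,
    bumpiness: float = 0.1,
    scalp_radius: float = 92.0,
    seed: int = 0,
    scalp_order: int = 4,
) -> SyntheticHead:
    """Build a synthetic head: radially perturbed icosphere cortex inside a
    spherical scalp.

    ``bumpiness`` scales a seeded band-limited spherical-harmonic radial
    perturbation; it must leave more than 5 mm clearance to the scalp.
    A non-zero default matters downstream: on an exactly spherical
    cortex every surface-normal dipole would be radial and hence
    magnetically silent.
    """
    if not 0.0 <= bumpiness <= 0.2:
        raise ValueError("bumpiness must be in [0, 0.2]")
    if scalp_radius <= cortex_radius * (1.0 + bumpiness) + 5.0:
        raise ValueError("scalp_radius leaves less than 5 mm clearance")
    sphere = make_icosphere(order, 1.0)
    rng = np.random.default_rng(seed)
    if bumpiness > 0:
        f = _random_harmonic_field(sphere.vertices, rng)
        radii = cortex_radius * (1.0 + bumpiness * f)
    else:
        radii = np.full(sphere.n_vertices, cortex_radius)
    cortex = TriangleMesh(sphere.vertices * radii[:, None], sphere.faces)
    scalp = make_icosphere(scalp_order, scalp_radius)
    head = SyntheticHead(cortex=cortex, scalp=scalp)
    if head.min_clearance() <= 5.0:
        raise ValueError("generated head violates the 5 mm clearance invariant")
    return head


def sample_lesion_count(
    rng, p: float = 0.6, k_range: tuple = (2, 14), size=None
):
    """Draw candidate-lesion counts from a truncated shifted geometric.

    P(k) proportional to p (1-p)^(k-2) on {k_min, ..., k_max}; the
    default (p = 0.6 on {2, ..., 14}) has median 2, matching the
    observed per-patient count statistics the cohort emulates.
    """
    kmin, kmax = k_range
    ks = np.arange(kmin, kmax + 1)
    w = p * (1.0 - p) ** (ks - 2)
    w = w / w.sum()
    return rng.choice(ks, size=size, p=w)


def generate_patient(
    head: SyntheticHead,
    k: int,
    area_range: tuple = (200.0, 1000.0),
    separation: tuple = (30.0, None),
    seed: int = 0,
    patient_id: str = "p0",
    max_retries: int = 400,
) -> Patient:
    """Place ``k`` disjoint geodesic-disk lesions on the cortex.

    Constraints: every pairwise COM distance >= ``separation[0]``; when
    ``separation[1]`` is set, every lesion's *nearest alternative* COM
    lies within it (an all-pairs upper bound is infeasible on a surface
    for k >= 4 with tight windows).  Seeds are rejection-sampled with a
    distance-windowed candidate set until the constraints hold.
    """
    if k < 2 or k > 14:
        raise ValueError("k must be in [2, 14]")
    sep_min, sep_max = separation
    cortex = head.cortex
    verts = cortex.vertices
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        seeds = [int(rng.integers(cortex.n_vertices))]
        ok = True
        for _j in range(1, k):
            d = np.linalg.norm(verts[:, None, :] - verts[seeds][None, :, :], axis=2)
            dmin = d.min(axis=1)
            mask = dmin >= sep_min
            if sep_max is not None:
                mask &= dmin <= sep_max
            cand = np.flatnonzero(mask)
            if len(cand) == 0:
                ok = False
                break
            seeds.append(int(rng.choice(cand)))
        if not ok:
            continue
        areas = rng.uniform(area_range[0], area_range[1], size=k)
        lesions = []
        used = np.zeros(cortex.n_vertices, dtype=bool)
        for j, (sv, ar) in enumerate(zip(seeds, areas)):
            patch = geodesic_disk(cortex, sv, ar, label=f"{patient_id}-L{j}")
            if used[patch.indices].any():
                ok = False
                break
            used[patch.indices] = True
            lesions.append(patch)
        if not ok:
            continue
        coms = np.array([verts[p.com_vertex] for p in lesions])
        dd = np.linalg.norm(coms[:, None, :] - coms[None, :, :], axis=2)
        np.fill_diagonal(dd, np.inf)
        if dd.min() < sep_min:
            continue
        if sep_max is not None and dd.min(axis=1).max() > sep_max:
            continue
        return Patient(id=patient_id, lesions=tuple(lesions))
    raise RuntimeError(
        f"could not pack {k} lesions with separation {separation} "
        f"after {max_retries} attempts"
    )


def generate_cohort(
    head: SyntheticHead,
    n_patients: int,
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
) -> Cohort:
    """Generate a reproducible cohort of multi-lesion patients."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_patients + 1)
    count_rng = np.random.default_rng(children[0])
    patients = []
    for i in range(n_patients):
        k = int(
            sample_lesion_count(count_rng, p=config.count_p, k_range=config.k_range)
        )
        child_seed = children[i + 1]
        try:
            patients.append(
                generate_patient(
                    head,
                    k,
                    area_range=config.area_range,
                    separation=config.separation,
                    seed=child_seed,
                    patient_id=f"p{i:03d}",
                    max_retries=config.max_retries,
                )
            )
        except RuntimeError as exc:
            raise RuntimeError(f"patient {i}: {exc}") from exc
    return Cohort(head=head, patients=tuple(patients), config=config, seed=seed)
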