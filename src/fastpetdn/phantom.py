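"""Synthetic whole-body FDG-PET phantoms and fast-acquisition simulation.

A phantom is a piecewise-constant SUV map: an ellipsoidal body of soft-tissue
background uptake, ellipsoidal liver and lung compartments of uniform uptake,
and hot spherical lesions. Acquisitions are simulated with a mixed
Gaussian-Poisson noise model: voxel intensities are converted to pseudo-counts
proportional to the acquisition-duration fraction, Poisson-resampled (count
thinning), rescaled back to SUV, and corrupted with additive zero-mean
Gaussian noise. Noise variance therefore scales as 1/duration_fraction, which
is exactly how shorter acquisitions degrade: a 20 s/AFOV scan carries 20/70 of
the reference counts and 3.5x the Poisson variance.

Default uptake conventions (body 1.0, liver 2.2, lungs 0.5 SUV) are a
plausible FDG biodistribution for a digital phantom, not measurements; the
default ``count_scale`` is tuned so the reference-duration liver SNR sits in
the 10-15 range typical of modern digital PET.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import yaml

from .volio import LabelMask, Volume

__all__ = [
    "Ellipsoid",
    "Lesion",
    "NoiseParams",
    "PhantomSpec",
    "LesionPopulation",
    "LesionSampler",
    "PhantomCase",
    "PhantomError",
    "default_spec",
    "build_activity_map",
    "build_label_mask",
    "simulate_acquisition",
    "sample_lesions",
    "make_dataset",
    "load_spec",
    "save_spec",
    "mtv_to_diameter_mm",
]

#: reference acquisition duration (s/AFOV) all fractions are quoted against
REFERENCE_DURATION_S = 70.0

#: label conventions for phantom masks
LABEL_BODY, LABEL_LIVER, LABEL_LUNG_L, LABEL_LUNG_R = 1, 2, 3, 4
LESION_LABEL_OFFSET = 100


class PhantomError(ValueError):
    """Invalid phantom specification."""


@dataclasses.dataclass
class Ellipsoid:
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """Membership of (..., 3) points by the voxel-center-in-geometry test."""
        c = np.asarray(self.center_mm, dtype=np.float64)
        a = np.asarray(self.semiaxes_mm, dtype=np.float64)
        u = (points_mm - c) / a
        return np.einsum("...i,...i->...", u, u) <= 1.0

    def surface_points(self, n: int = 146) -> np.ndarray:
        """Quasi-uniform surface samples (Fibonacci sphere), for containment checks."""
        i = np.arange(n, dtype=np.float64) + 0.5
        phi = np.arccos(1.0 - 2.0 * i / n)
        theta = math.pi * (1.0 + 5**0.5) * i
        unit = np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
            axis=1,
        )
        return np.asarray(self.center_mm) + unit * np.asarray(self.semiaxes_mm)


@dataclasses.dataclass
class Lesion:
    """A hot sphere: absolute SUV (g/mL), diameter in mm, center in mm."""

    id: int
    center_mm: tuple[float, float, float]
    diameter_mm: float
    suv: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise PhantomError(f"lesion {self.id}: diameter must be > 0")
        if self.suv <= 0:
            raise PhantomError(f"lesion {self.id}: SUV must be > 0")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        d2 = np.sum((points_mm - np.asarray(self.center_mm)) ** 2, axis=-1)
        return d2 <= self.radius_mm**2


@dataclasses.dataclass
class NoiseParams:
    """Mixed Gaussian-Poisson acquisition noise.

    count_scale: pseudo-counts per SUV unit at the reference duration.
    gaussian_sigma: additive Gaussian SD in SUV units.
    duration_fraction: acquisition time relative to the 70 s/AFOV reference.
    """

    count_scale: float = 70.0
    gaussian_sigma: float = 0.05
    duration_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.count_scale <= 0:
            raise PhantomError(f"count_scale must be > 0, got {self.count_scale}")
        if self.gaussian_sigma < 0:
            raise PhantomError("gaussian_sigma must be >= 0")
        if not (0 < self.duration_fraction <= 1):
            raise PhantomError(
                f"duration_fraction must lie in (0, 1], got {self.duration_fraction}"
            )


def _default_organs(fov_mm: np.ndarray) -> list[tuple[str, Ellipsoid, float]]:
    # geometry scaled to the field of view so any grid keeps whole-body proportions
    sx, sy, sz = fov_mm
    return [
        (
            "liver",
            Ellipsoid((0.35 * sx, 0.50 * sy, 0.55 * sz), (0.16 * sx, 0.14 * sy, 0.10 * sz)),
            2.2,
        ),
        (
            "lung_left",
            Ellipsoid((0.34 * sx, 0.48 * sy, 0.74 * sz), (0.12 * sx, 0.12 * sy, 0.11 * sz)),
            0.5,
        ),
        (
            "lung_right",
            Ellipsoid((0.66 * sx, 0.48 * sy, 0.74 * sz), (0.12 * sx, 0.12 * sy, 0.11 * sz)),
            0.5,
        ),
    ]


@dataclasses.dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 96)
    voxel_size_mm: float = 4.0
    body: Ellipsoid | None = None
    body_suv: float = 1.0
    organs: list[tuple[str, Ellipsoid, float]] | None = None
    lesions: list[Lesion] = dataclasses.field(default_factory=list)
    noise: NoiseParams = dataclasses.field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise PhantomError("voxel_size_mm must be > 0")
        fov = np.asarray(self.grid_shape, dtype=np.float64) * self.voxel_size_mm
        if self.body is None:
            self.body = Ellipsoid(tuple(fov / 2.0), tuple(fov * (0.44, 0.38, 0.49)))
        if self.organs is None:
            self.organs = _default_organs(fov)
        if self.body_suv <= 0:
            raise PhantomError("body SUV must be > 0")
        self.validate()

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.voxel_size_mm,) * 3

    def validate(self) -> None:
        for name, geom, suv in self.organs:
            if suv <= 0:
                raise PhantomError(f"organ {name}: SUV must be > 0")
            if not self.body.contains(geom.surface_points()).all():
                raise PhantomError(f"organ {name} is not contained in the body")
        for les in self.lesions:
            if not self.body.contains(np.asarray(les.center_mm)[None]).all():
                raise PhantomError(f"lesion {les.id} center lies outside the body")
            host = self.host_suv(np.asarray(les.center_mm))
            if les.suv <= host:
                raise PhantomError(
                    f"lesion {les.id}: SUV {les.suv} not above host-region SUV {host}"
                )
        for i, a in enumerate(self.lesions):
            for b in self.lesions[i + 1 :]:
                gap = np.linalg.norm(np.subtract(a.center_mm, b.center_mm))
                if gap < a.radius_mm + b.radius_mm:
                    raise PhantomError(f"lesions {a.id} and {b.id} overlap")

    def host_suv(self, point_mm: np.ndarray) -> float:
        """SUV of the innermost organ/body structure at a point (ignoring lesions)."""
        pt = np.asarray(point_mm, dtype=np.float64)[None]
        for _, geom, suv in reversed(self.organs):
            if geom.contains(pt)[0]:
                return float(suv)
        if self.body.contains(pt)[0]:
            return float(self.body_suv)
        return 0.0


def _voxel_centers(spec: PhantomSpec) -> np.ndarray:
    axes = [
        (np.arange(n, dtype=np.float64) + 0.5) * spec.voxel_size_mm
        for n in spec.grid_shape
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack(grid, axis=-1)  # (X, Y, Z, 3)


def build_activity_map(spec: PhantomSpec) -> Volume:
    """Noiseless piecewise-constant SUV map.

    Each voxel takes the value of the innermost enclosing structure
    (lesion > organ > body > 0 outside the body); membership is decided by
    the voxel-center-in-geometry test with no partial-volume antialiasing.
    """
    spec.validate()
    pts = _voxel_centers(spec)
    suv = np.zeros(spec.grid_shape, dtype=np.float32)
    suv[spec.body.contains(pts)] = spec.body_suv
    for _, geom, val in spec.organs:
        suv[geom.contains(pts)] = val
    for les in spec.lesions:
        suv[les.contains(pts)] = les.suv
    return Volume(suv, spec.spacing, {"kind": "truth", "seed": spec.seed})


def build_label_mask(spec: PhantomSpec) -> LabelMask:
    """Integer label volume: 0 air, 1 body, 2 liver, 3/4 lungs, 100+id lesions."""
    pts = _voxel_centers(spec)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    labels[spec.body.contains(pts)] = LABEL_BODY
    legend = {0: "background", LABEL_BODY: "body"}
    organ_labels = {"liver": LABEL_LIVER, "lung_left": LABEL_LUNG_L, "lung_right": LABEL_LUNG_R}
    for name, geom, _ in spec.organs:
        lab = organ_labels.get(name)
        if lab is None:
            lab = max(legend) + 1
        labels[geom.contains(pts)] = lab
        legend[lab] = name
    for les in spec.lesions:
        lab = LESION_LABEL_OFFSET + les.id
        labels[les.contains(pts)] = lab
        legend[lab] = f"lesion_{les.id}"
    return LabelMask(labels, spec.spacing, legend)


def simulate_acquisition(
    truth: Volume, noise: NoiseParams, seed: int | np.random.Generator
) -> Volume:
    """Simulate one acquisition of a noiseless activity map.

    Per voxel: draw Poisson with mean ``truth * count_scale * duration_fraction``,
    divide back to the SUV scale, add Gaussian(0, gaussian_sigma), clip at 0.
    The Poisson step is mean-preserving and its SUV-scale variance is
    ``truth / (count_scale * duration_fraction)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = noise.count_scale * noise.duration_fraction
    lam = np.asarray(truth.data, dtype=np.float64) * scale
    counts = rng.poisson(lam)
    suv = counts / scale + rng.normal(0.0, noise.gaussian_sigma, size=truth.shape)
    clipped = float(np.mean(suv < 0))
    out = np.clip(suv, 0.0, None).astype(np.float32)
    duration_s = noise.duration_fraction * REFERENCE_DURATION_S
    return Volume(
        out,
        truth.voxel_size_mm,
        {
            **truth.meta,
            "kind": "acquisition",
            "duration_fraction": noise.duration_fraction,
            "duration_s_per_afov": duration_s,
            "clip_fraction": clipped,
        },
    )


# ---------------------------------------------------------------------------
# Lesion population sampling


def mtv_to_diameter_mm(mtv_cm3: float) -> float:
    """Sphere diameter (mm) whose volume equals the given MTV in cm^3."""
    return 2.0 * (3.0 * mtv_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclasses.dataclass
class LesionPopulation:
    """Gaussian stratum of lesion SUV and metabolic volume."""

    mean_suv: float
    sd_suv: float
    mean_mtv_cm3: float
    sd_mtv_cm3: float
    weight: float = 1.0

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        suv = max(rng.normal(self.mean_suv, self.sd_suv), 1.3)
        mtv = max(rng.normal(self.mean_mtv_cm3, self.sd_mtv_cm3), 0.3)
        return suv, mtv_to_diameter_mm(mtv)


@dataclasses.dataclass
class LesionSampler:
    """Two-stratum lesion population.

    The defaults span the conspicuous stratum (SUV ~5, MTV ~9-10 cm^3,
    readily detected even on fast scans) and the faint stratum
    (SUV ~2.6-2.9, MTV ~1.8-2.8 cm^3, the kind a fast acquisition misses).
    """

    strata: list[LesionPopulation] = dataclasses.field(
        default_factory=lambda: [
            LesionPopulation(4.96, 0.50, 9.3, 1.5, weight=0.5),
            LesionPopulation(2.75, 0.15, 2.3, 0.5, weight=0.5),
        ]
    )

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        w = np.array([s.weight for s in self.strata], dtype=np.float64)
        idx = rng.choice(len(self.strata), p=w / w.sum())
        return self.strata[int(idx)].draw(rng)


def sample_lesions(
    spec: PhantomSpec,
    n_lesions: int,
    rng: np.random.Generator,
    sampler: LesionSampler | None = None,
    max_tries: int = 500,
) -> list[Lesion]:
    """Place non-overlapping hot lesions inside the body (liver or soft tissue)."""
    sampler = sampler or LesionSampler()
    lesions: list[Lesion] = []
    body = spec.body
    c = np.asarray(body.center_mm)
    a = np.asarray(body.semiaxes_mm)
    for lid in range(1, n_lesions + 1):
        for _ in range(max_tries):
            suv, diam = sampler.draw(rng)
            # rejection-sample a center comfortably inside the body
            u = rng.uniform(-0.75, 0.75, size=3)
            if (u**2).sum() > 0.75**2:
                continue
            center = tuple(c + u * a)
            host = spec.host_suv(np.asarray(center))
            if host <= 0 or suv <= host + 0.5:
                continue
            cand = Lesion(lid, center, diam, suv)
            margin = 2.0 * spec.voxel_size_mm
            if any(
                np.linalg.norm(np.subtract(cand.center_mm, o.center_mm))
                < cand.radius_mm + o.radius_mm + margin
                for o in lesions
            ):
                continue
            lesions.append(cand)
            break
        else:
            raise PhantomError(
                f"could not place lesion {lid} after {max_tries} tries"
            )
    return lesions


@dataclasses.dataclass
class PhantomCase:
    """One synthetic patient: truth, labels, reference and fast acquisitions."""

    spec: PhantomSpec
    truth: Volume
    labels: LabelMask
    reference: Volume
    fast: dict[float, Volume]  # duration_fraction -> Volume


def make_dataset(
    n_phantoms: int,
    durations: Sequence[float],
    seed: int,
    lesion_sampler: LesionSampler | None = None,
    n_lesions: tuple[int, int] = (2, 5),
    grid_shape: tuple[int, int, int] = (64, 64, 96),
    voxel_size_mm: float = 4.0,
    noise: NoiseParams | None = None,
) -> list[PhantomCase]:
    """Generate phantoms plus reference and fast acquisitions.

    Per phantom: one reference acquisition at duration fraction 1 and one fast
    acquisition per requested fraction. All are drawn from the same truth with
    independent noise streams, so they correlate only through the anatomy —
    mirroring how one raw listmode acquisition is rebinned into shorter
    time windows.
    """
    if n_phantoms < 1:
        raise PhantomError("n_phantoms must be >= 1")
    durations = list(durations)
    if not durations:
        raise PhantomError("durations must be a non-empty list of fractions")
    base_noise = noise or NoiseParams()
    root = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    for pid in range(n_phantoms):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        spec = PhantomSpec(
            grid_shape=grid_shape,
            voxel_size_mm=voxel_size_mm,
            noise=dataclasses.replace(base_noise, duration_fraction=1.0),
            seed=int(rng.integers(2**31 - 1)),
        )
        k = int(rng.integers(n_lesions[0], n_lesions[1] + 1))
        spec.lesions = sample_lesions(spec, k, rng, lesion_sampler)
        spec.validate()
        truth = build_activity_map(spec)
        truth.meta["phantom_id"] = pid
        labels = build_label_mask(spec)
        reference = simulate_acquisition(truth, spec.noise, rng)
        fast = {
            f: simulate_acquisition(
                truth, dataclasses.replace(base_noise, duration_fraction=f), rng
            )
            for f in durations
        }
        cases.append(PhantomCase(spec, truth, labels, reference, fast))
    return cases


# ---------------------------------------------------------------------------
# Spec (de)serialisation — structured text config


def save_spec(spec: PhantomSpec, path) -> None:
    def floats(seq):
        return [float(v) for v in seq]

    doc = {
        "grid_shape": [int(n) for n in spec.grid_shape],
        "voxel_size_mm": float(spec.voxel_size_mm),
        "body": {
            "center_mm": floats(spec.body.center_mm),
            "semiaxes_mm": floats(spec.body.semiaxes_mm),
            "suv": float(spec.body_suv),
        },
        "organs": [
            {
                "name": name,
                "center_mm": floats(g.center_mm),
                "semiaxes_mm": floats(g.semiaxes_mm),
                "suv": float(suv),
            }
            for name, g, suv in spec.organs
        ],
        "lesions": [
            {
                "id": int(l.id),
                "center_mm": floats(l.center_mm),
                "diameter_mm": float(l.diameter_mm),
                "suv": float(l.suv),
            }
            for l in spec.lesions
        ],
        "noise": {k: float(v) for k, v in dataclasses.asdict(spec.noise).items()},
        "seed": int(spec.seed),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_spec(path) -> PhantomSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    body = doc.get("body") or {}
    spec = PhantomSpec(
        grid_shape=tuple(doc.get("grid_shape", (64, 64, 96))),
        voxel_size_mm=float(doc.get("voxel_size_mm", 4.0)),
        body=Ellipsoid(tuple(body["center_mm"]), tuple(body["semiaxes_mm"]))
        if body
        else None,
        body_suv=float(body.get("suv", 1.0)) if body else 1.0,
        organs=[
            (o["name"], Ellipsoid(tuple(o["center_mm"]), tuple(o["semiaxes_mm"])), float(o["suv"]))
            for o in doc.get("organs", [])
        ]
        or None,
        lesions=[
            Lesion(int(l["id"]), tuple(l["center_mm"]), float(l["diameter_mm"]), float(l["suv"]))
            for l in doc.get("lesions", [])
        ],
        noise=NoiseParams(**(doc.get("noise") or {})),
        seed=int(doc.get("seed", 0)),
    )
    return spec
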