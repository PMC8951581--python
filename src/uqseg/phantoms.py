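"""Synthetic multimodal tumor phantoms.

Each phantom is a 4-contrast volume (t1, t1ce, t2, flair semantics) with
nested spherical tumor subregions per focus: an edema shell (label 2)
containing an enhancing rim (label 4) containing a necrotic center
(label 1).  Mean intensities per tissue class and contrast reproduce the
qualitative radiology of glioma MRI: enhancing tumor is hyperintense in
t1ce, edema is hyperintense in flair, and the necrotic core is
hypointense in t1ce.  I.i.d. Gaussian noise is added per channel; there
is no bias field, partial-volume or anatomy modelling — the phantoms
exist to exercise the segmentation/uncertainty pipeline end to end, not
to mimic MRI physics.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .io import MODALITIES, LabelMap, MultimodalVolume

__all__ = ["PhantomSpec", "PhantomCase", "default_intensity_table",
           "generate_phantom", "generate_cohort"]

#: tissue classes keyed by label code; 0 is normal parenchyma
TISSUE_CLASSES: tuple[int, ...] = (0, 1, 2, 4)

_MARGIN = 2  # voxels kept between any focus and the grid boundary


def default_intensity_table() -> dict[int, dict[str, float]]:
    """Class-mean intensities (arbitrary units) per tissue and contrast.

    Parenchyma is 1.0 everywhere; each lesion class is 2.0 in its
    defining contrast (enhancing tumor in t1ce, edema in flair), the
    necrotic core is 0.4 in t1ce, and lesions sit at 1.2 off-contrast so
    they remain mildly distinguishable in every channel.
    """
    table = {code: {m: 1.2 for m in MODALITIES} for code in TISSUE_CLASSES}
    table[0] = {m: 1.0 for m in MODALITIES}
    table[4]["t1ce"] = 2.0   # enhancing tumor: hyperintense under contrast
    table[2]["flair"] = 2.0  # edema: hyperintense in flair
    table[1]["t1ce"] = 0.4   # necrotic core: hypointense under contrast
    return table


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise settings for one phantom family."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    n_foci: int = 1
    radius_range_wt: tuple[float, float] = (6.0, 12.0)
    core_fraction: float = 0.6    # TC radius as a fraction of the WT radius
    et_fraction: float = 0.5      # enhancing rim thickness as a fraction of TC radius
    intensity_table: dict = field(default_factory=default_intensity_table)
    noise_sd: float = 0.15
    ellipsoid_deform: float = 0.0  # per-axis relative radius jitter; 0 = spheres
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.n_foci < 0:
            raise ValueError("n_foci must be non-negative")
        lo, hi = self.radius_range_wt
        if lo < 2.0 or hi < lo:
            raise ValueError("radius_range_wt lower bound must be >= 2 voxels")
        if not 0.0 < self.core_fraction < 1.0:
            raise ValueError("core_fraction must lie in (0, 1)")
        if not 0.0 < self.et_fraction < 1.0:
            raise ValueError("et_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        _check_contrast(self.intensity_table)


def _check_contrast(table: dict) -> None:
    """Enforce the glioma contrast orderings the phantom must reproduce."""
    par, net, ed, et = table[0], table[1], table[2], table[4]
    if not et["t1ce"] > par["t1ce"]:
        raise ValueError("enhancing tumor must be hyperintense vs parenchyma in t1ce")
    if not ed["flair"] > par["flair"]:
        raise ValueError("edema must be hyperintense vs parenchyma in flair")
    if not net["t1ce"] < et["t1ce"]:
        raise ValueError("necrotic core must be hypointense vs enhancing tumor in t1ce")


@dataclass
class PhantomCase:
    image: MultimodalVolume
    labels: LabelMap
    spec_used: PhantomSpec
    case_id: str


def _paint_focus(labels: np.ndarray, center: np.ndarray, r_wt: float,
                 spec: PhantomSpec, axis_scale: np.ndarray) -> None:
    shape = labels.shape
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = sum(((g - c) * s) ** 2
             for g, c, s in zip(grids, center, 1.0 / axis_scale))
    r_tc = r_wt * spec.core_fraction
    r_necrotic = r_tc * (1.0 - spec.et_fraction)
    labels[d2 <= r_wt**2] = 2            # edema shell (whole-tumor extent)
    labels[d2 <= r_tc**2] = 4            # enhancing rim (tumor-core extent)
    labels[d2 <= r_necrotic**2] = 1      # necrotic center


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> PhantomCase:
    """Generate one phantom; output is a pure function of (spec, seed)."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    labels = np.zeros(shape, dtype=np.int16)

    r_hi = spec.radius_range_wt[1]
    max_extent = r_hi * (1.0 + spec.ellipsoid_deform)
    if spec.n_foci > 0 and any(s < 2 * (max_extent + _MARGIN) + 1 for s in shape):
        raise ValueError(
            f"grid {shape} cannot contain a focus of radius {max_extent:.1f} "
            f"plus a {_MARGIN}-voxel margin; enlarge the grid or shrink "
            "radius_range_wt")

    for _ in range(spec.n_foci):
        r_wt = rng.uniform(*spec.radius_range_wt)
        if spec.ellipsoid_deform > 0:
            axis_scale = 1.0 + rng.uniform(-spec.ellipsoid_deform,
                                           spec.ellipsoid_deform, size=3)
        else:
            axis_scale = np.ones(3)
        lo = r_wt * axis_scale.max() + _MARGIN
        center = np.array([rng.uniform(lo, s - 1 - lo) for s in shape])
        _paint_focus(labels, center, r_wt, spec, axis_scale)

    image = np.empty((len(MODALITIES),) + shape, dtype=np.float32)
    for c, m in enumerate(MODALITIES):
        chan = np.empty(shape, dtype=np.float32)
        for code in TISSUE_CLASSES:
            chan[labels == code] = spec.intensity_table[code][m]
        image[c] = chan
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape).astype(np.float32)

    case_id = f"phantom-{seed:010d}"
    return PhantomCase(
        image=MultimodalVolume(image, case_id=case_id),
        labels=LabelMap(labels),
        spec_used=spec,
        case_id=case_id,
    )


def generate_cohort(spec: PhantomSpec, n_cases: int, seed: int
                    ) -> list[PhantomCase]:
    """Generate ``n_cases`` phantoms with seeds derived from a master seed."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_cases) % (2**31)
    cases = []
    for i, s in enumerate(child_seeds):
        case = generate_phantom(spec, int(s))
        cid = f"case-{i:03d}-{int(s):010d}"
        case.case_id = cid
        case.image.case_id = cid
        cases.append(case)
    return cases


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["grid_shape"] = list(spec.grid_shape)
    d["radius_range_wt"] = list(spec.radius_range_wt)
    d["intensity_table"] = {int(k): dict(v) for k, v in spec.intensity_table.items()}
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    d["grid_shape"] = tuple(d["grid_shape"])
    d["radius_range_wt"] = tuple(d["radius_range_wt"])
    if "intensity_table" in d:
        d["intensity_table"] = {int(k): dict(v)
                                for k, v in d["intensity_table"].items()}
    return PhantomSpec(**d)
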