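"""Synthetic ADPKD-like T2 MR phantoms with ground-truth masks.

Real coronal T2 scans of polycystic kidneys show two kidney bodies whose
parenchyma is progressively replaced by fluid-filled cysts: most cysts are
bright on T2, a minority ("complex" cysts with proteinaceous or hemorrhagic
content) are dark. Disease severity is summarized by the cystic index
(cyst volume / total kidney volume), which clinically spans ~0.5% up to ~90%.
The phantoms emulate exactly those features with deliberately simple
geometry — ellipsoidal kidneys, spherical cysts, additive Gaussian noise —
so the full segmentation pipeline can be trained and evaluated without
clinical data.

Intensity levels are arbitrary units; only their ordering is contractual:
bright cyst > parenchyma > complex cyst, background low for fat-saturated
scans and high with extra variance for non-fat-saturated scans. As in real
T2 scans, a few extra-renal fluid structures (CSF, gallbladder, vessels) are
rendered at fluid brightness outside the kidneys: they anchor the upper
intensity percentiles of every scan regardless of cyst burden — which is
what makes volume-wide percentile normalization meaningful — and they
exercise the two-channel constraint, since bright voxels outside the kidney
channel must not be segmented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BinaryMask, FeasibilityError, StudyCase, VoxelVolume

__all__ = [
    "PhantomSpec",
    "generate_case",
    "generate_cohort",
    "simulate_second_reader",
    "INTENSITY",
]

# Arbitrary-unit intensity levels; ordering (bright > parenchyma > complex,
# fat-sat background lowest) is the contract, the values are free choices.
INTENSITY = {
    "background_fat_sat": 50.0,
    "background_non_fat_sat": 400.0,
    "parenchyma": 300.0,
    "bright_cyst": 800.0,
    "complex_cyst": 100.0,
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    ``grid_shape`` defaults to 64x64x16 (test scale; demos use 256x256xZ),
    ``spacing`` to the nominal acquisition geometry of 1.5 mm in-plane and
    3.0 mm slice thickness. ``target_cystic_index`` is the requested cyst /
    kidney volume fraction; the generator lands within +-10% relative of it
    whenever geometrically feasible.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    n_cysts: int = 30
    cyst_radius_range: tuple[float, float] = (3.0, 24.0)  # mm
    complex_cyst_fraction: float = 0.1
    target_cystic_index: float = 0.2
    fat_saturated: bool = True
    noise_sigma: float = 30.0
    kidney_scale: float = 1.0
    seed: int = 0
    case_id: str = ""

    def __post_init__(self):
        if self.n_cysts < 0:
            raise ValueError("n_cysts must be non-negative")
        lo, hi = self.cyst_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("cyst_radius_range must be a positive interval")
        for name in ("complex_cyst_fraction", "target_cystic_index"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if any(int(g) < 1 for g in self.grid_shape):
            raise ValueError("grid_shape components must be positive")


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipsoid in voxel index units."""
    grids = np.ogrid[[slice(0, s) for s in shape]]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / max(a, 1e-9)) ** 2
    return acc <= 1.0


def _kidneys(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Two ellipsoidal kidney bodies with mild random axis jitter."""
    H, W, Z = spec.grid_shape
    mask = np.zeros(spec.grid_shape, dtype=bool)
    # Long axis along rows (superior-inferior on a coronal slice), kidneys
    # placed left and right of the midline.
    base = np.array([0.36 * H, 0.17 * W, 0.36 * Z]) * spec.kidney_scale
    for col_frac in (0.28, 0.72):
        jitter = rng.uniform(0.88, 1.12, size=3)
        semi = np.maximum(base * jitter, 1.0)
        center = (
            H / 2 + rng.uniform(-0.04, 0.04) * H,
            col_frac * W + rng.uniform(-0.03, 0.03) * W,
            Z / 2 + rng.uniform(-0.06, 0.06) * Z,
        )
        mask |= _ellipsoid_mask(spec.grid_shape, center, semi)
    return mask


def _sphere_voxels(shape, spacing, center, radius_mm) -> np.ndarray:
    """Boolean mask of a sphere of physical radius, anisotropic voxels."""
    semi = [max(radius_mm / s, 1e-9) for s in spacing]
    return _ellipsoid_mask(shape, center, semi)


def _place_cysts(spec: PhantomSpec, kidney: np.ndarray, rng: np.random.Generator):
    """Greedy sphere placement approaching the target cystic index.

    Spheres are centered at random kidney voxels and clipped to the kidney,
    which guarantees containment. The last sphere's radius is bisected so the
    achieved index never overshoots the target by more than the tolerance.
    """
    kidney_vox = int(kidney.sum())
    target_vox = spec.target_cystic_index * kidney_vox
    cyst = np.zeros(spec.grid_shape, dtype=bool)
    complex_cyst = np.zeros(spec.grid_shape, dtype=bool)
    if spec.n_cysts == 0 or target_vox <= 0:
        if target_vox > 0.5:
            raise FeasibilityError(
                "target_cystic_index > 0 requested with n_cysts = 0"
            )
        return cyst, complex_cyst

    r_lo, r_hi = spec.cyst_radius_range
    voxel_vol = float(np.prod(spec.spacing))
    max_sphere_vox = (4.0 / 3.0) * np.pi * r_hi**3 / voxel_vol
    if spec.n_cysts * max_sphere_vox < target_vox:
        raise FeasibilityError(
            f"target cystic index {spec.target_cystic_index:g} is unreachable: "
            f"{spec.n_cysts} cysts of radius <= {r_hi:g} mm cover at most "
            f"{spec.n_cysts * max_sphere_vox:.0f} of the required "
            f"{target_vox:.0f} kidney voxels"
        )

    inside = np.argwhere(kidney)
    placed = 0
    attempts = 0
    max_attempts = 60 * max(spec.n_cysts, 1)
    while placed < spec.n_cysts and attempts < max_attempts:
        attempts += 1
        current = int(cyst.sum())
        deficit = target_vox - current
        if deficit <= max(1.0, 0.02 * target_vox):
            break
        center = inside[rng.integers(len(inside))]
        radius = rng.uniform(r_lo, r_hi)
        cand = _sphere_voxels(spec.grid_shape, spec.spacing, center, radius) & kidney
        added = int((cand & ~cyst).sum())
        if added == 0:
            continue
        if added > deficit:
            # bisect the radius down so the target is approached from below
            lo, hi = 0.0, radius
            best = None
            for _ in range(24):
                mid = 0.5 * (lo + hi)
                c = _sphere_voxels(spec.grid_shape, spec.spacing, center, mid) & kidney
                a = int((c & ~cyst).sum())
                if a <= deficit:
                    best, lo = (c, a), mid
                else:
                    hi = mid
            if best is None or best[1] == 0:
                continue
            cand, added = best
        cyst |= cand
        # complex cysts stay a volume minority: flag this cyst dark only while
        # the complex share of total cyst volume remains below the fraction
        if (
            spec.complex_cyst_fraction > 0
            and (complex_cyst.sum() + added) <= spec.complex_cyst_fraction * cyst.sum()
            and rng.random() < 2 * spec.complex_cyst_fraction
        ):
            complex_cyst |= cand
        placed += 1

    achieved = cyst.sum() / kidney_vox
    # a couple of voxels of slack: tiny targets quantize to integer voxels
    off_by_vox = abs(float(cyst.sum()) - target_vox)
    if (
        target_vox >= 1
        and off_by_vox > 2.0
        and abs(achieved - spec.target_cystic_index) > 0.1 * spec.target_cystic_index
    ):
        raise FeasibilityError(
            f"could not reach cystic index {spec.target_cystic_index:g} "
            f"(achieved {achieved:.4f}) with n_cysts={spec.n_cysts}, "
            f"radius range {spec.cyst_radius_range} mm"
        )
    # complex cysts are a subset of the cyst mask by construction
    return cyst, complex_cyst & cyst


def _extrarenal_fluid(shape, spacing, kidney: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bright fluid-filled structures outside the kidneys (CSF, gallbladder...).

    Present on every scan, they pin the scan's upper intensity percentiles
    independently of cyst burden.
    """
    fluid = np.zeros(shape, dtype=bool)
    n_bodies = int(rng.integers(3, 6))
    for _ in range(n_bodies):
        center = [rng.uniform(0.1, 0.9) * s for s in shape]
        radii_mm = rng.uniform(8.0, 18.0, size=3)
        semi = [max(r / s, 1.0) for r, s in zip(radii_mm, spacing)]
        fluid |= _ellipsoid_mask(shape, center, semi)
    return fluid & ~kidney


def render_intensity(
    kidney: np.ndarray,
    cyst: np.ndarray,
    complex_cyst: np.ndarray,
    fluid: np.ndarray,
    fat_saturated: bool,
    rng: np.random.Generator,
    noise_sigma: float,
) -> np.ndarray:
    """Compose the noiseless tissue map, then add Gaussian noise."""
    img = np.full(kidney.shape, INTENSITY["background_fat_sat"], dtype=np.float32)
    if not fat_saturated:
        bg = ~kidney
        img[bg] = INTENSITY["background_non_fat_sat"] + 60.0 * rng.standard_normal(
            int(bg.sum())
        ).astype(np.float32)
    img[fluid] = INTENSITY["bright_cyst"]
    img[kidney] = INTENSITY["parenchyma"]
    img[cyst] = INTENSITY["bright_cyst"]
    img[complex_cyst] = INTENSITY["complex_cyst"]
    if noise_sigma > 0:
        img = img + noise_sigma * rng.standard_normal(img.shape).astype(np.float32)
    return img


def generate_case(spec: PhantomSpec) -> StudyCase:
    """Generate one phantom StudyCase; identical spec+seed is bit-identical."""
    rng = np.random.default_rng(spec.seed)
    kidney = _kidneys(spec, rng)
    cyst, complex_cyst = _place_cysts(spec, kidney, rng)
    fluid = _extrarenal_fluid(spec.grid_shape, spec.spacing, kidney, rng)
    img = render_intensity(
        kidney, cyst, complex_cyst, fluid, spec.fat_saturated, rng, spec.noise_sigma
    )
    case_id = spec.case_id or f"phantom-{spec.seed}"
    image = VoxelVolume(img, spec.spacing, case_id=case_id, fat_saturated=spec.fat_saturated)
    return StudyCase(
        image=image,
        kidney=BinaryMask(kidney.astype(np.uint8), spec.spacing, label_role="kidney"),
        cyst_by_source={
            "truth": BinaryMask(cyst.astype(np.uint8), spec.spacing, label_role="cyst")
        },
    )


def generate_cohort(
    n_cases: int,
    severity_range: tuple[float, float] = (0.005, 0.9),
    fat_sat_fraction: float = 0.7,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (64, 64, 16),
    spacing: tuple[float, float, float] = (1.5, 1.5, 3.0),
    noise_sigma: float = 30.0,
) -> list[StudyCase]:
    """Generate a cohort spanning the severity range.

    Cystic-index targets are evenly spread across ``severity_range`` and
    shuffled; exactly ``round(fat_sat_fraction * n_cases)`` cases are
    fat-saturated. Kidney size varies per case so TKV has a real distribution
    for stratification.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    lo, hi = severity_range
    if not (0 <= lo <= hi <= 1) or hi <= 0:
        raise ValueError(f"severity_range must be a non-empty interval in (0, 1], got {severity_range}")
    rng = np.random.default_rng(seed)
    if n_cases == 1:
        severities = np.array([0.5 * (lo + hi)])
    else:
        severities = np.linspace(lo, hi, n_cases)
        rng.shuffle(severities)
    n_fat = int(round(fat_sat_fraction * n_cases))
    fat_flags = np.zeros(n_cases, dtype=bool)
    fat_flags[:n_fat] = True
    rng.shuffle(fat_flags)
    seeds = rng.integers(0, 2**31 - 1, size=n_cases)
    scales = rng.uniform(0.8, 1.2, size=n_cases)
    cases = []
    for i in range(n_cases):
        spec = PhantomSpec(
            grid_shape=grid_shape,
            spacing=spacing,
            target_cystic_index=float(severities[i]),
            fat_saturated=bool(fat_flags[i]),
            noise_sigma=noise_sigma,
            kidney_scale=float(scales[i]),
            seed=int(seeds[i]),
            case_id=f"case-{i:03d}",
        )
        cases.append(generate_case(spec))
    return cases


def simulate_second_reader(
    truth: BinaryMask, perturbation_level: float, seed: int = 0
) -> BinaryMask:
    """Simulate an alternate manual tracing of the same structure.

    The truth boundary is displaced by a smooth random field: the mask is
    re-thresholded as ``signed_distance > level * field``, which erodes and
    dilates boundary voxels at random. Expected Dice against the truth
    decreases monotonically with ``perturbation_level``; level 0 returns the
    truth unchanged.
    """
    if perturbation_level < 0:
        raise ValueError("perturbation_level must be non-negative")
    m = truth.voxels.astype(bool)
    if perturbation_level == 0 or not m.any():
        return BinaryMask(truth.voxels.copy(), truth.spacing, label_role=truth.label_role)
    rng = np.random.default_rng(seed)
    inside = ndimage.distance_transform_edt(m)
    outside = ndimage.distance_transform_edt(~m)
    signed = inside - outside  # >0 inside, <0 outside, voxel units
    field = ndimage.gaussian_filter(rng.standard_normal(m.shape), sigma=2.0)
    field = field / max(field.std(), 1e-12)
    out = signed > perturbation_level * field
    return BinaryMask(out.astype(np.uint8), truth.spacing, label_role=truth.label_role)
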