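"""Digital thoracic CT phantoms with known ground truth.

No clinical data is required anywhere in this package: every stage of the
pipeline is validated against procedurally generated chest phantoms — an
elliptical soft-tissue body, two air-filled ellipsoidal lungs, a branching
vessel tree, parameterised interstitial disease patterns (septal sheets,
ground-glass blobs, consolidation blobs) and an optional organ-contact
indentation at the lung base that reproduces the "mask hole" geometry seen
on lower slices of real scans.  Paired ground-truth masks and the true
effective-ventilation fraction are recorded before noise is added.

The same module generates synthetic survival cohorts (ELVAR + outcome
columns) for the statistics layer.

Determinism: all randomness flows through ``numpy.random.default_rng(seed)``
(PCG64), so a spec + seed pair reproduces the phantom bit for bit on any
platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import BinaryMask, CTVolume

__all__ = [
    "VesselTreeSpec",
    "DiseaseSpec",
    "IndentationSpec",
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
]

# Pattern HU values sit inside conventional radiological ranges: thickened
# septa are soft-tissue-adjacent, ground glass is hazy (denser than aerated
# lung, vessels stay visible), consolidation is near water density.
PATTERN_HU = {"septal_sheet": -300.0, "ggo": -600.0, "consolidation": 20.0}


@dataclass
class VesselTreeSpec:
    """Procedural pulmonary vessel tree (one per lung)."""

    n_branches: int = 8
    radius_mm: tuple[float, float] = (1.0, 1.8)
    hu: float = 50.0


@dataclass
class DiseaseSpec:
    """Interstitial disease burden painted into the lungs.

    ``pattern_mix`` gives sampling weights over the three texture
    generators; ``target_fraction`` is the fraction of lung volume the
    disease must occupy (achieved to within ±0.01); ``peripheral_bias``
    confines lesion centres to the outer lung, matching the subpleural
    predominance of interstitial disease.
    """

    pattern_mix: dict[str, float] = field(
        default_factory=lambda: {"septal_sheet": 0.4, "ggo": 0.35, "consolidation": 0.25}
    )
    target_fraction: float = 0.0
    peripheral_bias: bool = True


@dataclass
class IndentationSpec:
    """Hemispheric organ contact at the lung base (diaphragm level)."""

    enabled: bool = False
    volume_mm3: float = 2000.0


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (40, 128, 128)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body_hu: float = 40.0
    lung_hu: float = -850.0
    air_hu: float = -1000.0
    vessel_tree: VesselTreeSpec = field(default_factory=VesselTreeSpec)
    disease: DiseaseSpec = field(default_factory=DiseaseSpec)
    organ_indentation: IndentationSpec = field(default_factory=IndentationSpec)
    noise_sigma_hu: float = 20.0
    count_vessels_in_truth: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.disease.target_fraction <= 0.5:
            raise ValueError("disease target_fraction must lie in [0, 0.5]")
        for hu in (self.body_hu, self.lung_hu, self.air_hu):
            if not -1024 <= hu <= 3071:
                raise ValueError(f"HU value {hu} outside [-1024, 3071]")


@dataclass
class PhantomTruth:
    """Ground truth recorded pre-noise; the oracle for L, I and ELVAR."""

    lung_mask_true: BinaryMask
    interstitium_mask_true: BinaryMask
    vessel_mask_true: BinaryMask
    disease_mask_true: BinaryMask
    indentation_mask: BinaryMask
    true_elvar: float
    spec: PhantomSpec

    @property
    def L_true(self) -> int:
        return self.lung_mask_true.popcount()

    @property
    def I_true(self) -> int:
        return self.interstitium_mask_true.popcount()


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _ellipsoid(shape, center, semi) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _paint_ball(mask: np.ndarray, center, radius) -> None:
    """Set voxels within ``radius`` of ``center`` (in voxel units), in place."""
    lo = [max(0, int(np.floor(c - radius)) - 1) for c in center]
    hi = [min(s, int(np.ceil(c + radius)) + 2) for c, s in zip(center, mask.shape)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    zz, yy, xx = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    ball = (
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    ) <= radius**2
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= ball


def _paint_tube(mask: np.ndarray, start, end, radius) -> None:
    start, end = np.asarray(start, float), np.asarray(end, float)
    length = float(np.linalg.norm(end - start))
    n_steps = max(2, int(np.ceil(length / 0.5)))
    for t in np.linspace(0.0, 1.0, n_steps):
        _paint_ball(mask, start + t * (end - start), radius)


def _lung_geometry(shape):
    """Centres and semi-axes of body ellipse and the two lung ellipsoids."""
    ns, nr, nc = shape
    body_center = (nr / 2.0, nc / 2.0)
    body_semi = (0.72 * nr / 2.0, 0.9 * nc / 2.0)
    lung_center_s = 0.475 * ns
    lung_semi = (0.375 * ns, 0.25 * nr, 0.16 * nc)
    lateral_offset = 0.235 * nc
    centers = [
        (lung_center_s, nr / 2.0, nc / 2.0 - lateral_offset),
        (lung_center_s, nr / 2.0, nc / 2.0 + lateral_offset),
    ]
    return body_center, body_semi, centers, lung_semi


def _grow_vessel_tree(
    rng: np.random.Generator,
    lung_interior: np.ndarray,
    center,
    semi,
    vt: VesselTreeSpec,
    medial_sign: float,
) -> np.ndarray:
    """Grow a connected tree of tapering tubes from a hilum-side root."""
    vessels = np.zeros_like(lung_interior)
    if vt.n_branches <= 0:
        return vessels
    r_min, r_max = vt.radius_mm
    root = np.array([center[0], center[1], center[2] + medial_sign * 0.45 * semi[2]])
    trunk_dir = np.array([0.0, 0.0, -medial_sign])
    segments = []  # (start, end, radius)
    for i in range(vt.n_branches):
        if not segments:
            start, direction, radius = root, trunk_dir, r_max
            length = 0.45 * semi[2]
        else:
            parent = segments[rng.integers(len(segments))]
            t = rng.uniform(0.3, 1.0)
            start = parent[0] + t * (parent[1] - parent[0])
            direction = rng.normal(size=3)
            direction[0] *= 0.6  # vessels run mostly in-plane
            direction /= np.linalg.norm(direction)
            radius = max(r_min, parent[2] * rng.uniform(0.7, 0.9))
            length = rng.uniform(8.0, 0.8 * semi[1])
        end = start + length * direction
        segments.append((start, end, radius))
        _paint_tube(vessels, start, end, radius)
    vessels &= lung_interior
    return vessels


def _sample_lesion_center(rng, centers, semi, peripheral: bool):
    """Uniform point inside a random lung, optionally confined to the outer shell."""
    lo, hi = (0.55, 0.92) if peripheral else (0.0, 0.92)
    for _ in range(200):
        c = centers[rng.integers(2)]
        u = rng.uniform(-1, 1, size=3)
        rho = float(np.linalg.norm(u))
        if lo <= rho <= hi:
            return np.array(c) + u * np.array(semi)
    # extremely unlikely; fall back to a shell point on the first lung
    u = rng.normal(size=3)
    u *= 0.75 / np.linalg.norm(u)
    return np.array(centers[0]) + u * np.array(semi)


def _paint_sheet(mask, center, normal, radius) -> None:
    """1-voxel-thick disk: |(x-c)·n| <= 0.5 within ``radius`` of the centre."""
    r = int(np.ceil(radius)) + 1
    lo = [max(0, int(c) - r) for c in center]
    hi = [min(s, int(c) + r + 1) for c, s in zip(center, mask.shape)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    zz, yy, xx = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    dz, dy, dx = zz - center[0], yy - center[1], xx - center[2]
    plane_dist = np.abs(dz * normal[0] + dy * normal[1] + dx * normal[2])
    in_disk = (plane_dist <= 0.5) & (dz**2 + dy**2 + dx**2 <= radius**2)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= in_disk


def _paint_disease(
    rng: np.random.Generator,
    spec: PhantomSpec,
    lung_interior: np.ndarray,
    centers,
    semi,
    L: int,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Add lesions until the occupied lung fraction is within ±0.01 of target."""
    target = spec.disease.target_fraction
    disease = np.zeros_like(lung_interior)
    per_pattern = {k: np.zeros_like(lung_interior) for k in PATTERN_HU}
    if target <= 0:
        return disease, per_pattern
    names = list(spec.disease.pattern_mix)
    weights = np.array([spec.disease.pattern_mix[k] for k in names], float)
    weights /= weights.sum()
    tol = 0.0095
    for _ in range(20000):
        frac = disease.sum() / L
        deficit = target - frac
        if abs(deficit) <= tol:
            break
        pattern = names[rng.choice(len(names), p=weights)]
        center = _sample_lesion_center(rng, centers, semi, spec.disease.peripheral_bias)
        if pattern == "septal_sheet":
            normal = rng.normal(size=3)
            normal /= np.linalg.norm(normal)
            radius = rng.uniform(5.0, 12.0)
        else:
            radius = rng.uniform(3.0, 8.0) if pattern == "ggo" else rng.uniform(3.0, 7.0)
        # shrink the element if it would overshoot the tolerance band
        for _attempt in range(12):
            stamp = np.zeros_like(lung_interior)
            if pattern == "septal_sheet":
                _paint_sheet(stamp, center, normal, radius)
            else:
                _paint_ball(stamp, center, radius)
            stamp &= lung_interior & ~disease
            added = stamp.sum()
            if added == 0:
                break
            if (frac + added / L) <= target + tol:
                disease |= stamp
                per_pattern[pattern] |= stamp
                break
            radius *= 0.7
            if radius < 1.2:
                break
    else:
        raise RuntimeError("disease painting did not converge")
    if abs(disease.sum() / L - target) > 0.01:
        raise ValueError(
            f"could not reach disease fraction {target:.3f} "
            f"(achieved {disease.sum() / L:.3f}) in this lung volume"
        )
    return disease, per_pattern


def _paint_indentation(
    lungs: np.ndarray, centers, semi, volume_mm3: float, vox_mm3: float
) -> np.ndarray:
    """Hemispheric organ bulge into the base of the first lung.

    The sphere is centred on the caudal lung surface so its upper half
    indents the lung while its lower half merges with the body tissue
    below — exactly the geometry that creates an enclosed dense 'hole' on
    axial slices that is nevertheless organ-connected in 3-D.
    """
    c = centers[0]
    pole = np.array([c[0] + semi[0] * 0.95, c[1], c[2]])
    target_vox = volume_mm3 / vox_mm3
    lo_r, hi_r = 1.0, float(max(semi))
    for _ in range(40):  # bisect on radius of the in-lung cap
        r = 0.5 * (lo_r + hi_r)
        stamp = np.zeros_like(lungs)
        _paint_ball(stamp, pole, r)
        inside = (stamp & lungs).sum()
        if inside < target_vox:
            lo_r = r
        else:
            hi_r = r
    stamp = np.zeros_like(lungs)
    _paint_ball(stamp, pole, hi_r)
    return stamp & lungs


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Build a thoracic phantom volume and its paired ground truth.

    Construction order: body → lung cavities → vessel trees → disease
    patterns (until the target burden is met to ±0.01) → optional organ
    indentation → Gaussian HU noise.  Truth masks are recorded pre-noise;
    ``true_elvar = (L − I)/L`` with I counting disease plus (by default)
    vessels.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    vox_mm3 = float(np.prod(spec.spacing_mm))

    body_center, body_semi, centers, semi = _lung_geometry(shape)
    yy, xx = np.ogrid[: shape[1], : shape[2]]
    body2d = (
        ((yy - body_center[0]) / body_semi[0]) ** 2
        + ((xx - body_center[1]) / body_semi[1]) ** 2
    ) <= 1.0
    body = np.broadcast_to(body2d, shape).copy()

    lungs = _ellipsoid(shape, centers[0], semi) | _ellipsoid(shape, centers[1], semi)
    lungs &= body

    if spec.organ_indentation.enabled:
        indentation = _paint_indentation(
            lungs, centers, semi, spec.organ_indentation.volume_mm3, vox_mm3
        )
    else:
        indentation = np.zeros(shape, dtype=bool)

    # keep vessels and lesions clear of the pleural and organ surfaces so
    # dense structures do not merge with extra-pulmonary tissue
    # (subpleural but not transpleural)
    lung_interior = ndimage.binary_erosion(lungs, iterations=2)
    if indentation.any():
        lung_interior &= ~ndimage.binary_dilation(indentation, iterations=2)

    vessels = _grow_vessel_tree(rng, lung_interior, centers[0], semi, spec.vessel_tree, +1.0)
    vessels |= _grow_vessel_tree(rng, lung_interior, centers[1], semi, spec.vessel_tree, -1.0)

    L_all = int((lungs & ~indentation).sum())
    disease, per_pattern = _paint_disease(rng, spec, lung_interior, centers, semi, L_all)

    vol_data = np.full(shape, spec.air_hu, dtype=np.float32)
    vol_data[body] = spec.body_hu
    vol_data[lungs] = spec.lung_hu
    vol_data[vessels] = spec.vessel_tree.hu
    for name, m in per_pattern.items():
        vol_data[m] = PATTERN_HU[name]
    vol_data[indentation] = spec.body_hu

    lung_true = lungs & ~indentation
    vessels &= lung_true
    disease &= lung_true
    interstitium = disease | vessels if spec.count_vessels_in_truth else disease.copy()

    if spec.noise_sigma_hu > 0:
        vol_data += rng.normal(0.0, spec.noise_sigma_hu, size=shape).astype(np.float32)

    vol = CTVolume(
        data=vol_data,
        spacing=spec.spacing_mm,
        source_meta={"phantom_seed": spec.seed, "synthetic": True},
    )
    L_true = int(lung_true.sum())
    I_true = int(interstitium.sum())
    truth = PhantomTruth(
        lung_mask_true=vol.new_mask(lung_true, "lung_final"),
        interstitium_mask_true=vol.new_mask(interstitium, "interstitium"),
        vessel_mask_true=vol.new_mask(vessels, "interstitium"),
        disease_mask_true=vol.new_mask(disease, "interstitium"),
        indentation_mask=vol.new_mask(indentation, "hole"),
        true_elvar=(L_true - I_true) / L_true if L_true else float("nan"),
        spec=spec,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# synthetic survival cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Two-group synthetic cohort: ELVAR scores plus right-censored outcomes.

    Defaults emulate the structure of a rapidly-progressive-ILD cohort
    split at an ELVAR cutoff: the low-ELVAR group has a high early hazard
    concentrated in the first three months, the high-ELVAR group a low,
    roughly constant hazard.  ``elvar_dist_*`` is (median, IQR width);
    scores are drawn from a clipped normal with matching quartile spread.
    ``hazard_*`` is a piecewise-constant hazard: list of
    (start_month, hazard per month) with the last piece open-ended.
    """

    n_per_group: int = 28
    elvar_dist_low: tuple[float, float] = (0.7893, 0.0701)
    elvar_dist_high: tuple[float, float] = (0.8823, 0.0387)
    hazard_low: tuple[tuple[float, float], ...] = ((0.0, 0.26), (3.0, 0.0))
    hazard_high: tuple[tuple[float, float], ...] = ((0.0, 0.034), (3.0, 0.004))
    follow_up_months: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        for med, _ in (self.elvar_dist_low, self.elvar_dist_high):
            if not 0.0 <= med <= 1.0:
                raise ValueError("group medians must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")


def _sample_piecewise_exponential(rng, pieces, n) -> np.ndarray:
    """Event times for a piecewise-constant hazard via cumulative-hazard inversion."""
    starts = np.array([p[0] for p in pieces], float)
    rates = np.array([p[1] for p in pieces], float)
    targets = -np.log(rng.uniform(size=n))  # required cumulative hazard
    times = np.full(n, np.inf)
    acc = np.zeros(n)
    for i, (t0, lam) in enumerate(zip(starts, rates)):
        t1 = starts[i + 1] if i + 1 < len(starts) else np.inf
        width = t1 - t0
        seg = lam * width if lam > 0 else 0.0  # open-ended piece: 0 * inf guard
        unfinished = np.isinf(times)
        if lam > 0:
            reach = unfinished & (acc + seg >= targets)
            times[reach] = t0 + (targets[reach] - acc[reach]) / lam
        acc = acc + (seg if np.isfinite(seg) else 0.0)
    return times


def generate_cohort(cs: CohortSpec) -> pd.DataFrame:
    """Simulate a two-group cohort table.

    Returns a DataFrame with columns ``id, group, elvar,
    event_time_months, event_flag``; subjects alive at the end of
    follow-up are censored there.
    """
    rng = np.random.default_rng(cs.seed)
    frames = []
    for group, (med, iqr), hazard in (
        ("low_elvar", cs.elvar_dist_low, cs.hazard_low),
        ("high_elvar", cs.elvar_dist_high, cs.hazard_high),
    ):
        sigma = iqr / 1.3489795  # normal IQR = 2*Phi^-1(0.75)*sigma
        elvar = np.clip(rng.normal(med, sigma, size=cs.n_per_group), 0.0, 1.0)
        t_event = _sample_piecewise_exponential(rng, hazard, cs.n_per_group)
        event = t_event <= cs.follow_up_months
        t_obs = np.minimum(t_event, cs.follow_up_months)
        frames.append(
            pd.DataFrame(
                {
                    "group": group,
                    "elvar": elvar,
                    "event_time_months": t_obs,
                    "event_flag": event,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "id", [f"S{i:04d}" for i in range(len(table))])
    return table
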