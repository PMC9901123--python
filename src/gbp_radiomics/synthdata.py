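"""Synthetic dual-modality (B-mode + SMI) gallbladder-polyp phantom cohorts.

Real dual-modality frames of gallbladder polypoid lesions are not publicly
deposited, so this module renders a statistically calibrated stand-in cohort:
speckled elliptical-to-irregular lesions on a darker lumen background in the
B-mode panel, optional curvilinear microvascular tracks in the SMI panel, and
simulated repeat delineations by two observers.  Class-conditional defaults
(prevalence 71:29, lesion diameters 13 mm [8-21] vs 17 mm [8-28], vascular
signal in 38/71 vs 26/29 lesions) follow the published clinical cohort this
pipeline models; rendering parameters without a published value (echo means,
speckle shape, hyperechoic-spot density, boundary roughness) are frozen
phantom choices documented in ``docs/methods.md``.

Speckle is multiplicative unit-mean gamma noise on a class-mean intensity
field -- the standard first-order approximation of fully developed ultrasound
speckle, sufficient for histogram and co-occurrence statistics.  No beam
physics (PSF, attenuation, scan conversion) is simulated.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter, gaussian_filter1d

CHOLESTEROL = "cholesterol"
NEOPLASTIC = "neoplastic"
LABELS = (CHOLESTEROL, NEOPLASTIC)

#: delineation keys the analysis expects: observer A twice, observer B once
DELINEATION_KEYS: Tuple[Tuple[str, int], ...] = (("A", 1), ("A", 2), ("B", 1))


class SpecValidationError(ValueError):
    """A cohort specification field violates its invariant."""


@dataclass(frozen=True)
class ClassParams:
    """Per-class rendering parameters.

    diameter_mm: (min, median, max) of the lesion diameter in mm; sampled
        from a triangular distribution with the median as mode.
    vascular_prob: probability that the SMI panel shows vessel signal.
    echo_mean: mean B-mode intensity of the lesion interior (8-bit scale).
    speckle_shape: gamma shape of the multiplicative speckle (higher = more
        homogeneous interior).
    spot_density: expected hyperechoic punctate spots per lesion pixel.
    shape_irregularity: relative amplitude of the low-order Fourier radial
        perturbation of the lesion boundary (0 = exact ellipse).
    """

    diameter_mm: Tuple[float, float, float]
    vascular_prob: float
    echo_mean: float
    speckle_shape: float
    spot_density: float
    shape_irregularity: float


#: defaults calibrated to the clinical cohort's class statistics; phantom-only
#: parameters (echo/speckle/spots) encode the reported qualitative contrast:
#: cholesterol polyps carry internal hyperechoic foci and a more heterogeneous
#: interior, neoplastic polyps are larger, more irregular and more homogeneous.
DEFAULT_CLASS_PARAMS: Dict[str, ClassParams] = {
    CHOLESTEROL: ClassParams(
        diameter_mm=(8.0, 13.0, 21.0),
        vascular_prob=38.0 / 71.0,
        echo_mean=115.0,
        speckle_shape=5.0,
        spot_density=0.015,
        shape_irregularity=0.04,
    ),
    NEOPLASTIC: ClassParams(
        diameter_mm=(8.0, 17.0, 28.0),
        vascular_prob=26.0 / 29.0,
        echo_mean=95.0,
        speckle_shape=12.0,
        spot_density=0.001,
        shape_irregularity=0.12,
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort.

    The defaults emulate the 100-lesion clinical cohort (71 cholesterol /
    29 neoplastic) at 256x256 px and 0.2 mm/px (51.2 mm field of view), which
    keeps 8-28 mm lesions both well resolved (>= 40 px across) and fully
    inside the frame while fast to process.
    """

    n_lesions: int = 100
    n_neoplastic: int = 29
    seed: int = 0
    image_size: int = 256
    pixel_spacing: float = 0.2
    class_params: Dict[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    jitter_px: float = 1.5
    n_contour_vertices: int = 180

    def validate(self) -> None:
        if self.n_lesions < 0:
            raise SpecValidationError("n_lesions must be >= 0")
        if not 0 <= self.n_neoplastic <= self.n_lesions:
            raise SpecValidationError(
                "n_neoplastic must satisfy 0 <= n_neoplastic <= n_lesions"
            )
        if self.image_size < 32:
            raise SpecValidationError("image_size must be >= 32 px")
        if self.pixel_spacing <= 0:
            raise SpecValidationError("pixel_spacing must be positive")
        if self.jitter_px < 0:
            raise SpecValidationError("jitter_px must be non-negative")
        for label in LABELS:
            if label not in self.class_params:
                raise SpecValidationError(f"class_params missing class {label!r}")
            p = self.class_params[label]
            lo, med, hi = p.diameter_mm
            if not (0 < lo <= med <= hi):
                raise SpecValidationError(
                    f"diameter_mm for {label!r} must satisfy 0 < min <= median <= max"
                )
            if not 0.0 <= p.vascular_prob <= 1.0:
                raise SpecValidationError(
                    f"vascular_prob for {label!r} must be in [0, 1]"
                )
            if p.speckle_shape <= 0:
                raise SpecValidationError(f"speckle_shape for {label!r} must be > 0")
            if p.spot_density < 0:
                raise SpecValidationError(f"spot_density for {label!r} must be >= 0")
            if p.shape_irregularity < 0 or p.shape_irregularity >= 0.5:
                raise SpecValidationError(
                    f"shape_irregularity for {label!r} must be in [0, 0.5)"
                )


@dataclass
class DualModalCase:
    """One lesion's paired B-mode and SMI panels plus contours and label.

    Contours are ordered (x=column, y=row) float vertex arrays in 0-based
    pixel coordinates, implicitly closed (last vertex connects to first),
    simple, and strictly inside the image bounds.  The two panels are
    co-registered: ``smi_offset`` is the (dx, dy) translation mapping B-mode
    coordinates onto the SMI panel (0, 0 for these phantoms).
    """

    case_id: str
    label: str
    bmode: np.ndarray
    smi: np.ndarray
    true_contour: np.ndarray
    observer_contours: Dict[Tuple[str, int], np.ndarray] = field(default_factory=dict)
    diameter_mm: float = float("nan")
    vascular: bool = False
    smi_offset: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.bmode.shape != self.smi.shape:
            raise ValueError("bmode and smi panels must have identical dimensions")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def _child_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-purpose child generator derived from (seed, tag)."""
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _lesion_radius_profile(
    base_radius_px: float,
    irregularity: float,
    aspect: float,
    angles: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Radius at each boundary angle: ellipse plus low-order Fourier ripple."""
    # ellipse with semi-axes a = r*aspect, b = r/aspect
    a = base_radius_px * aspect
    b = base_radius_px / aspect
    r = a * b / np.sqrt((b * np.cos(angles)) ** 2 + (a * np.sin(angles)) ** 2)
    if irregularity > 0:
        for k in (2, 3, 4, 5):
            amp = irregularity * base_radius_px * rng.uniform(0.2, 1.0) / k
            phase = rng.uniform(0, 2 * np.pi)
            r = r + amp * np.cos(k * angles + phase)
    return np.maximum(r, 2.0)


def _fill_radial_contour(
    center: Tuple[float, float], angles: np.ndarray, radii: np.ndarray, shape: Tuple[int, int]
) -> np.ndarray:
    """Boolean mask of pixels whose center lies inside the radial contour.

    Star-shaped region: a pixel is inside iff its distance to the center is
    below the (interpolated) boundary radius at its polar angle.
    """
    cx, cy = center
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)
    rr = np.hypot(xx - cx, yy - cy)
    bound = np.interp(theta, angles, radii, period=2 * np.pi)
    return rr < bound


def render_lesion(
    label: str,
    diameter_mm: float,
    spec: CohortSpec,
    seed: int,
    case_id: str | None = None,
    vascular: bool | None = None,
) -> DualModalCase:
    """Render one dual-modality phantom case.

    The B-mode panel holds a speckled lesion (multiplicative unit-mean gamma
    speckle on the class echo mean) on a darker lumen background; cholesterol
    lesions additionally carry bright punctate hyperechoic spots.  Vascular
    cases carry curvilinear bright vessel tracks in the SMI panel within the
    lesion.  ``true_contour`` traces the rendered boundary.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    params = spec.class_params[label]
    radius_px = diameter_mm / 2.0 / spec.pixel_spacing
    n = spec.image_size
    if 2 * radius_px > 0.7 * n:
        raise ValueError(
            f"diameter {diameter_mm} mm exceeds the usable image extent "
            f"({n} px at {spec.pixel_spacing} mm/px)"
        )
    rng = _child_rng(seed, f"render:{case_id or label}")

    margin = radius_px * 1.3 + 8
    cx = rng.uniform(margin, n - margin)
    cy = rng.uniform(margin, n - margin)
    aspect = rng.uniform(1.0, 1.25)

    angles = np.linspace(0, 2 * np.pi, spec.n_contour_vertices, endpoint=False)
    radii = _lesion_radius_profile(radius_px, params.shape_irregularity, aspect, angles, rng)
    contour = np.column_stack(
        [cx + radii * np.cos(angles), cy + radii * np.sin(angles)]
    )
    lesion = _fill_radial_contour((cx, cy), angles, radii, (n, n))

    # B-mode: lumen background + lesion interior, both speckled
    background_mean = 30.0
    mean_field = np.full((n, n), background_mean)
    mean_field[lesion] = params.echo_mean
    # soften the wall transition slightly so the edge is not a hard step
    mean_field = gaussian_filter(mean_field, sigma=1.0)
    shape_map = np.full((n, n), 4.0)
    shape_map[lesion] = params.speckle_shape
    speckle = rng.gamma(shape=shape_map, scale=1.0 / shape_map)
    bmode = mean_field * speckle

    if params.spot_density > 0:
        n_spots = rng.poisson(params.spot_density * lesion.sum())
        if n_spots > 0:
            ys, xs = np.nonzero(lesion)
            pick = rng.integers(0, len(xs), size=n_spots)
            spots = np.zeros((n, n))
            spots[ys[pick], xs[pick]] = rng.uniform(60.0, 140.0, size=n_spots)
            # blur to ~1.2 px foci; rescale so each focus peaks near its
            # drawn amplitude (delta response of the gaussian is 1/(2*pi*s^2))
            bmode = bmode + gaussian_filter(spots, sigma=1.2) * (2 * np.pi * 1.2**2)

    bmode = np.clip(bmode, 0, 255).astype(np.uint8)

    # SMI: dark flow panel; lesion interior at/below background unless vascular
    smi_mean = np.full((n, n), 25.0)
    smi_mean[lesion] = 18.0
    smi_speckle = rng.gamma(shape=4.0, scale=0.25, size=(n, n))
    smi = smi_mean * smi_speckle
    is_vascular = (
        bool(rng.random() < params.vascular_prob) if vascular is None else bool(vascular)
    )
    if is_vascular:
        smi = smi + _vessel_tracks(lesion, (cx, cy), radius_px, rng, (n, n))
    smi = np.clip(smi, 0, 255).astype(np.uint8)

    return DualModalCase(
        case_id=case_id or f"case_{label}_{seed}",
        label=label,
        bmode=bmode,
        smi=smi,
        true_contour=contour,
        diameter_mm=float(diameter_mm),
        vascular=is_vascular,
    )


def _vessel_tracks(
    lesion: np.ndarray,
    center: Tuple[float, float],
    radius_px: float,
    rng: np.random.Generator,
    shape: Tuple[int, int],
) -> np.ndarray:
    """Bright curvilinear tracks (random walks, 1-3 px wide) within the lesion."""
    h, w = shape
    canvas = np.zeros(shape)
    n_tracks = int(rng.integers(1, 4))
    for _ in range(n_tracks):
        # start near the lesion boundary or center, walk with inertia
        ang = rng.uniform(0, 2 * np.pi)
        x = center[0] + rng.uniform(0, 0.6) * radius_px * np.cos(ang)
        y = center[1] + rng.uniform(0, 0.6) * radius_px * np.sin(ang)
        heading = rng.uniform(0, 2 * np.pi)
        n_steps = int(max(10, radius_px * rng.uniform(1.0, 2.5)))
        for _ in range(n_steps):
            heading += rng.normal(0, 0.35)
            x += np.cos(heading)
            y += np.sin(heading)
            xi, yi = int(round(x)), int(round(y))
            if not (0 <= xi < w and 0 <= yi < h):
                break
            if not lesion[min(max(yi, 0), h - 1), min(max(xi, 0), w - 1)]:
                # stay within or immediately adjacent to the lesion
                if rng.random() < 0.5:
                    break
            canvas[yi, xi] = rng.uniform(150.0, 220.0)
    width_sigma = rng.uniform(0.4, 1.0)  # 1-3 px apparent width after blurring
    return gaussian_filter(canvas, sigma=width_sigma) * (2 * np.pi * width_sigma**2)


def simulate_delineations(
    case: DualModalCase, jitter_px: float, seed: int
) -> DualModalCase:
    """Populate the three observer delineations (A,1), (A,2), (B,1).

    Each contour is the true contour displaced radially by a smooth correlated
    noise field over vertex angle (Gaussian-smoothed white noise, circular),
    scaled so the mean absolute radial deviation equals ``jitter_px`` --
    observers err smoothly, not per-vertex independently.
    """
    if jitter_px < 0:
        raise ValueError("jitter_px must be non-negative")
    if case.true_contour is None or len(case.true_contour) < 3:
        raise ValueError("case has no true_contour to perturb")
    contour = np.asarray(case.true_contour, dtype=float)
    center = contour.mean(axis=0)
    rel = contour - center
    radii = np.hypot(rel[:, 0], rel[:, 1])
    unit = rel / radii[:, None]
    n_img = case.bmode.shape[0]

    case.observer_contours = {}
    for key in DELINEATION_KEYS:
        if jitter_px == 0:
            case.observer_contours[key] = contour.copy()
            continue
        rng = _child_rng(seed, f"delineate:{case.case_id}:{key[0]}:{key[1]}")
        noise = rng.normal(0.0, 1.0, size=len(contour))
        noise = gaussian_filter1d(noise, sigma=len(contour) / 24.0, mode="wrap")
        sd = noise.std()
        if sd > 0:
            # unit-variance smooth field; sigma chosen so E|dr| = jitter_px
            noise = noise / sd * jitter_px * np.sqrt(np.pi / 2.0)
        new_r = np.clip(radii + noise, 2.0, None)
        pts = center + unit * new_r[:, None]
        pts[:, 0] = np.clip(pts[:, 0], 1.0, n_img - 2.0)
        pts[:, 1] = np.clip(pts[:, 1], 1.0, n_img - 2.0)
        case.observer_contours[key] = pts
    return case


def generate_cohort(spec: CohortSpec) -> List[DualModalCase]:
    """Generate the full synthetic cohort described by ``spec``.

    Returns exactly ``spec.n_lesions`` cases with exactly ``spec.n_neoplastic``
    neoplastic labels, in a seed-determined shuffled order, each carrying the
    three simulated observer delineations.
    """
    spec.validate()
    if spec.n_lesions == 0:
        return []
    labels = np.array(
        [NEOPLASTIC] * spec.n_neoplastic
        + [CHOLESTEROL] * (spec.n_lesions - spec.n_neoplastic)
    )
    order_rng = _child_rng(spec.seed, "label-order")
    order_rng.shuffle(labels)

    cases: List[DualModalCase] = []
    for i, label in enumerate(labels):
        params = spec.class_params[label]
        lo, med, hi = params.diameter_mm
        size_rng = _child_rng(spec.seed, f"size:{i}")
        diameter = (
            float(size_rng.triangular(lo, med, hi)) if hi > lo else float(med)
        )
        case = render_lesion(
            label,
            diameter,
            spec,
            seed=spec.seed,
            case_id=f"case{i:03d}",
        )
        simulate_delineations(case, spec.jitter_px, seed=spec.seed)
        cases.append(case)
    return cases


# ---------------------------------------------------------------------------
# on-disk representation: PNG image pairs, JSON contours, CSV labels


def save_cohort(cases: List[DualModalCase], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        Image.fromarray(case.bmode).save(out / f"{case.case_id}_bmode.png")
        Image.fromarray(case.smi).save(out / f"{case.case_id}_smi.png")
        contours = [
            {
                "observer": obs,
                "rep": rep,
                "vertices": np.asarray(v).tolist(),
            }
            for (obs, rep), v in sorted(case.observer_contours.items())
        ]
        payload = {
            "case_id": case.case_id,
            "true_contour": np.asarray(case.true_contour).tolist(),
            "smi_offset": list(case.smi_offset),
            "delineations": contours,
        }
        (out / f"{case.case_id}_contours.json").write_text(
            json.dumps(payload, indent=None, separators=(",", ":"))
        )
        rows.append((case.case_id, case.label))
    with open(out / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "label"])
        writer.writerows(rows)


def load_cohort(data_dir: str | Path) -> List[DualModalCase]:
    data = Path(data_dir)
    cases = []
    with open(data / "labels.csv", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            cid, label = row["case_id"], row["label"]
            bmode = np.asarray(Image.open(data / f"{cid}_bmode.png"))
            smi = np.asarray(Image.open(data / f"{cid}_smi.png"))
            payload = json.loads((data / f"{cid}_contours.json").read_text())
            case = DualModalCase(
                case_id=cid,
                label=label,
                bmode=bmode,
                smi=smi,
                true_contour=np.asarray(payload["true_contour"], dtype=float),
                smi_offset=tuple(payload.get("smi_offset", (0.0, 0.0))),
            )
            for d in payload["delineations"]:
                case.observer_contours[(d["observer"], int(d["rep"]))] = np.asarray(
                    d["vertices"], dtype=float
                )
            cases.append(case)
    return cases
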