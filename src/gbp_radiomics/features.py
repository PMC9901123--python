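"""Radiomic feature bank: first-order, GLCM, binary-texture and morphology.

Per modality the spatial bank holds exactly 91 features:

* 28 first-order statistics of the within-lesion histogram (including the
  lesion/reference-band intensity ratios RImean and RImedian),
* 60 gray-level co-occurrence (GLCM) statistics — energy, contrast, entropy
  and homogeneity at every integer offset d = 1..15,
* 3 binary-texture features of the bright (high-intensity) sub-region:
  area ratio AR, center deviation degree CDD and dispersion degree DD.

Morphology adds 15 shape features computed once from the B-mode mask (the
lesion geometry is identical in both co-registered panels).  A B-mode vector
therefore has 106 features, an SMI vector 91, and the dual-modality table 197
columns with ``_B``/``_SMI`` suffixes.

Frozen numerical conventions (required for exact regression tests): GLCM uses
32 gray levels quantized over the within-lesion min-max range, symmetric
matrices averaged over the four directions 0/45/90/135 degrees, counting only
pixel pairs with both ends inside the lesion; entropies use log base 2 with
0*log(0) = 0; skewness and kurtosis are the population Fisher definitions;
CDD and DD are normalized by the lesion's equivalent radius sqrt(area/pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .preprocess import LesionMask, build_lesion_mask, map_to_smi
from .synthdata import DualModalCase

GLCM_OFFSETS: Tuple[int, ...] = tuple(range(1, 16))
GLCM_LEVELS = 32
HIST_BINS = 32

FIRST_ORDER_NAMES: Tuple[str, ...] = (
    # the nine canonical members
    "IMean", "IMedian", "Std_I", "CoV", "Entropy", "Skewness", "Kurtosis",
    "RImean", "RImedian",
    # frozen extension set (documented in docs/methods.md)
    "IMin", "IMax", "IRange", "P10", "P25", "P75", "P90", "IQR", "MAD",
    "RMS", "Energy", "Uniformity", "rMAD", "Variance", "PRange90_10",
    "RefMean", "RefStd", "MeanDiff", "StdRatio",
)

GLCM_STAT_NAMES: Tuple[str, ...] = ("Ener", "Cont", "Entr", "Homo")
GLCM_FEATURE_NAMES: Tuple[str, ...] = tuple(
    f"{stat}{d}" for stat in GLCM_STAT_NAMES for d in GLCM_OFFSETS
)
BINARY_TEXTURE_NAMES: Tuple[str, ...] = ("AR", "CDD", "DD")
SPATIAL_NAMES: Tuple[str, ...] = FIRST_ORDER_NAMES + GLCM_FEATURE_NAMES + BINARY_TEXTURE_NAMES

MORPHOLOGY_NAMES: Tuple[str, ...] = (
    "Area", "C.area", "Maj.Len", "Min.Len", "Perimeter", "Circularity",
    "Solidity", "Eccentricity", "Extent", "AspectRatio", "EqDiameter",
    "C.perimeter", "Convexity", "BBoxW", "BBoxH",
)

assert len(SPATIAL_NAMES) == 91
assert len(MORPHOLOGY_NAMES) == 15


@dataclass
class FeatureVector:
    case_id: str
    modality: str  # "B" or "SMI"
    values: Dict[str, float]
    provenance: Tuple[str, int]  # (observer, repetition)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def first_order(
    image: np.ndarray, lesion_mask: np.ndarray, ref_band: np.ndarray
) -> Dict[str, float]:
    """The 28 first-order statistics of the within-lesion intensities."""
    img = np.asarray(image, dtype=float)
    x = img[lesion_mask]
    ref = img[ref_band]
    if x.size == 0:
        raise ValueError("lesion mask is empty")
    if ref.size == 0:
        raise ValueError("reference band is empty")

    mean = float(x.mean())
    if mean == 0:
        raise ValueError("zero mean lesion intensity: CoV undefined")
    ref_mean = float(ref.mean())
    if ref_mean == 0:
        raise ValueError("zero mean reference intensity: RImean undefined")
    ref_median = float(np.median(ref))
    if ref_median == 0:
        raise ValueError("zero median reference intensity: RImedian undefined")
    sd = float(x.std())  # population
    variance = float(x.var())
    median = float(np.median(x))

    hist, _ = np.histogram(x, bins=HIST_BINS, range=(0, 255))
    p = hist / hist.sum()

    if sd > 0:
        z = (x - mean) / sd
        skewness = float(np.mean(z**3))
        kurtosis = float(np.mean(z**4) - 3.0)  # Fisher excess
    else:
        skewness = 0.0
        kurtosis = 0.0

    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))
    core = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(core - core.mean()).mean()) if core.size else 0.0
    ref_sd = float(ref.std())

    values = {
        "IMean": mean,
        "IMedian": median,
        "Std_I": sd,
        "CoV": sd / mean,
        "Entropy": _entropy_bits(p),
        "Skewness": skewness,
        "Kurtosis": kurtosis,
        "RImean": mean / ref_mean,
        "RImedian": median / ref_median,
        "IMin": float(x.min()),
        "IMax": float(x.max()),
        "IRange": float(x.max() - x.min()),
        "P10": p10,
        "P25": p25,
        "P75": p75,
        "P90": p90,
        "IQR": p75 - p25,
        "MAD": float(np.abs(x - mean).mean()),
        "RMS": float(np.sqrt(np.mean(x**2))),
        "Energy": float(np.sum(x**2)),
        "Uniformity": float(np.sum(p**2)),
        "rMAD": rmad,
        "Variance": variance,
        "PRange90_10": p90 - p10,
        "RefMean": ref_mean,
        "RefStd": ref_sd,
        "MeanDiff": mean - ref_mean,
        "StdRatio": sd / ref_sd if ref_sd > 0 else 0.0,
    }
    return values


def quantize(image: np.ndarray, lesion_mask: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Quantize within-lesion intensities to ``levels`` bins over their min-max.

    Returns an int array with -1 outside the lesion.  A constant lesion maps
    to level 0 everywhere inside.
    """
    img = np.asarray(image, dtype=float)
    out = np.full(img.shape, -1, dtype=np.int32)
    vals = img[lesion_mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax > vmin:
        q = np.floor((img - vmin) / (vmax - vmin) * levels).astype(np.int32)
        q = np.clip(q, 0, levels - 1)
    else:
        q = np.zeros(img.shape, dtype=np.int32)
    out[lesion_mask] = q[lesion_mask]
    return out


#: (drow, dcol) unit shifts for directions 0, 45, 90, 135 degrees
_DIRECTIONS: Tuple[Tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def glcm_matrix(
    image: np.ndarray,
    lesion_mask: np.ndarray,
    offset: int,
    directions: Sequence[Tuple[int, int]] = _DIRECTIONS,
    levels: int = GLCM_LEVELS,
) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix at one offset.

    Counts pairs of pixels separated by ``offset`` along each direction with
    both ends inside the lesion; each direction's matrix is symmetrized and
    normalized, then the directions with at least one valid pair are averaged.
    Returns an all-zero matrix if no direction has a valid pair.
    """
    q = quantize(image, lesion_mask, levels)
    h, w = q.shape
    mats: List[np.ndarray] = []
    for dr, dc in directions:
        dr, dc = dr * offset, dc * offset
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = (a >= 0) & (b >= 0)
        if not valid.any():
            continue
        ai, bi = a[valid], b[valid]
        mat = np.zeros((levels, levels))
        np.add.at(mat, (ai, bi), 1.0)
        mat = mat + mat.T  # symmetric: count both orders
        mats.append(mat / mat.sum())
    if not mats:
        return np.zeros((levels, levels))
    return np.mean(mats, axis=0)


def glcm_stats(p: np.ndarray) -> Dict[str, float]:
    """Energy, contrast, entropy (bits) and homogeneity of one GLCM."""
    i, j = np.indices(p.shape)
    return {
        "Ener": float(np.sum(p**2)),
        "Cont": float(np.sum((i - j) ** 2 * p)),
        "Entr": _entropy_bits(p.ravel()),
        "Homo": float(np.sum(p / (1.0 + np.abs(i - j)))),
    }


def glcm_features(
    image: np.ndarray,
    lesion_mask: np.ndarray,
    offsets: Iterable[int] = GLCM_OFFSETS,
    levels: int = GLCM_LEVELS,
) -> Dict[str, float]:
    """The 60 GLCM texture features (4 statistics x offsets 1..15)."""
    values: Dict[str, float] = {}
    for d in offsets:
        p = glcm_matrix(image, lesion_mask, d, levels=levels)
        if p.sum() == 0:
            warnings.warn(
                f"no valid pixel pair at offset {d}: degenerate GLCM values used",
                stacklevel=2,
            )
            stats = {"Ener": 1.0, "Cont": 0.0, "Entr": 0.0, "Homo": 1.0}
        else:
            stats = glcm_stats(p)
        for name, v in stats.items():
            values[f"{name}{d}"] = v
    # reorder to the canonical name order (all Ener, then Cont, Entr, Homo)
    return {name: values[name] for name in
            (f"{s}{d}" for s in GLCM_STAT_NAMES for d in offsets)}


def binary_texture(
    image: np.ndarray,
    lesion_mask: np.ndarray,
    high_intensity: np.ndarray,
) -> Dict[str, float]:
    """Area ratio, center deviation degree and dispersion degree.

    AR is the bright-area fraction of the lesion.  CDD is the mean distance
    from bright pixels to the lesion centroid, DD the mean distance from
    bright pixels to their own centroid, both normalized by the lesion's
    equivalent radius sqrt(area/pi).
    """
    n_lesion = int(lesion_mask.sum())
    if n_lesion == 0:
        raise ValueError("lesion mask is empty")
    n_high = int(high_intensity.sum())
    if n_high == 0:
        return {"AR": 0.0, "CDD": 0.0, "DD": 0.0}
    eq_radius = np.sqrt(n_lesion / np.pi)
    lr, lc = np.nonzero(lesion_mask)
    lesion_centroid = (lr.mean(), lc.mean())
    hr, hc = np.nonzero(high_intensity)
    high_centroid = (hr.mean(), hc.mean())
    d_lesion = np.hypot(hr - lesion_centroid[0], hc - lesion_centroid[1])
    d_high = np.hypot(hr - high_centroid[0], hc - high_centroid[1])
    return {
        "AR": n_high / n_lesion,
        "CDD": float(d_lesion.mean()) / eq_radius,
        "DD": float(d_high.mean()) / eq_radius,
    }


def _convex_hull_metrics(lesion_mask: np.ndarray) -> Tuple[float, float]:
    """(pixel count covered by the hull of pixel centers, hull perimeter).

    Counting lattice points covered by the hull polygon keeps the convex area
    on the same pixel-count scale as the mask area, so Area <= C.area holds
    by construction (every lesion pixel center lies in the hull) and a convex
    lesion has C.area ~= Area up to boundary lattice points.
    """
    import shapely
    from shapely.geometry import MultiPoint

    rows, cols = np.nonzero(lesion_mask)
    hull = MultiPoint(list(zip(cols.tolist(), rows.tolist()))).convex_hull
    if hull.geom_type != "Polygon":  # degenerate (collinear) mask
        return float(len(rows)), 2.0 * hull.length
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    covered = shapely.intersects_xy(hull, xx.ravel(), yy.ravel())
    return float(covered.sum()), float(hull.exterior.length)


def morphology(lesion_mask: np.ndarray, pixel_spacing: float = 1.0) -> Dict[str, float]:
    """The 15 shape features of the lesion mask, in mm / mm^2 units."""
    labelled, n_comp = cc_label(lesion_mask, connectivity=2, return_num=True)
    if n_comp != 1:
        raise ValueError(f"lesion mask must be a single connected component, got {n_comp}")
    props = regionprops(labelled)[0]
    s = float(pixel_spacing)
    area = props.area * s**2
    hull_px, hull_perim = _convex_hull_metrics(lesion_mask)
    c_area = hull_px * s**2
    perim = props.perimeter * s
    c_perim = hull_perim * s
    minr, minc, maxr, maxc = props.bbox
    maj = props.axis_major_length * s
    mino = props.axis_minor_length * s
    return {
        "Area": area,
        "C.area": c_area,
        "Maj.Len": maj,
        "Min.Len": mino,
        "Perimeter": perim,
        "Circularity": 4 * np.pi * area / perim**2 if perim > 0 else 0.0,
        "Solidity": area / c_area if c_area > 0 else 0.0,
        "Eccentricity": props.eccentricity,
        "Extent": props.extent,
        "AspectRatio": maj / mino if mino > 0 else 0.0,
        "EqDiameter": props.equivalent_diameter_area * s,
        "C.perimeter": c_perim,
        "Convexity": c_perim / perim if perim > 0 else 0.0,
        "BBoxW": (maxc - minc) * s,
        "BBoxH": (maxr - minr) * s,
    }


def spatial_features(
    image: np.ndarray, mask: LesionMask
) -> Dict[str, float]:
    """The full 91-feature spatial bank for one panel."""
    values = first_order(image, mask.lesion, mask.reference)
    values.update(glcm_features(image, mask.lesion))
    values.update(binary_texture(image, mask.lesion, mask.high_intensity))
    return values


def extract_case(
    case: DualModalCase,
    delineation_key: Tuple[str, int] | None = ("A", 1),
    margin_px: int = 10,
    pixel_spacing: float | None = None,
) -> Tuple[FeatureVector, FeatureVector]:
    """Extract the (B-mode, SMI) feature-vector pair for one case.

    The B-mode vector holds 91 spatial + 15 morphological features; the SMI
    vector holds the 91 spatial features computed on the SMI panel under the
    mapped contour.  Morphology is computed once from the B-mode mask since
    the lesion geometry is identical in the co-registered panels.
    """
    if delineation_key is None:
        contour = case.true_contour
        provenance = ("truth", 0)
    else:
        contour = case.observer_contours[delineation_key]
        provenance = delineation_key

    b_mask = build_lesion_mask(case.bmode, contour, margin_px=margin_px,
                               origin=(provenance[0], provenance[1], "B"))
    smi_contour = map_to_smi(contour, case.smi_offset, case.smi.shape)
    smi_lesion = build_lesion_mask(case.smi, smi_contour, margin_px=margin_px,
                                   origin=(provenance[0], provenance[1], "SMI"))

    spacing = case_pixel_spacing(case) if pixel_spacing is None else pixel_spacing
    b_values = spatial_features(case.bmode, b_mask)
    b_values.update(morphology(b_mask.lesion, spacing))
    smi_values = spatial_features(case.smi, smi_lesion)

    return (
        FeatureVector(case.case_id, "B", b_values, provenance),
        FeatureVector(case.case_id, "SMI", smi_values, provenance),
    )


def case_pixel_spacing(case: DualModalCase) -> float:
    """mm/px of a case; phantoms default to 0.2 mm/px."""
    return getattr(case, "pixel_spacing", 0.2)


@dataclass
class FeatureTables:
    """Row-aligned feature tables for the three modality models."""

    b: pd.DataFrame        # 106 columns
    smi: pd.DataFrame      # 91 columns
    dual: pd.DataFrame     # 197 columns, _B/_SMI suffixes
    labels: pd.Series      # aligned to rows; values in {cholesterol, neoplastic}


def build_tables(
    cohort: Sequence[DualModalCase],
    delineation_key: Tuple[str, int] | None = ("A", 1),
    margin_px: int = 10,
    pixel_spacing: float | None = None,
) -> FeatureTables:
    """Build the B / SMI / dual feature tables for a cohort.

    The dual table is the column-wise union of the B and SMI tables with
    ``_B`` / ``_SMI`` suffixes; row order is identical across the three.
    Any failing case aborts the build with its case id (no silent dropping).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    b_rows, smi_rows, labels = {}, {}, {}
    failures = []
    for case in cohort:
        try:
            b_vec, smi_vec = extract_case(
                case, delineation_key, margin_px=margin_px, pixel_spacing=pixel_spacing
            )
        except Exception as exc:  # noqa: BLE001 - reported, then aborted
            failures.append(f"{case.case_id}: {exc}")
            continue
        b_rows[case.case_id] = b_vec.values
        smi_rows[case.case_id] = smi_vec.values
        labels[case.case_id] = case.label
    if failures:
        raise RuntimeError("feature extraction failed for: " + "; ".join(failures))

    b = pd.DataFrame.from_dict(b_rows, orient="index")
    smi = pd.DataFrame.from_dict(smi_rows, orient="index")
    b.index.name = smi.index.name = "case_id"
    dual = pd.concat(
        [b[list(SPATIAL_NAMES) + list(MORPHOLOGY_NAMES)].add_suffix("_B"),
         smi.add_suffix("_SMI")],
        axis=1,
    )
    label_s = pd.Series(labels, name="label").loc[b.index]
    return FeatureTables(b=b, smi=smi, dual=dual, labels=label_s)


def save_table(df: pd.DataFrame, labels: pd.Series, path) -> None:
    """CSV with case_id first, features, label last (plus a params sidecar)."""
    out = df.copy()
    out["label"] = labels
    out.to_csv(path, float_format="%.10g")


EXTRACTOR_PARAMS: Mapping[str, object] = {
    "glcm_levels": GLCM_LEVELS,
    "glcm_offsets": list(GLCM_OFFSETS),
    "histogram_bins": HIST_BINS,
    "entropy_log_base": 2,
    "moments": "population, Fisher excess kurtosis",
    "reference_band_margin_px": 10,
    "high_intensity_rule": "otsu-within-lesion, > threshold",
    "cdd_dd_normalization": "lesion equivalent radius sqrt(area/pi)",
}
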