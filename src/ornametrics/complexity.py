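"""Congruence-based shape complexity and its sexual-dimorphism normalization.

The complexity of a closed trait outline is scored by comparing a coarse and
a fine Fourier reconstruction of it (defaults: 8 vs 1000 harmonics).  Both
reconstructions are filled regions in the outline's own pixel frame; the
*congruent* area is their intersection, the *non-congruent* area is their
symmetric difference, and

    complexity = non-congruent area / congruent area.

A band-limited shape (an ellipse, say) is fully captured at 8 harmonics, so
both reconstructions coincide and the score is 0; the more of the outline's
detail lives above the low-harmonic band, the larger the mismatch and the
score.  Because both reconstructions transform together under translation,
rotation and uniform scaling, the ratio is similarity-invariant.

Boolean areas are computed on cleaned polygons (low-harmonic reconstructions
may self-intersect; they are repaired to valid regions, even-odd fill, before
clipping).  A raster mode (pixel AND/XOR counts on a fine grid) is provided
as an independent cross-check; the vector (polygon-clipping) mode is
canonical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon
from shapely.ops import polygonize, unary_union

from .efa import compute_efa, reconstruct
from .outlines import Outline

__all__ = [
    "ComplexityScore",
    "NormalizedComplexity",
    "DegenerateCongruenceError",
    "congruence_areas",
    "complexity_score",
    "normalize_dimorphism",
    "sex_complexity_difference",
]

#: species/trait pair whose females lack the structure: the female baseline
#: is fixed to 1 so the male score passes through unchanged.
FEMALE_BASELINE_EXCEPTIONS = {("Perochaeta dikowi", "sternite")}


class DegenerateCongruenceError(ValueError):
    """Raised when the two regions do not overlap, leaving the score undefined."""


@dataclass(frozen=True)
class ComplexityScore:
    """Congruence ratio of one outline at a (low, high) harmonic pair."""

    value: float
    h_low: int
    h_high: int
    congruent_area: float
    noncongruent_area: float


@dataclass(frozen=True)
class NormalizedComplexity:
    """Male trait complexity relative to the female baseline (male/female)."""

    species: str
    trait: str
    male_score: float
    female_score: float
    normalized: float


def _crossing_parity(points: np.ndarray, px: float, py: float) -> int:
    """Even-odd ray-casting parity of one point against a closed polyline."""
    x, y = points[:, 0], points[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    straddle = (y > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        xcross = x + (py - y) * (x2 - x) / (y2 - y)
    return int(np.count_nonzero(straddle & (xcross > px)) % 2)


def _as_region(outline: Outline):
    """Filled region of a closed outline under the even-odd rule.

    Simple outlines fill directly.  Self-intersecting ones (low-harmonic
    reconstructions can curl over near high-curvature stretches) are noded
    into faces, and the faces whose even-odd ray-casting parity against the
    original closed curve is odd are kept — the region a plotted closed
    curve visually encloses, and the same rule the raster cross-check uses.
    """
    poly = Polygon(outline.points)
    if poly.is_valid:
        return poly
    ring = LineString(np.vstack([outline.points, outline.points[:1]]))
    faces = [f for f in polygonize(unary_union(ring))]
    kept = [f for f in faces
            if _crossing_parity(outline.points, *f.representative_point().coords[0])]
    if not kept:  # fall back to a validity repair
        repaired = shapely.make_valid(poly)
        parts = [g for g in getattr(repaired, "geoms", [repaired])
                 if g.geom_type in ("Polygon", "MultiPolygon")]
        return unary_union(parts) if parts else repaired
    return unary_union(kept)


def congruence_areas(outline_a: Outline, outline_b: Outline) -> tuple[float, float]:
    """Intersection (congruent) and symmetric-difference (non-congruent) areas.

    Both outlines must live in the same coordinate frame.  The identity
    ``congruent + noncongruent == union`` holds to numerical precision.
    """
    ra, rb = _as_region(outline_a), _as_region(outline_b)
    inter = ra.intersection(rb).area
    if inter <= 0:
        raise DegenerateCongruenceError(
            "outlines do not overlap: congruence score undefined"
        )
    noncon = ra.symmetric_difference(rb).area
    return float(inter), float(noncon)


def _scanline_fill(xy: np.ndarray, grid: int) -> np.ndarray:
    """Even-odd scanline fill of a closed polygon onto a ``grid``-square.

    A pixel (integer-center) is foreground when a leftward ray from its
    center crosses the polygon boundary an odd number of times — the same
    rule :func:`_as_region` applies in vector mode.  Vectorized over edges;
    independent of shapely.
    """
    x1, y1 = xy[:, 0], xy[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    mask = np.zeros((grid, grid), dtype=bool)
    rows = np.arange(grid, dtype=float)
    # (rows, edges) straddle matrix; half-open rule avoids vertex double counts
    straddle = (y1[None, :] > rows[:, None]) != (y2[None, :] > rows[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rows[:, None] - y1[None, :]) / (y2 - y1)[None, :]
    xcross = x1[None, :] + t * (x2 - x1)[None, :]
    for r in range(grid):
        xs = np.sort(xcross[r, straddle[r]])
        for k in range(0, len(xs) - 1, 2):
            lo = int(np.ceil(xs[k]))
            hi = int(np.floor(xs[k + 1]))
            # pixels with center strictly inside [xs[k], xs[k+1]]
            if xs[k + 1] == hi and hi >= lo:
                hi -= 1
            if hi >= lo >= 0:
                mask[r, max(lo, 0):min(hi, grid - 1) + 1] = True
    return mask


def congruence_areas_raster(outline_a: Outline, outline_b: Outline,
                            grid: int = 2048) -> tuple[float, float]:
    """Raster cross-check of :func:`congruence_areas`.

    Both outlines are scan-filled (even-odd) onto a common ``grid``-wide
    pixel lattice spanning their joint bounding box; congruent/non-congruent
    areas are AND/XOR pixel counts converted back to outline units.
    """
    pts = np.vstack([outline_a.points, outline_b.points])
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = float(max(hi - lo)) or 1.0
    pad = 0.01 * span
    scale = (grid - 1) / (span + 2 * pad)

    def rasterize(outline: Outline) -> np.ndarray:
        xy = (outline.points - lo + pad) * scale
        return _scanline_fill(xy, grid)

    ma, mb = rasterize(outline_a), rasterize(outline_b)
    px_area = 1.0 / scale**2
    inter = int(np.count_nonzero(ma & mb))
    if inter == 0:
        raise DegenerateCongruenceError(
            "outlines do not overlap: congruence score undefined"
        )
    noncon = int(np.count_nonzero(ma ^ mb))
    return inter * px_area, noncon * px_area


def complexity_score(outline: Outline, h_low: int = 8, h_high: int = 1000,
                     n_points: int = 4096, mode: str = "vector") -> ComplexityScore:
    """Score outline complexity as the (h_low, h_high) congruence ratio.

    The series is fitted in the outline's own vertex parameterization (see
    :func:`ornametrics.efa.compute_efa`), so a curve band-limited below
    ``h_low`` in its sampling parameter — any exact ellipse, in particular —
    scores 0 to numerical precision.  ``h_high`` is capped at the Nyquist
    bound of the fit density, so the conventional 1000-harmonic
    reconstruction is always representable at the default 4096-point
    refinement.  ``mode`` selects vector (canonical) or raster boolean areas.
    """
    if h_low >= h_high:
        raise ValueError(f"h_low must be < h_high, got {h_low} >= {h_high}")
    n_fit = max(4096, len(outline))
    h_high_eff = min(h_high, n_fit // 2)
    efa = compute_efa(outline, h_high_eff, n_points_fit=n_fit,
                      parameterization="uniform")
    lo = reconstruct(efa, h_low, n_points)
    hi = reconstruct(efa, h_high_eff, n_points)
    areas_fn = {"vector": congruence_areas,
                "raster": congruence_areas_raster}[mode]
    try:
        congruent, noncongruent = areas_fn(lo, hi)
    except DegenerateCongruenceError as exc:
        raise DegenerateCongruenceError(
            f"degenerate congruence between {h_low}- and {h_high_eff}-harmonic "
            f"reconstructions of {outline.source_id or 'outline'}"
        ) from exc
    return ComplexityScore(value=noncongruent / congruent, h_low=h_low,
                           h_high=h_high, congruent_area=congruent,
                           noncongruent_area=noncongruent)


def normalize_dimorphism(male_score: float, female_score: float | None,
                         species: str, trait: str) -> NormalizedComplexity:
    """Normalize a male complexity score against the female baseline.

    The female score is the denominator (male/female).  For species whose
    females lack the structure entirely (Perochaeta dikowi sternites), the
    baseline is fixed to 1 and the male score passes through unchanged.
    Claspers are male-only and must not be normalized at all.
    """
    if male_score < 0:
        raise ValueError(f"male_score must be >= 0, got {male_score}")
    if (species, trait) in FEMALE_BASELINE_EXCEPTIONS:
        female = 1.0
    else:
        if female_score is None or female_score <= 0:
            raise ValueError(
                f"{species}/{trait}: female baseline score must be > 0, "
                f"got {female_score}"
            )
        female = float(female_score)
    return NormalizedComplexity(species=species, trait=trait,
                                male_score=float(male_score),
                                female_score=female,
                                normalized=float(male_score) / female)


def sex_complexity_difference(panel: pd.DataFrame,
                              value_col: str = "complexity") -> pd.DataFrame:
    """Per-species male − female complexity differences.

    ``panel`` holds one row per species × sex with columns
    ``species, sex, <value_col>``.  Species missing either sex are excluded
    from the differences and listed in the returned frame's
    ``attrs['excluded']``.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    wide = (panel.pivot_table(index="species", columns="sex",
                              values=value_col, aggfunc="mean")
            .reindex(columns=["male", "female"]))
    complete = wide.dropna()
    out = pd.DataFrame({
        "male": complete["male"],
        "female": complete["female"],
        "difference": complete["male"] - complete["female"],
    })
    out.attrs["excluded"] = sorted(set(wide.index) - set(complete.index))
    return out
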