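"""Virtual-species landscape generator.

Creates everything a full pipeline run needs, with known ground truth:

* a stack of spatially autocorrelated environmental covariates (elevation,
  two bioclimatic temperature summaries, two distance-to-feature layers,
  and a categorical land-cover layer with a herbaceous class),
* a true habitat-suitability surface built from threshold-shaped (sigmoid)
  responses — by default the species prefers elevation above 2,800 m, a
  warmest-month maximum temperature below 20.5 °C, temperature seasonality
  above 7,800 units, and herbaceous land cover,
* presence and held-out testing points drawn in proportion to suitability,
* a synthetic human-influence raster (integers 0–64, distance-decay
  footprints around settlements), and
* synthetic protected-area polygons covering a requested area fraction.

Every generator is a pure function of its parameters and a seed, so each
artifact regenerates bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from shapely.geometry import box as shapely_box

from .grid import PointTable, PolygonSet, RasterGrid

__all__ = [
    "SigmoidResponse",
    "CategoricalResponse",
    "ResponseSpec",
    "SyntheticTruth",
    "default_response_spec",
    "generate_covariates",
    "true_suitability",
    "sample_occurrences",
    "generate_hii",
    "generate_protected_areas",
    "make_truth",
]

#: land-cover integer codes used by the synthetic landscape
LANDCOVER_CLASSES = {1: "herbaceous", 2: "shrubland", 3: "bare", 4: "water"}

#: min/max of each continuous synthetic covariate (plausible field ranges)
COVARIATE_RANGES = {
    "Altitude": (1000.0, 6000.0),   # m a.s.l.
    "Bio_5": (-5.0, 35.0),          # max temperature of warmest month, degC
    "Bio_4": (2000.0, 12000.0),     # temperature seasonality, sd*100
}

#: skew exponents applied to the rank-uniform fields: values > 1 push mass
#: toward the low end of the range, < 1 toward the high end.  High plateau
#: is rare in a continental window (Altitude skew 3), warm summers dominate
#: it (Bio_5 skew 0.45), and strongly continental seasonality is the
#: exception rather than the rule (Bio_4 skew 1.5).  Jointly this keeps the
#: suitable niche to a small percentage of the landscape, as in a realistic
#: wide study window around a high-plateau specialist.
FIELD_SKEW = {"Altitude": 3.0, "Bio_5": 0.45, "Bio_4": 1.5}


@dataclass(frozen=True)
class SigmoidResponse:
    """Logistic response of suitability to one continuous covariate.

    ``direction=+1`` rises with the covariate (half-maximum at the
    inflection), ``-1`` falls.  ``width`` is the logistic scale; the
    10–90% transition spans about 4.4 widths.
    """

    variable: str
    inflection: float
    width: float
    direction: int = 1

    def __call__(self, values: np.ndarray) -> np.ndarray:
        z = self.direction * (np.asarray(values, dtype=float) - self.inflection) / self.width
        return 1.0 / (1.0 + np.exp(-z))

    def to_dict(self) -> dict:
        return {
            "kind": "sigmoid",
            "variable": self.variable,
            "inflection": self.inflection,
            "width": self.width,
            "direction": self.direction,
        }


@dataclass(frozen=True)
class CategoricalResponse:
    """Per-class preference weights in [0, 1] for a categorical covariate."""

    variable: str
    weights: Mapping[int, float]

    def __call__(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values)
        out = np.zeros(values.shape, dtype=float)
        for cls, w in self.weights.items():
            out[values == cls] = w
        return out

    def to_dict(self) -> dict:
        return {
            "kind": "categorical",
            "variable": self.variable,
            "weights": {int(k): float(v) for k, v in self.weights.items()},
        }


@dataclass(frozen=True)
class ResponseSpec:
    """Multiplicative suitability model: product of per-covariate responses
    scaled by a prevalence factor (suitability at a fully suitable cell)."""

    responses: tuple = ()
    prevalence: float = 0.9

    def __post_init__(self):
        if not 0 < self.prevalence <= 1:
            raise ValueError(f"prevalence must be in (0, 1], got {self.prevalence}")

    @property
    def variables(self) -> list[str]:
        return [r.variable for r in self.responses]

    def to_dict(self) -> dict:
        return {
            "prevalence": self.prevalence,
            "responses": [r.to_dict() for r in self.responses],
        }


def default_response_spec() -> ResponseSpec:
    """The default synthetic truth: three threshold responses plus a
    herbaceous land-cover preference.

    Widths are ~2.3% of each covariate's range, so the 10–90% transition
    covers roughly a tenth of the range and the inflections are
    recoverable from fitted response curves.
    """
    return ResponseSpec(
        responses=(
            SigmoidResponse("Altitude", inflection=2800.0, width=115.0, direction=+1),
            SigmoidResponse("Bio_5", inflection=20.5, width=0.9, direction=-1),
            SigmoidResponse("Bio_4", inflection=7800.0, width=230.0, direction=+1),
            CategoricalResponse(
                "Landcv", weights={1: 1.0, 2: 0.3, 3: 0.05, 4: 0.0}
            ),
        ),
        prevalence=0.9,
    )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  autocorr_length: float) -> np.ndarray:
    """Gaussian-smoothed white noise, rank-transformed to uniform (0, 1).

    The rank transform pins the field's marginal distribution (exactly
    uniform) independently of grid size and smoothing length, so skew
    exponents applied on top give predictable area fractions above any
    threshold.
    """
    from scipy.stats import rankdata

    rows, cols = shape
    noise = rng.standard_normal((rows, cols))
    field_ = ndimage.gaussian_filter(noise, sigma=autocorr_length, mode="reflect")
    return (rankdata(field_.ravel()) / (field_.size + 1)).reshape(shape)


def generate_covariates(
    shape: tuple[int, int],
    cell_size: float = 1000.0,
    seed: int = 0,
    autocorr_length: float = 6.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> dict[str, RasterGrid]:
    """Generate the synthetic covariate stack.

    Returns an ordered mapping of layer name to aligned RasterGrid:
    Altitude, Bio_5, Bio_4 (smoothed random fields rescaled to plausible
    ranges), Dist_lake and Dist_road (Euclidean distance to random feature
    cells, metres), and integer-coded Landcv.

    ``autocorr_length`` is the Gaussian smoothing sigma in cells; the grid
    must comfortably contain the kernel.
    """
    rows, cols = shape
    if rows < 16 or cols < 16:
        raise ValueError(f"grid {shape} too small for the smoothing kernel; need >= 16x16")
    rng = np.random.default_rng(seed)
    origin_x, origin_y = origin

    def _grid(values, name):
        return RasterGrid(values, origin_x, origin_y, cell_size, nodata=None, name=name)

    stack: dict[str, RasterGrid] = {}
    for name, (lo, hi) in COVARIATE_RANGES.items():
        field_ = _smooth_field(rng, shape, autocorr_length) ** FIELD_SKEW[name]
        stack[name] = _grid(lo + (hi - lo) * field_, name)

    # distance-to-feature covariates: sparse random feature cells, then EDT
    for name, n_features in (("Dist_lake", max(3, rows * cols // 800)),
                             ("Dist_road", max(5, rows * cols // 400))):
        feat = np.zeros(shape, dtype=bool)
        idx = rng.choice(rows * cols, size=n_features, replace=False)
        feat.flat[idx] = True
        dist = ndimage.distance_transform_edt(~feat) * cell_size
        stack[name] = _grid(dist, name)

    # categorical land cover from a smoothed field cut at fixed quantiles:
    # ~40% herbaceous, 30% shrubland, 20% bare, 10% water
    lc_field = _smooth_field(rng, shape, autocorr_length)
    edges = np.quantile(lc_field, [0.4, 0.7, 0.9])
    landcv = np.digitize(lc_field, edges) + 1
    stack["Landcv"] = _grid(landcv.astype(np.int32), "Landcv")
    return stack


def true_suitability(stack: Mapping[str, RasterGrid], spec: ResponseSpec) -> RasterGrid:
    """Cellwise product of the spec's responses times the prevalence scaler."""
    missing = [v for v in spec.variables if v not in stack]
    if missing:
        raise KeyError(f"response references missing layer(s): {missing}")
    template = next(iter(stack.values()))
    suit = np.full(template.shape, spec.prevalence, dtype=float)
    for resp in spec.responses:
        suit *= resp(stack[resp.variable].values)
    return template.with_values(suit, name="true_suitability")


def sample_occurrences(
    suitability: RasterGrid,
    n_presence: int = 183,
    n_test: int = 102,
    seed: int = 0,
    region: tuple[float, float, float, float] | None = None,
) -> tuple[PointTable, PointTable]:
    """Draw presence and testing points at cell centres, without replacement,
    with inclusion probability proportional to true suitability.

    The two sets are disjoint by construction (a single draw, split).
    ``region`` (xmin, ymin, xmax, ymax) optionally restricts sampling to a
    surveyed sub-window, emulating field campaigns that cover only the
    known range and leave suitable habitat elsewhere unrecorded.
    """
    suit = np.asarray(suitability.values, dtype=float).ravel().copy()
    if region is not None:
        xmin, ymin, xmax, ymax = region
        cx, cy = suitability.centers()
        outside = ~((cx.ravel() >= xmin) & (cx.ravel() < xmax)
                    & (cy.ravel() > ymin) & (cy.ravel() <= ymax))
        suit[outside] = 0.0
    positive = suit > 0
    n_total = n_presence + n_test
    if positive.sum() < n_total:
        raise ValueError(
            f"only {int(positive.sum())} cells with positive suitability; "
            f"need {n_total}"
        )
    rng = np.random.default_rng(seed)
    p = suit / suit.sum()
    chosen = rng.choice(suit.size, size=n_total, replace=False, p=p)
    rows, cols = np.unravel_index(chosen, suitability.shape)
    x, y = suitability.cell_center(rows, cols)
    presence = PointTable.from_xy(x[:n_presence], y[:n_presence], "presence")
    test = PointTable.from_xy(x[n_presence:], y[n_presence:], "test",
                              start_id=n_presence)
    return presence, test


def generate_hii(
    shape: tuple[int, int],
    seed: int = 0,
    settlement_count: int = 25,
    cell_size: float = 1000.0,
    origin: tuple[float, float] = (0.0, 0.0),
    decay_cells: float = 8.0,
) -> RasterGrid:
    """Synthetic human-influence raster: integers 0 (no influence) to 64.

    Each settlement contributes an exponentially decaying footprint
    ``intensity * exp(-d / decay_cells)``; the cellwise maximum over
    settlements is rounded and clipped to [0, 64].
    """
    rows, cols = shape
    rng = np.random.default_rng(seed)
    hii = np.zeros(shape, dtype=float)
    if settlement_count > 0:
        centers = rng.choice(rows * cols, size=min(settlement_count, rows * cols),
                             replace=False)
        cr, cc = np.unravel_index(centers, shape)
        intensity = rng.uniform(30.0, 80.0, size=len(centers))
        rr, cc_grid = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        for r0, c0, a in zip(cr, cc, intensity):
            d = np.hypot(rr - r0, cc_grid - c0)
            np.maximum(hii, a * np.exp(-d / decay_cells), out=hii)
    hii = np.clip(np.rint(hii), 0, 64).astype(np.int32)
    return RasterGrid(hii, origin[0], origin[1], cell_size, nodata=None, name="HII")


def generate_protected_areas(
    shape: tuple[int, int],
    coverage_fraction: float,
    seed: int = 0,
    cell_size: float = 1000.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> PolygonSet:
    """Random rectangular reserves whose union covers roughly the requested
    fraction of the grid footprint.

    Rectangles are drawn until the union area first reaches the target;
    each is small (1–4% of the domain) so the overshoot stays well inside
    ±20% relative.
    """
    if not 0 <= coverage_fraction < 1:
        raise ValueError(f"coverage_fraction must be in [0, 1), got {coverage_fraction}")
    rows, cols = shape
    width = cols * cell_size
    height = rows * cell_size
    origin_x, origin_y = origin
    ymin = origin_y - height
    total_area = width * height
    target = coverage_fraction * total_area
    if target == 0:
        return PolygonSet(polygons=[], label="protected_area")

    import shapely

    rng = np.random.default_rng(seed)
    boxes = []
    union_area = 0.0
    while union_area < target:
        w = rng.uniform(0.10, 0.20) * width
        h = rng.uniform(0.10, 0.20) * height
        x0 = rng.uniform(origin_x, origin_x + width - w)
        y0 = rng.uniform(ymin, origin_y - h)
        boxes.append(shapely_box(x0, y0, x0 + w, y0 + h))
        union_area = shapely.union_all(boxes).area
    return PolygonSet(polygons=boxes, label="protected_area")


@dataclass
class SyntheticTruth:
    """Bundle of the generated landscape and its known ground truth."""

    spec: ResponseSpec
    seed: int
    stack: dict[str, RasterGrid]
    suitability: RasterGrid
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "parameters": self.parameters,
            "response_spec": self.spec.to_dict(),
        }


def make_truth(
    shape: tuple[int, int],
    cell_size: float = 1000.0,
    seed: int = 0,
    spec: ResponseSpec | None = None,
    autocorr_length: float = 6.0,
) -> SyntheticTruth:
    """Generate covariates and the true suitability surface in one call."""
    spec = spec or default_response_spec()
    stack = generate_covariates(shape, cell_size=cell_size, seed=seed,
                                autocorr_length=autocorr_length)
    suit = true_suitability(stack, spec)
    return SyntheticTruth(
        spec=spec,
        seed=seed,
        stack=stack,
        suitability=suit,
        parameters={
            "shape": list(shape),
            "cell_size": cell_size,
            "autocorr_length": autocorr_length,
        },
    )
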