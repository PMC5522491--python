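"""End-to-end orchestration: simulate -> sample -> fit -> score ->
evaluate -> surface -> gaps -> potential, from a single configuration.

Every stochastic stage derives its seed from the run's master seed by a
fixed offset, so one integer reproduces the entire run bit-for-bit.  The
default configuration is a desk-scale analogue of the full study design:
a 150 x 150 km landscape at 1 km resolution, 183 presences, 102 testing
points, 100 pseudo-absences per presence (18,300) and a 1,000-tree forest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, gap_analysis, io_formats, model as model_mod
from . import potential_areas, sampling, surfaces, synthetic
from .grid import PointTable, RasterGrid

__all__ = ["RunConfig", "PipelineResult", "run_all", "extract_surface_rio"]

logger = logging.getLogger(__name__)

# per-stage seed offsets from the master seed
_SEED_OFFSETS = {
    "landscape": 0,
    "occurrences": 1,
    "hii": 2,
    "protected": 3,
    "absences": 4,
    "model": 5,
    "bootstrap": 6,
}


@dataclass
class RunConfig:
    """All knobs of a pipeline run; round-trips through YAML losslessly."""

    seed: int = 0
    shape: tuple[int, int] = (150, 150)
    cell_size: float = 1000.0
    autocorr_length: float = 6.0
    n_presence: int = 183
    n_test: int = 102
    survey_fraction: float = 0.6
    ratio: int = 100
    n_trees: int = 1000
    threshold_step: float = 0.01
    idw_power: float = 2.0
    idw_k: int = 12
    hii_settlements: int = 25
    hii_cutoff: int = 10
    pa_coverage: float = 0.25
    buffer_distance: float = 10_000.0
    min_cluster_pixels: int = 10
    density_radius: float = 5000.0
    n_bootstrap: int = 1000
    out_dir: str | None = None

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + _SEED_OFFSETS[stage]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io_formats.read_config(path))

    def parameter_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def extract_surface_rio(points: PointTable, rio: RasterGrid) -> PointTable:
    """Attach the prediction surface's cell value to each point as its RIO
    (half-open cell rule; out-of-bounds points get NaN and are flagged)."""
    row, col = rio.index_of(points.x, points.y)
    inside = (row >= 0) & (row < rio.rows) & (col >= 0) & (col < rio.cols)
    vals = np.full(len(points), np.nan)
    vals[inside] = np.asarray(rio.values, dtype=float)[
        row[inside], col[inside]
    ]
    return points.with_columns(rio=vals, flagged=~inside | points.flagged)


@dataclass
class PipelineResult:
    """Everything a full run produces, in memory."""

    config: RunConfig
    truth: synthetic.SyntheticTruth
    presence: PointTable
    test: PointTable
    design: sampling.TrainingDesign
    model: model_mod.SuitabilityModel
    threshold_table: evaluation.ThresholdTable
    threshold: float
    auc: float
    tss_at_threshold: float
    tss_max: float
    validation: evaluation.ValidationSummary
    surface: surfaces.PredictionSurface
    hii: RasterGrid
    protected: synthetic.PolygonSet
    gaps: gap_analysis.GapSummary
    potential_mask: RasterGrid
    clusters: potential_areas.ClusterTable
    density: potential_areas.DensitySurface
    focal: list

    def metrics(self) -> dict:
        m = {
            "n_presence": len(self.presence),
            "n_test": len(self.test),
            "n_pseudo_absence": self.design.n_absence,
            "auc": self.auc,
            "threshold": self.threshold,
            "tss_at_threshold": self.tss_at_threshold,
            "tss_max": self.tss_max,
            "test_rio_median": self.validation.median,
            "test_rio_ci": [self.validation.ci_lower, self.validation.ci_upper],
            "protected_fraction": self.gaps.protected_fraction,
            "pressured_fraction": self.gaps.pressured_fraction,
            "protected_of_pressured": self.gaps.protected_of_pressured,
            "gap_fraction": self.gaps.gap_fraction,
            "gap_fraction_from_marginals": self.gaps.marginal_product(),
            "n_potential_pixels": self.clusters.total_pixels,
            "n_clusters": len(self.clusters),
            "cluster_shares_pct": self.clusters.table["share_pct"].tolist(),
        }
        return m


def run_all(config: RunConfig) -> PipelineResult:
    """Execute the whole workflow; see the module docstring for the stages.

    Raises at the first failing stage, naming it.  When ``config.out_dir``
    is set, every artifact plus ``metrics.json`` and a manifest are written
    there.
    """
    stage = "simulate"
    try:
        truth = synthetic.make_truth(
            config.shape, cell_size=config.cell_size,
            seed=config.stage_seed("landscape"),
            autocorr_length=config.autocorr_length,
        )
        # occurrences come from a surveyed window on the east side of the
        # domain: field records cover only the known range, and suitable
        # habitat outside it is what the potential-area stage looks for
        xmin, ymin, xmax, ymax = truth.suitability.bounds
        survey = (xmax - (xmax - xmin) * config.survey_fraction, ymin, xmax, ymax)
        presence, test = synthetic.sample_occurrences(
            truth.suitability, n_presence=config.n_presence,
            n_test=config.n_test, seed=config.stage_seed("occurrences"),
            region=survey if 0 < config.survey_fraction < 1 else None,
        )
        hii = synthetic.generate_hii(
            config.shape, seed=config.stage_seed("hii"),
            settlement_count=config.hii_settlements,
            cell_size=config.cell_size,
        )
        protected = synthetic.generate_protected_areas(
            config.shape, config.pa_coverage,
            seed=config.stage_seed("protected"),
            cell_size=config.cell_size,
        )

        stage = "sample"
        template = truth.suitability
        lattice = sampling.make_lattice(template.bounds, config.cell_size)
        absences = sampling.sample_pseudo_absences(
            lattice, presence, ratio=config.ratio,
            seed=config.stage_seed("absences"),
            cell_size=config.cell_size,
        )
        design = sampling.assemble_design(presence, absences, stack=truth.stack,
                                          ratio=config.ratio)

        stage = "fit"
        fitted = model_mod.fit(design, n_trees=config.n_trees,
                               seed=config.stage_seed("model"))

        stage = "evaluate"
        labels = design.labels
        auc = evaluation.roc_auc(labels, fitted.oob_scores)
        table = evaluation.threshold_table(labels, fitted.oob_scores,
                                           step=config.threshold_step)
        threshold = evaluation.select_threshold(table)
        tss_at = evaluation.tss(table.row_at(threshold))
        tss_max = float(table.table["tss"].max())

        stage = "score"
        lattice_cov = sampling.extract_covariates(lattice, truth.stack)
        scored = model_mod.score(fitted, lattice_cov)

        stage = "surface"
        surf = surfaces.make_surface(scored, template, threshold,
                                     power=config.idw_power,
                                     k_neighbors=config.idw_k)

        stage = "validate"
        test_scored = extract_surface_rio(test, surf.rio)
        validation = evaluation.validate_on_test(
            test_scored, n_bootstrap=config.n_bootstrap,
            seed=config.stage_seed("bootstrap"),
        )

        stage = "gaps"
        protected_mask = gap_analysis.rasterize_polygons(protected, template) \
            if len(protected) else template.with_values(
                np.zeros(template.shape, dtype=np.uint8), name="protected_area")
        gaps = gap_analysis.conservation_gaps(
            surf.mask, hii, protected_mask, hii_cutoff=config.hii_cutoff,
        )

        stage = "potential"
        records = PointTable.from_xy(
            np.concatenate([presence.x, test.x]),
            np.concatenate([presence.y, test.y]),
            role="presence",
        )
        potential = potential_areas.buffer_exclude(
            surf.mask, known_ranges=None, records=records,
            distance=config.buffer_distance,
        )
        clusters = potential_areas.aggregate_clusters(
            potential, min_pixels=config.min_cluster_pixels,
        )
        density = potential_areas.point_density(potential,
                                                radius=config.density_radius)
        focal = (potential_areas.rank_focal_regions(clusters, density)
                 if len(clusters) else [])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(
        config=config, truth=truth, presence=presence, test=test,
        design=design, model=fitted, threshold_table=table,
        threshold=threshold, auc=auc, tss_at_threshold=tss_at,
        tss_max=tss_max, validation=validation, surface=surf, hii=hii,
        protected=protected, gaps=gaps, potential_mask=potential,
        clusters=clusters, density=density, focal=focal,
    )
    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    io_formats.write_raster(list(result.truth.stack.values()), out / "covariates.tif")
    io_formats.write_raster(result.truth.suitability, out / "true_suitability.tif")
    io_formats.write_points(result.presence, out / "presence.csv")
    io_formats.write_points(result.test, out / "test.csv")
    io_formats.write_raster(result.hii, out / "hii.tif")
    io_formats.write_polygons(result.protected, out / "protected.geojson")
    (out / "truth.yaml").write_text(yaml.safe_dump(result.truth.to_dict()))
    rio32 = result.surface.rio.with_values(
        result.surface.rio.values.astype(np.float32))
    io_formats.write_raster(rio32, out / "rio.tif")
    io_formats.write_raster(result.surface.mask, out / "binary.tif")
    result.threshold_table.table.to_csv(out / "threshold_table.csv", index=False)
    io_formats.write_raster(result.gaps.gap_mask, out / "gap_mask.tif")
    io_formats.write_raster(result.potential_mask, out / "potential_mask.tif")
    result.clusters.table.to_csv(out / "clusters.csv", index=False)
    dens32 = result.density.density.with_values(
        result.density.density.values.astype(np.float32))
    io_formats.write_raster(dens32, out / "density.tif")
    (out / "metrics.json").write_text(json.dumps(result.metrics(), indent=2))
    manifest = {
        "config": cfg.to_dict(),
        "parameter_hash": cfg.parameter_hash(),
        "stage_seeds": {k: cfg.stage_seed(k) for k in _SEED_OFFSETS},
        "version": __import__("cranesdm").__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
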