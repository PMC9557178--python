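"""DHS-like synthetic multi-wave cluster data with known ground truth.

Everything is driven by a master seed; each component derives a stable
sub-seed from ``(master_seed, component_name)`` so individual stages are
reproducible in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from geoprev.core_io import ClusterRecord, CovariateGrid, project_points
from geoprev.spatial_model import (
    MaternParams,
    build_covariance,
    cholesky_with_escalation,
)

#: Per-survey cluster counts for the five waves (2000..2019).
DEFAULT_COUNTS_PER_WAVE = [535, 517, 571, 619, 305]
DEFAULT_WAVE_LABELS = ["2000", "2005", "2011", "2016", "2019"]


@dataclass
class GridSpec:
    """Geometry of a synthetic raster lattice."""

    n_rows: int = 50
    n_cols: int = 50
    origin_lon: float = 34.0
    origin_lat: float = 14.0
    cell_size: float = 0.2

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    def cell_centers(self) -> np.ndarray:
        """(n_rows*n_cols, 2) lon/lat of every cell center, row-major."""
        cols = self.origin_lon + self.cell_size * np.arange(self.n_cols)
        rows = self.origin_lat - self.cell_size * np.arange(self.n_rows)
        lon, lat = np.meshgrid(cols, rows)
        return np.column_stack([lon.ravel(), lat.ravel()])

    def bounding_box(self) -> tuple[float, float, float, float]:
        half = self.cell_size / 2.0
        return (
            self.origin_lon - half,
            self.origin_lat - (self.n_rows - 1) * self.cell_size - half,
            self.origin_lon + (self.n_cols - 1) * self.cell_size + half,
            self.origin_lat + half,
        )


@dataclass
class SyntheticTruth:
    """Generating values behind a synthetic dataset."""

    alpha_true: float
    beta_true: np.ndarray
    matern_true: MaternParams
    field_values: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        self.field_values = np.asarray(self.field_values, dtype=float)
        if not np.isfinite(self.field_values).all():
            raise ValueError("field_values must be finite")

    def to_json(self, path) -> None:
        doc = {
            "alpha_true": self.alpha_true,
            "beta_true": self.beta_true.tolist(),
            "matern_true": {
                "range_rho": self.matern_true.range_rho,
                "sigma": self.matern_true.sigma,
                "nu": self.matern_true.nu,
            },
            "field_values": self.field_values.tolist(),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def subseed(master_seed: int, component: str) -> np.random.SeedSequence:
    """Stable per-component seed: SeedSequence([master, crc32(component)])."""
    return np.random.SeedSequence([master_seed, zlib.crc32(component.encode())])


def simulate_covariate_surfaces(
    n_layers: int,
    grid_spec: GridSpec,
    smoothness_range: float = 1.0,
    seed: int = 0,
) -> list[CovariateGrid]:
    """Smooth standardized Gaussian random fields on the grid.

    Each layer is white noise blurred with a Gaussian kernel of width
    ``smoothness_range`` degrees, then z-scored over cells so every layer has
    cell mean 0 and SD 1 exactly.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if smoothness_range <= 0:
        raise ValueError("smoothness_range must be > 0")
    layers = []
    for k in range(n_layers):
        rng = np.random.default_rng(subseed(seed, f"covariate:{k}"))
        noise = rng.standard_normal((grid_spec.n_rows, grid_spec.n_cols))
        sigma_cells = smoothness_range / grid_spec.cell_size
        smooth = gaussian_filter(noise, sigma=sigma_cells, mode="nearest")
        smooth = (smooth - smooth.mean()) / smooth.std()
        layers.append(
            CovariateGrid(
                name=f"cov{k}",
                origin_lon=grid_spec.origin_lon,
                origin_lat=grid_spec.origin_lat,
                cell_size=grid_spec.cell_size,
                values=smooth,
            )
        )
    return layers


def simulate_clusters(
    counts_per_wave: list[int] | None = None,
    grid_spec: GridSpec | None = None,
    seed: int = 0,
    wave_labels: list[str] | None = None,
) -> list[tuple[float, float, str]]:
    """Cluster locations uniform over the grid bounding box, labeled by wave."""
    if counts_per_wave is None:
        counts_per_wave = DEFAULT_COUNTS_PER_WAVE
    if not counts_per_wave:
        raise ValueError("counts_per_wave must be non-empty")
    if any(c < 1 for c in counts_per_wave):
        raise ValueError("all wave counts must be >= 1")
    if grid_spec is None:
        grid_spec = GridSpec()
    if wave_labels is None:
        wave_labels = (
            DEFAULT_WAVE_LABELS
            if len(counts_per_wave) == len(DEFAULT_WAVE_LABELS)
            else [str(i) for i in range(len(counts_per_wave))]
        )
    if len(wave_labels) != len(counts_per_wave):
        raise ValueError("wave_labels length must match counts_per_wave")
    rng = np.random.default_rng(subseed(seed, "clusters"))
    lon_min, lat_min, lon_max, lat_max = grid_spec.bounding_box()
    out = []
    for wave, count in zip(wave_labels, counts_per_wave):
        lons = rng.uniform(lon_min, lon_max, size=count)
        lats = rng.uniform(lat_min, lat_max, size=count)
        out.extend((float(lo), float(la), wave) for lo, la in zip(lons, lats))
    return out


def simulate_field(
    points: list[tuple[float, float]],
    params: MaternParams,
    seed: int = 0,
) -> np.ndarray:
    """Exact zero-mean multivariate-normal draw with Matérn covariance.

    Duplicate points are fine (the covariance jitter keeps the factorization
    valid).  With sigma = 0 the draw is numerically zero.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("need at least one (lon, lat) point")
    if params.sigma == 0:
        # degenerate field: jitter only guards factorization, not variance
        return np.zeros(pts.shape[0])
    km = project_points(pts)
    cov = build_covariance(km, params)
    chol = cholesky_with_escalation(cov)
    rng = np.random.default_rng(subseed(seed, "field"))
    return chol @ rng.standard_normal(pts.shape[0])


def simulate_outcomes(
    points: list[tuple[float, float]],
    waves: list[str],
    design: np.ndarray,
    truth: SyntheticTruth,
    children_per_cluster: int | tuple[int, int] = (5, 25),
    seed: int = 0,
    regions: list[str] | None = None,
) -> list[ClusterRecord]:
    """Binomial outcomes through the logit linear predictor.

    p_j = expit(alpha + x_j . beta + zeta_j);  Y_j ~ Binomial(n_j, p_j).
    """
    design = np.asarray(design, dtype=float)
    n_pts = len(points)
    if design.shape[0] != n_pts or len(waves) != n_pts:
        raise ValueError("design rows and waves must match points")
    if design.shape[1] != truth.beta_true.shape[0]:
        raise ValueError("beta_true length must match design columns")
    if truth.field_values.shape[0] != n_pts:
        raise ValueError("truth.field_values length must match points")
    rng = np.random.default_rng(subseed(seed, "outcomes"))
    eta = truth.alpha_true + design @ truth.beta_true + truth.field_values
    p = expit(eta)
    if isinstance(children_per_cluster, int):
        n_children = np.full(n_pts, children_per_cluster, dtype=int)
    else:
        lo, hi = children_per_cluster
        n_children = rng.integers(lo, hi + 1, size=n_pts)
    y = rng.binomial(n_children, p)
    if regions is None:
        regions = ["R1"] * n_pts
    return [
        ClusterRecord(
            cluster_id=j + 1,
            wave=waves[j],
            lon=points[j][0],
            lat=points[j][1],
            n_children=int(n_children[j]),
            n_underweight=int(y[j]),
            region_id=regions[j],
        )
        for j in range(n_pts)
    ]


@dataclass
class SyntheticDataset:
    """Bundled output of :func:`simulate_dataset`."""

    records: list[ClusterRecord]
    grids: list[CovariateGrid]
    design: np.ndarray
    truth: SyntheticTruth
    grid_spec: GridSpec
    field_at_cells: np.ndarray | None = None


def simulate_dataset(
    seed: int = 0,
    counts_per_wave: list[int] | None = None,
    grid_spec: GridSpec | None = None,
    alpha_true: float = -0.55,
    beta_true=(-0.39, 0.09),
    matern_true: MaternParams | None = None,
    smoothness_range: float = 1.0,
    children_per_cluster: int | tuple[int, int] = (5, 25),
    field_at_cells: bool = False,
) -> SyntheticDataset:
    """End-to-end generator: surfaces, clusters, field, outcomes.

    Defaults echo realistic effect sizes (intercept giving ~37% baseline
    prevalence; one negative and one mild positive covariate effect).  With
    ``field_at_cells`` the latent field is drawn jointly at the cluster
    points and every grid cell center, so a ground-truth prevalence surface
    is available for prediction tests.
    """
    if grid_spec is None:
        grid_spec = GridSpec()
    beta_true = np.asarray(beta_true, dtype=float)
    if matern_true is None:
        box = grid_spec.bounding_box()
        diam_deg = float(np.hypot(box[2] - box[0], box[3] - box[1]))
        matern_true = MaternParams(range_rho=0.25 * diam_deg * 111.0, sigma=0.5)
    grids = simulate_covariate_surfaces(
        beta_true.shape[0], grid_spec, smoothness_range, seed
    )
    placed = simulate_clusters(counts_per_wave, grid_spec, seed)
    points = [(lon, lat) for lon, lat, _ in placed]
    waves = [w for _, _, w in placed]
    from geoprev.core_io import extract_covariates

    design = extract_covariates(grids, points)
    if field_at_cells:
        cells = grid_spec.cell_centers()
        all_pts = list(points) + [tuple(c) for c in cells]
        zeta_all = simulate_field(all_pts, matern_true, seed)
        zeta, zeta_cells = zeta_all[: len(points)], zeta_all[len(points):]
    else:
        zeta = simulate_field(points, matern_true, seed)
        zeta_cells = None
    truth = SyntheticTruth(
        alpha_true=alpha_true,
        beta_true=beta_true,
        matern_true=matern_true,
        field_values=zeta,
        seed=seed,
    )
    records = simulate_outcomes(
        points, waves, design, truth, children_per_cluster, seed
    )
    return SyntheticDataset(
        records=records,
        grids=grids,
        design=design,
        truth=truth,
        grid_spec=grid_spec,
        field_at_cells=zeta_cells,
    )
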