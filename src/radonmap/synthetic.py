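"""Synthetic inputs for the radon disease-mapping pipeline.

Real national radon surveys and cancer-registry microdata are not
distributable, so every pipeline input is emulated here with the statistical
structure the analysis assumes:

* a right-skewed lognormal indoor-radon field on a 1 km grid, calibrated to a
  target geometric mean (49 Bq/m^3) and sample skewness (7.84);
* an irregular survey of the field (defaults sized like the 5553-point
  national survey);
* a contiguous partition of the grid into administrative regions with a
  rook-adjacency graph (defaults near the 234 regions of the study);
* region covariates (deprivation z-score, sex-specific smoking rates);
* stratified populations and Poisson cancer counts generated from the same
  log-linear BYM (ICAR + iid) model the inference module fits, with the
  ground truth recorded for parameter-recovery checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, spatial

from .geostat import VariogramModel

#: five-year age bands used for stratification
AGE_GROUPS = (
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80+",
)
SEXES = ("male", "female")

# age-pyramid fractions per band (sums to 1); a generic aging population
_PYRAMID = np.array(
    [0.05, 0.055, 0.06, 0.065, 0.07, 0.075, 0.075, 0.075, 0.08, 0.085,
     0.08, 0.065, 0.05, 0.04, 0.03, 0.02, 0.025]
)

# per-person cases over the whole accrual period, by age band.
# "lung": steeply age-rising, male-dominant; "nhl": low and nearly flat.
_LUNG_MALE = np.array(
    [1e-5, 1e-5, 1e-5, 2e-5, 3e-5, 5e-5, 1e-4, 2e-4, 5e-4, 1.2e-3,
     2.5e-3, 5e-3, 9e-3, 1.5e-2, 2.2e-2, 3.0e-2, 3.5e-2]
)
_NHL_MALE = np.full(17, 6e-4)


@dataclass(frozen=True)
class GridSpec:
    """Regular interpolation grid; 1 km cell spacing by default.

    Cells are indexed (row, col) zero-based and stored row-major; the centre
    of cell (r, c) is (x0 + (c + 0.5) dx, y0 + (r + 0.5) dy), so row 0 is the
    southernmost row.
    """

    nx: int
    ny: int
    x0: float = 0.0
    y0: float = 0.0
    dx: float = 1.0
    dy: float = 1.0

    def __post_init__(self):
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell spacing must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-centre coordinates, row-major."""
        cols = np.arange(self.nx)
        rows = np.arange(self.ny)
        xs = self.x0 + (cols + 0.5) * self.dx
        ys = self.y0 + (rows + 0.5) * self.dy
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class FieldParams:
    """Parameters of the lognormal radon field on the log scale."""

    mu_log: float
    variogram: VariogramModel
    measurement_sd_log: float = 0.0

    def __post_init__(self):
        if self.measurement_sd_log < 0:
            raise ValueError("measurement_sd_log must be >= 0")
        if not np.isfinite(self.mu_log):
            raise ValueError("mu_log must be finite")


@dataclass(frozen=True)
class RegionMap:
    """Partition of the grid into regions plus the CAR neighbourhood graph.

    ``membership`` is an (ny, nx) integer array of region ids (total and
    surjective onto ``region_ids``); ``adjacency`` contains each unordered
    pair of regions sharing at least one cell edge exactly once, as (a, b)
    with a < b.
    """

    region_ids: tuple
    membership: np.ndarray
    adjacency: frozenset

    def __post_init__(self):
        ids = set(self.region_ids)
        present = set(np.unique(self.membership).tolist())
        if present != ids:
            raise ValueError("membership must cover exactly the declared region ids")
        for a, b in self.adjacency:
            if a == b:
                raise ValueError("adjacency must be irreflexive")
            if a not in ids or b not in ids:
                raise ValueError(f"adjacency edge ({a},{b}) references unknown region")
        if len(self.region_ids) > 1 and not nx.is_connected(self.graph()):
            raise ValueError("region adjacency graph must be connected")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        g.add_edges_from(self.adjacency)
        return g

    def cell_counts(self) -> pd.Series:
        vals, counts = np.unique(self.membership, return_counts=True)
        return pd.Series(counts, index=vals).reindex(list(self.region_ids))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth used to generate counts, kept for recovery tests.

    ``beta_radon`` is the log relative risk per 10 Bq/m^3; sigma_u and
    sigma_v are the scales (std dev) of the ICAR and unstructured effects.
    """

    alpha: float = 0.0
    beta_radon: float = 0.0
    beta_smoking: float = 0.0
    beta_di: tuple = (0.0, 0.0, 0.0, 0.0)
    sigma_u: float = 0.0
    sigma_v: float = 0.0
    seed: int = 0

    def __post_init__(self):
        vals = [self.alpha, self.beta_radon, self.beta_smoking,
                self.sigma_u, self.sigma_v, *self.beta_di]
        if not np.all(np.isfinite(vals)):
            raise ValueError("truth parameters must be finite")
        if len(self.beta_di) != 4:
            raise ValueError("beta_di must have 4 entries (quintiles 2-5)")

    def to_json(self) -> str:
        d = asdict(self)
        d["beta_di"] = list(d["beta_di"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        d["beta_di"] = tuple(d["beta_di"])
        return cls(**d)


def _skewness_to_logvar(skew: float) -> float:
    """Log-scale variance of a lognormal with the given skewness.

    Solves (w + 2) sqrt(w - 1) = skew for w = exp(sigma^2).
    """
    if skew <= 0:
        raise ValueError("target skewness must be positive")

    def f(w):
        return (w + 2.0) * np.sqrt(w - 1.0) - skew

    w = optimize.brentq(f, 1.0 + 1e-12, 1e6)
    return float(np.log(w))


def calibrate_field_params(
    target_gm: float = 49.0,
    target_skewness: float = 7.84,
    family: str = "spherical",
    range_km: float = 4.0,
    nugget_frac: float = 0.3,
    measurement_sd_log: float = 0.0,
) -> FieldParams:
    """Field parameters hitting a target geometric mean and skewness.

    For a lognormal field, GM = exp(mu_log) and the skewness fixes the total
    log-scale variance; that variance is split between the variogram sill and
    iid measurement noise, and the sill between nugget and partial sill.
    Defaults target the national-survey summaries (GM 49 Bq/m^3, skewness
    7.84).
    """
    if target_gm <= 0:
        raise ValueError("target geometric mean must be positive")
    if not 0 <= nugget_frac <= 1:
        raise ValueError("nugget_frac must lie in [0, 1]")
    total_var = _skewness_to_logvar(target_skewness)
    sill = total_var - measurement_sd_log**2
    if sill <= 0:
        raise ValueError(
            "measurement noise variance exceeds the total log variance "
            "implied by the target skewness"
        )
    model = VariogramModel(
        family=family,
        nugget=nugget_frac * sill,
        psill=(1.0 - nugget_frac) * sill,
        range=range_km,
    )
    return FieldParams(
        mu_log=float(np.log(target_gm)),
        variogram=model,
        measurement_sd_log=measurement_sd_log,
    )


#: dense-Cholesky field simulation is limited to this many grid cells
MAX_FIELD_CELLS = 10_000


def simulate_log_field(grid: GridSpec, params: FieldParams, seed) -> np.ndarray:
    """Simulate a Gaussian log-radon field on the grid (dense Cholesky).

    The covariance is C(h) = sill - gamma(h) implied by the variogram
    (diagonal = full sill, i.e. the nugget acts as iid cell-level noise).
    Returns an (ny, nx) array; exponentiation gives the lognormal field.
    Grids beyond ``MAX_FIELD_CELLS`` cells are rejected: national-scale
    simulation is out of scope for this generator.
    """
    if grid.n_cells > MAX_FIELD_CELLS:
        raise ValueError(
            f"grid has {grid.n_cells} cells; dense simulation is limited to "
            f"{MAX_FIELD_CELLS}"
        )
    rng = np.random.default_rng(seed)
    model = params.variogram
    if model.sill == 0:
        return np.full((grid.ny, grid.nx), params.mu_log)
    xy = grid.cell_centers()
    d = spatial.distance.squareform(spatial.distance.pdist(xy))
    cov = model.covariance(d)
    np.fill_diagonal(cov, model.sill)
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * model.sill * np.eye(grid.n_cells))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "covariance implied by the variogram is not positive definite "
            f"(family={model.family}, nugget={model.nugget}, "
            f"psill={model.psill}, range={model.range})"
        ) from exc
    z = rng.standard_normal(grid.n_cells)
    return (params.mu_log + chol @ z).reshape(grid.ny, grid.nx)


def sample_survey_points(
    log_field: np.ndarray,
    grid: GridSpec,
    n_points: int,
    measurement_sd_log: float = 0.0,
    seed=None,
    replace: bool = True,
    cluster_factor: float = 0.0,
    jitter: bool = True,
) -> pd.DataFrame:
    """Draw survey measurement points from the simulated field.

    Cells are chosen uniformly (optionally biased towards a few cluster
    centres when ``cluster_factor`` > 0); each point's concentration is
    exp(field at its cell + iid Normal(0, measurement_sd_log^2)). Points are
    placed uniformly within their cell when ``jitter`` is on, else at the
    cell centre. Returns columns x_km, y_km, radon_bqm3, row, col.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    n_cells = grid.n_cells
    if not replace and n_points > n_cells:
        raise ValueError(
            f"cannot sample {n_points} distinct cells from {n_cells} without replacement"
        )
    rng = np.random.default_rng(seed)
    if cluster_factor > 0:
        centers = grid.cell_centers()
        k = 5
        hubs = centers[rng.choice(n_cells, size=min(k, n_cells), replace=False)]
        scale = 0.15 * max(grid.nx * grid.dx, grid.ny * grid.dy)
        d2 = spatial.distance.cdist(centers, hubs) ** 2
        w = 1.0 + cluster_factor * np.exp(-d2 / (2 * scale**2)).sum(axis=1)
        p = w / w.sum()
    else:
        p = None
    cells = rng.choice(n_cells, size=n_points, replace=replace, p=p)
    rows, cols = np.divmod(cells, grid.nx)
    if jitter:
        ux = rng.uniform(0.0, 1.0, n_points)
        uy = rng.uniform(0.0, 1.0, n_points)
    else:
        ux = uy = np.full(n_points, 0.5)
    x = grid.x0 + (cols + ux) * grid.dx
    y = grid.y0 + (rows + uy) * grid.dy
    logz = np.asarray(log_field)[rows, cols]
    if measurement_sd_log > 0:
        logz = logz + rng.normal(0.0, measurement_sd_log, n_points)
    return pd.DataFrame(
        {"x_km": x, "y_km": y, "radon_bqm3": np.exp(logz), "row": rows, "col": cols}
    )


def _adjacency_from_membership(member: np.ndarray) -> frozenset:
    pairs = set()
    h = np.stack([member[:, :-1].ravel(), member[:, 1:].ravel()], axis=1)
    v = np.stack([member[:-1, :].ravel(), member[1:, :].ravel()], axis=1)
    for a, b in np.vstack([h, v]):
        if a != b:
            pairs.add((min(a, b), max(a, b)))
    return frozenset((int(a), int(b)) for a, b in pairs)


def _grow_regions(grid: GridSpec, n_regions: int, rng) -> np.ndarray:
    """Contiguous partition grown from random seed cells."""
    nx_, ny_ = grid.nx, grid.ny
    n_cells = nx_ * ny_
    member = np.full(n_cells, -1, dtype=int)
    seeds = rng.choice(n_cells, size=n_regions, replace=False)
    frontiers: list[list[int]] = [[] for _ in range(n_regions)]
    for rid, cell in enumerate(seeds):
        member[cell] = rid
    for rid, cell in enumerate(seeds):
        r, c = divmod(cell, nx_)
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < ny_ and 0 <= nc < nx_:
                frontiers[rid].append(nr * nx_ + nc)
    active = list(range(n_regions))
    n_assigned = n_regions
    while n_assigned < n_cells:
        rid = active[rng.integers(len(active))]
        fr = frontiers[rid]
        cell = -1
        while fr:
            j = rng.integers(len(fr))
            cand = fr[j]
            fr[j] = fr[-1]
            fr.pop()
            if member[cand] == -1:
                cell = cand
                break
        if cell == -1:
            active.remove(rid)
            continue
        member[cell] = rid
        n_assigned += 1
        r, c = divmod(cell, nx_)
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < ny_ and 0 <= nc < nx_:
                cand = nr * nx_ + nc
                if member[cand] == -1:
                    fr.append(cand)
    return member.reshape(ny_, nx_) + 1  # region ids 1..n


def make_regions(
    grid: GridSpec,
    n_regions: int,
    seed=None,
    mode: str = "random",
    max_retries: int = 10,
) -> RegionMap:
    """Partition the grid into contiguous regions with a rook adjacency graph.

    ``mode="random"`` grows regions from random seed cells; ``mode="blocks"``
    splits the grid deterministically into near-equal rectangular blocks
    (ids assigned row-major starting at 1 — four regions on a square grid
    give the four quadrants). The region adjacency graph is checked for
    connectivity, regenerating up to ``max_retries`` times before erroring.
    """
    if n_regions < 1 or n_regions > grid.n_cells:
        raise ValueError("n_regions must be between 1 and the number of cells")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        if mode == "blocks":
            n_brow = int(np.floor(np.sqrt(n_regions * grid.ny / grid.nx))) or 1
            while n_regions % n_brow:
                n_brow -= 1
            n_bcol = n_regions // n_brow
            row_edges = np.linspace(0, grid.ny, n_brow + 1).astype(int)
            col_edges = np.linspace(0, grid.nx, n_bcol + 1).astype(int)
            member = np.empty((grid.ny, grid.nx), dtype=int)
            rid = 1
            for i in range(n_brow):
                for j in range(n_bcol):
                    member[row_edges[i]:row_edges[i + 1],
                           col_edges[j]:col_edges[j + 1]] = rid
                    rid += 1
        elif mode == "random":
            member = _grow_regions(grid, n_regions, rng)
        else:
            raise ValueError(f"unknown region mode {mode!r}")
        adjacency = _adjacency_from_membership(member)
        ids = tuple(range(1, n_regions + 1))
        try:
            return RegionMap(ids, member, adjacency)
        except ValueError:
            if mode == "blocks":
                raise
            continue
    raise RuntimeError(
        f"failed to generate a connected region partition in {max_retries} tries"
    )


def sample_icar(regions: RegionMap, sigma: float, rng) -> np.ndarray:
    """Draw spatially structured effects from the intrinsic CAR prior.

    The ICAR prior is improper (flat along the constant vector), so the draw
    is taken on the proper (n-1)-dimensional subspace via eigendecomposition
    of the graph Laplacian, then recentred to sum exactly to zero. ``sigma``
    is the conditional scale 1/sqrt(tau_u).
    """
    n = regions.n_regions
    if sigma == 0 or n == 1:
        return np.zeros(n)
    lap = nx.laplacian_matrix(regions.graph(), nodelist=list(regions.region_ids))
    lam, vec = np.linalg.eigh(lap.toarray().astype(float))
    pos = lam > 1e-10
    z = rng.standard_normal(int(pos.sum()))
    u = sigma * (vec[:, pos] @ (z / np.sqrt(lam[pos])))
    return u - u.mean()


def default_reference_rates(kind: str = "lung") -> pd.DataFrame:
    """Built-in reference incidence per person over the accrual period.

    ``kind="lung"`` rises steeply with age and is male-dominant;
    ``kind="nhl"`` is low and nearly flat across ages. Returns columns
    sex, age_group, rate.
    """
    if kind == "lung":
        male, female = _LUNG_MALE, 0.35 * _LUNG_MALE
    elif kind == "nhl":
        male, female = _NHL_MALE, 0.75 * _NHL_MALE
    else:
        raise ValueError(f"unknown rate table {kind!r}")
    rows = []
    for sex, rates in (("male", male), ("female", female)):
        for ag, r in zip(AGE_GROUPS, rates):
            rows.append({"sex": sex, "age_group": ag, "rate": float(r)})
    return pd.DataFrame(rows)


def make_region_covariates(
    regions: RegionMap, radon_true: pd.Series | np.ndarray, seed=None
) -> pd.DataFrame:
    """Region-level confounders plus the true radon mean.

    Deprivation z-scores are standard normal; sex-specific smoking rates are
    uniform over the observed regional ranges of the study population
    (male 31.9-62.4%, female 0.4-12.5%).
    """
    rng = np.random.default_rng(seed)
    n = regions.n_regions
    radon = np.asarray(radon_true, float)
    if radon.shape != (n,):
        raise ValueError("radon_true must have one entry per region")
    return pd.DataFrame(
        {
            "region_id": list(regions.region_ids),
            "deprivation_z": rng.standard_normal(n),
            "smoking_male": rng.uniform(31.9, 62.4, n),
            "smoking_female": rng.uniform(0.4, 12.5, n),
            "radon_true": radon,
        }
    )


def simulate_strata_and_counts(
    regions: RegionMap,
    covariates: pd.DataFrame,
    truth: TruthRecord,
    reference_rates: pd.DataFrame | None = None,
    seed=None,
    mean_population: float = 172_857.0,
    population_sd_log: float = 0.8,
) -> pd.DataFrame:
    """Stratified populations and Poisson cancer counts per region.

    Region totals are lognormal around ``mean_population`` (default sized
    like the study regions), split by a fixed age pyramid and an even sex
    ratio. Expected counts come from the reference rates; observed counts are
    Poisson with the region relative risk
    exp(alpha + beta_radon * radon/10 + covariate terms + u + v), u drawn
    from the sum-to-zero ICAR prior and v iid normal — the same model the
    inference module fits. Returns the strata table (region_id, sex,
    age_group, population, observed).
    """
    from .carbayes import build_design  # shared design construction

    if reference_rates is None:
        reference_rates = default_reference_rates("lung")
    if (reference_rates["rate"] < 0).any():
        raise ValueError("reference rates must be nonnegative")
    rng = np.random.default_rng(seed)
    n = regions.n_regions
    ids = list(regions.region_ids)
    cov = covariates.set_index("region_id").loc[ids]

    # median-preserving lognormal totals
    totals = np.exp(
        np.log(mean_population) - population_sd_log**2 / 2
        + population_sd_log * rng.standard_normal(n)
    )
    u = sample_icar(regions, truth.sigma_u, rng)
    v = truth.sigma_v * rng.standard_normal(n) if truth.sigma_v > 0 else np.zeros(n)

    beta = np.array([truth.beta_radon, truth.beta_smoking, *truth.beta_di])
    theta = {}
    for sex in SEXES:
        x, _ = build_design(cov["radon_true"], covariates, sex=sex, adjusted=True)
        theta[sex] = np.exp(truth.alpha + x @ beta + u + v)

    rate_lut = reference_rates.set_index(["sex", "age_group"])["rate"]
    n_ag = len(AGE_GROUPS)
    frames = []
    for sex in SEXES:
        rates = rate_lut.loc[sex].reindex(list(AGE_GROUPS)).to_numpy()
        if np.isnan(rates).any():
            raise ValueError(f"reference rates incomplete for sex {sex!r}")
        pop = np.round(np.outer(totals, _PYRAMID) * 0.5).astype(int)  # (n, n_ag)
        lam = pop * rates[None, :] * theta[sex][:, None]
        obs = np.minimum(rng.poisson(lam), pop)
        frames.append(pd.DataFrame({
            "region_id": np.repeat(ids, n_ag),
            "sex": sex,
            "age_group": np.tile(AGE_GROUPS, n),
            "population": pop.ravel(),
            "observed": obs.ravel(),
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["region_id", "sex", "age_group"], kind="stable", ignore_index=True
    )
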