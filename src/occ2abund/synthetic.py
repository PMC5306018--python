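"""Virtual landscapes, species, and surveys for validating the two-stage pipeline.

The generator produces everything the real pipeline consumes, with known
truth attached:

* spatially autocorrelated environmental covariate rasters (1-km cells),
* virtual species with logistic occupancy surfaces and zero-inflated
  abundance surfaces in which other species' occupancy can suppress or boost
  abundance (pairwise biotic interactions such as competition),
* presence-only occurrence records produced by effort-dependent, imperfect
  detection surveys at tetrad (2x2 km) resolution, with a survey log,
* percent-cover abundance samples in two source dialects (within-patch
  percentages and linear/nonlinear plot percentages),
* true tree-cover covariate layers (all trees, woodland trees, non-woodland
  trees, woodland edge) derived from a fine-scale synthetic woodland mask.

Every generator is a pure function of its configuration and seed: the same
seed yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import CATEGORICAL, CONTINUOUS, CovariateStack, GridSpec
from .harmonize import compute_edge_cover

TETRAD = 2  # tetrad edge length in 1-km cells


def species_names(n: int) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(n)]


def tetrad_id(tx, ty) -> np.ndarray:
    tx = np.asarray(tx)
    ty = np.asarray(ty)
    flat = np.char.add(np.char.add("T", np.char.zfill(tx.astype(str), 3)),
                       np.char.add("_", np.char.zfill(ty.astype(str), 3)))
    return flat


@dataclass
class LandscapeConfig:
    """Configuration of a synthetic landscape.

    grid_size            cells per side (1-km cells); must be >= 8
    n_covariates         number of continuous environmental layers
    autocorrelation_range  Gaussian smoothing range, in cells
    n_species            number of virtual species (>= 2)
    seed                 master seed; same seed -> bit-identical outputs
    n_drivers            covariates with nonzero effect per species
    beta_range           |effect size| range for driver covariates
    prevalence_range     target fraction of cells with occupancy > 0.5
    occupancy_floor      occupancy below which true abundance is zero
    max_abundance_range  per-species abundance ceiling, ha/km²
    interaction_density  probability an ordered species pair interacts
    interaction_scale    |interaction coefficient| upper bound
    fine_cellsize        resolution (m) of the fine woodland mask
    """

    grid_size: int = 32
    n_covariates: int = 5
    autocorrelation_range: float = 4.0
    n_species: int = 5
    seed: int = 0
    n_categorical: int = 1
    n_drivers: int = 3
    beta_range: tuple[float, float] = (1.5, 2.5)
    prevalence_range: tuple[float, float] = (0.3, 0.5)
    occupancy_floor: float = 0.3
    max_abundance_range: tuple[float, float] = (20.0, 60.0)
    interaction_density: float = 0.2
    interaction_scale: float = 0.6
    fine_cellsize: float = 50.0
    cell_size: float = 1000.0

    def __post_init__(self):
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_covariates < 1:
            raise ValueError("n_covariates must be >= 1")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(nx=self.grid_size, ny=self.grid_size, cell_size=self.cell_size)

    @property
    def species(self) -> list[str]:
        return species_names(self.n_species)


@dataclass
class SyntheticTruth:
    """Generating surfaces and coefficients of a virtual-species landscape."""

    grid: GridSpec
    species: list[str]
    occupancy_surface: np.ndarray      # (S, ny, nx), true P(x) in [0, 1]
    realized_occurrence: np.ndarray    # (S, ny, nx) binary draw from P(x)
    abundance_surface: np.ndarray      # (S, ny, nx), ha/km² in [0, 100]
    interaction_matrix: np.ndarray     # (S, S) signed effects, zero diagonal
    cover_surfaces: dict[str, np.ndarray]  # C_A, C_W, C_O, C_E in [0, 1]
    woodland_fraction: np.ndarray      # fraction of each cell that is woodland
    linear_fraction: np.ndarray        # fraction covered by linear features
    occupancy_coefficients: np.ndarray  # (S, n_continuous) logistic betas
    occupancy_floor: float = 0.3

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def tetrad_occurrence(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Realized occupancy at tetrad level: species occupies a tetrad if it
        occupies any member 1-km cell. Returns (occ[S, ty, tx], tx_ids, ty_ids)."""
        s, ny, nx = self.realized_occurrence.shape
        cy, cx = -(-ny // TETRAD), -(-nx // TETRAD)
        occ = np.zeros((s, cy, cx), dtype=bool)
        for ty in range(cy):
            for tx in range(cx):
                block = self.realized_occurrence[:, ty * TETRAD:(ty + 1) * TETRAD,
                                                 tx * TETRAD:(tx + 1) * TETRAD]
                occ[:, ty, tx] = block.any(axis=(1, 2))
        return occ, np.arange(cx), np.arange(cy)

    def tetrad_centers(self, tx, ty):
        s = self.grid.cell_size * TETRAD
        return (np.asarray(tx) + 0.5) * s + self.grid.x0, \
               (np.asarray(ty) + 0.5) * s + self.grid.y0


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized Gaussian random field via convolution smoothing of white noise."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def gen_covariate_stack(config: LandscapeConfig) -> CovariateStack:
    """Generate the environmental covariate stack: ``n_covariates`` continuous
    spatially autocorrelated layers plus categorical layer(s) obtained by
    quantile-binning an independent smooth field into 4 classes."""
    rng = np.random.default_rng([config.seed, 101])
    n = config.grid_size
    stack = CovariateStack(config.grid)
    for i in range(config.n_covariates):
        layer = _smooth_field(rng, (n, n), config.autocorrelation_range)
        stack.add_layer(f"env{i + 1:02d}", layer, CONTINUOUS, priority=i + 1)
    for j in range(config.n_categorical):
        base = _smooth_field(rng, (n, n), config.autocorrelation_range)
        codes = np.searchsorted(np.quantile(base, [0.25, 0.5, 0.75]), base)
        stack.add_layer(f"class{j + 1:02d}", codes.astype(int), CATEGORICAL,
                        priority=config.n_covariates + j + 1)
    return stack


def _gen_cover_surfaces(rng: np.random.Generator, config: LandscapeConfig):
    """Fine woodland mask -> woodland fraction, canopy covers, and edge layer."""
    n = config.grid_size
    factor = int(round(config.cell_size / config.fine_cellsize))
    target = 1.0 / (1.0 + np.exp(-(1.5 * _smooth_field(rng, (n, n), 4.0) + 0.2)))
    target *= 0.9
    # clustered fine mask whose per-cell woodland count matches the target
    key = ndimage.gaussian_filter(rng.standard_normal((n * factor, n * factor)),
                                  sigma=3.0, mode="reflect")
    mask = np.zeros((n * factor, n * factor), dtype=bool)
    counts = np.round(target * factor * factor).astype(int)
    for iy in range(n):
        for ix in range(n):
            k = counts[iy, ix]
            if k == 0:
                continue
            block = key[iy * factor:(iy + 1) * factor, ix * factor:(ix + 1) * factor]
            thr = np.partition(block.ravel(), k - 1)[k - 1]
            sel = block <= thr
            mask[iy * factor:(iy + 1) * factor,
                 ix * factor:(ix + 1) * factor] = sel
    woodland_fraction = mask.reshape(n, factor, n, factor).mean(axis=(1, 3))
    canopy = 0.6 + 0.3 / (1.0 + np.exp(-_smooth_field(rng, (n, n), 4.0)))
    c_w = woodland_fraction * canopy
    c_o = (0.15 / (1.0 + np.exp(-_smooth_field(rng, (n, n), 4.0)))) \
        * (1.0 - woodland_fraction)
    c_a = np.clip(c_w + c_o, 0.0, 1.0)
    c_e = compute_edge_cover(mask, distance=50.0, fine_cellsize=config.fine_cellsize,
                             out_cellsize=config.cell_size)
    linear = 0.02 + 0.1 / (1.0 + np.exp(-_smooth_field(rng, (n, n), 4.0)))
    covers = {"C_A": c_a, "C_W": c_w, "C_O": c_o, "C_E": c_e}
    return covers, woodland_fraction, linear


def gen_virtual_species(stack: CovariateStack, config: LandscapeConfig,
                        interaction_matrix: np.ndarray | None = None) -> SyntheticTruth:
    """Create virtual species on a covariate stack.

    Occupancy is logistic in the continuous covariates: each species responds
    to ``n_drivers`` randomly chosen layers with effect sizes in
    ``beta_range``; the intercept is calibrated so the fraction of cells with
    P > 0.5 lands in ``prevalence_range``. Abundance is zero wherever
    occupancy is below ``occupancy_floor`` and otherwise scales linearly with
    occupancy above the floor, modulated multiplicatively by the
    interaction-weighted occupancy of the other species:

        A_s = clip(amax_s * (P_s - floor) / (1 - floor), 0, 100)
              * max(0, 1 + sum_j M[s, j] * P_j)

    With a zero interaction matrix, abundance is monotone in own occupancy.
    """
    rng = np.random.default_rng([config.seed, 202])
    cont = stack.continuous_names()
    x = np.stack([stack.layers[n] for n in cont])  # (C, ny, nx)
    s = config.n_species
    c = len(cont)
    betas = np.zeros((s, c))
    occupancy = np.zeros((s,) + x.shape[1:])
    for i in range(s):
        drivers = rng.choice(c, size=min(config.n_drivers, c), replace=False)
        mag = rng.uniform(*config.beta_range, size=drivers.size)
        sign = rng.choice([-1.0, 1.0], size=drivers.size)
        betas[i, drivers] = mag * sign
        eta = np.tensordot(betas[i], x, axes=(0, 0))
        prev = rng.uniform(*config.prevalence_range)
        intercept = -np.quantile(eta, 1.0 - prev)  # calibrate P>0.5 fraction
        occupancy[i] = 1.0 / (1.0 + np.exp(-(eta + intercept)))
    realized = rng.random(occupancy.shape) < occupancy

    if interaction_matrix is None:
        m = np.zeros((s, s))
        pairs = rng.random((s, s)) < config.interaction_density
        np.fill_diagonal(pairs, False)
        mag = rng.uniform(0.3, 1.0, size=(s, s)) * config.interaction_scale
        sign = np.where(rng.random((s, s)) < 0.7, -1.0, 1.0)  # competition-biased
        m = np.where(pairs, mag * sign, 0.0)
    else:
        m = np.asarray(interaction_matrix, dtype=float)
        if m.shape != (s, s):
            raise ValueError(f"interaction matrix must be {(s, s)}, got {m.shape}")

    amax = rng.uniform(*config.max_abundance_range, size=s)
    floor = config.occupancy_floor
    base = np.clip((occupancy - floor) / (1.0 - floor), 0.0, None)
    modifier = np.clip(1.0 + np.tensordot(m, occupancy, axes=(1, 0)), 0.0, None)
    abundance = np.clip(amax[:, None, None] * base * modifier, 0.0, 100.0)
    abundance[occupancy < floor] = 0.0

    covers, woodland_fraction, linear = _gen_cover_surfaces(
        np.random.default_rng([config.seed, 303]), config)
    return SyntheticTruth(
        grid=config.grid, species=config.species,
        occupancy_surface=occupancy, realized_occurrence=realized,
        abundance_surface=abundance, interaction_matrix=m,
        cover_surfaces=covers, woodland_fraction=woodland_fraction,
        linear_fraction=linear, occupancy_coefficients=betas,
        occupancy_floor=floor)


@dataclass
class EffortModel:
    """Survey-effort parameters for presence-only sampling.

    Tetrads are surveyed with probability ``p_surveyed``; each surveyed tetrad
    receives ``min_surveys + Poisson(extra_surveys_mean)`` survey visits. Each
    visit logs a total plant species count: well-resourced visits draw from
    Normal(species_count_mean, species_count_sd); a fraction
    ``undersurveyed_fraction`` of tetrads get poor visits (counts uniform in
    [10, 49], below the usual well-surveyed bar). During a visit each species
    realized-present in the tetrad is detected independently with probability
    ``detection_prob``; detections become presence-only records. A fraction of
    records carry finer-than-tetrad precision and a small fraction are coarse
    (10-km class) and thus unusable downstream.
    """

    p_surveyed: float = 1.0
    min_surveys: int = 0
    extra_surveys_mean: float = 2.0
    detection_prob: float = 0.9
    species_count_mean: float = 70.0
    species_count_sd: float = 12.0
    undersurveyed_fraction: float = 0.15
    year_range: tuple[int, int] = (1950, 2014)
    finer_fraction: float = 0.3
    coarse_fraction: float = 0.02


def sample_occurrences(truth: SyntheticTruth, effort: EffortModel, seed: int,
                       effort_mask: np.ndarray | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate presence-only records and a survey log.

    Returns ``(records, survey_log)``: records have columns (species,
    tetrad_id, year, precision in {monad, tetrad, hectad}); the log has one
    row per survey visit (tetrad_id, year, species_count). ``effort_mask``,
    if given, is a boolean (ty, tx) array: tetrads outside it receive no
    surveys at all (deliberately under-surveyed regions).
    """
    rng = np.random.default_rng([seed, 404])
    occ, txs, tys = truth.tetrad_occurrence()
    s = len(truth.species)
    rec_rows, log_rows = [], []
    y0, y1 = effort.year_range
    for ty in tys:
        for tx in txs:
            if effort_mask is not None and not effort_mask[ty, tx]:
                continue
            if rng.random() >= effort.p_surveyed:
                continue
            n_surveys = effort.min_surveys + rng.poisson(effort.extra_surveys_mean)
            if n_surveys == 0:
                continue
            tid = f"T{tx:03d}_{ty:03d}"
            poor = rng.random() < effort.undersurveyed_fraction
            for _ in range(n_surveys):
                year = int(rng.integers(y0, y1 + 1))
                if poor:
                    count = int(rng.integers(10, 50))
                else:
                    count = max(0, int(round(rng.normal(
                        effort.species_count_mean, effort.species_count_sd))))
                log_rows.append((tid, year, count))
                for i in range(s):
                    if occ[i, ty, tx] and rng.random() < effort.detection_prob:
                        u = rng.random()
                        if u < effort.coarse_fraction:
                            precision = "hectad"
                        elif u < effort.coarse_fraction + effort.finer_fraction:
                            precision = "monad"
                        else:
                            precision = "tetrad"
                        rec_rows.append((truth.species[i], tid, year, precision))
    records = pd.DataFrame(rec_rows, columns=["species", "tetrad_id", "year",
                                              "precision"])
    log = pd.DataFrame(log_rows, columns=["tetrad_id", "year", "species_count"])
    return records, log


def sample_abundance(truth: SyntheticTruth, n_patch_source: int,
                     n_plot_source: int, noise_sd: float,
                     seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw abundance records in the two raw source dialects.

    Patch records report percent cover of the species within the woodland of
    the cell (truth / woodland_fraction), drawn only in cells where that
    within-patch percentage is representable (woodland present and <= 100%).
    Plot records report linear and nonlinear plot percentages whose weighted
    combination reproduces the true cover exactly when ``noise_sd`` is 0.
    Gaussian noise of ``noise_sd`` (cover units) is added to raw percentages,
    which are then clipped to [0, 100].
    """
    if n_patch_source < 0 or n_plot_source < 0:
        raise ValueError("record counts must be non-negative")
    rng = np.random.default_rng([seed, 505])
    s = len(truth.species)
    abund = truth.abundance_surface.reshape(s, -1)
    wf = truth.woodland_fraction.ravel()
    lf = truth.linear_fraction.ravel()
    n_cells = wf.size

    patch_rows = []
    for _ in range(n_patch_source):
        i = int(rng.integers(s))
        for _attempt in range(200):
            cell = int(rng.integers(n_cells))
            if wf[cell] > 0 and abund[i, cell] <= 100.0 * wf[cell]:
                break
        else:
            continue
        pct = abund[i, cell] / wf[cell]
        if noise_sd > 0:
            pct = float(np.clip(pct + rng.normal(0.0, noise_sd), 0.0, 100.0))
        patch_rows.append((truth.species[i], cell, pct))
    patch = pd.DataFrame(patch_rows, columns=["species", "cell_id", "patch_percent"])

    plot_rows = []
    for _ in range(n_plot_source):
        i = int(rng.integers(s))
        cell = int(rng.integers(n_cells))
        a = abund[i, cell]
        f = lf[cell]
        linear = 1.5 * a
        nonlinear = (a - linear * f) / (1.0 - f)
        if linear > 100.0 or nonlinear > 100.0 or nonlinear < 0.0:
            linear = nonlinear = a  # degenerate but always representable
        if noise_sd > 0:
            linear = float(np.clip(linear + rng.normal(0.0, noise_sd), 0.0, 100.0))
            nonlinear = float(np.clip(nonlinear + rng.normal(0.0, noise_sd), 0.0, 100.0))
        plot_rows.append((truth.species[i], cell, linear, nonlinear, f))
    plot = pd.DataFrame(plot_rows, columns=["species", "cell_id", "linear_percent",
                                            "nonlinear_percent", "linear_fraction"])
    return patch, plot
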