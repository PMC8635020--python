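"""Local/global myocyte disarray, alignment, and log-normal statistics.

The orientation vector field is dissected into macrovoxels of m x m x m
vectors (sides of 32-96 um for m = 2..6 at the default 16-um chunk).
Within each valid macrovoxel the *local disarray*

    d_g = (1 - |mean of unit vectors|) * 100   [%]

measures the angular spread of nearby orientations (0% for perfectly
parallel vectors; the mean resultant length is the classic concentration
statistic for directional data), and the *local alignment* a_g is the mean
y-component, i.e. the projection on the strip's traction axis. Global
disarray D and alignment A average the valid macrovoxels. Sample-wide
local-disarray distributions (LDDs) are summarized by a log-normal fit
whose mode and standard deviation follow from the ln-scale parameters.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import Volume, logger
from .orientation import VectorField

#: a macrovoxel is valid iff at least this share of its m^3 vector slots
#: holds a reliable orientation vector
VALID_FRACTION = 0.5

#: minimum number of positive d values accepted for a log-normal fit
MIN_FIT_N = 20


def local_disarray(vectors: np.ndarray) -> float:
    """Local disarray (%) of a set of orientation vectors.

    Vectors are normalized to unit length and averaged; the disarray is
    ``(1 - |mean|) * 100``. Requires at least one vector.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[0] == 0:
        raise ValueError("no vectors")
    units = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    return float((1.0 - np.linalg.norm(units.mean(axis=0))) * 100.0)


def local_alignment(vectors: np.ndarray) -> float:
    """Mean y-component of unit orientation vectors ([vz, vy, vx] order)."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[0] == 0:
        raise ValueError("no vectors")
    units = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    return float(units[:, 1].mean())


@dataclasses.dataclass
class DisarrayMap:
    """Macrovoxel-scale disarray/alignment grids plus global statistics."""

    m: int                       # vectors per macrovoxel side
    side_um: float               # physical macrovoxel side
    d_g: np.ndarray              # local disarray (%), NaN where invalid
    a_g: np.ndarray              # local alignment, NaN where invalid
    n_g: np.ndarray              # reliable vectors per macrovoxel
    valid: np.ndarray            # >= 50% reliable slots
    N_v: int                     # number of valid macrovoxels
    D: float                     # global disarray (%)
    A: float                     # global alignment

    def valid_d(self) -> np.ndarray:
        return self.d_g[self.valid]


def disarray_map(field: VectorField, m: int, chunk_um: float = 16.0
                 ) -> DisarrayMap:
    """Compute the local disarray map of a vector field at scale m.

    The vector grid is tiled into non-overlapping m^3 macrovoxels from the
    grid origin (partial macrovoxels at the far edges are discarded). A
    macrovoxel is valid iff at least half of its slots hold reliable
    vectors; d_g and a_g are computed over the reliable vectors only, and
    the global statistics D, A are arithmetic means over valid
    macrovoxels.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    gz, gy, gx = (s // m for s in field.grid_shape)
    if min(gz, gy, gx) < 1:
        raise ValueError("vector field smaller than one macrovoxel")
    shape = (gz, gy, gx)
    d_g = np.full(shape, np.nan)
    a_g = np.full(shape, np.nan)
    n_g = np.zeros(shape, dtype=int)
    valid = np.zeros(shape, dtype=bool)
    slots = m ** 3
    for idx in np.ndindex(shape):
        block = field.records[idx[0] * m:(idx[0] + 1) * m,
                              idx[1] * m:(idx[1] + 1) * m,
                              idx[2] * m:(idx[2] + 1) * m]
        dirs = [r.direction for r in block.ravel() if r.is_reliable]
        n_g[idx] = len(dirs)
        if len(dirs) >= VALID_FRACTION * slots:
            valid[idx] = True
            arr = np.array(dirs)
            d_g[idx] = local_disarray(arr)
            a_g[idx] = local_alignment(arr)
    N_v = int(valid.sum())
    D = float(d_g[valid].mean()) if N_v else float("nan")
    A = float(a_g[valid].mean()) if N_v else float("nan")
    return DisarrayMap(m=m, side_um=m * chunk_um, d_g=d_g, a_g=a_g,
                       n_g=n_g, valid=valid, N_v=N_v, D=D, A=A)


# ---------------------------------------------------------------------------
# log-normal statistics

@dataclasses.dataclass
class LogNormalFit:
    """Log-normal fit of a local-disarray distribution.

    mu and sigma are the ln-scale mean and SD; the derived mode and
    standard deviation are

        mode    = exp(mu - sigma^2)
        std_dev = sqrt[(exp(sigma^2) - 1) * exp(2 mu + sigma^2)]

    Log-normality is checked with the D'Agostino-Pearson normality test
    applied to ln(d).
    """

    mu: float
    sigma: float
    mode: float
    std_dev: float
    statistic: float
    p_value: float
    n: int
    n_excluded: int

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = (1.0 / (x[pos] * self.sigma * np.sqrt(2 * np.pi))
                    * np.exp(-(np.log(x[pos]) - self.mu) ** 2
                             / (2 * self.sigma ** 2)))
        return out


def lognormal_mode_std(mu: float, sigma: float) -> tuple[float, float]:
    """Closed-form mode and SD of a log-normal with ln-scale (mu, sigma)."""
    mode = np.exp(mu - sigma ** 2)
    std = np.sqrt((np.exp(sigma ** 2) - 1.0) * np.exp(2 * mu + sigma ** 2))
    return float(mode), float(std)


def fit_lognormal(d_values: np.ndarray) -> LogNormalFit:
    """Fit a log-normal to positive local-disarray values.

    mu and sigma are ln-moment estimates (the MLE for a log-normal);
    values <= 0 are excluded (ln undefined) and counted. Refuses to fit
    fewer than 20 positive values.
    """
    d_values = np.asarray(d_values, dtype=float)
    d_values = d_values[np.isfinite(d_values)]
    pos = d_values[d_values > 0]
    n_excluded = d_values.size - pos.size
    if pos.size < MIN_FIT_N:
        raise ValueError(
            f"need >= {MIN_FIT_N} positive values to fit, got {pos.size}")
    ln = np.log(pos)
    mu = float(ln.mean())
    sigma = float(ln.std())
    mode, std = lognormal_mode_std(mu, sigma)
    stat, p = stats.normaltest(ln)
    return LogNormalFit(mu=mu, sigma=sigma, mode=mode, std_dev=std,
                        statistic=float(stat), p_value=float(p),
                        n=pos.size, n_excluded=n_excluded)


def multiresolution_table(field: VectorField, m_list=(2, 3, 4, 5, 6),
                          chunk_um: float = 16.0) -> pd.DataFrame:
    """Disarray statistics at several macrovoxel scales, one row per m.

    Columns: m, side_um, N_v, D, A, mode, std_dev, lognormal_p. The
    log-normal columns are NaN when too few positive d values exist at
    that scale.
    """
    rows = []
    for m in m_list:
        try:
            dmap = disarray_map(field, m, chunk_um)
        except ValueError as exc:
            logger.warning("m=%d skipped: %s", m, exc)
            continue
        mode = std = p = float("nan")
        try:
            fit = fit_lognormal(dmap.valid_d())
            mode, std, p = fit.mode, fit.std_dev, fit.p_value
        except ValueError as exc:
            logger.warning("m=%d log-normal fit skipped: %s", m, exc)
        rows.append((m, dmap.side_um, dmap.N_v, dmap.D, dmap.A,
                     mode, std, p))
    if not rows:
        logger.warning("empty field: no disarray statistics")
    return pd.DataFrame(rows, columns=["m", "side_um", "N_v", "D", "A",
                                       "mode", "std_dev", "lognormal_p"])


def render_disarray_volume(dmap: DisarrayMap, sigma_um: float = 10.0,
                           chunk_um: float = 16.0) -> Volume:
    """Smoothed 3D disarray map for visualization.

    Local disarray values are painted into a voxel grid at the orientation
    chunk resolution (one voxel per 16-um chunk), invalid regions set to
    0, then smoothed with an isotropic Gaussian of ``sigma_um``. Exported
    as a float volume whose voxel size is the chunk size.
    """
    if dmap.N_v < 1:
        raise ValueError("map has no valid macrovoxel")
    blocks = np.where(dmap.valid, dmap.d_g, 0.0)
    vox = np.repeat(np.repeat(np.repeat(blocks, dmap.m, axis=0),
                              dmap.m, axis=1), dmap.m, axis=2)
    if sigma_um > 0:
        vox = ndimage.gaussian_filter(vox, sigma=sigma_um / chunk_um)
    return Volume(vox.astype(np.float32), (chunk_um,) * 3)
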