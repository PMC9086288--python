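"""Reweighting the biased trajectory into free-energy surfaces.

A well-tempered metadynamics trajectory samples e^(−β(U + V(s,t))); the
time-dependent estimator of Tiwary and Parrinello removes the bias by
weighting each frame with

    w_i ∝ exp(β·(V(s_i, t_i) − c(t_i))),

where the offset

    c(t) = (1/β)·ln[ Σ_s e^(βγV(s,t)/(γ−1)) / Σ_s e^(βV(s,t)/(γ−1)) ]

is evaluated on a CV-space grid from the hills deposited before t.
The reweighted ensemble is projected onto two order parameters that
separate bound and unbound states — here the host-guest distance d
(nm) and the H-bond count N — giving a 2D free-energy surface with
per-cell block-average errors, from which basins and the binding free
energy are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import KB_KCAL_MOL_K, STANDARD_STATE_VOLUME_A3
from .cv_geometry import VolumeSpec
from .errors import ParameterError, RegionError, ResolutionError, SchemaError
from .io import ColvarTable

__all__ = [
    "CVGrid",
    "ReweightState",
    "FES2D",
    "Basin",
    "BasinSet",
    "grid_from_hills",
    "compute_ct",
    "frame_weights",
    "project_fes",
    "block_error",
    "find_basins",
    "classify_by_ranges",
    "delta_g",
    "restraint_shell_volume",
]

CV_NAMES = ("rho", "tau", "theta")
SIGMA_NAMES = ("sigma_rho", "sigma_tau", "sigma_theta")

#: required resolution: at least this many grid cells per hill width
CELLS_PER_SIGMA = 4


# ---------------------------------------------------------------------------
# grids and c(t)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVGrid:
    """Regular grid over the biased CV subspace.

    ``dims`` are indices into (ρ, τ, θ); ``centers`` one 1D array of
    cell centres per dim; ``periodic`` marks angular dims whose
    Gaussian distances are wrapped.
    """

    centers: tuple[np.ndarray, ...]
    dims: tuple[int, ...]
    periodic: tuple[bool, ...]

    def __post_init__(self):
        if len(self.centers) != len(self.dims) or len(self.dims) != len(self.periodic):
            raise ParameterError("centers/dims/periodic must have equal length")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.centers)


def grid_from_hills(
    hills: pd.DataFrame,
    dims: tuple[int, ...] = (0, 1, 2),
    pad_sigmas: float = 4.0,
    cells_per_sigma: int = CELLS_PER_SIGMA,
) -> CVGrid:
    """Build a grid covering the deposited hills plus a Gaussian tail pad.

    θ (dim 2) always spans the full period (−π, π) and is periodic.
    Cell spacing is the smallest hill width in that dim divided by
    ``cells_per_sigma``.
    """
    centers = []
    periodic = []
    for d in dims:
        sig = hills[SIGMA_NAMES[d]].to_numpy()
        c = hills[CV_NAMES[d]].to_numpy()
        spacing = sig.min() / cells_per_sigma
        if d == 2:
            n = max(8, int(np.ceil(2 * np.pi / spacing)))
            axis = np.linspace(-np.pi, np.pi, n, endpoint=False) + np.pi / n
            periodic.append(True)
        else:
            lo = c.min() - pad_sigmas * sig.max()
            hi = c.max() + pad_sigmas * sig.max()
            n = max(4, int(np.ceil((hi - lo) / spacing)))
            axis = np.linspace(lo, hi, n, endpoint=False) + 0.5 * (hi - lo) / n
            periodic.append(False)
        centers.append(axis)
    return CVGrid(centers=tuple(centers), dims=tuple(dims), periodic=tuple(periodic))


@dataclass
class ReweightState:
    """c(t) series plus the grid/β/γ used to compute it."""

    times: np.ndarray
    ct: np.ndarray
    grid: CVGrid
    beta: float
    gamma: float

    def at(self, t: np.ndarray) -> np.ndarray:
        """c at times ``t`` by nearest-preceding interpolation (0 before the first hill)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        out = np.where(idx >= 0, self.ct[np.clip(idx, 0, None)], 0.0)
        return out


def _check_resolution(grid: CVGrid, hills: pd.DataFrame):
    for axis, d, per in zip(grid.centers, grid.dims, grid.periodic):
        if len(axis) < 2:
            raise ResolutionError(f"grid dim {CV_NAMES[d]} has fewer than 2 cells")
        spacing = axis[1] - axis[0]
        sig_min = hills[SIGMA_NAMES[d]].to_numpy().min()
        if spacing > sig_min / CELLS_PER_SIGMA * (1 + 1e-9):
            raise ResolutionError(
                f"grid too coarse for {CV_NAMES[d]}: spacing {spacing:.4g} > "
                f"sigma_min/{CELLS_PER_SIGMA} = {sig_min / CELLS_PER_SIGMA:.4g}"
            )


def compute_ct(
    hills: pd.DataFrame,
    grid: CVGrid,
    gamma: float,
    beta: float,
    eval_times: np.ndarray | None = None,
) -> ReweightState:
    """Tiwary-Parrinello offset c(t) at each requested time.

    V(s, t) includes hills deposited strictly before t and is
    accumulated incrementally on the grid (the Gaussians are separable
    across CV dims).  Both grid sums use max-subtraction (logsumexp)
    for numerical stability.  Default eval_times: the hill times
    themselves.
    """
    if gamma <= 1:
        raise ParameterError("gamma must be > 1")
    hills = hills.sort_values("time", kind="stable").reset_index(drop=True)
    _check_resolution(grid, hills)
    if eval_times is None:
        eval_times = hills["time"].to_numpy()
    eval_times = np.asarray(eval_times, dtype=float)
    order = np.argsort(eval_times, kind="stable")

    shape = grid.shape
    V = np.zeros(shape)
    t_hills = hills["time"].to_numpy()
    heights = hills["height"].to_numpy()
    centers_h = [hills[CV_NAMES[d]].to_numpy() for d in grid.dims]
    sigmas_h = [hills[SIGMA_NAMES[d]].to_numpy() for d in grid.dims]

    def add_hill(k: int):
        factors = []
        for ax, c, s, per in zip(grid.centers, (ch[k] for ch in centers_h),
                                 (sh[k] for sh in sigmas_h), grid.periodic):
            delta = ax - c
            if per:
                delta = np.mod(delta + np.pi, 2 * np.pi) - np.pi
            factors.append(np.exp(-0.5 * (delta / s) ** 2))
        g = factors[0]
        for f in factors[1:]:
            g = g[..., None] * f
        V.__iadd__(heights[k] * g)

    a1 = beta * gamma / (gamma - 1.0)
    a2 = beta / (gamma - 1.0)
    ct = np.empty(len(eval_times))
    k = 0
    n_hills = len(hills)
    for j in order:
        t = eval_times[j]
        while k < n_hills and t_hills[k] < t - 1e-12:
            add_hill(k)
            k += 1
        flat = V.ravel()
        ct[j] = (logsumexp(a1 * flat) - logsumexp(a2 * flat)) / beta
    return ReweightState(times=eval_times, ct=ct, grid=grid, beta=beta, gamma=gamma)


# ---------------------------------------------------------------------------
# frame weights
# ---------------------------------------------------------------------------

def frame_weights(
    colvar: ColvarTable,
    ct: ReweightState,
    beta: float,
    t_start: float,
) -> np.ndarray:
    """Normalized Tiwary-Parrinello weights over frames with t ≥ t_start.

    w_i ∝ exp(β(V(s_i, t_i) − c(t_i))); frames before t_start get
    exactly zero.  The COLVAR table must carry the instantaneous bias
    in a "bias" column.
    """
    if "bias" not in colvar.columns:
        raise SchemaError("COLVAR table lacks the 'bias' column needed for reweighting")
    t = colvar["time"]
    v = colvar["bias"]
    keep = t >= t_start
    if not keep.any():
        raise ParameterError(f"no frames at or after t_start={t_start}")
    log_w = beta * (v - ct.at(t))
    log_w = np.where(keep, log_w, -np.inf)
    log_w = log_w - log_w.max()
    w = np.exp(log_w)
    return w / w.sum()


# ---------------------------------------------------------------------------
# FES projection
# ---------------------------------------------------------------------------

@dataclass
class FES2D:
    """Reweighted free-energy grid over two order parameters.

    F is min-shifted to zero over sampled cells; unsampled cells hold
    NaN and are flagged in ``sampled``; ``n_eff`` is the Kish effective
    sample size per cell.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    F: np.ndarray
    err: np.ndarray
    kT: float
    n_eff: np.ndarray
    sampled: np.ndarray
    x_name: str = "d"
    y_name: str = "nhb"

    def minimum_cell(self) -> tuple[int, int]:
        flat = np.nanargmin(np.where(self.sampled, self.F, np.nan))
        return np.unravel_index(flat, self.F.shape)


def project_fes(
    colvar: ColvarTable,
    weights: np.ndarray,
    x_col: str,
    y_col: str,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    kT: float,
) -> FES2D:
    """F(cell) = −kT·ln(Σ weights in cell), min-shifted to 0."""
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    if np.any(np.diff(x_edges) <= 0) or np.any(np.diff(y_edges) <= 0):
        raise ParameterError("bin edges must be strictly increasing")
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise RegionError("all weights are zero: empty selection")
    x = colvar[x_col]
    y = colvar[y_col]
    W, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges), weights=w)
    W2, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges), weights=w * w)
    sampled = W > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(sampled, -kT * np.log(np.where(sampled, W, 1.0)), np.nan)
        n_eff = np.where(sampled, W * W / np.where(W2 > 0, W2, 1.0), 0.0)
    F = F - np.nanmin(F)
    err = np.full_like(F, np.nan)
    return FES2D(
        x_edges=x_edges, y_edges=y_edges, F=F, err=err, kT=kT,
        n_eff=n_eff, sampled=sampled, x_name=x_col, y_name=y_col,
    )


def _block_slices(n: int, n_blocks: int) -> list[slice]:
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    return [slice(bounds[i], bounds[i + 1]) for i in range(n_blocks)]


def _weighted_se(values: np.ndarray, masses: np.ndarray) -> float:
    """Standard error of the weighted mean of ``values`` with block masses.

    With equal masses this reduces to std(ddof=1)/√n; in general the
    unbiased weighted variance is scaled by Σŵ² (ŵ the normalized
    masses).
    """
    m = masses / masses.sum()
    mean = float(np.sum(m * values))
    wsq = float(np.sum(m * m))
    if wsq >= 1.0 - 1e-12:  # single effective block
        return np.nan
    var = float(np.sum(m * (values - mean) ** 2)) / (1.0 - wsq)
    return float(np.sqrt(var * wsq))


def block_error(
    colvar: ColvarTable,
    weights: np.ndarray,
    x_col: str,
    y_col: str,
    edges: tuple[np.ndarray, np.ndarray],
    n_blocks: int = 5,
    kT: float = KB_KCAL_MOL_K * 298.0,
) -> np.ndarray:
    """Per-cell block-average error of the reweighted FES (kcal/mol).

    The reweighted window (frames with weight > 0) is split into
    ``n_blocks`` contiguous time blocks; each block yields its own
    normalized FES, and the error is the weighted standard error of F
    across the blocks that sampled the cell (weights = block weight
    mass).  Cells sampled by fewer than two blocks are flagged NaN.
    """
    if n_blocks < 2:
        raise ParameterError("n_blocks must be >= 2")
    x_edges, y_edges = (np.asarray(e, dtype=float) for e in edges)
    w = np.asarray(weights, dtype=float)
    active = np.nonzero(w > 0)[0]
    if len(active) < n_blocks:
        raise ParameterError("fewer weighted frames than blocks")
    x = colvar[x_col][active]
    y = colvar[y_col][active]
    wa = w[active]
    shape = (len(x_edges) - 1, len(y_edges) - 1)
    F_blocks = np.full((n_blocks, *shape), np.nan)
    masses = np.zeros(n_blocks)
    for b, sl in enumerate(_block_slices(len(active), n_blocks)):
        wb = wa[sl]
        masses[b] = wb.sum()
        if masses[b] <= 0:
            continue
        Wb, _, _ = np.histogram2d(x[sl], y[sl], bins=(x_edges, y_edges), weights=wb / wb.sum())
        with np.errstate(divide="ignore"):
            F_blocks[b] = np.where(Wb > 0, -kT * np.log(np.where(Wb > 0, Wb, 1.0)), np.nan)
    err = np.full(shape, np.nan)
    for i in range(shape[0]):
        for j in range(shape[1]):
            vals = F_blocks[:, i, j]
            ok = np.isfinite(vals) & (masses > 0)
            if ok.sum() < 2:
                continue
            err[i, j] = _weighted_se(vals[ok], masses[ok])
    return err


# ---------------------------------------------------------------------------
# basins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Basin:
    label: int
    cells: frozenset
    F_min: float
    min_cell: tuple[int, int]
    x_range: tuple[float, float]
    y_range: tuple[float, float]


@dataclass
class BasinSet:
    basins: list[Basin]
    assignment: np.ndarray  # cell → basin label, −1 where unsampled

    def basin_of_point(self, x: float, y: float, fes: FES2D) -> int:
        i = int(np.searchsorted(fes.x_edges, x, side="right")) - 1
        j = int(np.searchsorted(fes.y_edges, y, side="right")) - 1
        if not (0 <= i < self.assignment.shape[0] and 0 <= j < self.assignment.shape[1]):
            raise RegionError(f"point ({x}, {y}) outside the FES grid")
        return int(self.assignment[i, j])


def _neighbors(i, j, shape):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ni, nj = i + di, j + dj
            if 0 <= ni < shape[0] and 0 <= nj < shape[1]:
                yield ni, nj


def find_basins(fes: FES2D, depth_cutoff: float, min_prominence: float = 0.0) -> BasinSet:
    """Watershed decomposition of the FES into basins.

    Every sampled cell descends along its steepest-descent neighbour
    (8-connected) to a local minimum; on flat plateaus ties are broken
    toward the lower flat cell index, so each plateau resolves to one
    minimum.  Minima whose value exceeds global-min + ``depth_cutoff``
    do not count as basins: their catchments are merged into the
    adjacent basin across the lowest shared saddle.  ``min_prominence``
    (kcal/mol) optionally also merges minima whose barrier toward a
    deeper neighbour is shallower than the threshold — useful for
    sampling-noise ripples.  Final labels are 0, 1, ... in order of
    increasing basin minimum.
    """
    F = fes.F
    shape = F.shape
    sampled = fes.sampled
    if not sampled.any():
        raise RegionError("FES has no sampled cells")

    def flat_index(cell):
        return cell[0] * shape[1] + cell[1]

    # steepest-descent target per cell (memoized); equal-valued moves
    # only toward a smaller flat index, so descent always terminates
    target: dict = {}

    def descend(cell):
        path = []
        while cell not in target:
            path.append(cell)
            i, j = cell
            best = cell
            best_f = F[i, j]
            for nb in _neighbors(i, j, shape):
                if not sampled[nb]:
                    continue
                f = F[nb]
                if f < best_f - 1e-15:
                    best, best_f = nb, f
                elif abs(f - best_f) <= 1e-15 and flat_index(nb) < flat_index(best):
                    best, best_f = nb, f
            if best == cell:  # local minimum (or plateau representative)
                target[cell] = cell
                break
            cell = best
        root = target[cell]
        for c in path:
            target[c] = root
        return root

    cells = [(i, j) for i in range(shape[0]) for j in range(shape[1]) if sampled[i, j]]
    minima = sorted({descend(c) for c in cells}, key=lambda c: (F[c], flat_index(c)))
    f_global = F[minima[0]]

    groups = {m: {c for c in cells if target[c] == m} for m in minima}

    def lowest_saddle(root):
        """(saddle height, neighbour root) of the cheapest exit from a group."""
        members = groups[root]
        best_saddle, best_target = np.inf, None
        for (i, j) in members:
            for nb in _neighbors(i, j, shape):
                if not sampled[nb] or nb in members:
                    continue
                other = next(r for r, g in groups.items() if nb in g)
                saddle = max(F[i, j], F[nb])
                if saddle < best_saddle or (
                    saddle == best_saddle and best_target is not None
                    and F[other] < F[best_target]
                ):
                    best_saddle, best_target = saddle, other
        return best_saddle, best_target

    changed = True
    while changed and len(groups) > 1:
        changed = False
        # shallowest-minimum group first keeps merges deterministic
        for root in sorted(groups, key=lambda c: (-F[c], flat_index(c))):
            too_high = F[root] > f_global + depth_cutoff
            saddle, other = lowest_saddle(root)
            if other is None:
                continue
            low_prominence = (
                min_prominence > 0
                and F[other] <= F[root]
                and (saddle - F[root]) < min_prominence
            )
            if too_high or low_prominence:
                groups[other] = groups[other] | groups[root]
                del groups[root]
                changed = True
                break

    roots = sorted(groups, key=lambda c: (F[c], flat_index(c)))
    final_groups = groups

    assignment = np.full(shape, -1, dtype=int)
    basins = []
    xc = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
    yc = 0.5 * (fes.y_edges[:-1] + fes.y_edges[1:])
    for label, root in enumerate(roots):
        members = final_groups[root]
        for (i, j) in members:
            assignment[i, j] = label
        xi = [xc[i] for i, _ in members]
        yj = [yc[j] for _, j in members]
        basins.append(
            Basin(
                label=label,
                cells=frozenset(members),
                F_min=float(F[root]),
                min_cell=root,
                x_range=(float(min(xi)), float(max(xi))),
                y_range=(float(min(yj)), float(max(yj))),
            )
        )
    return BasinSet(basins=basins, assignment=assignment)


def classify_by_ranges(x: float, y: float, ranges: dict[str, tuple[tuple[float, float], tuple[float, float]]]) -> str | None:
    """Assign a (d, N) point to a named window, e.g. published basin ranges.

    ``ranges`` maps label → ((x_lo, x_hi), (y_lo, y_hi)); the first
    (insertion-ordered) window containing the point wins; None if no
    window matches.
    """
    for label, ((xlo, xhi), (ylo, yhi)) in ranges.items():
        if xlo < x < xhi and ylo < y < yhi:
            return label
    return None


# ---------------------------------------------------------------------------
# binding free energy
# ---------------------------------------------------------------------------

def _region_mask(colvar: ColvarTable, region: dict[str, tuple[float, float]]) -> np.ndarray:
    mask = np.ones(len(colvar), dtype=bool)
    for col, (lo, hi) in region.items():
        v = colvar[col]
        mask &= (v >= lo) & (v < hi)
    return mask


def delta_g(
    weights: np.ndarray,
    colvar: ColvarTable,
    bound_region: dict[str, tuple[float, float]],
    unbound_region: dict[str, tuple[float, float]],
    kT: float,
    standard_volume: float | None = None,
    unbound_volume: float | None = None,
    n_blocks: int = 5,
) -> tuple[float, float]:
    """Binding free energy ΔG = −kT·ln(W_bound/W_unbound) with block error.

    Regions are {column: (lo, hi)} windows on COLVAR columns and must
    be disjoint.  Negative ΔG means binding is favourable; the
    unbinding free energy is −ΔG.  With ``standard_volume`` (ų per
    molecule; 1660 ų at 1 M) the result is referenced to standard
    concentration by adding kT·ln(V_unbound/V°), where ``unbound_volume``
    is the geometric volume (ų) of the unbound region inside the
    restraint (see :func:`restraint_shell_volume`).  The error is the
    block standard error of ΔG over contiguous time blocks weighted by
    block weight mass.
    """
    w = np.asarray(weights, dtype=float)
    in_b = _region_mask(colvar, bound_region)
    in_u = _region_mask(colvar, unbound_region)
    if np.any(in_b & in_u & (w > 0)):
        raise RegionError("bound and unbound regions overlap on weighted frames")
    Wb = w[in_b].sum()
    Wu = w[in_u].sum()
    if Wb <= 0 or Wu <= 0:
        raise RegionError(
            f"zero weight in a region (bound={Wb:.3g}, unbound={Wu:.3g}): ΔG undefined"
        )
    dg = -kT * np.log(Wb / Wu)
    if standard_volume is not None:
        if unbound_volume is None:
            raise ParameterError("standard_volume given but unbound_volume missing")
        dg = dg - kT * np.log(unbound_volume / standard_volume)

    active = np.nonzero(w > 0)[0]
    vals, masses = [], []
    for sl in _block_slices(len(active), n_blocks):
        idx = active[sl]
        wb = w[idx][in_b[idx]].sum()
        wu = w[idx][in_u[idx]].sum()
        if wb <= 0 or wu <= 0:
            continue  # block missing one region: dropped from the error estimate
        vals.append(-kT * np.log(wb / wu))
        masses.append(w[idx].sum())
    if len(vals) < 2:
        return float(dg), np.nan
    err = _weighted_se(np.asarray(vals), np.asarray(masses))
    return float(dg), float(err)


def restraint_shell_volume(
    vol: VolumeSpec,
    host_com,
    r_lo: float,
    r_hi: float,
    n_per_dim: int = 160,
) -> float:
    """Geometric volume (ų) of {r_lo ≤ ρ < r_hi, τ ≤ τ_max, a ≥ a_min}.

    Grid count over the bounding box; this is the "sampled unbound
    volume" entering the standard-state correction.
    """
    host = np.asarray(host_com, dtype=float)
    half = r_hi + 1.0
    axes = [np.linspace(-half, half, n_per_dim, endpoint=False) + half / n_per_dim + h for h in host]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    rho = np.linalg.norm(pts - host, axis=-1)
    r = pts - vol.origin
    a = r @ vol.axis
    rp = np.linalg.norm(r - a[:, None] * vol.axis, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(a > vol.a0, rp / np.sqrt(vol.steepness * np.maximum(a - vol.a0, 1e-12)), np.inf)
    inside = (rho >= r_lo) & (rho < r_hi) & (tau <= vol.tau_max) & (a >= vol.a_min)
    cell = (2 * half / n_per_dim) ** 3
    return float(inside.sum() * cell)
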