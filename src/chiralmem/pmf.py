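"""Umbrella-sampling reweighting into a 2D potential of mean force.

Harmonically biased windows along the adsorption coordinate ``dz`` are
combined into unbiased free energies over ``(dz, theta)`` with either of
two estimators implemented here:

* WHAM  -- self-consistent iteration on a dz histogram,
* MBAR  -- the binless multistate Bennett acceptance ratio estimating
           equations, solved by minimizing the convex MBAR objective and
           polished by self-consistent iteration.

Both solve for the dimensionless window free energies ``f_i``; unbiased
per-sample weights ``w_n = 1 / sum_i N_i exp(f_i - u_i(x_n))`` then give
the 2D PMF by binning, reweighted conditional expectations of arbitrary
observables, and the 1D profile along dz.  All free energies are in kBT at
the window set's temperature; the sampled-bin minimum is normalized to 0
and unsampled bins are masked, never interpolated.

The adsorption barrier is measured on the binned surface as a minimax
path: the lowest level at which the pre- and post-adsorption basins become
connected through sampled bins (8-connected, periodic in theta).  The
saddle is the bin where the connection happens and the barrier is its free
energy above the approach-side (pre-adsorption) basin minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

KB_KJ_PER_MOL_K = 0.008314462618  # Boltzmann constant, kJ/mol/K
DEFAULT_TEMPERATURE = 303.15  # K


class OverlapError(RuntimeError):
    """Adjacent umbrella windows share no configuration-space overlap."""


class ConvergenceError(RuntimeError):
    """Free-energy solver failed to reach tolerance."""


class BarrierError(RuntimeError):
    """Basins cannot be connected through sampled bins."""


@dataclass
class UmbrellaWindow:
    """Biased samples from one harmonic window.

    center in nm, k_bias in kJ/mol/nm^2, dz in nm, theta in degrees;
    ``observables`` maps names to per-sample arrays.  ``bias_offset``
    (kJ/mol) is an additive constant in the bias, physically irrelevant --
    the PMF is gauge invariant against it.
    """

    center: float
    k_bias: float
    dz: np.ndarray
    theta: np.ndarray = None
    observables: dict = field(default_factory=dict)
    bias_offset: float = 0.0
    seed: int | None = None
    burn_in: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dz = np.asarray(self.dz, dtype=float)
        if not np.all(np.isfinite(self.dz)):
            raise ValueError(f"window at {self.center}: non-finite dz samples")
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)

    @property
    def n_samples(self):
        return self.dz.size


@dataclass
class UmbrellaWindowSet:
    """Ordered collection of umbrella windows.

    Windows are kept sorted by center; the 1-based window index therefore
    increases with dz (window 16 of a 16-window ladder on [1.0, 2.5] nm is
    the outermost, dz = 2.5 nm).
    """

    windows: list
    temperature: float = DEFAULT_TEMPERATURE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.windows = sorted(self.windows, key=lambda w: w.center)

    @property
    def centers(self):
        return np.array([w.center for w in self.windows])

    @property
    def kT(self):
        """kBT in kJ/mol."""
        return KB_KJ_PER_MOL_K * self.temperature

    def window(self, index: int) -> UmbrellaWindow:
        """1-based, center-ascending window lookup."""
        return self.windows[index - 1]


@dataclass
class GridSpec:
    """Bin layout of the (dz, theta) surface."""

    dz_min: float = 1.0
    dz_max: float = 2.5
    n_dz: int = 30
    n_theta: int = 36

    @property
    def dz_edges(self):
        return np.linspace(self.dz_min, self.dz_max, self.n_dz + 1)

    @property
    def theta_edges(self):
        return np.linspace(0.0, 360.0, self.n_theta + 1)


@dataclass
class PmfSurface:
    """Binned free-energy surface in kBT, minimum over sampled bins = 0."""

    dz_edges: np.ndarray
    theta_edges: np.ndarray
    free_energy: np.ndarray  # (n_dz, n_theta), NaN where unsampled
    mask: np.ndarray  # True where sampled
    estimator: str
    f_windows: np.ndarray
    pmf_dz: np.ndarray = None  # 1D profile along dz, NaN where unsampled
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def dz_centers(self):
        return 0.5 * (self.dz_edges[:-1] + self.dz_edges[1:])

    @property
    def theta_centers(self):
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    def bin_index(self, dz: float, theta: float):
        i = int(np.searchsorted(self.dz_edges, dz, side="right")) - 1
        j = int(np.searchsorted(self.theta_edges, theta % 360.0, side="right")) - 1
        i = min(max(i, 0), len(self.dz_edges) - 2)
        j = min(max(j, 0), len(self.theta_edges) - 2)
        return i, j


def statistical_inefficiency(x: np.ndarray, mintime: int = 3) -> float:
    """g = 1 + 2 * integrated autocorrelation time of the series.

    Normalized fluctuation autocorrelation summed until it first goes
    negative (initial positive sequence estimator).  Returns >= 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        return 1.0
    dx = x - x.mean()
    var = float(np.dot(dx, dx) / n)
    if var <= 0:
        return 1.0
    g = 1.0
    for t in range(1, n - 1):
        c = float(np.dot(dx[:-t], dx[t:]) / ((n - t) * var))
        if c <= 0 and t > mintime:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(g, 1.0)


def _prepare_samples(windows: UmbrellaWindowSet, discard_fraction: float,
                     subsample: bool):
    """Equilibration discard + decorrelation subsampling, per window."""
    kept = []
    for w in windows.windows:
        start = int(np.floor(discard_fraction * w.n_samples))
        idx = np.arange(start, w.n_samples)
        if subsample and idx.size >= 10:
            g = statistical_inefficiency(w.dz[idx])
            idx = idx[::max(int(np.ceil(g)), 1)]
        kept.append(idx)
    return kept


def _check_overlap(windows: UmbrellaWindowSet, kept, min_overlap=0.01):
    """Histogram overlap of adjacent windows along dz; error on zero."""
    overlaps = []
    ws = windows.windows
    for a, b in zip(range(len(ws) - 1), range(1, len(ws))):
        xa, xb = ws[a].dz[kept[a]], ws[b].dz[kept[b]]
        lo = min(xa.min(), xb.min())
        hi = max(xa.max(), xb.max())
        if hi <= lo:
            overlaps.append(0.0)
            continue
        edges = np.linspace(lo, hi, 51)
        ha, _ = np.histogram(xa, bins=edges, density=False)
        hb, _ = np.histogram(xb, bins=edges, density=False)
        ov = float(np.minimum(ha / max(ha.sum(), 1), hb / max(hb.sum(), 1)).sum())
        overlaps.append(ov)
        if ov == 0.0:
            raise OverlapError(
                f"no overlap between windows at dz={ws[a].center:.3f} and "
                f"{ws[b].center:.3f} nm")
    small = [i for i, ov in enumerate(overlaps) if ov < min_overlap]
    if small:
        warnings.warn(f"adjacent-window overlap below {min_overlap:.0%} at pairs {small}")
    return np.array(overlaps)


def _reduced_bias_matrix(windows: UmbrellaWindowSet, dz_all: np.ndarray):
    """u[i, n]: dimensionless bias energy of window i at sample n."""
    beta = 1.0 / windows.kT
    centers = windows.centers
    ks = np.array([w.k_bias for w in windows.windows])
    offs = np.array([w.bias_offset for w in windows.windows])
    diff = dz_all[None, :] - centers[:, None]
    return beta * (0.5 * ks[:, None] * diff**2 + offs[:, None])


def _solve_mbar(u: np.ndarray, counts: np.ndarray, tol: float = 1e-7,
                max_iter: int = 2000) -> np.ndarray:
    """Dimensionless window free energies from the MBAR equations.

    Minimizes the convex MBAR objective, then polishes with
    self-consistent iteration until max |delta f| < tol (kBT).
    """
    K = u.shape[0]
    log_n = np.log(counts)

    def objective(fr):
        f = np.concatenate([[0.0], fr])
        d = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
        val = d.sum() - np.dot(counts, f)
        w = np.exp(log_n[:, None] + f[:, None] - u - d[None, :])
        grad = w.sum(axis=1) - counts
        return val, grad[1:]

    res = optimize.minimize(objective, np.zeros(K - 1), jac=True, method="L-BFGS-B",
                            options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10})
    f = np.concatenate([[0.0], res.x])
    for _ in range(max_iter):
        d = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
        f_new = -logsumexp(-u - d[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            return f
    raise ConvergenceError(f"MBAR self-consistent polish: residual {delta:.2e} > {tol}")


def _solve_wham(windows: UmbrellaWindowSet, kept, n_bins: int = 120,
                tol: float = 1e-7, max_iter: int = 100000) -> np.ndarray:
    """Window free energies by histogram WHAM self-consistent iteration."""
    dz_all = np.concatenate([w.dz[k] for w, k in zip(windows.windows, kept)])
    edges = np.linspace(dz_all.min() - 1e-9, dz_all.max() + 1e-9, n_bins + 1)
    centers_b = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array([k.size for k in kept], dtype=float)
    m_b = np.zeros(n_bins)
    for w, k in zip(windows.windows, kept):
        h, _ = np.histogram(w.dz[k], bins=edges)
        m_b += h
    u_ib = _reduced_bias_matrix(windows, centers_b)  # (K, B)
    f = np.zeros(len(windows.windows))
    for it in range(max_iter):
        log_denom = logsumexp(np.log(counts)[:, None] + f[:, None] - u_ib, axis=0)
        with np.errstate(divide="ignore"):
            log_p = np.where(m_b > 0, np.log(m_b) - log_denom, -np.inf)
        f_new = -logsumexp(log_p[None, :] - u_ib, axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            return f
    raise ConvergenceError(f"WHAM iteration: residual {delta:.2e} > {tol}")


@dataclass
class ReweightedSamples:
    """Pooled samples with unbiased weights and solved window free energies."""

    dz: np.ndarray
    theta: np.ndarray
    weights: np.ndarray  # normalized to 1
    observables: dict
    f_windows: np.ndarray
    estimator: str
    overlaps: np.ndarray
    temperature: float


def reweight(windows: UmbrellaWindowSet, estimator: str = "mbar",
             discard_fraction: float = 0.1, subsample: bool = True,
             tol: float = 1e-7) -> ReweightedSamples:
    """Solve window free energies and attach unbiased weights to samples.

    ``discard_fraction`` drops the leading fraction of every window as
    equilibration; ``subsample`` thins each window by its estimated
    statistical inefficiency before solving.
    """
    if len(windows.windows) < 1:
        raise ValueError("empty window set")
    kept = _prepare_samples(windows, discard_fraction, subsample)
    overlaps = (_check_overlap(windows, kept)
                if len(windows.windows) > 1 else np.array([]))
    dz_all = np.concatenate([w.dz[k] for w, k in zip(windows.windows, kept)])
    theta_all = (np.concatenate([w.theta[k] for w, k in zip(windows.windows, kept)])
                 if all(w.theta is not None for w in windows.windows) else None)
    obs_names = set.intersection(*(set(w.observables) for w in windows.windows)) \
        if windows.windows else set()
    obs = {name: np.concatenate([np.asarray(w.observables[name])[k]
                                 for w, k in zip(windows.windows, kept)])
           for name in obs_names}
    counts = np.array([k.size for k in kept], dtype=float)
    u = _reduced_bias_matrix(windows, dz_all)
    if estimator == "mbar":
        f = _solve_mbar(u, counts, tol=tol)
    elif estimator == "wham":
        f = _solve_wham(windows, kept, tol=tol)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    log_w = -logsumexp(np.log(counts)[:, None] + f[:, None] - u, axis=0)
    log_w -= logsumexp(log_w)
    return ReweightedSamples(dz=dz_all, theta=theta_all, weights=np.exp(log_w),
                             observables=obs, f_windows=f, estimator=estimator,
                             overlaps=overlaps, temperature=windows.temperature)


def estimate_pmf(windows: UmbrellaWindowSet, grid: GridSpec | None = None,
                 estimator: str = "mbar", discard_fraction: float = 0.1,
                 subsample: bool = True, tol: float = 1e-7,
                 reweighted: ReweightedSamples | None = None) -> PmfSurface:
    """2D PMF over (dz, theta) in kBT, plus the 1D profile along dz.

    Bins that receive no sample weight are masked (NaN), never filled in.
    The minimum over sampled 2D bins is normalized to zero.
    """
    grid = grid or GridSpec()
    rw = reweighted or reweight(windows, estimator=estimator,
                                discard_fraction=discard_fraction,
                                subsample=subsample, tol=tol)
    if rw.theta is None:
        raise ValueError("2D PMF requires theta samples in every window")
    dz_e, th_e = grid.dz_edges, grid.theta_edges
    w2d, _, _ = np.histogram2d(rw.dz, rw.theta % 360.0, bins=(dz_e, th_e),
                               weights=rw.weights)
    mask = w2d > 0
    free = np.full(w2d.shape, np.nan)
    with np.errstate(divide="ignore"):
        free[mask] = -np.log(w2d[mask])
    free -= np.nanmin(free)
    w1d, _ = np.histogram(rw.dz, bins=dz_e, weights=rw.weights)
    pmf_dz = np.full(w1d.shape, np.nan)
    m1 = w1d > 0
    pmf_dz[m1] = -np.log(w1d[m1])
    pmf_dz -= np.nanmin(pmf_dz)
    return PmfSurface(dz_edges=dz_e, theta_edges=th_e, free_energy=free,
                      mask=mask, estimator=rw.estimator, f_windows=rw.f_windows,
                      pmf_dz=pmf_dz, temperature=rw.temperature)


def reweighted_expectation(windows: UmbrellaWindowSet, observable: str,
                           dz_edges: np.ndarray | None = None,
                           estimator: str = "mbar",
                           discard_fraction: float = 0.1, subsample: bool = True,
                           reweighted: ReweightedSamples | None = None):
    """Unbiased conditional expectation E[O | dz bin] with spread.

    Returns a dict of arrays: ``dz`` (bin centers), ``mean``, ``std``
    (weighted standard deviation, describing the equilibrium fluctuation of
    the observable), ``n_eff`` (Kish effective sample count) and ``mask``.
    Bins with zero weight are masked.
    """
    rw = reweighted or reweight(windows, estimator=estimator,
                                discard_fraction=discard_fraction,
                                subsample=subsample)
    if observable not in rw.observables:
        raise KeyError(f"observable {observable!r} not recorded in every window")
    o = np.asarray(rw.observables[observable], dtype=float)
    edges = np.asarray(dz_edges) if dz_edges is not None else GridSpec().dz_edges
    nb = edges.size - 1
    idx = np.digitize(rw.dz, edges) - 1
    mean = np.full(nb, np.nan)
    std = np.full(nb, np.nan)
    n_eff = np.zeros(nb)
    mask = np.zeros(nb, dtype=bool)
    for b in range(nb):
        sel = idx == b
        wt = rw.weights[sel]
        tot = wt.sum()
        if tot <= 0:
            continue
        mask[b] = True
        mu = float(np.dot(wt, o[sel]) / tot)
        var = float(np.dot(wt, (o[sel] - mu) ** 2) / tot)
        mean[b] = mu
        std[b] = np.sqrt(var)
        n_eff[b] = tot**2 / np.dot(wt, wt)
    return {"dz": 0.5 * (edges[:-1] + edges[1:]), "mean": mean, "std": std,
            "n_eff": n_eff, "mask": mask}


# ---------------------------------------------------------------------------
# minimax-path barrier search


def _neighbors(i, j, ni, nj, periodic_j=True):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            a, b = i + di, j + dj
            if a < 0 or a >= ni:
                continue
            if periodic_j:
                b %= nj
            elif b < 0 or b >= nj:
                continue
            yield a, b


def _descend(F, mask, start, ni, nj, periodic_j=True):
    """Greedy steepest-descent on the bin graph to a local minimum."""
    cur = start
    while True:
        i, j = cur
        best = cur
        best_val = F[i, j]
        for a, b in _neighbors(i, j, ni, nj, periodic_j):
            if mask[a, b] and F[a, b] < best_val:
                best_val = F[a, b]
                best = (a, b)
        if best == cur:
            return cur
        cur = best


def minimax_on_grid(F: np.ndarray, mask: np.ndarray, seed_a, seed_b,
                    periodic_j: bool = True):
    """Minimax path between two basins on a binned surface.

    Bins are activated in order of increasing F (union-find percolation);
    the first bin whose activation connects the two basin minima is the
    saddle, and its level is the minimum over paths of the path maximum.
    Returns (basin_a, basin_b, saddle, path) as index tuples / lists.
    """
    ni, nj = F.shape
    a = _descend(F, mask, tuple(seed_a), ni, nj, periodic_j)
    b = _descend(F, mask, tuple(seed_b), ni, nj, periodic_j)
    if a == b:
        return a, b, a, [a]

    flat = lambda ij: ij[0] * nj + ij[1]
    parent = np.arange(ni * nj)

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    order = np.argsort(F[mask].ravel(), kind="stable")
    cells = np.argwhere(mask)[order]
    active = np.zeros((ni, nj), dtype=bool)
    fa, fb = flat(a), flat(b)
    saddle = None
    for (i, j) in cells:
        active[i, j] = True
        for p, q in _neighbors(i, j, ni, nj, periodic_j):
            if active[p, q]:
                ra, rb = find(flat((i, j))), find(flat((p, q)))
                if ra != rb:
                    parent[ra] = rb
        if find(fa) == find(fb):
            saddle = (int(i), int(j))
            break
    if saddle is None:
        raise BarrierError("basins are not connected through sampled bins")

    # shortest path within the sub-level set F <= F[saddle]
    level = F[saddle]
    allowed = mask & (F <= level + 1e-12)
    prev = {a: None}
    frontier = [a]
    while frontier and b not in prev:
        nxt = []
        for (i, j) in frontier:
            for p, q in _neighbors(i, j, ni, nj, periodic_j):
                if allowed[p, q] and (p, q) not in prev:
                    prev[(p, q)] = (i, j)
                    nxt.append((p, q))
        frontier = nxt
    path = []
    cur = b
    while cur is not None:
        path.append(cur)
        cur = prev[cur]
    path.reverse()
    return a, b, saddle, path


@dataclass
class BarrierReport:
    """Adsorption barrier along the minimax path between two basins.

    ``barrier`` is F(saddle) - F(pre-basin minimum) in kBT, measured from
    the approach-side (larger-dz, pre-adsorption) basin.
    """

    basin_pre: tuple  # (dz, theta) of the pre-adsorption basin minimum
    basin_post: tuple
    saddle: tuple
    barrier: float
    path: list  # list of (dz, theta) bin centers, pre -> post
    f_basin_pre: float
    f_basin_post: float
    f_saddle: float


def find_barrier(surface: PmfSurface, seed_pre, seed_post) -> BarrierReport:
    """Locate the saddle and barrier between two basins of a PMF surface.

    ``seed_pre`` / ``seed_post`` are (dz, theta) points inside the
    pre-adsorption (approach side) and post-adsorption basins; each is
    first relaxed to its local minimum on the bin graph.
    """
    F, mask = surface.free_energy, surface.mask
    ia = surface.bin_index(*seed_pre)
    ib = surface.bin_index(*seed_post)
    for name, idx in (("pre", ia), ("post", ib)):
        if not mask[idx]:
            raise BarrierError(f"{name} basin seed falls in an unsampled bin")
    Fs = np.where(mask, F, np.inf)
    a, b, saddle, path = minimax_on_grid(Fs, mask, ia, ib, periodic_j=True)
    to_xy = lambda ij: (float(surface.dz_centers[ij[0]]),
                        float(surface.theta_centers[ij[1]]))
    return BarrierReport(
        basin_pre=to_xy(a), basin_post=to_xy(b), saddle=to_xy(saddle),
        barrier=float(Fs[saddle] - Fs[a]), path=[to_xy(p) for p in path],
        f_basin_pre=float(Fs[a]), f_basin_post=float(Fs[b]),
        f_saddle=float(Fs[saddle]))
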