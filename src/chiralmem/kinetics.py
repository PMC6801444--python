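"""First-passage-time kinetics of peptide adsorption.

The adsorption progress coordinate is ``dz``, the z component of the
distance between the centers of mass of the peptide and the bilayer.  A
trajectory's first passage time (FPT) is the first time ``dz`` reaches the
adsorption threshold (1.5 nm by convention); trajectories that end before
crossing are right-censored at their final time.

The survival function of the FPT sample -- the complementary cumulative
distribution (CCD) -- is estimated with the Kaplan-Meier product-limit
estimator and fitted by maximum likelihood under three parametric models:

* ``exp1``   : S(t) = exp(-t / tau)
* ``exp2``   : S(t) = w exp(-t / tau_fast) + (1 - w) exp(-t / tau_slow),
               with the weights normalized (w in [0, 1])
* ``gamma``  : S(t) = Q(shape, t / scale)  (regularized upper incomplete
               gamma function)

Censored observations contribute ``log S(t)`` terms to the likelihood;
events contribute ``log f(t)``.  A single-exponential CCD is the signature
of barrier-free (downhill) adsorption with a single rate; a two-exponential
mixture with a small slow weight is the signature of an additional
activated (barrier-crossing) channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from lifelines import KaplanMeierFitter


class FitError(RuntimeError):
    """Raised when no optimization start converges."""


class TraceError(ValueError):
    """Raised for malformed kinetic traces."""


@dataclass
class KineticTrace:
    """Time series of (dz, theta) for one trajectory.

    time is in ns and strictly increasing; dz in nm; theta in degrees in
    [0, 360).  ``metadata`` carries generator provenance (seed, dt, surface
    preset, ...).
    """

    time: np.ndarray
    dz: np.ndarray
    theta: np.ndarray = None
    trajectory_id: str = "traj-0"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.dz = np.asarray(self.dz, dtype=float)
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
        if self.time.size != self.dz.size:
            raise TraceError("time and dz must have equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            bad = int(np.argmin(np.diff(self.time) > 0))
            raise TraceError(f"time must be strictly increasing (violated at row {bad + 1})")


@dataclass
class FptSample:
    """One first-passage-time observation in ns.

    ``censored`` marks trajectories that ended (at ``value``) before
    reaching the threshold; ``start_below`` marks trajectories that began
    already past the threshold (FPT = 0).
    """

    value: float
    censored: bool = False
    trajectory_id: str = ""
    start_below: bool = False


def extract_fpt(trace: KineticTrace, threshold: float = 1.5) -> FptSample:
    """First time ``dz`` reaches ``threshold`` from above.

    The crossing time is linearly interpolated between the bracketing
    samples, which removes the frame-stride bias of reporting the first
    frame at or below the threshold.  Touching the threshold exactly counts
    as a crossing.  Traces that never cross are censored at their end time.
    """
    if trace.time.size < 2:
        raise TraceError("trace needs at least 2 samples")
    below = trace.dz <= threshold
    if below[0]:
        return FptSample(value=0.0, censored=False,
                         trajectory_id=trace.trajectory_id, start_below=True)
    if not below.any():
        return FptSample(value=float(trace.time[-1]), censored=True,
                         trajectory_id=trace.trajectory_id)
    i = int(np.argmax(below))
    t0, t1 = trace.time[i - 1], trace.time[i]
    z0, z1 = trace.dz[i - 1], trace.dz[i]
    t_cross = t0 + (z0 - threshold) / (z0 - z1) * (t1 - t0)
    return FptSample(value=float(t_cross), censored=False,
                     trajectory_id=trace.trajectory_id)


@dataclass
class CcdCurve:
    """Step-function survival estimate: S(t) = survival[searchsorted(times, t)]."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.survival) - 1)]


def empirical_ccd(samples: list[FptSample]) -> CcdCurve:
    """Kaplan-Meier product-limit estimate of the FPT survival function.

    Censored samples are honored; with no censoring this reduces to the
    complement of the empirical CDF.
    """
    if not samples:
        raise ValueError("empirical_ccd needs at least one sample")
    durations = np.array([s.value for s in samples], dtype=float)
    observed = np.array([not s.censored for s in samples], dtype=bool)
    if not observed.any():
        warnings.warn("all samples censored; survival is identically 1")
        return CcdCurve(times=np.array([0.0]), survival=np.array([1.0]))
    km = KaplanMeierFitter()
    km.fit(durations, event_observed=observed)
    sf = km.survival_function_
    return CcdCurve(times=sf.index.to_numpy(dtype=float),
                    survival=sf.iloc[:, 0].to_numpy(dtype=float))


@dataclass
class CcdFit:
    """Parametric fit of the FPT survival function.

    ``params``/``se`` hold natural-scale parameter estimates and asymptotic
    standard errors from the observed information matrix.  For ``exp2`` the
    components are ordered so that ``tau_fast <= tau_slow`` and
    ``weight_fast + weight_slow == 1``.
    """

    model: str
    params: dict
    se: dict
    loglik: float
    aic: float
    n_events: int
    n_censored: int
    converged: bool = True
    degenerate: bool = False
    message: str = ""

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.model == "exp1":
            return np.exp(-t / p["tau"])
        if self.model == "exp2":
            return (p["weight_fast"] * np.exp(-t / p["tau_fast"])
                    + p["weight_slow"] * np.exp(-t / p["tau_slow"]))
        if self.model == "gamma":
            return special.gammaincc(p["shape"], t / p["scale"])
        raise ValueError(self.model)


def _loglik_terms(model, theta, t_event, t_cens):
    """Log-likelihood for natural-scale parameter vector theta (>= 0 checks done)."""
    if model == "exp1":
        (tau,) = theta
        ll = -np.sum(np.log(tau) + t_event / tau)
        if t_cens.size:
            ll += -np.sum(t_cens / tau)
        return ll
    if model == "exp2":
        w, tf, ts = theta
        # log pdf via logsumexp of the two component log-densities
        def logpdf(t):
            a = np.log(w) - np.log(tf) - t / tf
            b = np.log1p(-w) - np.log(ts) - t / ts
            return np.logaddexp(a, b)

        def logsf(t):
            a = np.log(w) - t / tf
            b = np.log1p(-w) - t / ts
            return np.logaddexp(a, b)

        ll = np.sum(logpdf(t_event))
        if t_cens.size:
            ll += np.sum(logsf(t_cens))
        return ll
    if model == "gamma":
        shape, scale = theta
        x = t_event / scale
        ll = np.sum((shape - 1) * np.log(x) - x - special.gammaln(shape) - np.log(scale))
        if t_cens.size:
            sf = special.gammaincc(shape, t_cens / scale)
            ll += np.sum(np.log(np.clip(sf, 1e-300, None)))
        return ll
    raise ValueError(model)


_TRANSFORMS = {
    # free-space parameterization <-> natural scale
    "exp1": (lambda x: np.array([np.exp(x[0])]),
             lambda p: np.array([np.log(p[0])])),
    "exp2": (lambda x: np.array([special.expit(x[0]), np.exp(x[1]), np.exp(x[2])]),
             lambda p: np.array([special.logit(p[0]), np.log(p[1]), np.log(p[2])])),
    "gamma": (lambda x: np.exp(x),
              lambda p: np.log(p)),
}

_N_PARAMS = {"exp1": 1, "exp2": 3, "gamma": 2}


def _numeric_hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian of scalar f at x (natural scale)."""
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-8)
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def _starts(model, t_event, n_starts, rng):
    """Quantile-based multistart initial guesses on the natural scale."""
    mean = float(np.mean(t_event))
    lower = float(np.mean(t_event[t_event <= np.quantile(t_event, 0.5)]))
    upper = float(np.mean(t_event[t_event >= np.quantile(t_event, 0.9)]))
    lower = max(lower, 1e-6)
    upper = max(upper, lower * 1.5)
    starts = []
    if model == "exp1":
        base = [np.array([mean])]
        while len(base) < n_starts:
            base.append(np.array([mean * np.exp(rng.normal(0, 0.5))]))
        starts = base
    elif model == "exp2":
        base = [np.array([0.9, lower, upper]),
                np.array([0.8, lower, upper * 1.5]),
                np.array([0.95, mean * 0.8, upper]),
                np.array([0.5, lower * 0.7, upper])]
        while len(base) < n_starts:
            base.append(np.array([
                float(np.clip(rng.uniform(0.3, 0.98), 1e-3, 1 - 1e-3)),
                lower * np.exp(rng.normal(0, 0.4)),
                upper * np.exp(rng.normal(0, 0.4)),
            ]))
        starts = base
    elif model == "gamma":
        var = float(np.var(t_event))
        shape0 = mean**2 / var if var > 0 else 1.0
        scale0 = var / mean if var > 0 else mean
        base = [np.array([max(shape0, 0.05), max(scale0, 1e-6)]),
                np.array([1.0, mean])]
        while len(base) < n_starts:
            base.append(np.array([max(shape0, 0.05) * np.exp(rng.normal(0, 0.4)),
                                  max(scale0, 1e-6) * np.exp(rng.normal(0, 0.4))]))
        starts = base
    return starts[:n_starts]


def fit_ccd(samples: list[FptSample], model: str = "exp1", init=None,
            n_starts: int = 8, seed: int = 0, method: str = "mle") -> CcdFit:
    """Fit a parametric survival model to FPT samples by censored MLE.

    Multistart optimization (quantile-based initial guesses plus seeded
    jitter) guards against local optima and label switching in the
    two-exponential mixture.  Standard errors are asymptotic, from the
    inverse observed information (numerical Hessian of the negative
    log-likelihood at the MLE on the natural scale).  ``aic`` enables model
    comparison across exp1/exp2/gamma.

    ``method="lsq-log"`` instead minimizes squared residuals between the
    model log-survival and the Kaplan-Meier log-survival at the event
    times; it is provided for sensitivity checks and reports no standard
    errors.
    """
    if model not in _N_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    t_event = np.array([s.value for s in samples if not s.censored], dtype=float)
    t_cens = np.array([s.value for s in samples if s.censored], dtype=float)
    t_event = np.maximum(t_event, 1e-12)  # zero FPTs (start below) would break log pdfs
    min_events = 10 if model == "exp2" else 5
    if t_event.size < min_events:
        raise FitError(f"model {model} needs >= {min_events} uncensored samples, "
                       f"got {t_event.size}")

    if method == "lsq-log":
        return _fit_lsq_log(samples, model, t_event, t_cens, n_starts, seed)
    if method != "mle":
        raise ValueError(f"unknown method {method!r}")

    fwd, inv = _TRANSFORMS[model]

    def neg_ll_free(x):
        theta = fwd(x)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ll = _loglik_terms(model, theta, t_event, t_cens)
        return np.inf if not np.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    starts = [np.asarray(init, dtype=float)] if init is not None \
        else _starts(model, t_event, n_starts, rng)

    best = None
    for x0_nat in starts:
        x0 = inv(np.asarray(x0_nat, dtype=float))
        res = optimize.minimize(neg_ll_free, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"no start converged for model {model}")

    theta = fwd(best.x)
    if model == "exp1":
        # Newton polish on the analytic score: d ll / d tau = -n/tau + S/tau^2
        tau = float(theta[0])
        n_e, total = t_event.size, float(t_event.sum() + t_cens.sum())
        for _ in range(4):
            score = -n_e / tau + total / tau**2
            curv = n_e / tau**2 - 2 * total / tau**3
            if curv == 0:
                break
            tau -= score / curv
        theta = np.array([tau])
        best.fun = -_loglik_terms(model, theta, t_event, t_cens)
    loglik = -best.fun
    k = _N_PARAMS[model]
    aic = 2 * k - 2 * loglik

    def neg_ll_nat(p):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ll = _loglik_terms(model, p, t_event, t_cens)
        return np.inf if not np.isfinite(ll) else -ll

    hess = _numeric_hessian(neg_ll_nat, theta)
    try:
        cov = np.linalg.inv(hess)
        se_vec = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_vec = np.full(k, np.nan)

    degenerate = False
    if model == "exp1":
        params = {"tau": float(theta[0])}
        se = {"tau": float(se_vec[0])}
    elif model == "exp2":
        w, tf, ts = (float(v) for v in theta)
        se_w, se_tf, se_ts = (float(v) for v in se_vec)
        if tf > ts:  # enforce fast <= slow ordering
            tf, ts = ts, tf
            se_tf, se_ts = se_ts, se_tf
            w = 1.0 - w
        if ts > 0 and tf / ts > 0.8:
            degenerate = True
        if w > 0.995 or w < 0.005:
            degenerate = True
        params = {"weight_fast": w, "weight_slow": 1.0 - w,
                  "tau_fast": tf, "tau_slow": ts}
        se = {"weight_fast": se_w, "weight_slow": se_w,
              "tau_fast": se_tf, "tau_slow": se_ts}
    else:
        params = {"shape": float(theta[0]), "scale": float(theta[1])}
        se = {"shape": float(se_vec[0]), "scale": float(se_vec[1])}

    return CcdFit(model=model, params=params, se=se, loglik=float(loglik),
                  aic=float(aic), n_events=int(t_event.size),
                  n_censored=int(t_cens.size), converged=True,
                  degenerate=degenerate,
                  message="degenerate mixture (effective exp1)" if degenerate else "")


def _fit_lsq_log(samples, model, t_event, t_cens, n_starts, seed):
    """Least squares on the log Kaplan-Meier survival (secondary mode)."""
    curve = empirical_ccd(samples)
    # evaluate at event times with positive survival
    mask = curve.survival > 0
    tt = curve.times[mask]
    logs = np.log(curve.survival[mask])
    fwd, inv = _TRANSFORMS[model]

    def resid(x):
        theta = fwd(x)
        fit = CcdFit(model=model, params=_named(model, theta), se={},
                     loglik=np.nan, aic=np.nan, n_events=0, n_censored=0)
        with np.errstate(divide="ignore"):
            return np.log(np.clip(fit.survival(tt), 1e-300, None)) - logs

    rng = np.random.default_rng(seed)
    best = None
    for x0_nat in _starts(model, t_event, n_starts, rng):
        res = optimize.least_squares(resid, inv(x0_nat))
        if best is None or res.cost < best.cost:
            best = res
    theta = fwd(best.x)
    params = _named(model, theta)
    k = _N_PARAMS[model]
    return CcdFit(model=model, params=params, se={}, loglik=np.nan, aic=np.nan,
                  n_events=int(t_event.size), n_censored=int(t_cens.size),
                  message="lsq-log fit: no likelihood-based errors")


def _named(model, theta):
    if model == "exp1":
        return {"tau": float(theta[0])}
    if model == "exp2":
        w, tf, ts = (float(v) for v in theta)
        if tf > ts:
            tf, ts = ts, tf
            w = 1.0 - w
        return {"weight_fast": w, "weight_slow": 1.0 - w,
                "tau_fast": tf, "tau_slow": ts}
    return {"shape": float(theta[0]), "scale": float(theta[1])}


def bootstrap_se(samples: list[FptSample], model: str, n_boot: int = 500,
                 seed: int = 0, n_starts: int = 4) -> dict:
    """Bootstrap standard errors for the fitted parameters (seeded).

    Resamples trajectories with replacement and refits; reported as an
    alternative to the asymptotic errors when the sample is small.
    """
    rng = np.random.default_rng(seed)
    samples = list(samples)
    n = len(samples)
    draws: dict[str, list] = {}
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = [samples[i] for i in idx]
        try:
            fit = fit_ccd(boot, model=model, n_starts=n_starts,
                          seed=int(rng.integers(0, 2**31 - 1)))
        except FitError:
            continue
        for key, val in fit.params.items():
            draws.setdefault(key, []).append(val)
    return {k: float(np.std(v, ddof=1)) for k, v in draws.items() if len(v) > 1}
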