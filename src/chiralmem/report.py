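"""State-conditioned statistics and report assembly.

The rotation angle theta partitions configurations into a pre-adsorption
and a post-adsorption state.  The thresholds are chirality-dependent and
map onto each other under the parity transformation theta -> 360 - theta:

    pre  : theta > 225 deg (L)   /  theta < 135 deg (D)
    post : theta < 180 deg (L)   /  theta > 180 deg (D)

Strict inequalities, as the thresholds are stated; boundary frames and the
gap between the regions are labeled ``neither`` and excluded from state
averages.

Per umbrella window and state this module reports the mean, the standard
error of the mean (s / sqrt(n)) and n for any recorded observable, plus
Welch unequal-variance t-tests between window pairs (no multiplicity
correction is applied -- flagged in the output metadata so downstream
users can correct).

``assemble_report`` writes the figure-level summary bundle (JSON + CSV)
with every table stamped with the configuration hash and seeds, and
``run_full_analysis`` drives the whole synthetic pipeline end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

PRE = "pre"
POST = "post"
NEITHER = "neither"


class MissingInputError(ValueError):
    """Report assembly is missing upstream artifacts."""


@dataclass
class StatePolicy:
    """Chirality-dependent pre/post-adsorption thresholds on theta."""

    chirality: str

    def __post_init__(self):
        if self.chirality not in ("L", "D"):
            raise ValueError(f"chirality must be 'L' or 'D', got {self.chirality!r}")


def label_state(theta, policy: StatePolicy):
    """Label theta values as pre / post / neither (vectorized).

    Boundary values (exactly at a threshold) are ``neither`` since the
    state regions are defined by strict inequalities.
    """
    th = np.asarray(theta, dtype=float)
    scalar = th.ndim == 0
    th = np.atleast_1d(th)
    if np.any((th < 0) | (th >= 360.0)):
        raise ValueError("theta must lie in [0, 360)")
    if policy.chirality == "L":
        pre = th > 225.0
        post = th < 180.0
    else:
        pre = th < 135.0
        post = th > 180.0
    out = np.where(pre, PRE, np.where(post, POST, NEITHER))
    return out[0] if scalar else out


@dataclass
class WindowStats:
    """Per-(window, state) summary plus pairwise Welch tests.

    ``table`` columns: window (1-based, center-ascending), center, state,
    mean, sem, n.  ``welch`` columns: window_a, window_b, state, p_value.
    """

    table: pd.DataFrame
    welch: pd.DataFrame
    observable: str
    metadata: dict = field(default_factory=dict)


def window_state_summary(windows, observable: str, policy: StatePolicy,
                         states=(PRE, POST), alpha: float = 0.1,
                         welch_state: str = PRE) -> WindowStats:
    """Mean / SEM / n of an observable per umbrella window and state.

    SEM is s / sqrt(n) with the sample standard deviation s; states with
    n < 2 report the mean with a masked (NaN) SEM.  Welch's t-test is run
    for every pair of windows within ``welch_state`` (p-values reported
    raw, no multiplicity correction).
    """
    rows = []
    samples_by_window = {}
    for idx, w in enumerate(windows.windows, start=1):
        if w.theta is None or observable not in w.observables:
            raise MissingInputError(
                f"window {idx} lacks theta or observable {observable!r}")
        labels = label_state(w.theta, policy)
        obs = np.asarray(w.observables[observable], dtype=float)
        for state in states:
            vals = obs[labels == state]
            n = int(vals.size)
            mean = float(vals.mean()) if n else np.nan
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
            rows.append({"window": idx, "center": w.center, "state": state,
                         "mean": mean, "sem": sem, "n": n})
            if state == welch_state:
                samples_by_window[idx] = vals
    table = pd.DataFrame(rows)

    pairs = []
    keys = sorted(samples_by_window)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            va, vb = samples_by_window[a], samples_by_window[b]
            if va.size >= 2 and vb.size >= 2:
                p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
            else:
                p = np.nan
            pairs.append({"window_a": a, "window_b": b, "state": welch_state,
                          "p_value": p})
    welch = pd.DataFrame(pairs)
    return WindowStats(table=table, welch=welch, observable=observable,
                       metadata={"alpha": alpha,
                                 "multiplicity_correction": "none"})


# ---------------------------------------------------------------------------
# report bundle


REQUIRED_INPUTS = ("ccd_fits", "pmf", "barrier", "window_stats", "tl_values",
                   "switch")

_BARRIER_NEGLIGIBLE = 0.3  # kBT; below this the surface counts as downhill


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, payload: dict):
    text = json.dumps(payload, sort_keys=True, indent=1, default=_json_default)
    path.write_text(text + "\n")


def _write_csv(path: Path, df: pd.DataFrame):
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def assemble_report(results: dict, outdir, config_hash: str = "unconfigured",
                    seeds: dict | None = None, tl_bin_width: float = 0.05) -> dict:
    """Write the figure-level summary bundle and return its manifest.

    ``results`` must provide: ``ccd_fits`` (name -> CcdFit), ``pmf``
    (PmfSurface), ``barrier`` (BarrierReport or None for a downhill
    surface), ``window_stats`` (WindowStats), ``tl_values`` (array of
    t.l dot products) and ``switch`` (name -> SwitchReport).  Every file
    is stamped with the config hash and seeds; reruns with identical
    inputs produce byte-identical tables.
    """
    missing = [k for k in REQUIRED_INPUTS if k not in results]
    if missing:
        raise MissingInputError(f"missing upstream inputs: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = seeds or {}
    stamp = {"config_hash": config_hash, "seeds": seeds}

    fits = {name: {"model": f.model, "params": f.params, "se": f.se,
                   "loglik": f.loglik, "aic": f.aic, "n_events": f.n_events,
                   "n_censored": f.n_censored, "degenerate": f.degenerate}
            for name, f in results["ccd_fits"].items()}
    _write_json(outdir / "ccd_fits.json", {**stamp, "fits": fits})

    surf = results["pmf"]
    dz_c, th_c = surf.dz_centers, surf.theta_centers
    ii, jj = np.meshgrid(np.arange(dz_c.size), np.arange(th_c.size), indexing="ij")
    _write_csv(outdir / "pmf_2d.csv", pd.DataFrame({
        "dz_nm": dz_c[ii.ravel()], "theta_deg": th_c[jj.ravel()],
        "free_energy_kT": surf.free_energy.ravel(),
        "sampled": surf.mask.ravel().astype(int)}))
    _write_csv(outdir / "pmf_dz.csv", pd.DataFrame({
        "dz_nm": dz_c, "free_energy_kT": surf.pmf_dz}))

    barrier = results["barrier"]
    if barrier is None:
        payload = {**stamp, "barrier_kT": 0.0, "negligible": True,
                   "note": "single funnel: no saddle between the basin seeds"}
    else:
        payload = {**stamp, "barrier_kT": barrier.barrier,
                   "negligible": barrier.barrier < _BARRIER_NEGLIGIBLE,
                   "saddle_dz_nm": barrier.saddle[0],
                   "saddle_theta_deg": barrier.saddle[1],
                   "basin_pre": list(barrier.basin_pre),
                   "basin_post": list(barrier.basin_post)}
    _write_json(outdir / "barrier.json", payload)

    ws = results["window_stats"]
    _write_csv(outdir / "window_stats.csv", ws.table)
    _write_csv(outdir / "welch_tests.csv", ws.welch)

    tl = np.asarray(results["tl_values"], dtype=float)
    edges = np.arange(-1.0, 1.0 + tl_bin_width / 2, tl_bin_width)
    hist, _ = np.histogram(tl, bins=edges)
    _write_csv(outdir / "tl_hist.csv", pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}))

    switch = {name: {"n_switching_lipids": r.n_switching_lipids,
                     "total_switches": r.total_switches,
                     "debounce": r.debounce}
              for name, r in results["switch"].items()}
    if {"L", "D"} <= set(results["switch"]):
        switch["delta_n_switch"] = (results["switch"]["L"].n_switching_lipids
                                    - results["switch"]["D"].n_switching_lipids)
    _write_json(outdir / "switch.json", {**stamp, **switch})

    manifest = {**stamp,
                "files": sorted(p.name for p in outdir.iterdir()
                                if p.name != "manifest.json"),
                "tl_bin_width": tl_bin_width,
                "welch_multiplicity_correction": "none"}
    _write_json(outdir / "manifest.json", manifest)
    return manifest


def validate_bundle(outdir) -> dict:
    """Check a report bundle against its manifest; return the manifest."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise MissingInputError("bundle has no manifest.json")
    manifest = json.loads(manifest_path.read_text())
    missing = [f for f in manifest["files"] if not (outdir / f).exists()]
    if missing:
        raise MissingInputError(f"bundle missing files: {missing}")
    for key in ("config_hash", "seeds", "files"):
        if key not in manifest:
            raise MissingInputError(f"manifest lacks key {key!r}")
    return manifest


# ---------------------------------------------------------------------------
# end-to-end synthetic pipeline


def run_full_analysis(seed: int = 0, outdir=None, preset: str = "barrier",
                      n_traj: int = 20, n_samples_per_window: int = 4000,
                      n_windows: int = 16, config_hash: str = "default") -> dict:
    """Drive the whole synthetic pipeline and (optionally) write the bundle.

    Generates kinetic traces and umbrella windows on the requested surface
    preset, extracts and fits the FPT survival function, reweights the
    PMF, locates the barrier, summarizes a planted per-sample observable
    by window and state, computes Trp-orientation values on constructed
    fixtures, counts planted side switches, and assembles the bundle.
    Returns the in-memory results dict (with the manifest under
    ``"manifest"`` when ``outdir`` is given).
    """
    from . import contacts, geometry, kinetics, pmf as pmf_mod, synthetic

    rng = np.random.default_rng(seed)
    surface = (synthetic.ReferenceSurface.barrier() if preset == "barrier"
               else synthetic.ReferenceSurface.downhill())

    config = synthetic.LangevinConfig(total_time=100.0, seed=int(seed))
    traces = synthetic.simulate_traces(surface, config, n_traj=n_traj)
    fpts = [kinetics.extract_fpt(t, threshold=1.5) for t in traces]
    fits = {}
    for model in ("exp1", "gamma"):
        try:
            fits[model] = kinetics.fit_ccd(fpts, model=model, seed=int(seed))
        except kinetics.FitError:
            pass
    try:
        fits["exp2"] = kinetics.fit_ccd(fpts, model="exp2", seed=int(seed))
    except kinetics.FitError:
        pass

    centers = np.linspace(1.0, 2.5, n_windows)
    observables = {"srot_proxy": lambda dz, th: 10.0 + 10.0 * np.cos(np.radians(th))}
    windows = synthetic.sample_umbrella(surface, centers=centers,
                                        n_samples=n_samples_per_window,
                                        seed=int(seed), observables=observables)
    surf = pmf_mod.estimate_pmf(windows, estimator="mbar")
    # the approach-side seed sits where the preset's pre-adsorption basin is:
    # (2.2 nm, 90 deg) for the activated surface, on the funnel line otherwise
    seed_pre = (2.2, 90.0) if preset == "barrier" else (2.2, 230.0)
    try:
        barrier = pmf_mod.find_barrier(surf, seed_pre=seed_pre,
                                       seed_post=(1.2, 230.0))
    except pmf_mod.BarrierError:
        barrier = None

    chirality = "D" if preset == "barrier" else "L"
    policy = StatePolicy(chirality=chirality)
    ws = window_state_summary(windows, "srot_proxy", policy)

    # Trp orientation across constructed indole tilts, with angular noise
    tl_values = []
    for tilt in rng.uniform(0.0, 180.0, size=200):
        pep = synthetic.build_peptide(chirality=chirality, trp_tilt_deg=float(tilt))
        tl_values.append(geometry.trp_orientation(pep).dot)
    tl_values = np.array(tl_values)

    # planted side-switching: D lipids hop more often than L lipids
    def planted_series(p_hop, n_lipids=24, n_frames=200):
        out = {}
        for lid in range(n_lipids):
            labels = [geometry.DESCENDING if rng.random() < 0.5
                      else geometry.ASCENDING]
            for _ in range(n_frames - 1):
                cur = labels[-1]
                if rng.random() < p_hop:
                    cur = (geometry.ASCENDING if cur == geometry.DESCENDING
                           else geometry.DESCENDING)
                labels.append(cur)
            out[lid] = labels
        return out

    switch = {"L": contacts.switch_events(planted_series(0.002), debounce=5),
              "D": contacts.switch_events(planted_series(0.02), debounce=5)}

    results = {"ccd_fits": fits, "pmf": surf, "barrier": barrier,
               "window_stats": ws, "tl_values": tl_values, "switch": switch}
    if outdir is not None:
        results["manifest"] = assemble_report(
            results, outdir, config_hash=config_hash,
            seeds={"pipeline": int(seed)})
    return results
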