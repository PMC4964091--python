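"""Monte-Carlo maximum-likelihood estimation of the valued ERGM.

The estimator is importance-sampling MC-MLE (Geyer-Thompson): networks are
sampled at the current coefficient vector, the log-normaliser ratio is
estimated by importance weights, and trust-region Newton steps solve the
exponential-family moment equation g_obs = E_theta[g(Y)].  Standard errors
come from the inverse estimated Fisher information, i.e. the covariance of
the sufficient statistics at the solution.

``refit_until_stable`` reproduces the practical convergence procedure of
re-running the fit with the previous estimates as starting values until
the coefficients stop moving.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ergm_model import ERGMSpec, ThetaVector, sufficient_statistics
from .ergm_sample import SamplerControl, derive_seed, simulate_networks
from .netdata import ClosenessMatrix, ValuedNetwork


class DegenerateNetworkError(ValueError):
    """Observed network cannot identify the model (all-zero or saturated)."""


@dataclass
class FitControl:
    """Tuning knobs for the MC-MLE loop.

    ``n_sims`` networks are drawn per outer iteration with a short thinning
    interval (``interval_mult`` x n_dyads); Newton steps are clamped to
    ``step_max`` in the infinity norm and stopped early when the effective
    sample size of the importance weights falls below ``ess_frac`` of the
    batch.  To keep the update inside the region where importance sampling
    is trustworthy, each iteration solves towards a partial pseudo-target
    gamma * g_obs + (1 - gamma) * gbar with gamma chosen so the target
    lies within ``step_mahalanobis`` Mahalanobis units of the simulated
    statistic cloud (partial stepping); gamma reaches 1 as the fit
    converges.  Convergence requires gamma = 1 and every moment-equation
    z-score (observed minus simulated mean statistic over its Monte-Carlo
    standard error) below ``z_tol``.
    """

    n_sims: int = 256
    burnin_mult: float = 20.0
    interval_mult: float = 2.0
    n_verify: int = 64
    verify_z_tol: float = 4.0
    drift_factor: float = 3.0
    max_iter: int = 30
    # max over 6 correlated |z| scores sits near 2 even at the exact
    # solution; 2.8 keeps the false-nonconvergence rate around a few %
    z_tol: float = 2.8
    step_max: float = 0.5
    step_mahalanobis: float = 2.0
    ess_frac: float = 0.33
    ridge: float = 1e-6
    seed: int = 0
    max_weight: int | None = None
    method: str = "is"  # "is" (importance sampling) or "sa" (stoch. approx.)


@dataclass
class FitResult:
    theta_hat: ThetaVector
    standard_errors: np.ndarray
    n_restarts: int
    converged: bool
    theta_path: np.ndarray  # per-iteration theta log
    info: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return self.standard_errors

    def to_json(self, path) -> None:
        """Serialise estimates in the coefficient-vector fixture format."""
        import json

        doc = self.theta_hat.to_dict()
        doc["converged"] = bool(self.converged)
        doc["n_restarts"] = int(self.n_restarts)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    def write_theta_path(self, path) -> None:
        """Per-iteration coefficient log as TSV, for diagnostics."""
        import pandas as pd

        frame = pd.DataFrame(self.theta_path, columns=self.theta_hat.terms)
        frame.index.name = "iteration"
        frame.to_csv(path, sep="\t")


def _mcse(stats: np.ndarray, n_batches: int = 16) -> np.ndarray:
    """Batch-means Monte-Carlo SE of the mean of autocorrelated draws."""
    m = stats.shape[0]
    nb = min(n_batches, max(2, m // 8))
    usable = (m // nb) * nb
    batches = stats[:usable].reshape(nb, -1, stats.shape[1]).mean(axis=1)
    return batches.std(axis=0, ddof=1) / np.sqrt(nb)


def _default_init(net: ValuedNetwork, spec: ERGMSpec) -> ThetaVector:
    """Zeros, except the sparsity term set from observed density via its
    closed form under the Poisson reference."""
    vals = np.zeros(spec.n_terms)
    if "nonzero" in spec.terms:
        m = net.n * (net.n - 1) // 2
        k = net.n_edges
        k = min(max(k, 1), m - 1)
        vals[spec.terms.index("nonzero")] = (
            np.log(k / (m - k)) - np.log(np.e - 1.0)
        )
    return ThetaVector(spec.terms, vals)


def _check_nondegenerate(net: ValuedNetwork, control: FitControl) -> None:
    n_dyads = net.n * (net.n - 1) // 2
    if net.n_edges == 0:
        raise DegenerateNetworkError("network has no nonzero dyad")
    if net.n_edges == n_dyads and control.max_weight is None:
        raise DegenerateNetworkError("network is complete; model unidentified")


def fit_ergm(
    net: ValuedNetwork,
    spec: ERGMSpec = ERGMSpec(),
    init: ThetaVector | None = None,
    control: FitControl = FitControl(),
    closeness: ClosenessMatrix | None = None,
) -> FitResult:
    """Monte-Carlo MLE of theta for one observed network."""
    _check_nondegenerate(net, control)
    g_obs = sufficient_statistics(net, spec, closeness)
    theta = (init or _default_init(net, spec)).values.astype(float).copy()
    p = spec.n_terms
    path = [theta.copy()]
    converged = False
    info: dict = {}
    sampler = SamplerControl(
        burnin=max(1, int(control.burnin_mult * net.n * (net.n - 1) // 2)),
        interval=max(1, int(control.interval_mult * net.n * (net.n - 1) // 2)),
        max_weight=control.max_weight,
    )

    if control.method == "sa":
        return _fit_sa(net, spec, theta, g_obs, control, sampler, closeness)

    nz_idx = spec.terms.index("nonzero") if "nonzero" in spec.terms else None

    def sample_at(theta_arr: np.ndarray, it: int):
        """Sample the batch in chunks, aborting early if the chain drifts
        towards the degenerate dense region (bounds the cost of a bad
        coefficient proposal)."""
        chunks = []
        n_chunks = 4
        per = int(np.ceil(control.n_sims / n_chunks))
        for c in range(n_chunks):
            sc = replace(sampler, seed=derive_seed(control.seed, it, c))
            s = simulate_networks(
                net, ThetaVector(spec.terms, theta_arr), spec, per, sc,
                closeness, return_stats=True,
            )
            chunks.append(s)
            if nz_idx is not None and s[:, nz_idx].mean() > (
                    control.drift_factor * max(g_obs[nz_idx], 10.0)):
                return np.concatenate(chunks), True
        return np.concatenate(chunks), False

    stats = cov = None
    anchor = _default_init(net, spec).values  # density-matched fallback
    last_good = theta.copy()
    n_drift = 0
    last_maxz = np.inf
    for it in range(control.max_iter):
        stats, drifted = sample_at(theta, it)
        if drifted:
            # pull back towards the last non-drifting estimate; if the
            # starting value itself drifts, fall back to the density anchor
            n_drift += 1
            if np.max(np.abs(theta - last_good)) < 1e-9:
                last_good = anchor.copy()
            theta = 0.5 * (theta + last_good)
            path.append(theta.copy())
            continue
        last_good = theta.copy()
        gbar = stats.mean(axis=0)
        cov = np.cov(stats.T).reshape(p, p)
        mcse = _mcse(stats)
        z = (g_obs - gbar) / np.maximum(mcse, 1e-12)
        # partial stepping: pull the target inside the simulated cloud
        covr = cov + control.ridge * np.eye(p)
        try:
            maha = float(np.sqrt(
                (g_obs - gbar) @ np.linalg.solve(covr, g_obs - gbar)))
        except np.linalg.LinAlgError:
            maha = np.inf
        gamma = min(1.0, control.step_mahalanobis / max(maha, 1e-12))
        if gamma >= 1.0:
            last_maxz = float(np.max(np.abs(z)))
        if gamma >= 1.0 and np.max(np.abs(z)) < control.z_tol:
            converged = True
            info = {"z": z, "mcse": mcse, "gbar": gbar, "n_iter": it + 1}
            break
        target = gamma * g_obs + (1.0 - gamma) * gbar
        # trust-region Newton on the importance-sampled log-likelihood
        theta0 = theta.copy()
        for _ in range(25):
            lw = stats @ (theta - theta0)
            lw -= lw.max()
            w = np.exp(lw)
            w /= w.sum()
            ess = 1.0 / np.sum(w**2)
            if ess < control.ess_frac * control.n_sims:
                break
            gw = w @ stats
            grad = target - gw
            centred = stats - gw
            H = (centred * w[:, None]).T @ centred
            H += control.ridge * np.eye(p)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = grad / np.maximum(np.diag(H), 1e-8)
            if not np.isfinite(step).all():
                info = {"error": "non-finite update", "n_iter": it + 1}
                theta = theta0
                break
            smax = np.max(np.abs(step))
            if smax > control.step_max:
                step *= control.step_max / smax
            theta = theta + step
            if np.max(np.abs(theta - theta0)) >= control.step_max:
                break
            if smax < 1e-6:
                break
        if not np.isfinite(theta).all() or "error" in info:
            info.setdefault("error", "non-finite update")
            theta = path[-1]
            break
        path.append(theta.copy())
    else:
        info = {"n_iter": control.max_iter}

    # verification: a longer, better-decorrelated chain at theta_hat must
    # still reproduce the observed statistics — short fitting chains can
    # report a spurious moment match at degenerate coefficient values
    if converged and control.n_verify > 0:
        vctl = SamplerControl(
            burnin=max(1, int(50 * net.n * (net.n - 1) // 2)),
            interval=max(1, int(8 * net.n * (net.n - 1) // 2)),
            seed=derive_seed(control.seed, 4242),
            max_weight=control.max_weight,
        )
        vstats = simulate_networks(
            net, ThetaVector(spec.terms, theta), spec,
            control.n_verify, vctl, closeness, return_stats=True,
        )
        vmcse = _mcse(vstats)
        vz = (g_obs - vstats.mean(axis=0)) / np.maximum(vmcse, 1e-12)
        info["verify_z"] = vz
        if np.max(np.abs(vz)) > control.verify_z_tol:
            converged = False
            info["error"] = "verification failed"
        cov = np.cov(vstats.T).reshape(p, p)

    if cov is None and stats is not None:
        cov = np.cov(stats.T).reshape(p, p)
    se = np.full(p, np.nan)
    if cov is not None:
        try:
            fisher_inv = np.linalg.inv(cov + control.ridge * np.eye(p))
            se = np.sqrt(np.maximum(np.diag(fisher_inv), 0.0))
        except np.linalg.LinAlgError:
            converged = False
    info["n_drift"] = n_drift
    info["last_maxz"] = last_maxz
    if converged and not (np.isfinite(se).all() and (se > 0).all()):
        converged = False
    theta_hat = ThetaVector(spec.terms, theta, se if np.isfinite(se).all() else None)
    return FitResult(theta_hat, se, 0, converged, np.array(path), info)


def _fit_sa(net, spec, theta, g_obs, control, sampler, closeness):
    """Robbins-Monro stochastic-approximation fallback."""
    p = spec.n_terms
    path = [theta.copy()]
    batch = max(8, control.n_sims // 8)
    scale = None
    stats = None
    for it in range(control.max_iter * 2):
        sc = replace(sampler, seed=derive_seed(control.seed, 1000 + it))
        stats = simulate_networks(
            net, ThetaVector(spec.terms, theta), spec, batch, sc,
            closeness, return_stats=True,
        )
        gbar = stats.mean(axis=0)
        if scale is None:
            scale = np.maximum(stats.std(axis=0), 1e-3) ** 2
        gain = 0.5 / (1.0 + it)
        step = gain * (g_obs - gbar) / scale
        smax = np.max(np.abs(step))
        if smax > control.step_max:
            step *= control.step_max / smax
        theta = theta + step
        path.append(theta.copy())
    sc = replace(sampler, seed=derive_seed(control.seed, 9999))
    stats = simulate_networks(
        net, ThetaVector(spec.terms, theta), spec, control.n_sims, sc,
        closeness, return_stats=True,
    )
    gbar = stats.mean(axis=0)
    mcse = _mcse(stats)
    z = (g_obs - gbar) / np.maximum(mcse, 1e-12)
    converged = bool(np.max(np.abs(z)) < control.z_tol)
    cov = np.cov(stats.T).reshape(p, p)
    fisher_inv = np.linalg.inv(cov + control.ridge * np.eye(p))
    se = np.sqrt(np.maximum(np.diag(fisher_inv), 0.0))
    theta_hat = ThetaVector(spec.terms, theta, se)
    return FitResult(theta_hat, se, 0, converged, np.array(path),
                     {"z": z, "mcse": mcse, "method": "sa"})


def refit_until_stable(
    net: ValuedNetwork,
    spec: ERGMSpec = ERGMSpec(),
    control: FitControl = FitControl(),
    max_restarts: int = 4,
    tol: float = 0.05,
    closeness: ClosenessMatrix | None = None,
    init: ThetaVector | None = None,
) -> FitResult:
    """Re-run the fit seeded with the previous estimates until stable.

    Stability means max |delta theta| < ``tol`` between consecutive runs
    (comparable to typical coefficient standard errors); a fit that keeps
    moving after ``max_restarts`` re-runs is returned flagged
    non-converged rather than raising.
    """
    if max_restarts < 1:
        raise ValueError("max_restarts must be >= 1")
    fit = fit_ergm(net, spec, init, control, closeness)
    for r in range(1, max_restarts + 1):
        ctl = replace(control, seed=derive_seed(control.seed, 7, r))
        nxt = fit_ergm(net, spec, fit.theta_hat, ctl, closeness)
        delta = np.max(np.abs(nxt.theta_hat.values - fit.theta_hat.values))
        nxt.n_restarts = r
        nxt.info["stability_delta"] = float(delta)
        fit = nxt
        if delta < tol:
            # "small differences to the coefficients" counts as converged,
            # but only when the fit at least roughly matched the observed
            # statistics (a drift-stuck fit is also trivially stable)
            near_match = fit.info.get("last_maxz", np.inf) < 2 * control.z_tol
            fit.converged = fit.converged or bool(
                np.isfinite(fit.standard_errors).all() and near_match
            )
            fit.info["converged_by_stability"] = True
            return fit
    fit.converged = False
    fit.info["converged_by_stability"] = False
    return fit
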