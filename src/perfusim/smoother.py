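"""Iterative regularized Levenberg-Marquardt ensemble smoother.

All concentration data are assimilated jointly.  Each iteration simulates
every ensemble member, scales the predicted-data anomalies by the inverse
square-root observation covariance, projects them onto the dominant singular
directions (TSVD keeping 99.9% of the singular-value sum), computes a binary
correlation-based tapering (localization) matrix between parameters and
projected innovations, and applies the damped update

    m_j <- m_j + Lambda o [S_m V_p W_p (W_p^2 + (N-1) gamma I)^-1] U_p^T
                 C_c^{-1/2} (c_o - c_j + eps_j)

The damping weight gamma shrinks by 0.9 after an iteration that lowers the
ensemble-average data mismatch and doubles (with the step rejected and
retried) otherwise.  Iterations stop at a maximum count or when the relative
mismatch change falls below a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

log = logging.getLogger(__name__)


def data_mismatch(c_o: np.ndarray, c_j: np.ndarray, var: np.ndarray) -> float:
    """Quadratic data mismatch (c_o - c_j)^T C_c^{-1} (c_o - c_j) for a
    diagonal observation covariance with variances ``var``."""
    var = np.asarray(var, dtype=float)
    if np.any(var <= 0):
        raise ValueError("observation variances must be positive")
    r = np.asarray(c_o, dtype=float) - np.asarray(c_j, dtype=float)
    return float(r @ (r / var))


@dataclass
class ProjectedData:
    """TSVD factors of the scaled anomaly matrix and the retained rank."""

    U: np.ndarray
    w: np.ndarray
    V: np.ndarray
    p: int
    energy: float


def tsvd_project(S_tilde: np.ndarray, energy: float = 0.999) -> ProjectedData:
    """Truncate the SVD of the scaled anomaly matrix at the smallest rank
    whose singular-value sum reaches ``energy`` of the total."""
    if not (0 < energy <= 1):
        raise ValueError("energy must lie in (0, 1]")
    U, w, Vt = np.linalg.svd(S_tilde, full_matrices=False)
    total = w.sum()
    if total == 0:
        return ProjectedData(U[:, :0], w[:0], Vt[:0].T, 0, energy)
    nonzero = w > 1e-14 * w[0]
    cum = np.cumsum(w) / total
    p = int(np.searchsorted(cum, energy - 1e-12) + 1)
    p = min(p, int(nonzero.sum()))
    return ProjectedData(U[:, :p], w[:p], Vt[:p].T, p, energy)


def correlation_threshold(N: int, alpha: float = 0.01) -> float:
    """(1 - alpha) two-sided null quantile of the sample correlation of N
    independent pairs, via the Fisher z approximation: tanh(z_{1-a/2}/sqrt(N-3))."""
    if N <= 3:
        return 1.0
    return float(np.tanh(norm.ppf(1 - alpha / 2) / np.sqrt(N - 3)))


def compute_taper(S_m: np.ndarray, dproj: np.ndarray,
                  alpha: float = 0.01) -> np.ndarray:
    """Binary tapering matrix Lambda (N_m x p).

    Lambda_kl = 1 iff the sample correlation across the ensemble between
    parameter k and projected innovation component l exceeds, in magnitude,
    the null threshold for spurious correlation at the current ensemble size.
    """
    N = S_m.shape[1]
    thr = correlation_threshold(N, alpha)
    sm = S_m - S_m.mean(axis=1, keepdims=True)
    sd = dproj - dproj.mean(axis=1, keepdims=True)
    nm = np.sqrt((sm * sm).sum(axis=1))
    ndp = np.sqrt((sd * sd).sum(axis=1))
    nm[nm == 0] = np.inf
    ndp[ndp == 0] = np.inf
    corr = (sm @ sd.T) / np.outer(nm, ndp)
    return (np.abs(corr) > thr).astype(np.float64)


def update_step(members: np.ndarray, pred: np.ndarray, c_o: np.ndarray,
                var: np.ndarray, gamma: float, rng: np.random.Generator,
                pred_mean_run: np.ndarray | None = None,
                energy: float = 0.999, localize: bool = True,
                taper_alpha: float = 0.01):
    """One localized LM ensemble update; returns (new members, diagnostics).

    ``members`` is (N_m, N), ``pred`` the per-member predicted data (N_d, N),
    ``pred_mean_run`` the forward run of the ensemble-mean parameters (the
    anomaly reference; defaults to the ensemble mean of ``pred``).
    Perturbations eps_j are drawn from the data-error distribution.
    """
    Nm, N = members.shape
    Nd = pred.shape[0]
    if pred.shape[1] != N or c_o.size != Nd:
        raise ValueError("dimension mismatch between members, predictions and data")
    sd = np.sqrt(np.asarray(var, dtype=float))
    if pred_mean_run is None:
        pred_mean_run = pred.mean(axis=1)
    S_m = members - members.mean(axis=1, keepdims=True)
    S_c = pred - pred_mean_run[:, None]
    S_ct = S_c / sd[:, None]

    proj = tsvd_project(S_ct, energy)
    if proj.p == 0:
        return members.copy(), dict(p=0, taper_fraction=0.0)

    eps = sd[:, None] * rng.standard_normal((Nd, N))
    innov = (c_o[:, None] - pred + eps) / sd[:, None]
    dproj = proj.U.T @ innov  # (p, N)

    denom = proj.w**2 + (N - 1) * gamma
    gain = S_m @ (proj.V * (proj.w / denom)[None, :])  # (N_m, p)
    if localize:
        Lam = compute_taper(S_m, dproj, taper_alpha)
        gain = Lam * gain
        taper_fraction = float(Lam.mean())
    else:
        taper_fraction = 1.0
    new = members + gain @ dproj
    return new, dict(p=proj.p, taper_fraction=taper_fraction)


def adapt_gamma(gamma: float, prev_mismatch: float, new_mismatch: float,
                reduce: float = 0.9, increase: float = 2.0):
    """LM damping schedule: non-increase of the average mismatch accepts the
    step and relaxes gamma by ``reduce``; an increase rejects it and
    tightens gamma by ``increase``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if new_mismatch <= prev_mismatch:
        return gamma * reduce, True
    return gamma * increase, False


@dataclass
class SmootherConfig:
    max_iterations: int = 10
    rel_change_tol: float = 0.1
    gamma0: float = 1.0
    gamma_reduce: float = 0.9
    gamma_increase: float = 2.0
    max_retries: int = 3
    svd_energy: float = 0.999
    localize: bool = True
    taper_alpha: float = 0.01
    redraw_perturbations: bool = True


@dataclass
class SmootherResult:
    members: np.ndarray
    mismatch_history: list          # average mismatch after each accepted iteration
    member_mismatch: list           # per-member mismatch arrays per accepted state
    gamma_history: list
    accepted: list                  # bool per attempted step
    diagnostics: list
    n_forward_runs: int
    stop_reason: str

    def posterior_mean(self) -> np.ndarray:
        return self.members.mean(axis=1)

    def posterior_sd(self) -> np.ndarray:
        return self.members.std(axis=1, ddof=1)


def run_smoother(ensemble_members: np.ndarray, c_o: np.ndarray,
                 var: np.ndarray, forward, config: SmootherConfig | None = None,
                 seed: int = 0, postprocess=None) -> SmootherResult:
    """Iterate simulate -> project -> taper -> update -> adapt-gamma.

    Parameters
    ----------
    ensemble_members : (N_m, N) array
        Initial ensemble (columns are members).
    c_o, var : (N_d,) arrays
        Observation vector and diagonal observation-error variances.
    forward : callable (N_m,) -> (N_d,)
        Forward model mapping one parameter vector to predicted data.
    postprocess : callable (N_m,) -> (N_m,), optional
        Applied to every member after each update (bound clipping, vessel
        overrides).
    """
    cfg = config or SmootherConfig()
    rng = np.random.default_rng(seed)
    members = ensemble_members.copy()
    N = members.shape[1]

    def simulate(M):
        cols = []
        for j in range(M.shape[1]):
            cols.append(np.asarray(forward(M[:, j]), dtype=float))
        return np.column_stack(cols)

    nruns = 0
    pred = simulate(members); nruns += N
    mean_run = np.asarray(forward(members.mean(axis=1)), dtype=float); nruns += 1
    mm = np.array([data_mismatch(c_o, pred[:, j], var) for j in range(N)])
    history = [float(mm.mean())]
    member_mm = [mm.copy()]
    gamma = cfg.gamma0
    gam_hist = [gamma]
    accepted_flags = []
    diags = []
    stop = "max_iterations"

    it = 0
    while it < cfg.max_iterations:
        retries = 0
        while True:
            step_rng = np.random.default_rng(rng.integers(2**31)) \
                if cfg.redraw_perturbations else np.random.default_rng(seed + 1)
            new_members, d = update_step(members, pred, c_o, var, gamma,
                                         step_rng, pred_mean_run=mean_run,
                                         energy=cfg.svd_energy,
                                         localize=cfg.localize,
                                         taper_alpha=cfg.taper_alpha)
            if postprocess is not None:
                for j in range(N):
                    new_members[:, j] = postprocess(new_members[:, j])
            new_pred = simulate(new_members); nruns += N
            new_mm = np.array([data_mismatch(c_o, new_pred[:, j], var)
                               for j in range(N)])
            gamma_new, ok = adapt_gamma(gamma, history[-1], float(new_mm.mean()),
                                        cfg.gamma_reduce, cfg.gamma_increase)
            accepted_flags.append(ok)
            diags.append(d | dict(iteration=it, gamma=gamma,
                                  mismatch=float(new_mm.mean())))
            gamma = gamma_new
            if ok:
                members = new_members
                pred = new_pred
                mean_run = np.asarray(forward(members.mean(axis=1)), dtype=float)
                nruns += 1
                history.append(float(new_mm.mean()))
                member_mm.append(new_mm.copy())
                gam_hist.append(gamma)
                break
            retries += 1
            log.info("iteration %d rejected (mismatch %.4g > %.4g); gamma -> %g",
                     it, new_mm.mean(), history[-1], gamma)
            if retries > cfg.max_retries:
                return SmootherResult(members, history, member_mm, gam_hist,
                                      accepted_flags, diags, nruns,
                                      "max_retries_exceeded")
        it += 1
        rel = abs(history[-1] - history[-2]) / max(history[-2], 1e-300)
        if rel < cfg.rel_change_tol:
            stop = "converged"
            break

    return SmootherResult(members, history, member_mm, gam_hist,
                          accepted_flags, diags, nruns, stop)
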