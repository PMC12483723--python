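"""Stage-2 fitting: DWLS minimization, robust covariance, adjusted chi-square.

The sample statistics are s = (probit-scale thresholds, polychoric
correlations).  Their asymptotic covariance Gamma is obtained from stacked
influence functions of the two-step estimator: thresholds are explicit
functions of cumulative proportions, and each polychoric solves a pseudo-ML
estimating equation with thresholds plugged in, so the correction for
threshold estimation enters through the chain rule.  A subject-resampling
bootstrap is available as a cross-check.

The DWLS estimator minimizes F = (s - sigma(theta))' W^{-1} (s - sigma(theta))
with W = diag(Gamma); standard errors use the full-Gamma sandwich and the test
statistic n F is mean-and-variance adjusted (Satterthwaite second-order):
T_adj = (m1/m2) n F with df* = m1^2/m2 where m_k = tr((U Gamma)^k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr, ndtri
from scipy.stats import chi2 as chi2_dist

from .bvn import bvn_pdf, rectangle_probs
from .models import (
    Family,
    ModelSpec,
    build_spec,
    count_df,
    model_stats,
    recover_params,
    stat_inventory,
    stats_jacobian,
)
from .panel import OrdinalPanel, crosstab
from .auxiliary import estimate_thresholds, polychoric_matrix
from .panel import margins as panel_margins

logger = logging.getLogger(__name__)

__all__ = [
    "SampleStats",
    "FitResult",
    "compute_sample_stats",
    "estimate_acov",
    "dwls_fit",
    "robust_se",
    "adjusted_chi2",
    "fit_indices",
]

_NORM_PDF = lambda x: np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)  # noqa: E731


@dataclass
class SampleStats:
    """Stacked sample statistics with their asymptotic covariance."""

    s: np.ndarray
    Gamma: np.ndarray  # asymptotic covariance of sqrt(n) (s - s0)
    n: int
    T: int
    C: tuple[int, ...]
    flags: list[str] = field(default_factory=list)

    @property
    def inventory(self):
        return stat_inventory(self.T, self.C)


@dataclass
class FitResult:
    """DWLS/WLSMV fit summary."""

    theta: np.ndarray
    param_names: list[str]
    se_robust: np.ndarray
    F_min: float
    chi2_adj: float
    df: int
    df_star: float
    p_value: float
    fit_indices: dict
    n: int
    converged: bool
    gradient_norm: float
    n_iter: int
    warnings: list[str] = field(default_factory=list)
    chi2_unadjusted: float = 0.0

    def summary(self) -> str:
        lines = [
            f"DWLS fit: chi2_adj = {self.chi2_adj:.4f}, df = {self.df} "
            f"(df* = {self.df_star:.2f}), p = {self.p_value:.4f}",
            f"converged = {self.converged} (|grad| = {self.gradient_norm:.2e})",
        ]
        for k, v in self.fit_indices.items():
            lines.append(f"  {k} = {v:.4f}")
        for name, est, se in zip(self.param_names, self.theta, self.se_robust):
            lines.append(f"  {name:24s} {est: .4f}  (se {se:.4f})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Sample statistics and Gamma
# ---------------------------------------------------------------------------


def _threshold_influence(panel: OrdinalPanel) -> tuple[np.ndarray, np.ndarray, list]:
    """Thresholds tau_hat and per-subject influence columns for each (v,t,c)."""
    n = panel.n
    cols = []
    taus = []
    index = []
    for v in range(panel.V):
        ts = estimate_thresholds(panel_margins(panel, v))
        taus.append(ts)
        for t in range(panel.T):
            y = panel.column(v, t)
            for c in range(panel.C[v] - 1):
                p = np.mean(y <= c)
                tau = ts.tau[t, c]
                phi = _NORM_PDF(tau) if np.isfinite(tau) else np.nan
                iff = ((y <= c).astype(float) - p) / phi
                cols.append(iff)
                index.append((v, t, c))
    return taus, np.column_stack(cols), index


def _polychoric_influence(
    panel: OrdinalPanel, R: np.ndarray, thresholds, if_tau: np.ndarray, tau_index
) -> np.ndarray:
    """Influence columns for each polychoric, with threshold-estimation correction."""
    T, V = panel.T, panel.V
    VT = V * T
    n = panel.n
    cuts = [thresholds[i // T].cuts(i % T) for i in range(VT)]
    tau_pos = {key: k for k, key in enumerate(tau_index)}
    cols = []
    for i in range(VT):
        vi, ti = i // T, i % T
        for j in range(i + 1, VT):
            vj, tj = j // T, j % T
            rho = R[i, j]
            ci, cj = cuts[i], cuts[j]
            tab = crosstab(panel, i, j).cells
            pi = np.maximum(rectangle_probs(ci, cj, rho), 1e-12)
            # d pi / d rho: bivariate density at the cell corners
            dens = bvn_pdf(ci[:, None], cj[None, :], rho)
            dpi_drho = dens[1:, 1:] - dens[:-1, 1:] - dens[1:, :-1] + dens[:-1, :-1]
            score_cell = dpi_drho / pi
            A = float(np.sum(dpi_drho**2 / pi))  # -E d(score)/d rho
            s2 = np.sqrt(1.0 - rho * rho)

            # expected cross-derivatives wrt each finite threshold
            corr = np.zeros((panel.C[vi] - 1 + panel.C[vj] - 1,))
            corr_ifs = []
            k = 0
            for c in range(panel.C[vi] - 1):
                a_c = ci[c + 1]
                if np.isfinite(a_c):
                    g = _NORM_PDF(a_c) * (
                        ndtr((cj[1:] - rho * a_c) / s2) - ndtr((cj[:-1] - rho * a_c) / s2)
                    )
                    dpi_dtau = np.zeros_like(pi)
                    dpi_dtau[c, :] += g
                    dpi_dtau[c + 1, :] -= g
                    corr[k] = -float(np.sum(dpi_drho * dpi_dtau / pi))
                    corr_ifs.append(if_tau[:, tau_pos[(vi, ti, c)]])
                else:
                    corr_ifs.append(np.zeros(n))
                k += 1
            for c in range(panel.C[vj] - 1):
                b_c = cj[c + 1]
                if np.isfinite(b_c):
                    g = _NORM_PDF(b_c) * (
                        ndtr((ci[1:] - rho * b_c) / s2) - ndtr((ci[:-1] - rho * b_c) / s2)
                    )
                    dpi_dtau = np.zeros_like(pi)
                    dpi_dtau[:, c] += g
                    dpi_dtau[:, c + 1] -= g
                    corr[k] = -float(np.sum(dpi_drho * dpi_dtau / pi))
                    corr_ifs.append(if_tau[:, tau_pos[(vj, tj, c)]])
                else:
                    corr_ifs.append(np.zeros(n))
                k += 1

            yi = panel.data[:, i]
            yj = panel.data[:, j]
            subject_score = score_cell[yi, yj]
            extra = np.zeros(n)
            for w, iff in zip(corr, corr_ifs):
                if w != 0.0:
                    extra += w * iff
            cols.append((subject_score + extra) / max(A, 1e-12))
    return np.column_stack(cols) if cols else np.empty((n, 0))


def compute_sample_stats(panel: OrdinalPanel, *, method: str = "analytic", B: int = 500, seed: int = 0) -> SampleStats:
    """Thresholds, polychoric correlations, and their asymptotic covariance."""
    R, thresholds, flags = polychoric_matrix(panel)
    _, if_tau, tau_index = _threshold_influence(panel)
    iu = np.triu_indices(panel.V * panel.T, k=1)
    s = np.concatenate(
        [np.concatenate([ts.tau.reshape(-1) for ts in thresholds]), R[iu]]
    )
    if method == "analytic":
        if_rho = _polychoric_influence(panel, R, thresholds, if_tau, tau_index)
        IF = np.column_stack([if_tau, if_rho])
        IF = IF - IF.mean(axis=0)
        Gamma = (IF.T @ IF) / panel.n
    elif method == "bootstrap":
        Gamma = _bootstrap_gamma(panel, B=B, seed=seed)
    else:
        raise ValueError("method must be 'analytic' or 'bootstrap'")
    return SampleStats(s=s, Gamma=Gamma, n=panel.n, T=panel.T, C=panel.C, flags=flags)


def _bootstrap_gamma(panel: OrdinalPanel, B: int, seed: int) -> np.ndarray:
    if B < 100:
        logger.warning("bootstrap with B=%d < 100 resamples is noisy", B)
    rng = np.random.default_rng(seed)
    reps = []
    from .panel import panel_from_array

    for _ in range(B):
        idx = rng.integers(0, panel.n, size=panel.n)
        bp = panel_from_array(panel.data[idx], panel.T, panel.C, panel.var_names)
        Rb, tb, _ = polychoric_matrix(bp)
        iu = np.triu_indices(panel.V * panel.T, k=1)
        reps.append(
            np.concatenate([np.concatenate([ts.tau.reshape(-1) for ts in tb]), Rb[iu]])
        )
    reps = np.asarray(reps)
    return np.cov(reps.T, ddof=1) * panel.n


def estimate_acov(panel: OrdinalPanel, *, method: str = "analytic", B: int = 500, seed: int = 0) -> np.ndarray:
    """Asymptotic covariance Gamma of the stacked sample statistics."""
    return compute_sample_stats(panel, method=method, B=B, seed=seed).Gamma


# ---------------------------------------------------------------------------
# DWLS fit
# ---------------------------------------------------------------------------


def _mom_start(spec: ModelSpec, stats: SampleStats) -> np.ndarray:
    T, C = stats.T, stats.C
    n_tau = sum(T * (c - 1) for c in C)
    std_tau = []
    k = 0
    for cv in C:
        std_tau.append(stats.s[k : k + T * (cv - 1)].reshape(T, cv - 1))
        k += T * (cv - 1)
    VT = len(C) * T
    R = np.eye(VT)
    iu = np.triu_indices(VT, k=1)
    R[iu] = stats.s[n_tau:]
    R = R + R.T - np.eye(VT)
    return recover_params(spec, std_tau, R)


def dwls_fit(
    stats: SampleStats,
    spec: ModelSpec,
    start: np.ndarray | None = None,
    *,
    n_starts: int = 3,
    xtol: float = 1e-14,
) -> FitResult:
    """Diagonally weighted least squares with robust (WLSMV-style) inference.

    Multistart: method-of-moments recovery from the sample statistics, a
    perturbed copy, and any user-supplied start.  Equality and fixed
    constraints are built into the spec's parameter maps, so df accounting is
    exact by construction.
    """
    if spec.n_stats != stats.s.size:
        raise ValueError("spec and sample statistics have mismatching dimensions")
    w = np.diag(stats.Gamma).copy()
    if np.any(w <= 0):
        raise ValueError("weight matrix has nonpositive diagonal entries")
    sw = np.sqrt(w)
    s_obs = stats.s

    def resid(th):
        return (s_obs - model_stats(spec, th)) / sw

    starts: list[np.ndarray] = []
    if start is not None:
        starts.append(np.asarray(start, dtype=float))
    mom = _mom_start(spec, stats)
    starts.append(mom)
    rng = np.random.default_rng(0)
    while len(starts) < n_starts:
        starts.append(mom + rng.normal(scale=0.05, size=mom.size))

    best = None
    for th0 in starts:
        try:
            sol = least_squares(resid, th0, method="lm", xtol=xtol, ftol=xtol, gtol=1e-12, max_nfev=4000)
        except Exception:  # lm can fail on exactly-singular Jacobians
            sol = least_squares(resid, th0, method="trf", xtol=xtol, ftol=xtol, gtol=1e-12, max_nfev=4000)
        if best is None or sol.cost < best.cost:
            best = sol
    sol = best

    theta = sol.x
    F_min = 2.0 * sol.cost  # residuals are W^{-1/2}-scaled
    grad_norm = float(np.max(np.abs(sol.grad))) if sol.grad is not None else np.nan
    converged = bool(sol.status > 0 and np.isfinite(F_min))
    warnings = []
    if not converged:
        warnings.append(f"optimizer did not converge: {sol.message}")
    from .models import structural_moments

    warnings.extend(structural_moments(spec, theta).warnings)

    df = count_df(spec)
    Delta = stats_jacobian(spec, theta)
    try:
        se, acov = robust_se(Delta, w, stats.Gamma, stats.n)
    except np.linalg.LinAlgError as exc:
        # boundary optimum with a locally deficient Jacobian: the fit value
        # remains comparable, but no standard errors exist there
        warnings.append(str(exc))
        se = np.full(theta.size, np.nan)
    chi2a, df_star, p_val, chi2_raw = adjusted_chi2(F_min, Delta, w, stats.Gamma, stats.n, df)
    indices = fit_indices(chi2a, df, stats.n, baseline=_baseline_chi2(stats, spec), df_star=df_star)
    return FitResult(
        theta=theta,
        param_names=list(spec.param_names),
        se_robust=se,
        F_min=F_min,
        chi2_adj=chi2a,
        df=df,
        df_star=df_star,
        p_value=p_val,
        fit_indices=indices,
        n=stats.n,
        converged=converged,
        gradient_norm=grad_norm,
        n_iter=int(sol.nfev),
        warnings=warnings,
        chi2_unadjusted=chi2_raw,
    )


def robust_se(Delta: np.ndarray, w: np.ndarray, Gamma: np.ndarray, n: int):
    """Sandwich covariance (D'W-1D)^-1 D'W-1 Gamma W-1 D (D'W-1D)^-1 / n.

    Collapses to (D'W-1D)^-1 / n when Gamma = W.  Raises on rank-deficient
    Delta (an identification failure at the optimum).
    """
    Wd = Delta / w[:, None]
    H = Delta.T @ Wd
    sv = np.linalg.svd(H, compute_uv=False)
    if Delta.shape[1] and sv[-1] < 1e-10 * max(sv[0], 1e-300):
        raise np.linalg.LinAlgError(
            "Jacobian of the moment map is rank deficient at the optimum: "
            "model not locally identified"
        )
    Hinv = np.linalg.inv(H)
    M = Wd.T @ Gamma @ Wd
    acov = Hinv @ M @ Hinv / n
    se = np.sqrt(np.maximum(np.diag(acov), 0.0))
    return se, acov


def adjusted_chi2(F_min: float, Delta: np.ndarray, w: np.ndarray, Gamma: np.ndarray, n: int, df: int):
    """Mean-and-variance (Satterthwaite) adjusted test statistic.

    T = n F is asymptotically sum lambda_i chi2_1 with lambda_i the eigenvalues
    of U Gamma, U = W^-1 - W^-1 D (D'W^-1 D)^-1 D'W^-1.  The second-order
    adjustment T_adj = (m1/m2) T with df* = m1^2/m2 matches the first two
    moments of the reference chi-square.
    """
    T_stat = n * F_min
    if df <= 0:
        return 0.0, 0.0, 1.0, T_stat
    Winv_D = Delta / w[:, None]
    H = Delta.T @ Winv_D
    UG = Gamma / w[:, None]
    if Delta.shape[1] > 0:
        # pinv tolerates a boundary-deficient Jacobian (projects on its range)
        K = np.linalg.pinv(H) @ (Winv_D.T @ Gamma)
        UG = UG - Winv_D @ K
    m1 = float(np.trace(UG))
    m2 = float(np.sum(UG * UG.T))
    if m1 <= 0 or m2 <= 0:
        return T_stat, float(df), float(chi2_dist.sf(T_stat, df)), T_stat
    chi2a = T_stat * m1 / m2
    df_star = m1 * m1 / m2
    p = float(chi2_dist.sf(chi2a, df_star))
    return chi2a, df_star, p, T_stat


def _baseline_chi2(stats: SampleStats, spec: ModelSpec):
    """Independence baseline (free thresholds, all correlations zero)."""
    if spec.baseline:
        return None
    base = build_spec(
        Family.SATURATED, "standard", stats.T, stats.C, baseline=True
    )
    fit = dwls_fit(stats, base)
    return fit.chi2_adj, fit.df


def fit_indices(chi2_adj: float, df: int, n: int, baseline=None, df_star: float | None = None) -> dict:
    """CFI, TLI, RMSEA and the Raftery BIC' = chi2 - df ln(n).

    df = 0 returns the perfect-fit conventions (CFI = 1, RMSEA = 0).
    """
    out = {}
    if df <= 0:
        out.update(CFI=1.0, TLI=1.0, RMSEA=0.0, BICp=0.0)
        return out
    d = df_star if df_star else df
    out["RMSEA"] = float(np.sqrt(max(chi2_adj - d, 0.0) / (d * n)))
    out["BICp"] = float(chi2_adj - df * np.log(n))
    if baseline is not None:
        chi2_b, df_b = baseline
        num = max(chi2_adj - d, 0.0)
        den = max(chi2_b - df_b, num, 1e-12)
        out["CFI"] = float(1.0 - num / den)
        if chi2_b / max(df_b, 1e-12) > 1.0:
            tli = ((chi2_b / df_b) - (chi2_adj / d)) / ((chi2_b / df_b) - 1.0)
            out["TLI"] = float(min(tli, 1.0))
        else:
            out["TLI"] = 1.0
    return out
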