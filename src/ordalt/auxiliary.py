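"""Stage-1 measurement (auxiliary) layer for ordinal panels.

Estimates the probit-scale thresholds from univariate margins, polychoric
correlations from bivariate tables by pseudo maximum likelihood with the
thresholds held fixed (Olsson's conditional two-step), and re-expresses the
estimates under the alternative identification rows: free underlying means and
variances identified either through two time-invariant thresholds (alt1, after
Millsap & Yun-Tein / Muthen & Asparouhov) or through thresholds fixed at 0 and
1 (alt2, after Joreskog), plus the binary rows.

Threshold invariance is a testable restriction for C >= 3; the constrained
auxiliary model is fitted by DWLS through :mod:`ordalt.estimation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtri

from .bvn import rectangle_probs
from .models import (
    Family,
    ModelSpec,
    Parameterization,
    SpecError,
    build_spec,
    recover_params,
    _scales_from_std,
)
from .panel import MarginTable, ContingencyTable, OrdinalPanel, crosstab, margins

__all__ = [
    "ThresholdSet",
    "AuxiliaryEstimate",
    "estimate_thresholds",
    "polychoric_rho",
    "polychoric_matrix",
    "build_auxiliary",
    "reparameterize",
    "invariance_ratio_diagnostic",
    "test_threshold_invariance",
]

_RHO_BOUND = 1.0 - 1e-6
_PROB_FLOOR = 1e-12


@dataclass
class ThresholdSet:
    """Per-occasion threshold vectors (tau_1,..,tau_{C-1}); +-inf for empty extremes."""

    tau: np.ndarray  # (T, C-1)
    flags: list[str] = field(default_factory=list)

    def cuts(self, t: int) -> np.ndarray:
        """Full cut vector (-inf, tau_1, .., tau_{C-1}, +inf) at occasion t."""
        return np.concatenate([[-np.inf], self.tau[t], [np.inf]])


@dataclass
class AuxiliaryEstimate:
    """Thresholds, underlying means/SDs and polychoric matrix under one row."""

    thresholds: list[ThresholdSet]  # per variable
    mu_star: np.ndarray  # (V, T)
    sigma_star: np.ndarray  # (V, T) standard deviations
    P_star: np.ndarray  # (VT, VT) correlation (standard row) or covariance
    parameterization: str
    T: int
    C: tuple[int, ...]
    flags: list[str] = field(default_factory=list)
    acov: np.ndarray | None = None
    fit: object | None = None  # FitResult for constrained (invariance) rows

    @property
    def is_correlation(self) -> bool:
        return bool(np.allclose(np.diag(self.P_star), 1.0))

    def to_dict(self) -> dict:
        return {
            "parameterization": self.parameterization,
            "T": self.T,
            "C": list(self.C),
            "thresholds": [ts.tau.tolist() for ts in self.thresholds],
            "mu_star": self.mu_star.tolist(),
            "sigma_star": self.sigma_star.tolist(),
            "P_star": self.P_star.tolist(),
            "flags": self.flags,
        }


def estimate_thresholds(margin: MarginTable) -> ThresholdSet:
    """Thresholds as standard-normal percentiles of the cumulative proportions.

    tau_{c,t} = Phi^{-1}( sum_{r<=c} n_{r,t} / n ).  Empty extreme categories
    give +-inf thresholds (flagged); an empty interior category produces a tied
    threshold, flagged as degenerate — downstream polychoric estimation refuses
    such occasions.
    """
    prop = margin.proportions
    cum = np.cumsum(prop, axis=1)[:, :-1]
    with np.errstate(divide="ignore"):
        tau = ndtri(np.clip(cum, 0.0, 1.0))
    flags = []
    for t in range(tau.shape[0]):
        if np.any(~np.isfinite(tau[t])):
            flags.append(f"occasion {t + 1}: infinite threshold (empty extreme category)")
        interior = tau[t][np.isfinite(tau[t])]
        if interior.size > 1 and np.any(np.diff(interior) <= 0):
            flags.append(f"occasion {t + 1}: tied thresholds (empty interior category)")
    return ThresholdSet(tau=tau, flags=flags)


def _olsson_loglik(table: np.ndarray, cuts_r: np.ndarray, cuts_c: np.ndarray, rho: float) -> float:
    """Olsson log-likelihood sum n_jk log pi_jk(rho), thresholds fixed."""
    p = rectangle_probs(cuts_r, cuts_c, rho)
    return float(np.sum(table * np.log(np.maximum(p, _PROB_FLOOR))))


def polychoric_rho(
    table: ContingencyTable | np.ndarray,
    cuts_row: np.ndarray,
    cuts_col: np.ndarray,
    *,
    tol: float = 1e-8,
) -> tuple[float, list[str]]:
    """Pseudo-ML polychoric correlation with thresholds held fixed.

    Maximizes the Olsson log-likelihood over rho in (-1, 1) via a bounded
    search on the Fisher-z scale.  Returns (rho_hat, flags); boundary solutions
    and degenerate tables are flagged rather than patched.
    """
    cells = table.cells if isinstance(table, ContingencyTable) else np.asarray(table)
    flags: list[str] = []
    nz = np.count_nonzero(cells)
    if nz <= 1:
        flags.append("degenerate table: all mass in one cell")
        return 0.0, flags
    fin_r = np.isfinite(cuts_row[1:-1])
    fin_c = np.isfinite(cuts_col[1:-1])
    if not (np.all(np.diff(cuts_row[1:-1][fin_r]) > 0) and np.all(np.diff(cuts_col[1:-1][fin_c]) > 0)):
        raise ValueError("tied thresholds: polychoric correlation undefined")

    zmax = np.arctanh(_RHO_BOUND)
    res = minimize_scalar(
        lambda z: -_olsson_loglik(cells, cuts_row, cuts_col, np.tanh(z)),
        bounds=(-zmax, zmax),
        method="bounded",
        options={"xatol": tol},
    )
    rho = float(np.tanh(res.x))
    if abs(rho) > 1.0 - 1e-4:
        flags.append("boundary solution |rho| ~ 1")
    return rho, flags


def polychoric_matrix(panel: OrdinalPanel) -> tuple[np.ndarray, list[ThresholdSet], list[str]]:
    """Thresholds for every (variable, occasion) and all pairwise polychorics."""
    flags: list[str] = []
    thresholds = []
    for v in range(panel.V):
        ts = estimate_thresholds(margins(panel, v))
        thresholds.append(ts)
        flags.extend(f"{panel.var_names[v]}: {f}" for f in ts.flags)
    VT = panel.V * panel.T
    R = np.eye(VT)
    cuts = [thresholds[i // panel.T].cuts(i % panel.T) for i in range(VT)]
    for i in range(VT):
        for j in range(i + 1, VT):
            tab = crosstab(panel, i, j)
            r, fl = polychoric_rho(tab, cuts[i], cuts[j])
            R[i, j] = R[j, i] = r
            flags.extend(f"pair ({i},{j}): {f}" for f in fl)
    return R, thresholds, flags


def _standard_estimate(panel: OrdinalPanel) -> AuxiliaryEstimate:
    R, thresholds, flags = polychoric_matrix(panel)
    return AuxiliaryEstimate(
        thresholds=thresholds,
        mu_star=np.zeros((panel.V, panel.T)),
        sigma_star=np.ones((panel.V, panel.T)),
        P_star=R,
        parameterization=Parameterization.STANDARD,
        T=panel.T,
        C=panel.C,
        flags=flags,
    )


def _map_from_standard(aux: AuxiliaryEstimate, target: str, binary_alt1: str = "myt") -> AuxiliaryEstimate:
    """Closed-form one-to-one map from the standard row to a no-invariance row."""
    V, T = len(aux.C), aux.T
    mu = np.zeros((V, T))
    sd = np.ones((V, T))
    taus = []
    for v in range(V):
        pv = _variable_row(target, aux.C[v], binary_alt1)
        mu_v, sd_v, tau_v = _scales_from_std(pv, aux.thresholds[v].tau)
        mu[v], sd[v] = mu_v, sd_v
        taus.append(ThresholdSet(tau=tau_v, flags=list(aux.thresholds[v].flags)))
    d = sd.reshape(-1)
    P = aux.P_star * np.outer(d, d) if target != Parameterization.STANDARD else aux.P_star
    return AuxiliaryEstimate(
        thresholds=taus,
        mu_star=mu,
        sigma_star=sd,
        P_star=P,
        parameterization=target,
        T=T,
        C=aux.C,
        flags=list(aux.flags),
    )


def _variable_row(parameterization: str, C: int, binary_alt1: str) -> str:
    from .models import _resolve_vparam

    return _resolve_vparam(parameterization, C, binary_alt1)


def build_auxiliary(
    panel: OrdinalPanel,
    parameterization: str = Parameterization.STANDARD,
    *,
    binary_alt1: str = "myt",
) -> AuxiliaryEstimate:
    """Estimate the auxiliary model under a named identification row.

    No-invariance rows (standard, alt1, alt2 and binary analogues) are
    just-identified: the estimate is the closed-form reparameterization of the
    standard two-step estimate.  Invariance rows (alt1_inv / alt2_inv) impose a
    real restriction and are obtained from a constrained DWLS fit.
    """
    P = Parameterization
    if parameterization in (P.ALT2, P.ALT2_INV) and all(c == 2 for c in panel.C):
        raise SpecError(
            "alt2 thresholds (0/1) need C >= 3; for binary data use the binary rows"
        )
    std = _standard_estimate(panel)
    if parameterization == P.STANDARD:
        return std
    if parameterization in (P.ALT1_INV, P.ALT2_INV):
        return _constrained_auxiliary(panel, parameterization, binary_alt1, std)
    return _map_from_standard(std, parameterization, binary_alt1)


def reparameterize(aux: AuxiliaryEstimate, target: str, *, binary_alt1: str = "myt") -> AuxiliaryEstimate:
    """Map between no-invariance rows; the round trip is the identity.

    Invariance rows are restrictions, not reparameterizations, and are refused.
    """
    P = Parameterization
    no_inv = (P.STANDARD, P.ALT1, P.ALT2, P.BIN_MYT, P.BIN_MM, P.BIN_JORESKOG)
    if aux.parameterization not in no_inv or target not in no_inv:
        raise SpecError(
            "reparameterize maps between just-identified rows only; threshold "
            "invariance is a restriction — use test_threshold_invariance"
        )
    # pull back to standard: standardize thresholds and correlation matrix
    V, T = len(aux.C), aux.T
    d = aux.sigma_star.reshape(-1)
    R = aux.P_star / np.outer(d, d)
    std_taus = []
    for v in range(V):
        std_taus.append(
            ThresholdSet(
                tau=(aux.thresholds[v].tau - aux.mu_star[v][:, None]) / aux.sigma_star[v][:, None],
                flags=list(aux.thresholds[v].flags),
            )
        )
    std = AuxiliaryEstimate(
        thresholds=std_taus,
        mu_star=np.zeros((V, T)),
        sigma_star=np.ones((V, T)),
        P_star=R,
        parameterization=P.STANDARD,
        T=T,
        C=aux.C,
        flags=list(aux.flags),
    )
    if target == P.STANDARD:
        return std
    return _map_from_standard(std, target, binary_alt1)


def invariance_ratio_diagnostic(aux_standard: AuxiliaryEstimate, *, tol: float = 0.05) -> dict:
    """Threshold-difference ratios across occasion pairs, per variable.

    Under invariant thresholds, (tau_{c,t} - tau_{c',t}) / (tau_{c,t'} -
    tau_{c',t'}) is the same for every threshold pair (c, c') — it equals the
    SD ratio sigma*_{t'} / sigma*_t.  A spread across threshold pairs larger
    than ``tol`` (relative) flags non-invariance at that occasion pair.
    """
    if aux_standard.parameterization != Parameterization.STANDARD:
        raise SpecError("diagnostic requires the standard-parameterization estimate")
    out = {}
    for v, C in enumerate(aux_standard.C):
        if C < 3:
            raise SpecError(
                "ratio diagnostic undefined for binary variables (single threshold)"
            )
        tau = aux_standard.thresholds[v].tau
        T, K = tau.shape
        pairs = [(c, cp) for c in range(K) for cp in range(c + 1, K)]
        table = {}
        flags = []
        for t in range(T):
            for tp in range(t + 1, T):
                ratios = np.array(
                    [(tau[t, c2] - tau[t, c1]) / (tau[tp, c2] - tau[tp, c1]) for c1, c2 in pairs]
                )
                table[(t, tp)] = ratios
                spread = np.max(ratios) - np.min(ratios)
                if spread > tol * max(np.abs(ratios).max(), 1e-12):
                    flags.append((t, tp))
        out[v] = {
            "threshold_pairs": pairs,
            "ratios": table,
            "inconsistent_occasion_pairs": flags,
        }
    return out


def invariance_spec(panel_T: int, panel_C, parameterization: str, binary_alt1: str = "myt") -> ModelSpec:
    """Constrained auxiliary ModelSpec (saturated correlations, invariant thresholds)."""
    return build_spec(
        Family.SATURATED,
        parameterization,
        panel_T,
        panel_C,
        binary_alt1=binary_alt1,
    )


def test_threshold_invariance(
    panel: OrdinalPanel,
    parameterization: str = Parameterization.ALT1_INV,
    *,
    binary_alt1: str = "myt",
):
    """DWLS fit of the auxiliary model with every threshold held time-invariant.

    Returns a FitResult with the mean-and-variance-adjusted chi-square; df is
    sum_v [T (C_v - 1) - (C_v - 1) - 2(T - 1)] under either alternative row
    (the two rows are equivalent and give identical fit).  Binary-only panels
    are refused: with a single threshold, invariance is needed for the model to
    be just-identified and is not testable.
    """
    if parameterization not in (Parameterization.ALT1_INV, Parameterization.ALT2_INV):
        raise SpecError("invariance test uses alt1_inv or alt2_inv")
    if all(c == 2 for c in panel.C):
        raise SpecError(
            "binary panel: threshold invariance is required for identification "
            "and cannot be tested"
        )
    from .estimation import compute_sample_stats, dwls_fit

    spec = invariance_spec(panel.T, panel.C, parameterization, binary_alt1)
    stats = compute_sample_stats(panel)
    return dwls_fit(stats, spec)


def _constrained_auxiliary(
    panel: OrdinalPanel, parameterization: str, binary_alt1: str, std: AuxiliaryEstimate
) -> AuxiliaryEstimate:
    from .estimation import compute_sample_stats, dwls_fit

    spec = invariance_spec(panel.T, panel.C, parameterization, binary_alt1)
    stats = compute_sample_stats(panel)
    fit = dwls_fit(stats, spec)
    from .models import structural_moments

    mom = structural_moments(spec, fit.theta)
    V, T = panel.V, panel.T
    sd = np.sqrt(np.diag(mom.sigma_star)).reshape(V, T)
    return AuxiliaryEstimate(
        thresholds=[ThresholdSet(tau=mom.tau[v]) for v in range(V)],
        mu_star=mom.mu_star.reshape(V, T),
        sigma_star=sd,
        P_star=mom.sigma_star,
        parameterization=parameterization,
        T=T,
        C=panel.C,
        flags=list(std.flags),
        fit=fit,
    )
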