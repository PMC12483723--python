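"""Structural layers for ordinal panel SEM and their identification rows.

The data only identify the *standardized* scale of the underlying normal
variables: probit-scale thresholds and polychoric correlations.  Every
parameterization (standard delta/theta, the Millsap--Yun-Tein style "alt1"
rows, the Joreskog style "alt2" rows, and the binary variants) is therefore
expressed as a model-side map

    theta  ->  (mu*(theta), Sigma*(theta), tau_model(theta))
           ->  standardized thresholds (tau - mu*)/sigma*  and  correlations,

fitted against the same sample-statistic vector.  Equivalent specifications
are exactly those whose standardized-moment manifolds coincide; degrees of
freedom are uniformly

    df = sum_v T (C_v - 1) + VT (VT - 1)/2 - (# free parameters).

Families
--------
SATURATED   auxiliary (measurement) model only: free correlation matrix plus
            per-occasion means/variances/thresholds under the chosen
            identification row; used for threshold-invariance tests.
LGM         linear latent growth: y*_t = alpha + (t-1) beta + eps_t.
AR1         first-order autoregression with predetermined first occasion:
            y*_t = nu_t + rho_t y*_{t-1} + eps_t.
ALT         autoregressive latent trajectory (predetermined y*_1):
            y*_t = rho_t y*_{t-1} + alpha + (t-1) beta + eps_t, t >= 2;
            with V >= 2 series it becomes the multivariate ALT with
            cross-lagged coefficients and concomitant error covariances.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Family",
    "Parameterization",
    "ModelSpec",
    "Moments",
    "build_spec",
    "structural_moments",
    "model_stats",
    "stat_inventory",
    "stat_labels",
    "reduced_form_moments",
    "implied_moments_lgm",
    "implied_moments_ar1",
    "implied_moments_alt",
    "implied_moments_malt",
    "count_df",
    "check_identification",
    "sample_admissible_theta",
    "recover_params",
    "SpecError",
]


class SpecError(ValueError):
    """Inadmissible model specification."""


class Family:
    SATURATED = "saturated"
    LGM = "lgm"
    AR1 = "ar1"
    ALT = "alt"

    ALL = (SATURATED, LGM, AR1, ALT)


class Parameterization:
    """Identification rows of the auxiliary model.

    Ordinal rows (C >= 3): STANDARD fixes mu*_t = 0, sigma*_t = 1 on every
    occasion with free time-varying thresholds.  ALT1 fixes (mu*_1, sigma*_1) =
    (0, 1), frees later means/variances and holds the first two thresholds
    time-invariant; ALT1_INV holds *all* thresholds invariant.  ALT2 fixes the
    first two thresholds to 0 and 1 on every occasion, freeing all means and
    variances; ALT2_INV additionally holds the remaining thresholds invariant.

    Binary rows (C = 2): BIN_MYT frees the means (except occasion 1) with unit
    variances and an invariant threshold; BIN_MM frees the variances (except
    occasion 1) with zero means and an invariant threshold; BIN_JORESKOG fixes
    the threshold to zero with unit variances and free means.
    """

    STANDARD = "standard"
    ALT1 = "alt1"
    ALT1_INV = "alt1_inv"
    ALT2 = "alt2"
    ALT2_INV = "alt2_inv"
    BIN_MYT = "bin_myt"
    BIN_MM = "bin_mm"
    BIN_JORESKOG = "bin_joreskog"

    ORDINAL = (STANDARD, ALT1, ALT1_INV, ALT2, ALT2_INV)
    BINARY = (STANDARD, BIN_MYT, BIN_MM, BIN_JORESKOG)
    INVARIANT = (ALT1_INV, ALT2_INV, BIN_MYT, BIN_MM, BIN_JORESKOG)


class _ParamArray:
    """Array whose elements are either fixed numbers or references to free slots."""

    def __init__(self, shape):
        self.fixed = np.zeros(shape, dtype=float)
        self.map = np.full(shape, -1, dtype=np.int64)

    def resolve(self, theta: np.ndarray) -> np.ndarray:
        out = self.fixed.copy()
        m = self.map >= 0
        if np.any(m):
            out[m] = theta[self.map[m]]
        return out


class _Builder:
    def __init__(self):
        self.names: list[str] = []
        self.index: dict[str, int] = {}

    def slot(self, name: str) -> int:
        if name not in self.index:
            self.index[name] = len(self.names)
            self.names.append(name)
        return self.index[name]


@dataclass
class ModelSpec:
    """A structural family plus one identification row, compiled to parameter maps."""

    family: str
    parameterization: str
    placement: str  # "delta" | "theta" (variance-constraint placement)
    T: int
    C: tuple[int, ...]
    var_names: tuple[str, ...]
    vparam: tuple[str, ...]  # per-variable resolved row (binary rows substituted)
    stationary: bool
    cross_lagged: bool
    concomitant: bool
    baseline: bool
    param_names: list[str] = field(default_factory=list)
    arrays: dict = field(default_factory=dict)

    @property
    def V(self) -> int:
        return len(self.C)

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    @property
    def n_stats(self) -> int:
        VT = self.V * self.T
        return sum(self.T * (c - 1) for c in self.C) + VT * (VT - 1) // 2

    def describe(self) -> str:
        return (
            f"{self.family}/{self.parameterization}/{self.placement} "
            f"T={self.T} C={self.C} free={self.n_free} df={count_df(self)}"
        )


@dataclass
class Moments:
    """Model-implied moments of the underlying variables plus model thresholds."""

    mu_star: np.ndarray  # (VT,)
    sigma_star: np.ndarray  # (VT, VT)
    tau: list[np.ndarray]  # per variable, (T, C_v - 1) on the model scale
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Spec construction
# ---------------------------------------------------------------------------


def _resolve_vparam(parameterization: str, C: int, binary_alt1: str) -> str:
    P = Parameterization
    if C >= 3:
        if parameterization in P.ORDINAL:
            return parameterization
        raise SpecError(
            f"parameterization {parameterization!r} is a binary row; variable has C={C}"
        )
    # binary variable
    if parameterization == P.STANDARD:
        return P.STANDARD
    if parameterization in (P.ALT1, P.ALT1_INV):
        return P.BIN_MYT if binary_alt1 == "myt" else P.BIN_MM
    if parameterization in (P.ALT2, P.ALT2_INV):
        return P.BIN_JORESKOG
    if parameterization in (P.BIN_MYT, P.BIN_MM, P.BIN_JORESKOG):
        return parameterization
    raise SpecError(f"unknown parameterization {parameterization!r}")


def build_spec(
    family: str,
    parameterization: str,
    T: int,
    C: int | Sequence[int],
    *,
    placement: str | None = None,
    stationary: bool = False,
    cross_lagged: bool | None = None,
    concomitant: bool | None = None,
    binary_alt1: str = "myt",
    var_names: Sequence[str] | None = None,
    baseline: bool = False,
) -> ModelSpec:
    """Compile a (family, identification row) pair into a :class:`ModelSpec`.

    ``placement`` selects where the unit-variance constraint sits for rows that
    admit both versions of the linear growth model: ``"delta"`` constrains the
    underlying-variable variances, ``"theta"`` the error variances.  For AR1 and
    ALT only the theta placement is supported, because with autoregressive
    components the underlying-variable variances are nonlinear functions of the
    coefficients and cannot be directly constrained.
    """
    P = Parameterization
    C_list = tuple([int(C)] if np.isscalar(C) else [int(c) for c in C])
    V = len(C_list)
    if family not in Family.ALL:
        raise SpecError(f"unknown family {family!r}")
    if T < 2:
        raise SpecError("at least two occasions required")
    if family in (Family.LGM, Family.AR1) and V != 1:
        raise SpecError(f"{family} supports a single series; use family='alt' for V>1")
    if parameterization in (P.ALT2, P.ALT2_INV) and all(c == 2 for c in C_list):
        raise SpecError(
            "the alt2 (Joreskog) threshold constraints need C >= 3; with binary "
            "data use the binary rows (bin_myt, bin_mm, bin_joreskog)"
        )
    if placement is None:
        placement = "theta" if family in (Family.AR1, Family.ALT) else "delta"
    if placement not in ("delta", "theta"):
        raise SpecError("placement must be 'delta' or 'theta'")
    if family in (Family.AR1, Family.ALT) and placement != "theta":
        raise SpecError(f"{family} supports only the theta placement")
    if cross_lagged is None:
        cross_lagged = V > 1
    if concomitant is None:
        concomitant = V > 1

    vparam = tuple(_resolve_vparam(parameterization, c, binary_alt1) for c in C_list)
    names = tuple(var_names) if var_names else tuple(f"y{v}" for v in range(V))

    b = _Builder()
    arrays: dict = {}

    # --- thresholds ---------------------------------------------------------
    taus = []
    for v, (c_v, pv) in enumerate(zip(C_list, vparam)):
        pa = _ParamArray((T, c_v - 1))
        for t in range(T):
            for c in range(c_v - 1):
                if pv == P.STANDARD:
                    pa.map[t, c] = b.slot(f"tau[{v}][t{t}][{c}]")
                elif pv == P.ALT1:
                    if c <= 1:
                        pa.map[t, c] = b.slot(f"tau[{v}][{c}]")
                    elif t == 0:
                        pa.map[t, c] = b.slot(f"tau[{v}][t0][{c}]")
                    else:
                        pa.map[t, c] = b.slot(f"tau[{v}][t{t}][{c}]")
                elif pv == P.ALT1_INV:
                    pa.map[t, c] = b.slot(f"tau[{v}][{c}]")
                elif pv == P.ALT2:
                    if c == 0:
                        pa.fixed[t, c] = 0.0
                    elif c == 1:
                        pa.fixed[t, c] = 1.0
                    else:
                        pa.map[t, c] = b.slot(f"tau[{v}][t{t}][{c}]")
                elif pv == P.ALT2_INV:
                    if c == 0:
                        pa.fixed[t, c] = 0.0
                    elif c == 1:
                        pa.fixed[t, c] = 1.0
                    else:
                        pa.map[t, c] = b.slot(f"tau[{v}][{c}]")
                elif pv in (P.BIN_MYT, P.BIN_MM):
                    pa.map[t, c] = b.slot(f"tau[{v}][{c}]")
                elif pv == P.BIN_JORESKOG:
                    pa.fixed[t, c] = 0.0
                else:  # pragma: no cover
                    raise SpecError(pv)
        taus.append(pa)
    arrays["tau"] = taus

    # --- per-family structural parameters ----------------------------------
    if family == Family.SATURATED:
        mu = _ParamArray((V, T))
        sig2 = _ParamArray((V, T))
        sig2.fixed[:] = 1.0
        for v, pv in enumerate(vparam):
            for t in range(T):
                free_mu, free_s2 = _aux_free_mean_var(pv, t)
                if free_mu:
                    mu.map[v, t] = b.slot(f"mu[{v}][{t}]")
                if free_s2:
                    sig2.map[v, t] = b.slot(f"sigma2[{v}][{t}]")
        VT = V * T
        rr = _ParamArray((VT, VT))
        if not baseline:
            for i in range(VT):
                for j in range(i + 1, VT):
                    rr.map[i, j] = b.slot(f"r[{i}][{j}]")
        arrays.update(mu=mu, sigma2=sig2, rcorr=rr)

    elif family == Family.LGM:
        pv = vparam[0]
        mu_ab = _ParamArray((2,))
        free_a, free_bq = _lgm_free_growth_means(pv)
        if free_a:
            mu_ab.map[0] = b.slot("mu_alpha[0]")
        if free_bq:
            mu_ab.map[1] = b.slot("mu_beta[0]")
        psi = _sym_param(b, 2, "psi[0]", free=True)
        vp = _ParamArray((T,))
        vp.fixed[:] = 1.0
        free_from = _lgm_variance_free_from(pv)
        if free_from is not None:
            for t in range(T):
                if t >= free_from:
                    vp.map[t] = b.slot(f"{placement}[0][{t}]")
        arrays.update(mu_ab=mu_ab, psi=psi, vplace=vp)

    elif family == Family.AR1:
        pv = vparam[0]
        m1 = _ParamArray((1,))
        p11 = _ParamArray((1, 1))
        p11.fixed[0, 0] = 1.0
        nu = _ParamArray((T - 1,))
        th = _ParamArray((T - 1,))
        th.fixed[:] = 1.0
        rho = _ParamArray((T - 1,))
        free_mean, free_var = _ar1_free(pv)
        if free_mean:
            if pv in (P.ALT2, P.ALT2_INV, P.BIN_JORESKOG):
                m1.map[0] = b.slot("m1[0]")
            for t in range(T - 1):
                nu.map[t] = b.slot(f"nu[0][{t + 1}]")
        if free_var:
            if pv in (P.ALT2, P.ALT2_INV):
                p11.map[0, 0] = b.slot("p11[0][0]")
            for t in range(T - 1):
                th.map[t] = b.slot(f"theta[0][{t + 1}]")
        for t in range(T - 1):
            key = "rho[0]" if stationary else f"rho[0][{t + 1}]"
            rho.map[t] = b.slot(key)
        arrays.update(m1=m1, p11=p11, nu=nu, theta=th, rho=rho)

    elif family == Family.ALT:
        G = 2 * V
        m1 = _ParamArray((V,))
        p11 = _ParamArray((V, V))
        p1g = _ParamArray((V, G))
        mu_ab = _ParamArray((V, 2))
        psi = _sym_param(b, G, "psi", free=True)
        rho = _ParamArray((V, T - 1))
        cross = _ParamArray((V, V, T - 1))
        th = _ParamArray((V, T - 1))
        conc = _ParamArray((V, V, T - 1))
        for v, pv in enumerate(vparam):
            fm1, fp11, fma, fmb, fth = _alt_free(pv)
            p11.fixed[v, v] = 1.0
            th.fixed[v, :] = 1.0
            if fm1:
                m1.map[v] = b.slot(f"m1[{v}]")
            if fp11:
                p11.map[v, v] = b.slot(f"p11[{v}][{v}]")
            if fma:
                mu_ab.map[v, 0] = b.slot(f"mu_alpha[{v}]")
            if fmb:
                mu_ab.map[v, 1] = b.slot(f"mu_beta[{v}]")
            if fth:
                for t in range(T - 1):
                    th.map[v, t] = b.slot(f"theta[{v}][{t + 1}]")
            for t in range(T - 1):
                key = f"rho[{v}]" if stationary else f"rho[{v}][{t + 1}]"
                rho.map[v, t] = b.slot(key)
            for g in range(G):
                p1g.map[v, g] = b.slot(f"p1g[{v}][{g}]")
        for a in range(V):
            for bb in range(a + 1, V):
                p11.map[a, bb] = p11.map[bb, a] = b.slot(f"p11[{a}][{bb}]")
        if cross_lagged:
            for a in range(V):
                for bb in range(V):
                    if a == bb:
                        continue
                    for t in range(T - 1):
                        key = (
                            f"cross[{a}][{bb}]"
                            if stationary
                            else f"cross[{a}][{bb}][{t + 1}]"
                        )
                        cross.map[a, bb, t] = b.slot(key)
        if concomitant:
            for a in range(V):
                for bb in range(a + 1, V):
                    for t in range(T - 1):
                        s = b.slot(f"conc[{a}][{bb}][{t + 1}]")
                        conc.map[a, bb, t] = conc.map[bb, a, t] = s
        arrays.update(
            m1=m1, p11=p11, p1g=p1g, mu_ab=mu_ab, psi=psi, rho=rho, cross=cross,
            theta=th, conc=conc,
        )

    return ModelSpec(
        family=family,
        parameterization=parameterization,
        placement=placement,
        T=T,
        C=C_list,
        var_names=names,
        vparam=vparam,
        stationary=stationary,
        cross_lagged=cross_lagged,
        concomitant=concomitant,
        baseline=baseline,
        param_names=b.names,
        arrays=arrays,
    )


def _sym_param(b: _Builder, k: int, prefix: str, free: bool) -> _ParamArray:
    pa = _ParamArray((k, k))
    if free:
        for i in range(k):
            for j in range(i + 1):
                pa.map[i, j] = pa.map[j, i] = b.slot(f"{prefix}[{i}][{j}]")
    return pa


def _aux_free_mean_var(pv: str, t: int) -> tuple[bool, bool]:
    P = Parameterization
    if pv == P.STANDARD:
        return False, False
    if pv in (P.ALT1, P.ALT1_INV):
        return t > 0, t > 0
    if pv in (P.ALT2, P.ALT2_INV):
        return True, True
    if pv == P.BIN_MYT:
        return t > 0, False
    if pv == P.BIN_MM:
        return False, t > 0
    if pv == P.BIN_JORESKOG:
        return True, False
    raise SpecError(pv)


def _lgm_free_growth_means(pv: str) -> tuple[bool, bool]:
    P = Parameterization
    if pv in (P.STANDARD, P.BIN_MM):
        return False, False
    if pv in (P.ALT1, P.ALT1_INV, P.BIN_MYT):
        return False, True
    if pv in (P.ALT2, P.ALT2_INV, P.BIN_JORESKOG):
        return True, True
    raise SpecError(pv)


def _lgm_variance_free_from(pv: str):
    """First occasion index (0-based) from which the placed variance is free."""
    P = Parameterization
    if pv in (P.STANDARD, P.BIN_MYT, P.BIN_JORESKOG):
        return None  # all fixed at 1
    if pv in (P.ALT1, P.ALT1_INV, P.BIN_MM):
        return 1  # first occasion fixed at 1 (Models C / D)
    if pv in (P.ALT2, P.ALT2_INV):
        return 0  # all free; scale set by the 0/1 thresholds
    raise SpecError(pv)


def _ar1_free(pv: str) -> tuple[bool, bool]:
    """(means free, variances free) for the AR(1) rows."""
    P = Parameterization
    if pv == P.STANDARD:
        return False, False
    if pv in (P.ALT1, P.ALT1_INV):
        return True, True
    if pv in (P.ALT2, P.ALT2_INV):
        return True, True
    if pv == P.BIN_MYT:
        return True, False
    if pv == P.BIN_MM:
        return False, True
    if pv == P.BIN_JORESKOG:
        return True, False
    raise SpecError(pv)


def _alt_free(pv: str):
    """(m1, p11, mu_alpha, mu_beta, theta) freedom for the ALT rows."""
    P = Parameterization
    if pv == P.STANDARD:
        return False, False, False, False, False
    if pv in (P.ALT1, P.ALT1_INV):
        return False, False, True, True, True
    if pv in (P.ALT2, P.ALT2_INV):
        return True, True, True, True, True
    if pv == P.BIN_MYT:
        return False, False, True, True, False
    if pv == P.BIN_MM:
        return False, False, False, False, True
    if pv == P.BIN_JORESKOG:
        return True, False, True, True, False
    raise SpecError(pv)


# ---------------------------------------------------------------------------
# Implied moments
# ---------------------------------------------------------------------------


def structural_moments(spec: ModelSpec, theta: np.ndarray) -> Moments:
    """Model-implied (mu*, Sigma*) of the VT underlying variables + thresholds."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_free,):
        raise ValueError(f"theta must have length {spec.n_free}, got {theta.shape}")
    T, V = spec.T, spec.V
    A = spec.arrays
    tau = [pa.resolve(theta) for pa in A["tau"]]
    warn: list[str] = []

    if spec.family == Family.SATURATED:
        mu = A["mu"].resolve(theta).reshape(-1)
        sig2 = A["sigma2"].resolve(theta).reshape(-1)
        rr = A["rcorr"].resolve(theta)
        R = rr + rr.T + np.eye(V * T)
        d = np.sqrt(np.maximum(sig2, 1e-12))
        Sigma = R * np.outer(d, d)

    elif spec.family == Family.LGM:
        lam = np.column_stack([np.ones(T), np.arange(T, dtype=float)])
        mu = lam @ A["mu_ab"].resolve(theta)
        S = lam @ A["psi"].resolve(theta) @ lam.T
        vp = A["vplace"].resolve(theta)
        if spec.placement == "delta":
            resid = vp - np.diag(S)
            if np.any(resid <= 0):
                warn.append("negative error-variance remainder under delta placement")
            Sigma = S - np.diag(np.diag(S)) + np.diag(vp)
        else:
            if np.any(vp <= 0):
                warn.append("nonpositive error variance")
            Sigma = S + np.diag(vp)

    elif spec.family == Family.AR1:
        m1 = A["m1"].resolve(theta)[0]
        p11 = A["p11"].resolve(theta)[0, 0]
        nu = A["nu"].resolve(theta)
        th = A["theta"].resolve(theta)
        rho = A["rho"].resolve(theta)
        mu = np.empty(T)
        Sigma = np.zeros((T, T))
        mu[0] = m1
        Sigma[0, 0] = p11
        for t in range(1, T):
            r = rho[t - 1]
            mu[t] = nu[t - 1] + r * mu[t - 1]
            Sigma[t, :t] = r * Sigma[t - 1, :t]
            Sigma[:t, t] = Sigma[t, :t]
            Sigma[t, t] = r * r * Sigma[t - 1, t - 1] + th[t - 1]
        if np.any(th <= 0) or p11 <= 0:
            warn.append("nonpositive variance parameter")

    elif spec.family == Family.ALT:
        mu, Sigma, w = _alt_moments(spec, theta)
        warn.extend(w)
    else:  # pragma: no cover
        raise SpecError(spec.family)

    return Moments(mu_star=np.atleast_1d(mu), sigma_star=np.atleast_2d(Sigma), tau=tau, warnings=warn)


def _alt_moments(spec: ModelSpec, theta: np.ndarray):
    """Forward recursion over occasions for the (multivariate) ALT model."""
    T, V = spec.T, spec.V
    A = spec.arrays
    G = 2 * V
    m1 = A["m1"].resolve(theta)
    p11 = A["p11"].resolve(theta)
    p1g = A["p1g"].resolve(theta)
    mu_ab = A["mu_ab"].resolve(theta)  # (V, 2)
    psi = A["psi"].resolve(theta)  # (G, G)
    rho = A["rho"].resolve(theta)  # (V, T-1)
    cross = A["cross"].resolve(theta)  # (V, V, T-1)
    th = A["theta"].resolve(theta)  # (V, T-1)
    conc = A["conc"].resolve(theta)  # (V, V, T-1)

    warn = []
    n_eta = V * T + G
    mu = np.zeros(n_eta)
    S = np.zeros((n_eta, n_eta))
    y_idx = lambda v, t: v * T + t  # noqa: E731
    g0 = V * T

    # exogenous block: predetermined first occasions + growth factors
    first = [y_idx(v, 0) for v in range(V)]
    growth = list(range(g0, g0 + G))
    mu[first] = m1
    mu[growth] = mu_ab.reshape(-1)  # (alpha_0, beta_0, alpha_1, beta_1, ...)
    S[np.ix_(first, first)] = p11
    S[np.ix_(first, growth)] = p1g
    S[np.ix_(growth, first)] = p1g.T
    S[np.ix_(growth, growth)] = psi
    exo = S[np.ix_(first + growth, first + growth)]
    if np.min(np.linalg.eigvalsh((exo + exo.T) / 2)) < -1e-10:
        warn.append("exogenous covariance block not positive semidefinite")

    for t in range(1, T):
        prev = [y_idx(v, t - 1) for v in range(V)]
        cur = [y_idx(v, t) for v in range(V)]
        W = np.zeros((V, V + G))
        for a in range(V):
            W[a, a] = rho[a, t - 1]
            for bb in range(V):
                if bb != a:
                    W[a, bb] = cross[a, bb, t - 1]
            W[a, V + 2 * a] = 1.0  # alpha loading
            W[a, V + 2 * a + 1] = float(t)  # slope loading t (= occasion-1)
        R = prev + growth
        Theta_t = np.diag(th[:, t - 1]) + (conc[:, :, t - 1] - np.diag(np.diag(conc[:, :, t - 1])))
        mu[cur] = W @ mu[R]
        cov_rows = W @ S[R, :]
        S[cur, :] = cov_rows
        S[:, cur] = cov_rows.T
        S[np.ix_(cur, cur)] = W @ S[np.ix_(R, R)] @ W.T + Theta_t
    if np.any(th <= 0) or np.any(np.diag(p11) <= 0):
        warn.append("nonpositive variance parameter")
    yy = [y_idx(v, t) for v in range(V) for t in range(T)]
    return mu[yy], S[np.ix_(yy, yy)], warn


# ---------------------------------------------------------------------------
# Standardized statistics
# ---------------------------------------------------------------------------


def stat_inventory(T: int, C: Sequence[int]):
    """Ordered inventory: thresholds (v, t, c) then correlations (i < j)."""
    inv = [("tau", v, t, c) for v, cv in enumerate(C) for t in range(T) for c in range(cv - 1)]
    VT = len(C) * T
    inv += [("r", i, j) for i in range(VT) for j in range(i + 1, VT)]
    return inv


def stat_labels(spec_or_T, C: Sequence[int] | None = None) -> list[str]:
    if isinstance(spec_or_T, ModelSpec):
        T, C = spec_or_T.T, spec_or_T.C
    else:
        T = spec_or_T
    out = []
    for kind, *rest in stat_inventory(T, C):
        if kind == "tau":
            v, t, c = rest
            out.append(f"tau[{v}][t{t}][{c}]")
        else:
            i, j = rest
            out.append(f"r[{i}][{j}]")
    return out


def model_stats(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """Standardized implied statistics, aligned with :func:`stat_inventory`."""
    mom = structural_moments(spec, theta)
    T, V = spec.T, spec.V
    d = np.sqrt(np.maximum(np.diag(mom.sigma_star), 1e-12))
    parts = []
    for v in range(V):
        mu_v = mom.mu_star[v * T : (v + 1) * T]
        d_v = d[v * T : (v + 1) * T]
        parts.append(((mom.tau[v] - mu_v[:, None]) / d_v[:, None]).reshape(-1))
    R = mom.sigma_star / np.outer(d, d)
    iu = np.triu_indices(V * T, k=1)
    parts.append(R[iu])
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# Generic reduced-form oracle
# ---------------------------------------------------------------------------


def reduced_form_moments(spec: ModelSpec, theta: np.ndarray):
    """Independent evaluator mu = Gsel (I-B)^-1 nu, Sigma = Gsel (I-B)^-1 Psi (I-B)^-T Gsel'.

    Builds the full coefficient matrices of the latent system explicitly and
    inverts; used as the algebra oracle for the recursion-based implementations.
    Supports LGM (theta placement), AR1 and (multivariate) ALT.
    """
    T, V = spec.T, spec.V
    A = spec.arrays
    theta = np.asarray(theta, dtype=float)

    if spec.family == Family.LGM:
        if spec.placement != "theta":
            # express the delta placement through its implied error variances
            mom = structural_moments(spec, theta)
            return mom.mu_star, mom.sigma_star
        n = T + 2
        B = np.zeros((n, n))
        nu = np.zeros(n)
        Psi = np.zeros((n, n))
        B[:T, T] = 1.0
        B[:T, T + 1] = np.arange(T, dtype=float)
        nu[T:] = A["mu_ab"].resolve(theta)
        Psi[:T, :T] = np.diag(A["vplace"].resolve(theta))
        Psi[T:, T:] = A["psi"].resolve(theta)
        sel = np.arange(T)
    elif spec.family == Family.AR1:
        n = T
        B = np.zeros((n, n))
        nu = np.zeros(n)
        Psi = np.zeros((n, n))
        rho = A["rho"].resolve(theta)
        for t in range(1, T):
            B[t, t - 1] = rho[t - 1]
        nu[0] = A["m1"].resolve(theta)[0]
        nu[1:] = A["nu"].resolve(theta)
        Psi[0, 0] = A["p11"].resolve(theta)[0, 0]
        Psi[1:, 1:] = np.diag(A["theta"].resolve(theta))
        sel = np.arange(T)
    elif spec.family == Family.ALT:
        G = 2 * V
        n = V * T + G
        B = np.zeros((n, n))
        nu = np.zeros(n)
        Psi = np.zeros((n, n))
        rho = A["rho"].resolve(theta)
        cross = A["cross"].resolve(theta)
        th = A["theta"].resolve(theta)
        conc = A["conc"].resolve(theta)
        yi = lambda v, t: v * T + t  # noqa: E731
        g0 = V * T
        for t in range(1, T):
            for a in range(V):
                B[yi(a, t), yi(a, t - 1)] = rho[a, t - 1]
                for bb in range(V):
                    if bb != a:
                        B[yi(a, t), yi(bb, t - 1)] = cross[a, bb, t - 1]
                B[yi(a, t), g0 + 2 * a] = 1.0
                B[yi(a, t), g0 + 2 * a + 1] = float(t)
        nu[[yi(v, 0) for v in range(V)]] = A["m1"].resolve(theta)
        nu[g0:] = A["mu_ab"].resolve(theta).reshape(-1)
        first = [yi(v, 0) for v in range(V)]
        Psi[np.ix_(first, first)] = A["p11"].resolve(theta)
        p1g = A["p1g"].resolve(theta)
        Psi[np.ix_(first, range(g0, n))] = p1g
        Psi[np.ix_(range(g0, n), first)] = p1g.T
        Psi[g0:, g0:] = A["psi"].resolve(theta)
        for t in range(1, T):
            for a in range(V):
                Psi[yi(a, t), yi(a, t)] = th[a, t - 1]
                for bb in range(a + 1, V):
                    Psi[yi(a, t), yi(bb, t)] = Psi[yi(bb, t), yi(a, t)] = conc[a, bb, t - 1]
        sel = np.array([yi(v, t) for v in range(V) for t in range(T)])
    else:
        raise SpecError(f"reduced form undefined for family {spec.family!r}")

    IB = np.linalg.inv(np.eye(n) - B)
    mu_eta = IB @ nu
    Sigma_eta = IB @ Psi @ IB.T
    return mu_eta[sel], Sigma_eta[np.ix_(sel, sel)]


def implied_moments_lgm(spec: ModelSpec, theta: np.ndarray) -> Moments:
    if spec.family != Family.LGM:
        raise SpecError("spec is not a linear growth model")
    return structural_moments(spec, theta)


def implied_moments_ar1(spec: ModelSpec, theta: np.ndarray) -> Moments:
    if spec.family != Family.AR1:
        raise SpecError("spec is not a first-order autoregressive model")
    return structural_moments(spec, theta)


def implied_moments_alt(spec: ModelSpec, theta: np.ndarray) -> Moments:
    if spec.family != Family.ALT or spec.V != 1:
        raise SpecError("spec is not a univariate ALT model")
    return structural_moments(spec, theta)


def implied_moments_malt(spec: ModelSpec, theta: np.ndarray) -> Moments:
    if spec.family != Family.ALT or spec.V < 2:
        raise SpecError("spec is not a multivariate ALT model")
    return structural_moments(spec, theta)


# ---------------------------------------------------------------------------
# Degrees of freedom and identification
# ---------------------------------------------------------------------------


def count_df(spec: ModelSpec) -> int:
    """df = [sum_v T(C_v - 1) + VT(VT-1)/2] - (# free parameters)."""
    return spec.n_stats - spec.n_free


def stats_jacobian(spec: ModelSpec, theta: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the standardized statistics map."""
    theta = np.asarray(theta, dtype=float)
    f0 = model_stats(spec, theta)
    J = np.empty((f0.size, theta.size))
    for k in range(theta.size):
        h = rel_step * max(1.0, abs(theta[k]))
        tp = theta.copy()
        tm = theta.copy()
        tp[k] += h
        tm[k] -= h
        J[:, k] = (model_stats(spec, tp) - model_stats(spec, tm)) / (2 * h)
    return J


def check_identification(
    spec: ModelSpec, n_draws: int = 10, seed: int = 7, rtol: float = 1e-8
) -> dict:
    """Local identification by Jacobian column rank at random admissible points.

    Returns a report with the verdict, per-draw ranks, and (for deficient
    draws) the parameter combination spanning the null space.
    """
    rng = np.random.default_rng(seed)
    ranks = []
    null_dirs = []
    for _ in range(n_draws):
        theta = sample_admissible_theta(spec, rng)
        J = stats_jacobian(spec, theta)
        s = np.linalg.svd(J, compute_uv=False)
        rank = int(np.sum(s > rtol * s[0]))
        ranks.append(rank)
        if rank < spec.n_free:
            _, _, Vt = np.linalg.svd(J)
            null = Vt[rank:]
            top = np.argsort(-np.abs(null[0]))[:6]
            null_dirs.append(
                {spec.param_names[i]: float(null[0][i]) for i in top}
            )
    identified = all(r == spec.n_free for r in ranks)
    return {
        "identified": identified,
        "n_free": spec.n_free,
        "ranks": ranks,
        "df": count_df(spec),
        "null_space": null_dirs[:3],
    }


# ---------------------------------------------------------------------------
# Admissible draws and closed-form parameter recovery
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"([a-z_0-9]+)((?:\[[^\]]*\])*)")


def _parse_name(name: str):
    m = _NAME_RE.fullmatch(name)
    kind = m.group(1)
    idx = re.findall(r"\[([^\]]*)\]", m.group(2))
    return kind, idx


def sample_admissible_theta(spec: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    """Random parameter vector respecting ordering/positivity/PSD constraints."""
    for _ in range(60):
        theta = np.empty(spec.n_free)
        for s, name in enumerate(spec.param_names):
            kind, idx = _parse_name(name)
            if kind == "tau":
                v = int(idx[0])
                c = int(idx[-1])
                cv = spec.C[v]
                pv = spec.vparam[v]
                if pv in (Parameterization.ALT2, Parameterization.ALT2_INV):
                    base = float(c)  # scale where tau_1 = 0, tau_2 = 1
                    theta[s] = base + rng.uniform(-0.15, 0.15)
                else:
                    from scipy.special import ndtri

                    # binary: keep the single threshold away from zero so the
                    # scale-by-threshold rows (bin_mm) stay in their domain
                    base = 0.6 if cv == 2 else ndtri((c + 1) / cv)
                    theta[s] = base + rng.uniform(-0.1, 0.1)
            elif kind in ("sigma2", "theta", "vplace", "delta"):
                theta[s] = rng.uniform(0.6, 1.5)
            elif kind == "p11":
                i, j = int(idx[-2]), int(idx[-1])
                theta[s] = rng.uniform(0.7, 1.4) if i == j else rng.uniform(-0.3, 0.3)
            elif kind == "psi":
                i, j = int(idx[-2]), int(idx[-1])
                if i == j:
                    theta[s] = rng.uniform(0.15, 0.6) if i % 2 == 0 else rng.uniform(0.05, 0.2)
                else:
                    theta[s] = rng.uniform(-0.05, 0.05)
            elif kind == "p1g":
                theta[s] = rng.uniform(-0.12, 0.12)
            elif kind == "rho":
                theta[s] = rng.uniform(-0.55, 0.55)
            elif kind == "cross":
                theta[s] = rng.uniform(-0.2, 0.2)
            elif kind == "conc":
                theta[s] = rng.uniform(-0.25, 0.25)
            elif kind in ("mu", "nu", "m1", "mu_alpha"):
                theta[s] = rng.uniform(-0.4, 0.4)
            elif kind == "mu_beta":
                theta[s] = rng.uniform(-0.25, 0.25)
            elif kind == "r":
                theta[s] = rng.uniform(-0.35, 0.35)
            else:  # pragma: no cover
                theta[s] = rng.uniform(-0.3, 0.3)
        if spec.family == Family.LGM and spec.placement == "delta":
            # the underlying variances must exceed the growth part at every
            # occasion for the error-variance remainder to stay positive
            psi = spec.arrays["psi"].resolve(theta)
            lam = np.column_stack([np.ones(spec.T), np.arange(spec.T, dtype=float)])
            h = np.einsum("ti,ij,tj->t", lam, psi, lam)
            vp = spec.arrays["vplace"]
            for t in range(spec.T):
                if vp.map[t] >= 0:
                    theta[vp.map[t]] = h[t] + rng.uniform(0.4, 1.2)
        mom = structural_moments(spec, theta)
        if mom.warnings:
            continue
        ev = np.linalg.eigvalsh((mom.sigma_star + mom.sigma_star.T) / 2)
        if ev.min() <= 1e-6:
            continue
        ok = all(np.all(np.diff(tv, axis=1) > 1e-3) for tv in mom.tau if tv.shape[1] > 1)
        if spec.family == Family.SATURATED and spec.V * spec.T > 2:
            # random pairwise correlations can produce an indefinite matrix
            R = mom.sigma_star / np.sqrt(np.outer(np.diag(mom.sigma_star), np.diag(mom.sigma_star)))
            if np.linalg.eigvalsh(R).min() <= 1e-4:
                continue
        if ok:
            return theta
    raise RuntimeError("failed to draw an admissible parameter vector")


def _scales_from_std(pv: str, std_tau: np.ndarray):
    """Recover (mu_t, sd_t, model thresholds) from probit-scale thresholds.

    ``std_tau`` is (T, C-1).  Inverts the identification row's standardization
    (tau_model - mu)/sd = std_tau exactly when the row's invariance pattern
    holds in the input; otherwise uses the designated reference thresholds,
    which is the conventional estimator.
    """
    P = Parameterization
    T = std_tau.shape[0]
    if pv == P.STANDARD:
        return np.zeros(T), np.ones(T), std_tau.copy()
    if pv in (P.ALT1, P.ALT1_INV):
        d1 = std_tau[0, 1] - std_tau[0, 0]
        sd = d1 / (std_tau[:, 1] - std_tau[:, 0])
        mu = std_tau[0, 0] - sd * std_tau[:, 0]
        tau = mu[:, None] + sd[:, None] * std_tau
        return mu, sd, tau
    if pv in (P.ALT2, P.ALT2_INV):
        sd = 1.0 / (std_tau[:, 1] - std_tau[:, 0])
        mu = -std_tau[:, 0] * sd
        tau = mu[:, None] + sd[:, None] * std_tau
        return mu, sd, tau
    if pv == P.BIN_MYT:
        sd = np.ones(T)
        mu = std_tau[0, 0] - std_tau[:, 0]
        tau = mu[:, None] + std_tau
        return mu, sd, tau
    if pv == P.BIN_MM:
        mu = np.zeros(T)
        with np.errstate(divide="ignore"):
            sd = std_tau[0, 0] / std_tau[:, 0]
        sd = np.where(np.isfinite(sd) & (sd > 0), sd, 1.0)
        tau = sd[:, None] * std_tau
        return mu, sd, tau
    if pv == P.BIN_JORESKOG:
        sd = np.ones(T)
        mu = -std_tau[:, 0]
        tau = np.zeros_like(std_tau)
        return mu, sd, tau
    raise SpecError(pv)


def _lgm_psi_from_offdiag(Sigma: np.ndarray) -> np.ndarray:
    """Least-squares fit of the 2x2 growth covariance from off-diagonal moments."""
    T = Sigma.shape[0]
    lam = np.arange(T, dtype=float)
    rows, rhs = [], []
    for s in range(T):
        for t in range(s + 1, T):
            rows.append([1.0, lam[s] + lam[t], lam[s] * lam[t]])
            rhs.append(Sigma[s, t])
    coef, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    return np.array([[coef[0], coef[1]], [coef[1], coef[2]]])


def _recover_scales(spec: ModelSpec, v: int, std_tau_v: np.ndarray, R: np.ndarray):
    """Occasion scales (mu_t, sd_t) and model thresholds for one variable.

    Rows whose thresholds pin the scale invert the standardization directly;
    rows whose fixed error variances pin it (standard / bin_myt / bin_joreskog
    under AR1 or a theta-placement LGM) recover the scale from the correlation
    structure via the corresponding variance anchors.
    """
    P = Parameterization
    pv = spec.vparam[v]
    T = spec.T
    Rv = R[v * T : (v + 1) * T, v * T : (v + 1) * T]
    theta_pinned = pv in (P.STANDARD, P.BIN_MYT, P.BIN_JORESKOG)

    if spec.family == Family.AR1 and theta_pinned:
        # p11 = 1 and theta_t = 1 fixed: d_t^2 (1 - r_{t,t-1}^2) = 1.
        d = np.ones(T)
        for t in range(1, T):
            d[t] = 1.0 / np.sqrt(max(1.0 - Rv[t, t - 1] ** 2, 1e-10))
        return _row_mean_thresholds(pv, std_tau_v, d)

    if spec.family == Family.LGM and spec.placement == "theta":
        if pv in (P.ALT2, P.ALT2_INV):
            return _scales_from_std(pv, std_tau_v)
        if pv in (P.ALT1, P.ALT1_INV, P.BIN_MM):
            # relative scale (sd_1 = 1) from thresholds, then global rescale so
            # that the anchor theta_1 = 1 holds: k^2 (1 - psi0_aa) = ... = 1.
            mu0, sd0, tau0 = _scales_from_std(pv, std_tau_v)
            psi0 = _lgm_psi_from_offdiag(Rv * np.outer(sd0, sd0))
            k = 1.0 / np.sqrt(max(1.0 - psi0[0, 0], 1e-10))
            return mu0 * k, sd0 * k, tau0 * k
        # theta_t = 1 on every occasion: fixed point on d_t^2 = h_tt + 1
        d = np.ones(T)
        for _ in range(200):
            psi = _lgm_psi_from_offdiag(Rv * np.outer(d, d))
            lam = np.column_stack([np.ones(T), np.arange(T, dtype=float)])
            h = np.einsum("ti,ij,tj->t", lam, psi, lam)
            d_new = np.sqrt(np.maximum(h + 1.0, 1e-10))
            if np.max(np.abs(d_new - d)) < 1e-14:
                d = d_new
                break
            d = d_new
        return _row_mean_thresholds(pv, std_tau_v, d)

    if spec.family == Family.ALT and theta_pinned:
        # start-value quality only; use the AR-style anchor
        d = np.ones(T)
        for t in range(1, T):
            d[t] = 1.0 / np.sqrt(max(1.0 - Rv[t, t - 1] ** 2, 1e-10))
        return _row_mean_thresholds(pv, std_tau_v, d)

    return _scales_from_std(pv, std_tau_v)


def _row_mean_thresholds(pv: str, std_tau: np.ndarray, d: np.ndarray):
    """Means and model thresholds for rows with externally recovered sd's."""
    P = Parameterization
    if pv == P.STANDARD:
        mu = np.zeros_like(d)
        tau = d[:, None] * std_tau
    elif pv == P.BIN_MYT:
        tau_shared = d[0] * std_tau[0, 0]  # mu_1 = 0
        mu = tau_shared - d * std_tau[:, 0]
        tau = np.full_like(std_tau, tau_shared)
    elif pv == P.BIN_JORESKOG:
        mu = -d * std_tau[:, 0]
        tau = np.zeros_like(std_tau)
    else:  # pragma: no cover
        raise SpecError(pv)
    return mu, d, tau


def recover_params(
    spec: ModelSpec, std_tau: Sequence[np.ndarray], R: np.ndarray
) -> np.ndarray:
    """Closed-form / least-squares parameter recovery from standardized stats.

    Exact (moment-preserving) for SATURATED, LGM and AR1 specs whenever the
    input lies on the spec's manifold — this is what powers the equivalence
    transformation maps.  For ALT specs the autoregressive and variance pieces
    are recovered by moment heuristics and serve as optimizer starting values.
    """
    T, V = spec.T, spec.V
    A = spec.arrays
    theta = np.zeros(spec.n_free)
    counts = np.zeros(spec.n_free)

    def put(pa: _ParamArray, index, value):
        s = pa.map[index]
        if s >= 0:
            theta[s] += value
            counts[s] += 1.0

    R = np.asarray(R)
    mus, sds, tau_models = [], [], []
    for v in range(V):
        mu_v, sd_v, tau_v = _recover_scales(spec, v, np.asarray(std_tau[v]), R)
        mus.append(mu_v)
        sds.append(sd_v)
        tau_models.append(tau_v)
        for t in range(T):
            for c in range(spec.C[v] - 1):
                put(A["tau"][v], (t, c), tau_v[t, c])
    mu_star = np.concatenate(mus)
    d = np.concatenate(sds)
    Sigma = R * np.outer(d, d)

    if spec.family == Family.SATURATED:
        for v in range(V):
            for t in range(T):
                put(A["mu"], (v, t), mus[v][t])
                put(A["sigma2"], (v, t), sds[v][t] ** 2)
        VT = V * T
        for i in range(VT):
            for j in range(i + 1, VT):
                put(A["rcorr"], (i, j), R[i, j])

    elif spec.family == Family.LGM:
        lam = np.column_stack([np.ones(T), np.arange(T, dtype=float)])
        free = [A["mu_ab"].map[k] >= 0 for k in range(2)]
        if any(free):
            cols = [k for k in range(2) if free[k]]
            sol, *_ = np.linalg.lstsq(lam[:, cols], mu_star, rcond=None)
            for k, c in zip(cols, sol):
                put(A["mu_ab"], (k,), c)
        rows, rhs = [], []
        for s in range(T):
            for t in range(s + 1, T):
                rows.append([1.0, lam[s, 1] + lam[t, 1], lam[s, 1] * lam[t, 1]])
                rhs.append(Sigma[s, t])
        coef, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
        psi = np.array([[coef[0], coef[1]], [coef[1], coef[2]]])
        for i in range(2):
            for j in range(i + 1):
                put(A["psi"], (i, j), psi[i, j])
        hdiag = np.einsum("ti,ij,tj->t", lam, psi, lam)
        for t in range(T):
            val = Sigma[t, t] if spec.placement == "delta" else max(Sigma[t, t] - hdiag[t], 1e-3)
            put(A["vplace"], (t,), val)

    elif spec.family == Family.AR1:
        put(A["m1"], (0,), mu_star[0])
        put(A["p11"], (0, 0), Sigma[0, 0])
        for t in range(1, T):
            r = Sigma[t, t - 1] / Sigma[t - 1, t - 1]
            put(A["rho"], (t - 1,), r)
            put(A["theta"], (t - 1,), max(Sigma[t, t] - r * r * Sigma[t - 1, t - 1], 1e-3))
            put(A["nu"], (t - 1,), mu_star[t] - r * mu_star[t - 1])

    elif spec.family == Family.ALT:
        for v in range(V):
            Sv = Sigma[v * T : (v + 1) * T, v * T : (v + 1) * T]
            mv = mu_star[v * T : (v + 1) * T]
            put(A["m1"], (v,), mv[0])
            put(A["p11"], (v, v), Sv[0, 0])
            rr = np.empty(T - 1)
            for t in range(1, T):
                rr[t - 1] = Sv[t, t - 1] / Sv[t - 1, t - 1]
                put(A["rho"], (v, t - 1), 0.8 * rr[t - 1])
                put(A["theta"], (v, t - 1), max(0.7 * (Sv[t, t] - rr[t - 1] ** 2 * Sv[t - 1, t - 1]), 0.05))
            # growth means from AR-filtered trajectory means
            resid = np.array([mv[t] - rr[t - 1] * mv[t - 1] for t in range(1, T)])
            lam2 = np.column_stack([np.ones(T - 1), np.arange(1, T, dtype=float)])
            free = [A["mu_ab"].map[v, k] >= 0 for k in range(2)]
            if any(free):
                cols = [k for k in range(2) if free[k]]
                sol, *_ = np.linalg.lstsq(lam2[:, cols], resid, rcond=None)
                for k, cval in zip(cols, sol):
                    put(A["mu_ab"], (v, k), cval)
            put(A["psi"], (2 * v, 2 * v), 0.2)
            put(A["psi"], (2 * v + 1, 2 * v + 1), 0.05)
            for g in range(2 * V):
                put(A["p1g"], (v, g), 0.0)
        for a in range(V):
            for bb in range(a + 1, V):
                put(A["p11"], (a, bb), Sigma[a * T, bb * T])
                for t in range(1, T):
                    put(A["conc"], (a, bb, t - 1), 0.3 * Sigma[a * T + t, bb * T + t])
        # remaining psi cross terms and cross-lags default to 0 (already zero)

    counts[counts == 0] = 1.0
    return theta / counts
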