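"""Parameter-transformation maps and numerical equivalence checking.

Two specifications are equivalent (in the Raykov--Penev / Steiger sense) when
an invertible parameter transformation maps one onto the other while
preserving the implied moments — hence identical fit, test statistics and
degrees of freedom on *any* dataset.  For the families here the shipped maps
are induced by an affine change of the latent scale: re-anchoring which
quantities are fixed (the first-occasion variance, the first error variance,
or the first two thresholds) rescales and shifts every remaining parameter.
The ALT model is the deliberate exception: a location shift cannot be absorbed
by its recursion (the occasion intercept it would need is not a parameter), so
its alternative identification rows are *not* equivalent.

``transform_params`` realizes the maps by transporting the implied
standardized moments and re-solving the target's parameters in closed form;
moment preservation is verified on every call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    Family,
    ModelSpec,
    Parameterization,
    SpecError,
    build_spec,
    count_df,
    model_stats,
    recover_params,
    sample_admissible_theta,
    stats_jacobian,
    structural_moments,
)

__all__ = [
    "TransformMap",
    "equivalent_rows",
    "transform_params",
    "check_equivalence",
    "omega_constraint_report",
    "EquivalenceError",
]


class EquivalenceError(SpecError):
    """Requested a map between non-equivalent specifications."""


@dataclass(frozen=True)
class TransformMap:
    """A validated parameter map between two equivalent specifications."""

    source: ModelSpec
    target: ModelSpec

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        return transform_params(theta, self.source, self.target)


def _row_group(spec: ModelSpec) -> str:
    """Equivalence class label of a spec's identification row within its family."""
    P = Parameterization
    pv = spec.vparam[0] if spec.V == 1 else None
    fam = spec.family
    if fam == Family.SATURATED:
        inv = all(p in Parameterization.INVARIANT for p in spec.vparam)
        return "sat-inv" if inv else "sat-free"
    if fam == Family.LGM:
        if pv in (P.ALT1, P.ALT1_INV, P.ALT2, P.ALT2_INV, P.BIN_MM):
            return "lgm-alt"  # Models A/B/C/D: all mutually equivalent
        if pv == P.STANDARD:
            return f"lgm-standard-{spec.placement}"
        if pv in (P.BIN_MYT, P.BIN_JORESKOG):
            return f"lgm-bin-anchor-{spec.placement}"  # MYT <-> Joreskog pair
        raise SpecError(pv)
    if fam == Family.AR1:
        if pv in (P.STANDARD, P.ALT1, P.ALT2, P.BIN_MYT, P.BIN_MM, P.BIN_JORESKOG):
            # free-threshold ordinal rows and all binary rows: one class each
            binary = spec.C[0] == 2
            return "ar1-bin" if binary else "ar1-free"
        if pv in (P.ALT1_INV, P.ALT2_INV):
            return "ar1-inv"  # Models E <-> F
        raise SpecError(pv)
    # ALT with time-varying coefficients: every row is its own class.  A
    # location shift of the latent scale would need a time-varying occasion
    # intercept a(rho_t - 1), which the ALT recursion does not contain — this
    # is the non-equivalence of the alternative rows.  With a *stationary*
    # autoregression that term is constant and folds into the random
    # intercept's mean, so the two alternative rows do map onto each other.
    P = Parameterization
    if spec.stationary and spec.V == 1 and spec.vparam[0] in (P.ALT1_INV, P.ALT2_INV):
        return "alt-stationary-inv"
    return f"alt:{spec.parameterization}:{spec.placement}"


def equivalent_rows(a: ModelSpec, b: ModelSpec) -> bool:
    """Whether two specs lie in the same (paper-established) equivalence class."""
    if (a.family, a.T, a.C, a.stationary) != (b.family, b.T, b.C, b.stationary):
        return False
    return _row_group(a) == _row_group(b)


def transform_params(theta: np.ndarray, source: ModelSpec, target: ModelSpec, *, tol: float = 1e-10) -> np.ndarray:
    """Map a parameter vector onto an equivalent specification.

    The implied standardized moments of ``source`` at ``theta`` are transported
    and the ``target`` parameters solved in closed form; the result reproduces
    the moments entrywise below ``tol``.  Raises :class:`EquivalenceError` for
    pairs the theory shows non-equivalent (notably any two ALT rows, and the
    standard delta vs theta growth models).
    """
    same = (
        source.family == target.family
        and source.parameterization == target.parameterization
        and source.placement == target.placement
        and source.T == target.T
        and source.C == target.C
        and source.stationary == target.stationary
    )
    theta = np.asarray(theta, dtype=float)
    if same:
        return theta.copy()
    if not equivalent_rows(source, target):
        raise EquivalenceError(
            f"no moment-preserving map exists between {source.describe()} and "
            f"{target.describe()}: the specifications are not equivalent"
        )
    if source.family == Family.ALT:
        theta_t = _alt_stationary_affine(theta, source, target)
        err = float(
            np.max(np.abs(model_stats(source, theta) - model_stats(target, theta_t)))
        )
        if err > tol:
            raise EquivalenceError(
                f"transported parameters fail moment preservation (max err {err:.2e})"
            )
        return theta_t
    mom = structural_moments(source, theta)
    d = np.sqrt(np.diag(mom.sigma_star))
    T = source.T
    std_tau = [
        (mom.tau[v] - mom.mu_star[v * T : (v + 1) * T, None]) / d[v * T : (v + 1) * T, None]
        for v in range(source.V)
    ]
    R = mom.sigma_star / np.outer(d, d)
    theta_t = recover_params(target, std_tau, R)
    err = float(np.max(np.abs(model_stats(source, theta) - model_stats(target, theta_t))))
    if err > tol:
        raise EquivalenceError(
            f"transported parameters fail moment preservation (max err {err:.2e})"
        )
    return theta_t


def _alt_stationary_affine(theta: np.ndarray, src: ModelSpec, tgt: ModelSpec) -> np.ndarray:
    """Closed-form map between the stationary univariate ALT alternative rows.

    With y' = (y - a)/k the recursion transforms as rho' = rho,
    alpha' = (alpha + a(rho - 1))/k, beta' = beta/k, and every (co)variance
    scales by 1/k^2.  alt1 -> alt2 anchors a = tau_1, k = tau_2 - tau_1;
    alt2 -> alt1 anchors a = m_1, k = sqrt(p_11).
    """
    P = Parameterization
    s_idx = {n: i for i, n in enumerate(src.param_names)}
    t_idx = {n: i for i, n in enumerate(tgt.param_names)}

    def g(name, default=0.0):
        return theta[s_idx[name]] if name in s_idx else default

    C = src.C[0]
    if src.vparam[0] == P.ALT1_INV:
        tau = np.array([g(f"tau[0][{c}]") for c in range(C - 1)])
        a, k = tau[0], tau[1] - tau[0]
        m1, p11 = 0.0, 1.0
    else:
        tau = np.concatenate([[0.0, 1.0], [g(f"tau[0][{c}]") for c in range(2, C - 1)]])
        m1, p11 = g("m1[0]"), g("p11[0][0]", 1.0)
        a, k = m1, np.sqrt(p11)
    rho = g("rho[0]")
    out = np.zeros(tgt.n_free)

    def put(name, value):
        if name in t_idx:
            out[t_idx[name]] = value

    new_tau = (tau - a) / k
    for c in range(C - 1):
        put(f"tau[0][{c}]", new_tau[c])
    put("m1[0]", (m1 - a) / k)
    put("p11[0][0]", p11 / k**2)
    put("rho[0]", rho)
    put("mu_alpha[0]", (g("mu_alpha[0]") + a * (rho - 1.0)) / k)
    put("mu_beta[0]", g("mu_beta[0]") / k)
    for nm in ("psi[0][0]", "psi[1][0]", "psi[1][1]", "p1g[0][0]", "p1g[0][1]"):
        put(nm, g(nm) / k**2)
    for t in range(1, src.T):
        put(f"theta[0][{t}]", g(f"theta[0][{t}]") / k**2)
    return out


def check_equivalence(
    spec_a: ModelSpec,
    spec_b: ModelSpec,
    *,
    n_probes: int = 20,
    n: int = 2000,
    seed: int = 0,
    chi2_tol: float = 1e-4,
) -> dict:
    """Empirical equivalence verdict on seeded probe panels.

    Probes are simulated from saturated (unstructured) latent processes, so
    both candidate models are misspecified — equivalence must hold *off* the
    truth, which is exactly the content of the shared-constraint criterion.
    Verdict EQUIVALENT requires equal df, |delta chi2| < ``chi2_tol`` on every
    probe, and a moment-preserving map at random parameter draws; otherwise the
    largest-difference probe is reported as a witness.
    """
    from .estimation import compute_sample_stats, dwls_fit
    from .simulate import SimScenario, simulate

    if (spec_a.T, spec_a.C) != (spec_b.T, spec_b.C):
        raise SpecError("specs must share panel dimensions")
    rng = np.random.default_rng(seed)
    gen = build_spec(Family.SATURATED, "standard", spec_a.T, spec_a.C)
    df_a, df_b = count_df(spec_a), count_df(spec_b)
    diffs = []
    for k in range(n_probes):
        th = sample_admissible_theta(gen, rng)
        panel = simulate(SimScenario(gen, th, n=n), seed=int(rng.integers(2**31 - 1)))
        stats = compute_sample_stats(panel)
        fa = dwls_fit(stats, spec_a)
        fb = dwls_fit(stats, spec_b)
        diffs.append(abs(fa.n * fa.F_min - fb.n * fb.F_min))
    max_diff = float(np.max(diffs))
    map_ok = None
    if df_a == df_b and max_diff < chi2_tol:
        try:
            th_a = sample_admissible_theta(spec_a, rng)
            transform_params(th_a, spec_a, spec_b)
            map_ok = True
        except EquivalenceError:
            map_ok = False
    verdict = "EQUIVALENT" if (df_a == df_b and max_diff < chi2_tol and map_ok) else "NOT_EQUIVALENT"
    return {
        "verdict": verdict,
        "df": (df_a, df_b),
        "max_chi2_diff": max_diff,
        "chi2_diffs": diffs,
        "witness_probe": int(np.argmax(diffs)) if verdict == "NOT_EQUIVALENT" else None,
        "map_validated": map_ok,
    }


def omega_constraint_report(spec: ModelSpec, *, n_draws: int = 20, seed: int = 0) -> dict:
    """Counts of constraints the spec places on the latent moment structure.

    Constraint counts are computed as (number of moment elements) minus the
    Jacobian rank of the moment map at random admissible draws:

    * ``omega`` — on the covariance structure vech(Sigma*), dimension
      VT(VT+1)/2 (the convention under which the T = 4 growth model carries
      T(T+1)/2 - 3 = 7 constraints);
    * ``mu`` — on the mean structure relative to the means the identification
      row leaves free on the data side;
    * ``stats`` — on the standardized statistics vector (these equal the
      degrees of freedom).

    Rank stability across draws is reported; a varying rank indicates boundary
    or non-generic draws.
    """
    rng = np.random.default_rng(seed)
    VT = spec.V * spec.T
    n_cov = VT * (VT + 1) // 2
    iu = np.triu_indices(VT)
    r_cov, r_mu, r_stats = [], [], []
    for _ in range(n_draws):
        theta = sample_admissible_theta(spec, rng)
        eps = 1e-6

        def cov_vec(th):
            m = structural_moments(spec, th)
            return m.sigma_star[iu]

        def mu_vec(th):
            return structural_moments(spec, th).mu_star

        J_cov = _num_jac(cov_vec, theta, eps)
        J_mu = _num_jac(mu_vec, theta, eps)
        J_s = stats_jacobian(spec, theta)
        r_cov.append(_rank(J_cov))
        r_mu.append(_rank(J_mu))
        r_stats.append(_rank(J_s))
    free_mu = _free_data_means(spec)
    return {
        "omega_constraints": n_cov - max(r_cov),
        "mu_constraints": max(free_mu - max(r_mu), 0),
        "stat_constraints": spec.n_stats - max(r_stats),
        "df": count_df(spec),
        "ranks": {"cov": sorted(set(r_cov)), "mu": sorted(set(r_mu)), "stats": sorted(set(r_stats))},
    }


def _free_data_means(spec: ModelSpec) -> int:
    """Number of underlying means the identification row leaves free on the data side."""
    P = Parameterization
    total = 0
    for pv in spec.vparam:
        if pv == P.STANDARD or pv == P.BIN_MM:
            total += 0
        elif pv in (P.ALT1, P.ALT1_INV, P.BIN_MYT):
            total += spec.T - 1
        else:  # alt2 rows, bin_joreskog
            total += spec.T
    return total


def _num_jac(fn, theta, eps):
    f0 = fn(theta)
    J = np.empty((f0.size, theta.size))
    for k in range(theta.size):
        h = eps * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        J[:, k] = (fn(tp) - fn(tm)) / (2 * h)
    return J


def _rank(J, rtol=1e-8):
    s = np.linalg.svd(J, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > rtol * s[0]))
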