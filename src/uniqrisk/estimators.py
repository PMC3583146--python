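"""Sample-based estimators of population uniqueness (lambda3).

Each estimator consumes only the sample's frequency spectrum together with a
:class:`SamplingContext` (sample size n, population size N, sampling fraction
pi = n/N) and returns an estimate of lambda3, the proportion of population
records that are unique on the quasi-identifiers.

Four estimators are provided:

``pitman``
    Two-parameter Poisson–Dirichlet (Pitman) partition model with discount
    ``0 <= alpha < 1`` and concentration ``theta > -alpha``; the Ewens model
    is the ``alpha = 0`` submodel.  (alpha, theta) are fit by maximum
    likelihood on the Pitman sampling formula.  The estimate is the
    predictive expected number of singleton classes in a population-sized
    draw, divided by N:

        E[K_{N,1}] / N = (theta+alpha)_{N-1} / (theta+1)_{N-1}

    with ``(x)_m`` the rising factorial; at alpha = 0 this reduces to
    ``theta / (theta + N - 1)``.

``snb``
    Slide (shifted) negative binomial superpopulation model: population
    class sizes are i.i.d. ``F = 1 + NegBin(k, p)``.  Under binomial
    subsampling at rate pi the observable class size is
    ``f = Bernoulli(pi) + NegBin(k, p~)`` with
    ``p~ = p / (p + (1-p) pi)`` (thinning of a negative binomial is again
    negative binomial).  (k, p) are fit by zero-truncated maximum likelihood
    on the sample spectrum; the number of population classes is *estimated*
    as ``K_hat = u / (1 - P(f=0))`` rather than assumed known, and
    ``lambda3_hat = K_hat * p^k / N``.

``zayatz``
    Model-free plug-in: the exact hypergeometric subsampling probabilities
    ``P(f=1 | F=j, n, N)`` are weighted by the observed sample class-size
    distribution (standing in for the population class-size distribution) to
    form ``P_hat(F=1 | f=1)``; then ``lambda3_hat = u1 * P_hat / (pi * N)``.

``mu_argus``
    Benedetti–Franconi individual-risk model: given a sample class of size
    f, the population class size follows the shifted negative binomial
    posterior ``F - f | f ~ NegBin(f, pi)``.  The lambda3 extension sums
    ``P(F=1 | f=1) = pi`` over the sample uniques and rescales by
    ``1 / (pi * N)``.

Zayatz and mu-argus are deterministic closed forms and always converge.  The
model-based fits report a ``converged`` flag; a failed fit is surfaced as
``converged=False`` with ``lambda3_hat=None`` — never a silent fallback,
because the decision rule consumes the flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional

import numpy as np
from scipy import optimize
from scipy.special import gammaln, psi

from .exceptions import InputError, ParameterError
from .frequency import FrequencySpectrum

__all__ = [
    "SamplingContext",
    "EstimateResult",
    "estimate_pitman",
    "estimate_snb",
    "estimate_zayatz",
    "estimate_mu_argus",
    "estimate_all",
    "ESTIMATOR_NAMES",
    "pitman_expected_singleton_fraction",
]

ESTIMATOR_NAMES = ("pitman", "snb", "zayatz", "mu_argus")

_ALPHA_MAX = 1.0 - 1e-6  # Pitman discount clamped below 1
_PSI_BOUNDS = (-30.0, 30.0)  # log(theta + alpha)


@dataclass(frozen=True)
class SamplingContext:
    """Sample size n and population size N; pi = n/N is always derived."""

    n: int
    N: int

    def __post_init__(self):
        if not (1 <= self.n <= self.N):
            raise ParameterError(f"need 1 <= n <= N, got n={self.n}, N={self.N}")

    @property
    def pi(self) -> float:
        return self.n / self.N


@dataclass
class EstimateResult:
    """One estimator's lambda3 estimate with convergence and diagnostics."""

    estimator_name: str
    lambda3_hat: Optional[float]
    converged: bool
    params: Dict[str, float] = field(default_factory=dict)
    diagnostics: Dict[str, object] = field(default_factory=dict)


def _check_spectrum(spec: FrequencySpectrum, ctx: SamplingContext) -> None:
    if spec.total != ctx.n:
        raise InputError(
            f"spectrum total {spec.total} does not match sample size n={ctx.n}"
        )


def _clamp_unit(x: float) -> tuple[float, bool]:
    if x < 0.0:
        return 0.0, True
    if x > 1.0:
        return 1.0, True
    return x, False


# ---------------------------------------------------------------------------
# Pitman
# ---------------------------------------------------------------------------

def pitman_expected_singleton_fraction(alpha: float, theta: float, N: int) -> float:
    """E[number of singleton classes in a size-N draw] / N under Pitman(alpha, theta).

    E[K_{N,1}] = N * (theta+alpha)_{N-1} / (theta+1)_{N-1} with rising
    factorials, evaluated in log space.  Reduces to N*theta/(theta+N-1) at
    alpha = 0 (Ewens).
    """
    if N == 1:
        return 1.0
    ta = theta + alpha
    if ta <= 0:
        return 0.0
    log_ratio = (
        gammaln(ta + N - 1) - gammaln(ta) - gammaln(theta + N) + gammaln(theta + 1)
    )
    return float(np.exp(log_ratio))


def _pitman_negloglik_and_grad(x: np.ndarray, js: np.ndarray, cs: np.ndarray, n: int, u: int):
    """Negative Pitman sampling-formula log-likelihood in (alpha, psi) coordinates.

    theta = exp(psi) - alpha keeps theta + alpha > 0 for free.  Terms:
      sum_{i=1}^{u-1} log(theta + i*alpha)
      - [lgamma(theta+n) - lgamma(theta+1)]
      + sum_{j>=2} c_j [lgamma(j-alpha) - lgamma(1-alpha)]
    """
    alpha, psi_ = x
    theta = math.exp(psi_) - alpha

    i = np.arange(1.0, u)
    denom = theta + i * alpha  # > 0 in the admissible region
    ll = float(np.sum(np.log(denom)))
    dll_dalpha = float(np.sum(i / denom))
    dll_dtheta = float(np.sum(1.0 / denom))

    ll -= gammaln(theta + n) - gammaln(theta + 1)
    dll_dtheta -= psi(theta + n) - psi(theta + 1)

    big = js >= 2
    if np.any(big):
        jb = js[big].astype(float)
        cb = cs[big].astype(float)
        ll += float(np.sum(cb * (gammaln(jb - alpha) - gammaln(1.0 - alpha))))
        dll_dalpha += float(np.sum(cb * (-psi(jb - alpha) + psi(1.0 - alpha))))

    # chain rule: theta depends on (alpha, psi)
    g_alpha = dll_dalpha - dll_dtheta
    g_psi = dll_dtheta * math.exp(psi_)
    return -ll, np.array([-g_alpha, -g_psi])


def pitman_loglik(alpha: float, theta: float, spec: FrequencySpectrum) -> float:
    """Pitman sampling-formula log-likelihood of a spectrum at (alpha, theta)."""
    js, cs = spec.sizes_and_counts()
    x = np.array([alpha, math.log(theta + alpha)])
    nll, _ = _pitman_negloglik_and_grad(x, js, cs, spec.total, spec.num_classes)
    return -nll


def estimate_pitman(spec: FrequencySpectrum, ctx: SamplingContext) -> EstimateResult:
    """Maximum-likelihood Pitman fit and predictive singleton fraction at size N.

    Multi-start box-constrained quasi-Newton over (alpha, log(theta+alpha))
    from a 3x3 grid of starting points; the likelihood can be flat in theta,
    so multi-start guards against local optima.  An all-singleton spectrum
    drives alpha to its upper boundary (clamped at 1 - 1e-6) and is reported
    as converged with a boundary flag.
    """
    _check_spectrum(spec, ctx)
    js, cs = spec.sizes_and_counts()
    n, u = spec.total, spec.num_classes

    starts = [
        (a0, math.log(t0 + a0))
        for a0 in (0.01, 0.5, 0.9)
        for t0 in (1.0, 10.0, 100.0)
    ]
    best = None
    n_success = 0
    total_iters = 0
    for x0 in starts:
        res = optimize.minimize(
            _pitman_negloglik_and_grad,
            np.array(x0),
            args=(js, cs, n, u),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, _ALPHA_MAX), _PSI_BOUNDS],
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        total_iters += int(res.nit)
        if res.success:
            n_success += 1
        if best is None or res.fun < best.fun:
            best = res

    alpha_hat = float(best.x[0])
    theta_hat = float(math.exp(best.x[1]) - alpha_hat)
    converged = n_success > 0
    boundary_alpha = bool(alpha_hat >= _ALPHA_MAX - 1e-9 or alpha_hat <= 1e-12)
    boundary_theta = bool(
        best.x[1] <= _PSI_BOUNDS[0] + 1e-6 or best.x[1] >= _PSI_BOUNDS[1] - 1e-6
    )

    raw = pitman_expected_singleton_fraction(alpha_hat, theta_hat, ctx.N)
    lam, clamped = _clamp_unit(raw)
    return EstimateResult(
        estimator_name="pitman",
        lambda3_hat=lam if converged else None,
        converged=converged,
        params={"alpha": alpha_hat, "theta": theta_hat},
        diagnostics={
            "loglik": -float(best.fun),
            "iterations": total_iters,
            "n_starts": len(starts),
            "n_successful_starts": n_success,
            "boundary_alpha": boundary_alpha,
            "boundary_theta": boundary_theta,
            "clamped": clamped,
        },
    )


# ---------------------------------------------------------------------------
# Slide negative binomial (SNB)
# ---------------------------------------------------------------------------

def snb_pmf(j, k: float, p: float):
    """P(F = j) under the slide negative binomial: F - 1 ~ NegBin(k, p), j >= 1."""
    j = np.asarray(j, dtype=float)
    m = j - 1.0
    out = np.where(
        m >= 0,
        np.exp(
            gammaln(m + k)
            - gammaln(k)
            - gammaln(m + 1.0)
            + k * math.log(p)
            + m * math.log1p(-p)
        ),
        0.0,
    )
    return out


def _snb_sample_logpmf(m: np.ndarray, k: float, p: float, pi: float) -> np.ndarray:
    """log P(f = m) for the binomially subsampled SNB class size.

    f = Bernoulli(pi) + Y with Y ~ NegBin(k, p_tilde), p_tilde = p/(p+(1-p)pi).
    """
    pt = p / (p + (1.0 - p) * pi)
    log_pt, log_qt = math.log(pt), math.log1p(-pt)

    def lognb(mm):
        return gammaln(mm + k) - gammaln(k) - gammaln(mm + 1.0) + k * log_pt + mm * log_qt

    m = np.asarray(m, dtype=float)
    if pi >= 1.0:
        return lognb(m - 1.0)
    a = math.log1p(-pi) + lognb(m)  # Bernoulli part = 0
    with np.errstate(divide="ignore"):
        b = np.where(m >= 1.0, math.log(pi) + lognb(np.maximum(m - 1.0, 0.0)), -np.inf)
    return np.logaddexp(a, b)


def _snb_negloglik(x: np.ndarray, ms: np.ndarray, cs: np.ndarray, pi: float) -> float:
    logk, logitp = x
    k = math.exp(logk)
    p = 1.0 / (1.0 + math.exp(-logitp))
    logpm = _snb_sample_logpmf(ms, k, p, pi)
    if pi >= 1.0:
        log_trunc = 0.0
    else:
        log_p0 = _snb_sample_logpmf(np.array([0.0]), k, p, pi)[0]
        p0 = math.exp(log_p0)
        if p0 >= 1.0 - 1e-300:
            return 1e300
        log_trunc = math.log1p(-p0)
    val = -float(np.sum(cs * (logpm - log_trunc)))
    if not math.isfinite(val):
        return 1e300
    return val


_SNB_BOUNDS = [(-8.0, 8.0), (-10.0, 10.0)]  # (log k, logit p)
_SNB_STARTS = [
    (math.log(k0), math.log(p0 / (1 - p0)))
    for k0 in (1.0, 5.0)
    for p0 in (0.2, 0.7)
]


def estimate_snb(spec: FrequencySpectrum, ctx: SamplingContext) -> EstimateResult:
    """Zero-truncated ML fit of the subsampled SNB law; K estimated, never assumed.

    Convergence requires optimizer success, a small gradient of the
    per-class average log-likelihood, and an interior optimum; anything else
    is surfaced as ``converged=False`` with no estimate.
    """
    _check_spectrum(spec, ctx)
    ms, cs = spec.sizes_and_counts()
    ms = ms.astype(float)
    cs = cs.astype(float)
    u = spec.num_classes
    pi = ctx.pi

    best = None
    total_iters = 0
    any_success = False
    for x0 in _SNB_STARTS:
        res = optimize.minimize(
            _snb_negloglik,
            np.array(x0),
            args=(ms, cs, pi),
            method="L-BFGS-B",
            bounds=_SNB_BOUNDS,
            options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 500},
        )
        total_iters += int(res.nit)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    logk, logitp = best.x
    k_hat = math.exp(float(logk))
    p_hat = 1.0 / (1.0 + math.exp(-float(logitp)))

    # Convergence is declared on the projected gradient of the per-class
    # average log-likelihood; a fit parked on the Poisson limit of the
    # negative binomial (k large, p -> 1 with k(1-p) fixed) is a flat but
    # well-determined ridge and still counts, so the boundary is reported as
    # a diagnostic rather than a failure.
    grad_norm = float(np.max(np.abs(best.jac))) / max(u, 1)
    boundary = not (
        _SNB_BOUNDS[0][0] + 1e-3 < logk < _SNB_BOUNDS[0][1] - 1e-3
        and _SNB_BOUNDS[1][0] + 1e-3 < logitp < _SNB_BOUNDS[1][1] - 1e-3
    )
    converged = bool(any_success and best.success and grad_norm < 1e-6)

    diagnostics = {
        "loglik": -float(best.fun),
        "iterations": total_iters,
        "grad_norm_per_class": grad_norm,
        "boundary": boundary,
        "n_starts": len(_SNB_STARTS),
        "clamped": False,
    }
    if not converged:
        return EstimateResult("snb", None, False, {"k": k_hat, "p": p_hat}, diagnostics)

    if pi >= 1.0:
        p0 = 0.0
    else:
        p0 = math.exp(_snb_sample_logpmf(np.array([0.0]), k_hat, p_hat, pi)[0])
    K_hat = u / (1.0 - p0)
    raw = K_hat * (p_hat ** k_hat) / ctx.N
    lam, clamped = _clamp_unit(raw)
    diagnostics["clamped"] = clamped
    diagnostics["K_hat"] = K_hat
    return EstimateResult("snb", lam, True, {"k": k_hat, "p": p_hat}, diagnostics)


# ---------------------------------------------------------------------------
# Zayatz
# ---------------------------------------------------------------------------

def _log_hyp_prob_one(j: np.ndarray, n: int, N: int) -> np.ndarray:
    """log P(f=1 | F=j, n, N) = log[ j * C(N-j, n-1) / C(N, n) ] via log-gamma."""
    j = np.asarray(j, dtype=float)
    with np.errstate(invalid="ignore"):
        val = (
            np.log(j)
            + gammaln(N - j + 1)
            - gammaln(n)  # (n-1)!
            - gammaln(N - j - n + 2)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
        )
    return np.where(N - j >= n - 1, val, -np.inf)


def estimate_zayatz(spec: FrequencySpectrum, ctx: SamplingContext) -> EstimateResult:
    """Model-free plug-in estimator; closed form, always converges.

    P_hat(F=1 | f=1) plugs the observed sample class-size distribution in
    for the unknown population class-size distribution, with exact
    hypergeometric subsampling probabilities (exact at pi = 1 by
    construction).
    """
    _check_spectrum(spec, ctx)
    u1 = spec.num_singletons
    if u1 == 0:
        return EstimateResult(
            "zayatz", 0.0, True, {}, {"p_pop_unique_given_sample_unique": 0.0, "clamped": False}
        )
    js, cs = spec.sizes_and_counts()
    logp = _log_hyp_prob_one(js, ctx.n, ctx.N)
    weights = cs / spec.num_classes
    terms = np.where(np.isfinite(logp), np.exp(logp) * weights, 0.0)
    den = float(np.sum(terms))
    num = float(terms[js == 1][0])
    p_cond = num / den if den > 0 else 0.0
    raw = u1 * p_cond / (ctx.pi * ctx.N)
    lam, clamped = _clamp_unit(raw)
    return EstimateResult(
        "zayatz",
        lam,
        True,
        {},
        {"p_pop_unique_given_sample_unique": p_cond, "clamped": clamped},
    )


# ---------------------------------------------------------------------------
# mu-argus
# ---------------------------------------------------------------------------

def mu_argus_posterior_pmf(F: int, f: int, pi: float) -> float:
    """P(population class size = F | sample class size = f) under mu-argus.

    Shifted negative binomial posterior: F - f | f ~ NegBin(f, pi), i.e.
    P(F | f) = C(F-1, f-1) * pi^f * (1-pi)^(F-f) for F >= f.
    """
    if F < f or f < 1:
        return 0.0
    return math.comb(F - 1, f - 1) * (pi ** f) * ((1.0 - pi) ** (F - f))


def estimate_mu_argus(spec: FrequencySpectrum, ctx: SamplingContext) -> EstimateResult:
    """mu-argus (Benedetti–Franconi) model extended to a lambda3 estimate.

    Sums P(F=1 | f=1) over the sample uniques and rescales by 1/(pi*N),
    mirroring the Zayatz extension.  Deterministic closed form.
    """
    _check_spectrum(spec, ctx)
    u1 = spec.num_singletons
    pi = ctx.pi
    p_unique = mu_argus_posterior_pmf(1, 1, pi)
    raw = u1 * p_unique / (pi * ctx.N)
    lam, clamped = _clamp_unit(raw)
    return EstimateResult(
        "mu_argus",
        lam,
        True,
        {},
        {"p_pop_unique_given_sample_unique": p_unique, "clamped": clamped},
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

_ESTIMATORS: Dict[str, Callable[[FrequencySpectrum, SamplingContext], EstimateResult]] = {
    "pitman": estimate_pitman,
    "snb": estimate_snb,
    "zayatz": estimate_zayatz,
    "mu_argus": estimate_mu_argus,
}


def get_estimator(name: str) -> Callable[[FrequencySpectrum, SamplingContext], EstimateResult]:
    try:
        return _ESTIMATORS[name]
    except KeyError:
        raise ParameterError(
            f"unknown estimator {name!r}; available: {list(_ESTIMATORS)}"
        ) from None


def estimate_all(spec: FrequencySpectrum, ctx: SamplingContext) -> List[EstimateResult]:
    """Run all four estimators in stable order; individual failures never raise."""
    results = []
    for name in ESTIMATOR_NAMES:
        try:
            results.append(_ESTIMATORS[name](spec, ctx))
        except Exception as exc:  # estimator crash -> non-converged result
            results.append(
                EstimateResult(name, None, False, {}, {"error": repr(exc)})
            )
    return results
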