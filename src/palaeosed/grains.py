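"""Statistical models for single-grain equivalent-dose (D_e) distributions.

Single-grain luminescence dating yields, for each sediment sample, a set of
equivalent doses ``D_e`` (Gy) with individual standard errors. All models here
operate on ``log D_e``, where measurement error is well approximated by the
relative standard error of each grain:

* the **central age model (CAM)** fits a single dose population with an
  overdispersion term sigma beyond measurement error;
* the **finite mixture model (FMM)** fits k discrete dose components with a
  fixed between-grain overdispersion sigma_b, selecting k by BIC;
* the **minimum age model (MAM)** estimates the dose of the youngest grain
  population via a truncated-normal formulation in log space;
* **nMAD outlier rejection** removes grains whose robust z-score of log dose
  exceeds a threshold before CAM fitting;
* **reliability classification** labels a fitted distribution single-component,
  dominant-component (largest component holds >= 70% of grains) or mixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GrainSample",
    "ComponentFit",
    "ReliabilityClass",
    "nmad_outlier_filter",
    "central_age_model",
    "finite_mixture_model",
    "minimum_age_model",
    "classify_reliability",
]

#: Largest-component proportion at or above which a multi-component
#: distribution is treated as reliably dominated by a single population.
DOMINANCE_THRESHOLD = 0.70


@dataclass
class GrainSample:
    """Per-grain equivalent doses and errors for one dated sediment sample."""

    sample_id: str
    de: np.ndarray  # Gy, > 0
    se: np.ndarray  # Gy, > 0 (one-sigma per grain)
    mineral: str = "quartz"  # quartz | kfeldspar
    layer_id: str | None = None
    truth_component: np.ndarray | None = None  # synthetic-data labels

    def __post_init__(self) -> None:
        self.de = np.asarray(self.de, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.de.shape != self.se.shape:
            raise ValueError("de and se must have the same length")
        if np.any(self.de <= 0) or np.any(self.se <= 0):
            raise ValueError("all D_e and se values must be strictly positive")
        if self.mineral not in ("quartz", "kfeldspar"):
            raise ValueError(f"unknown mineral {self.mineral!r}")

    @property
    def n_grains(self) -> int:
        return self.de.size

    @property
    def log_de(self) -> np.ndarray:
        return np.log(self.de)

    @property
    def rel_se(self) -> np.ndarray:
        """Relative errors, used as standard errors of log D_e."""
        return self.se / self.de

    def subset(self, mask: np.ndarray) -> "GrainSample":
        truth = None if self.truth_component is None else self.truth_component[mask]
        return GrainSample(self.sample_id, self.de[mask], self.se[mask],
                           self.mineral, self.layer_id, truth)


@dataclass
class ComponentFit:
    """Fitted component structure of a D_e distribution.

    ``components`` holds ``(dose Gy, se Gy, proportion)`` triples sorted by
    ascending dose; proportions sum to one. ``overdispersion`` is the relative
    between-grain spread (sigma for CAM, the fixed sigma_b for FMM/MAM).
    """

    model: str  # CAM | FMM | MAM
    components: list[tuple[float, float, float]]
    overdispersion: float
    log_likelihood: float
    n_used: int
    n_rejected_outliers: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.components = sorted(self.components, key=lambda c: c[0])
        props = np.array([c[2] for c in self.components])
        if np.any(props <= 0) or np.any(props > 1 + 1e-9):
            raise ValueError("component proportions must lie in (0, 1]")
        if abs(props.sum() - 1.0) > 1e-6:
            raise ValueError("component proportions must sum to 1")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be non-negative")

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def dose(self) -> float:
        """Headline dose: the single component (CAM/MAM) or the largest one."""
        return max(self.components, key=lambda c: c[2])[0]

    @property
    def dose_se(self) -> float:
        return max(self.components, key=lambda c: c[2])[1]


@dataclass(frozen=True)
class ReliabilityClass:
    label: str  # single_component | dominant_component | mixed
    dominant_proportion: float


# ---------------------------------------------------------------------------
# Outlier rejection


def nmad_outlier_filter(
    sample: GrainSample, threshold: float = 2.0
) -> tuple[GrainSample, GrainSample]:
    """Reject grains whose normalized-MAD score of log D_e exceeds ``threshold``.

    The score of grain i is ``|log d_i - median| / (1.4826 * MAD)``. With zero
    spread (MAD = 0) no grain has a finite score and all are kept.

    Returns ``(kept, rejected)`` as two :class:`GrainSample` views.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if sample.n_grains < 5:
        raise ValueError("need at least 5 grains")
    z = sample.log_de
    med = np.median(z)
    dev = np.abs(z - med)
    mad = np.median(dev)
    if mad == 0:
        # zero spread: grains at the median have score 0/0 -> keep; any grain
        # off the median has an infinite score -> reject
        keep = dev == 0
    else:
        keep = dev / (1.4826 * mad) <= threshold
    if not keep.any():  # pragma: no cover - median grain always scores 0
        raise ValueError("all grains rejected: degenerate distribution")
    return sample.subset(keep), sample.subset(~keep)


# ---------------------------------------------------------------------------
# Central age model


def _cam_negloglik(params: np.ndarray, z: np.ndarray, s2: np.ndarray) -> float:
    mu, sigma = params
    v = sigma * sigma + s2
    return 0.5 * np.sum(np.log(2 * np.pi * v) + (z - mu) ** 2 / v)


def central_age_model(sample: GrainSample, n_rejected_outliers: int = 0) -> ComponentFit:
    """Maximum-likelihood CAM fit: ``log d_i ~ N(log delta, sigma^2 + s_i^2)``.

    Returns the characteristic dose ``delta`` (Gy) with its standard error from
    the observed information, and the overdispersion ``sigma`` (relative).
    """
    if sample.n_grains < 5:
        raise ValueError("need at least 5 grains for a CAM fit")
    z = sample.log_de
    s2 = sample.rel_se**2
    mu0 = np.average(z, weights=1.0 / s2)
    sig0 = max(np.sqrt(max(np.var(z) - s2.mean(), 0.0)), 1e-3)
    res = optimize.minimize(
        _cam_negloglik, x0=[mu0, sig0], args=(z, s2),
        method="L-BFGS-B", bounds=[(None, None), (0.0, None)],
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"CAM fit did not converge: {res.message}")
    mu, sigma = res.x
    w = 1.0 / (sigma * sigma + s2)
    se_mu = 1.0 / np.sqrt(w.sum())
    delta = float(np.exp(mu))
    return ComponentFit(
        model="CAM",
        components=[(delta, delta * float(se_mu), 1.0)],
        overdispersion=float(sigma),
        log_likelihood=float(-res.fun),
        n_used=sample.n_grains,
        n_rejected_outliers=n_rejected_outliers,
        extra={"log_dose": float(mu), "log_dose_se": float(se_mu)},
    )


# ---------------------------------------------------------------------------
# Finite mixture model


def _em_fit(z, sd, k, mu_init, max_iter=500, tol=1e-8):
    """One EM run of a k-component normal mixture with fixed per-grain sd."""
    n = z.size
    mu = np.array(mu_init, dtype=float)
    pi = np.full(k, 1.0 / k)
    prec = 1.0 / sd**2
    ll_old = -np.inf
    for _ in range(max_iter):
        # E-step: responsibilities (n, k)
        logp = (
            np.log(pi)[None, :]
            - 0.5 * np.log(2 * np.pi * sd[:, None] ** 2)
            - 0.5 * (z[:, None] - mu[None, :]) ** 2 * prec[:, None]
        )
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        r = p / tot
        ll = float(np.sum(m.ravel() + np.log(tot.ravel())))
        # M-step
        nk = r.sum(axis=0)
        pi = nk / n
        wk = r * prec[:, None]
        denom = wk.sum(axis=0)
        mu = np.where(denom > 0, (wk * z[:, None]).sum(axis=0) / np.maximum(denom, 1e-300), mu)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    se = 1.0 / np.sqrt(np.maximum((r * prec[:, None]).sum(axis=0), 1e-300))
    return mu, pi, se, ll


def finite_mixture_model(
    sample: GrainSample,
    k_candidates: list[int] | None = None,
    sigma_b: float = 0.10,
    n_restarts: int = 10,
    seed: int = 0,
) -> ComponentFit:
    """Fit log-normal dose mixtures for each candidate k; select k by BIC.

    ``sigma_b`` is the fixed relative overdispersion added in quadrature to each
    grain's relative error. Each k is fitted with ``n_restarts`` EM runs started
    from jittered dose quantiles (deterministic for fixed ``seed``); ties in BIC
    break toward higher likelihood, then lower k. Components whose proportion
    collapses are dropped and the smaller mixture refitted.
    """
    if sigma_b < 0:
        raise ValueError("sigma_b must be non-negative")
    if k_candidates is None:
        k_candidates = list(range(1, max(2, sample.n_grains // 3) + 1))[:4]
    if not k_candidates:
        raise ValueError("k_candidates must be non-empty")
    if max(k_candidates) > sample.n_grains / 3:
        raise ValueError("max k exceeds n_grains / 3")
    z = sample.log_de
    sd = np.sqrt(sample.rel_se**2 + sigma_b**2)
    n = z.size
    rng = np.random.default_rng(seed)

    def fit_k(k):
        best = None
        qs = np.quantile(z, np.linspace(0.1, 0.9, k))
        for _ in range(n_restarts):
            init = qs + rng.normal(0, 0.25 * (z.std() + 1e-6), size=k)
            mu, pi, se, ll = _em_fit(z, sd, k, init)
            if best is None or ll > best[3]:
                best = (mu, pi, se, ll)
        return best

    results = {}
    for k in sorted(set(k_candidates)):
        mu, pi, se, ll = fit_k(k)
        # drop collapsed components and refit at reduced k
        while k > 1 and pi.min() < 1e-3:
            k -= 1
            mu, pi, se, ll = fit_k(k)
        bic = -2 * ll + (2 * k - 1) * np.log(n)
        if k not in results or ll > results[k][3]:
            results[k] = (mu, pi, se, ll, bic)

    # select by BIC; ties -> higher likelihood, then lower k
    best_k = min(results, key=lambda k: (round(results[k][4], 9), -results[k][3], k))
    mu, pi, se, ll, bic = results[best_k]
    order = np.argsort(mu)
    comps = [
        (float(np.exp(mu[j])), float(np.exp(mu[j]) * se[j]), float(pi[j]))
        for j in order
    ]
    # renormalise tiny float drift
    tot = sum(c[2] for c in comps)
    comps = [(d, s, p / tot) for d, s, p in comps]
    return ComponentFit(
        model="FMM",
        components=comps,
        overdispersion=float(sigma_b),
        log_likelihood=float(ll),
        n_used=n,
        extra={"bic": {k: float(v[4]) for k, v in results.items()}},
    )


# ---------------------------------------------------------------------------
# Minimum age model


def _mam_negloglik(params, z, se2):
    """Negative log-likelihood of the 3-parameter minimum age model.

    Latent log doses: a proportion ``p`` exactly at the minimum ``gamma``
    (fully bleached grains), the rest a normal of mean ``gamma`` and sd
    ``sigma`` truncated below at ``gamma`` (partially bleached / intruded
    grains); each observation adds Gaussian noise of variance ``se2``.
    """
    logit_p, gamma, log_sigma = params
    p = 1.0 / (1.0 + np.exp(-logit_p))
    sigma = np.exp(log_sigma)
    sig0 = np.sqrt(1.0 / (1.0 / sigma**2 + 1.0 / se2))
    mu0 = (gamma / sigma**2 + z / se2) * sig0**2
    log_point = stats.norm.logpdf(z, gamma, np.sqrt(se2))
    log_trunc = (
        np.log(2.0)
        + stats.norm.logpdf(z, gamma, np.sqrt(sigma**2 + se2))
        + stats.norm.logcdf((mu0 - gamma) / sig0)
    )
    logf = np.logaddexp(np.log(p) + log_point, np.log1p(-p) + log_trunc)
    val = -np.sum(logf)
    return val if np.isfinite(val) else 1e12


def minimum_age_model(
    sample: GrainSample, sigma_b: float = 0.10
) -> ComponentFit:
    """Estimate the dose of the youngest grain population (3-parameter MAM).

    Log doses follow a point mass of weight ``p`` at the log minimum dose
    ``gamma`` plus a normal of mean ``gamma``, sd ``sigma``, truncated below at
    ``gamma``; each grain adds measurement noise ``sqrt(s_i^2 + sigma_b^2)``.
    ``exp(gamma)`` is reported with a profile-likelihood standard error. When
    the truncation is uninformative (all grains consistent with a single dose)
    the CAM result is returned with a warning.
    """
    if sigma_b < 0:
        raise ValueError("sigma_b must be non-negative")
    if sample.n_grains < 5:
        raise ValueError("need at least 5 grains")
    z = sample.log_de
    se2 = sample.rel_se**2 + sigma_b**2
    x0 = [0.0, np.quantile(z, 0.05), np.log(max(z.std(), 0.05))]
    res = optimize.minimize(_mam_negloglik, x0, args=(z, se2), method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9})
    gamma_hat = res.x[1]
    cam = central_age_model(sample)

    # profile-likelihood curvature in gamma
    def profile(g):
        r = optimize.minimize(
            lambda q: _mam_negloglik([q[0], g, q[1]], z, se2),
            res.x[[0, 2]], method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-7, "fatol": 1e-9})
        return -r.fun

    h = 0.02
    l0 = -res.fun
    curv = (profile(gamma_hat + h) - 2 * l0 + profile(gamma_hat - h)) / h**2
    flat = curv >= -1e-6
    if flat or not np.isfinite(l0):
        warnings.warn(
            "MAM likelihood surface flat; falling back to CAM", RuntimeWarning)
        fit = cam
        return ComponentFit(
            model="MAM", components=fit.components,
            overdispersion=fit.overdispersion, log_likelihood=fit.log_likelihood,
            n_used=fit.n_used, extra={"fallback_cam": True},
        )
    se_gamma = float(np.sqrt(-1.0 / curv))
    dose = float(np.exp(gamma_hat))
    return ComponentFit(
        model="MAM",
        components=[(dose, dose * se_gamma, 1.0)],
        overdispersion=float(sigma_b),
        log_likelihood=float(l0),
        n_used=sample.n_grains,
        extra={"gamma": float(gamma_hat), "gamma_se": se_gamma,
               "p": float(1.0 / (1.0 + np.exp(-res.x[0]))),
               "sigma": float(np.exp(res.x[2])), "fallback_cam": False},
    )


# ---------------------------------------------------------------------------
# Reliability classification


def classify_reliability(fit: ComponentFit) -> ReliabilityClass:
    """Label a fit single_component, dominant_component (max proportion >= 70%)
    or mixed. Invariant to component ordering."""
    dom = max(c[2] for c in fit.components)
    if fit.k == 1:
        label = "single_component"
    elif dom >= DOMINANCE_THRESHOLD:
        label = "dominant_component"
    else:
        label = "mixed"
    return ReliabilityClass(label=label, dominant_proportion=float(dom))
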