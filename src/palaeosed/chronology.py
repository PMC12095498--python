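"""Bayesian stratigraphic age model: ordered phases fitted by MCMC.

Layers (phases) are ordered oldest to youngest, each bounded by a start (older)
and end (younger) boundary in ka before present. Sample i in phase p has a
latent true age ``theta_i`` uniform a priori on ``[end_p, start_p]`` and an
observed age ``age_i ~ Normal(theta_i, unshared_se_i^2)`` — only the random
(unshared) error component enters the likelihood. Boundaries are a priori
uniformly ordered below ``prior_max_age``; adjacent phases may either share a
boundary (no gaps) or have a free gap between them.

The sampler is Metropolis-within-Gibbs: latent ages are drawn exactly from
their truncated-normal conditionals; boundaries take random-walk Metropolis
steps whose scales are tuned to a 20-40% acceptance rate during burn-in and
frozen afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .ages import AgeEstimate

__all__ = [
    "PhaseModel",
    "BoundaryPosterior",
    "build_phase_model",
    "sample_posterior",
    "summarize_boundaries",
    "hpd_interval",
]


@dataclass
class PhaseModel:
    """Ordered phases (oldest -> youngest) with their member ages."""

    phases: list[tuple[str, list[AgeEstimate]]]
    allow_gaps: bool = True
    prior_max_age: float = 500.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("need at least one phase")
        ages = [a.age for _, members in self.phases for a in members]
        if ages and max(ages) >= self.prior_max_age:
            raise ValueError("prior_max_age must exceed all observed ages")
        for pid, members in self.phases:
            if not members:
                warnings.warn(f"phase {pid!r} has no samples", RuntimeWarning)

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def n_boundaries(self) -> int:
        """Free boundaries: 2 per phase with gaps, n+1 without."""
        p = self.n_phases
        return 2 * p if self.allow_gaps else p + 1


def build_phase_model(
    layer_order: list[str],
    age_table: pd.DataFrame,
    allow_gaps: bool = True,
    prior_max_age: float = 500.0,
) -> PhaseModel:
    """Build a phase model from a layer order (oldest first) and an age table.

    ``age_table`` needs columns ``sample``, ``layer``, ``age``, ``unshared_se``
    (ka). Every sample must map to a layer in ``layer_order``.
    """
    known = set(layer_order)
    bad = set(age_table["layer"]) - known
    if bad:
        raise ValueError(f"samples mapped to unknown layers: {sorted(bad)}")
    phases = []
    for lid in layer_order:
        rows = age_table[age_table["layer"] == lid]
        members = [
            AgeEstimate(age=float(r.age), unshared_se=float(r.unshared_se),
                        shared_se=0.0, sample_id=str(r.sample))
            for r in rows.itertuples()
        ]
        phases.append((lid, members))
    return PhaseModel(phases=phases, allow_gaps=allow_gaps,
                      prior_max_age=prior_max_age)


@dataclass
class BoundaryPosterior:
    """Retained MCMC draws for boundaries and per-sample modelled ages."""

    phase_ids: list[str]
    starts: np.ndarray  # (n_draws, n_phases), ka
    ends: np.ndarray    # (n_draws, n_phases), ka
    sample_ids: list[str]
    thetas: np.ndarray  # (n_draws, n_samples), ka
    acceptance: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.starts.shape[0]


def _phase_layout(model: PhaseModel):
    """Map phases to indices into the internal boundary vector.

    The vector is ordered old -> young and must be non-increasing. With gaps:
    ``[s1, e1, s2, e2, ...]``; without: ``[s1, s2, ..., s_P, e_P]`` where
    ``e_p = s_(p+1)``.
    """
    P = model.n_phases
    if model.allow_gaps:
        return [(2 * p, 2 * p + 1) for p in range(P)], 2 * P
    return [(p, p + 1) for p in range(P)], P + 1


def _init_state(model: PhaseModel, layout, nb):
    ages = [np.array([a.age for a in m]) for _, m in model.phases]
    hi = np.empty(model.n_phases)
    lo = np.empty(model.n_phases)
    prev = model.prior_max_age * 0.95
    for p, a in enumerate(ages):
        if a.size:
            hi[p], lo[p] = a.max(), a.min()
        else:
            hi[p] = lo[p] = prev * 0.9
        prev = lo[p]
    b = np.empty(nb)
    for p, (si, ei) in enumerate(layout):
        b[si] = hi[p] * 1.05 + 1.0
        b[ei] = max(lo[p] * 0.95 - 1.0, 0.0)
    # enforce non-increasing order old -> young
    for j in range(1, nb):
        b[j] = min(b[j], b[j - 1] - 1e-6)
    b = np.maximum(b, 0.0)
    for j in range(nb - 2, -1, -1):
        b[j] = max(b[j], b[j + 1] + 1e-6)
    if b[0] >= model.prior_max_age:
        offenders = [pid for (pid, m) in model.phases
                     if m and max(a.age for a in m) * 1.05 + 1 >= model.prior_max_age]
        raise RuntimeError(
            "cannot initialize ordered boundaries under prior_max_age; "
            f"offending phases: {offenders or [model.phases[0][0]]}")
    return b


def _trunc_norm(rng, mean, sd, lo, hi):
    """Exact truncated-normal draws via inverse CDF (vectorized)."""
    a = ndtr((lo - mean) / sd)
    bb = ndtr((hi - mean) / sd)
    u = rng.uniform(a, np.maximum(bb, a + 1e-15))
    x = mean + sd * ndtri(np.clip(u, 1e-15, 1 - 1e-15))
    return np.clip(x, lo, hi)


def sample_posterior(
    model: PhaseModel,
    n_iter: int = 20000,
    n_burn: int = 4000,
    seed: int = 0,
) -> BoundaryPosterior:
    """Run the Metropolis-within-Gibbs sampler; deterministic for fixed seed."""
    if not n_iter > n_burn >= 0:
        raise ValueError("need n_iter > n_burn >= 0")
    rng = np.random.default_rng(seed)
    layout, nb = _phase_layout(model)
    P = model.n_phases
    b = _init_state(model, layout, nb)

    sample_ids, obs, obs_se, phase_of = [], [], [], []
    for p, (_, members) in enumerate(model.phases):
        for a in members:
            sample_ids.append(a.sample_id or f"s{len(sample_ids)}")
            obs.append(a.age)
            obs_se.append(a.unshared_se)
            phase_of.append(p)
    obs = np.array(obs)
    obs_se = np.array(obs_se)
    phase_of = np.array(phase_of, dtype=int)
    n_per_phase = np.bincount(phase_of, minlength=P)
    theta = np.clip(obs, [b[layout[p][1]] for p in phase_of],
                    [b[layout[p][0]] for p in phase_of])

    scales = np.full(nb, max(obs_se.mean() if obs_se.size else 1.0, 1e-3))
    acc = np.zeros(nb)
    prop = np.zeros(nb)
    keep = n_iter - n_burn
    starts = np.empty((keep, P))
    ends = np.empty((keep, P))
    thetas = np.empty((keep, obs.size))

    start_idx = np.array([layout[p][0] for p in range(P)])
    end_idx = np.array([layout[p][1] for p in range(P)])
    # which phases each boundary index belongs to (span factor bookkeeping)
    phases_of_b = [[] for _ in range(nb)]
    for p in range(P):
        phases_of_b[layout[p][0]].append(p)
        phases_of_b[layout[p][1]].append(p)

    def log_span_factor(bvec, plist):
        out = 0.0
        for p in plist:
            span = bvec[start_idx[p]] - bvec[end_idx[p]]
            if span <= 0:
                return -np.inf
            out -= n_per_phase[p] * np.log(span)
        return out

    for it in range(n_iter):
        # Gibbs update of latent ages within their phase intervals
        if obs.size:
            lo = b[end_idx][phase_of]
            hi = b[start_idx][phase_of]
            theta = _trunc_norm(rng, obs, obs_se, lo, hi)
        # Metropolis update of each boundary
        for j in rng.permutation(nb):
            upper = b[j - 1] if j > 0 else model.prior_max_age
            lower = b[j + 1] if j < nb - 1 else 0.0
            # boundary must keep its phases' latent ages inside
            for p in phases_of_b[j]:
                mask = phase_of == p
                if not mask.any():
                    continue
                if j == start_idx[p]:
                    lower = max(lower, theta[mask].max())
                else:
                    upper = min(upper, theta[mask].min())
            newb = b[j] + rng.normal(0, scales[j])
            prop[j] += 1
            if not (lower <= newb <= upper):
                continue
            old_lf = log_span_factor(b, phases_of_b[j])
            bj_old = b[j]
            b[j] = newb
            new_lf = log_span_factor(b, phases_of_b[j])
            if np.log(rng.random() + 1e-300) < new_lf - old_lf:
                acc[j] += 1
            else:
                b[j] = bj_old
        # tune proposal scales during burn-in only
        if it < n_burn and (it + 1) % 100 == 0:
            rate = np.divide(acc, np.maximum(prop, 1))
            scales *= np.where(rate > 0.40, 1.25, np.where(rate < 0.20, 0.8, 1.0))
            acc[:] = 0
            prop[:] = 0
        if it >= n_burn:
            k = it - n_burn
            starts[k] = b[start_idx]
            ends[k] = b[end_idx]
            thetas[k] = theta

    rate = dict(zip(range(nb), np.divide(acc, np.maximum(prop, 1))))
    ess = {}
    for p, (pid, _) in enumerate(model.phases):
        ess[f"{pid}:start"] = _ess(starts[:, p])
        ess[f"{pid}:end"] = _ess(ends[:, p])
    return BoundaryPosterior(
        phase_ids=[pid for pid, _ in model.phases],
        starts=starts, ends=ends, sample_ids=sample_ids, thetas=thetas,
        acceptance={f"b{j}": float(r) for j, r in rate.items()}, ess=ess,
    )


def _ess(x: np.ndarray, max_lag: int | None = None) -> float:
    """Effective sample size from the initial positive autocorrelation sum."""
    n = x.size
    if n < 10 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    max_lag = max_lag or min(n // 3, 1000)
    var = float(xc @ xc) / n
    s = 0.0
    for lag in range(1, max_lag):
        rho = float(xc[:-lag] @ xc[lag:]) / ((n - lag) * var)
        if rho < 0.05:
            break
        s += rho
    return float(n / (1 + 2 * s))


def hpd_interval(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the draws."""
    x = np.sort(np.asarray(draws))
    n = x.size
    m = max(int(np.ceil(level * n)), 1)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def summarize_boundaries(
    post: BoundaryPosterior,
    levels: tuple[float, ...] = (0.68, 0.95),
    min_draws: int = 1000,
    round_years: int | None = None,
) -> pd.DataFrame:
    """Highest-posterior-density summaries per boundary.

    One row per (phase, start|end) with the posterior mean and HPD bounds at
    each level, in ka — or in years rounded to the nearest ``round_years``
    (e.g. 10 for nearest-decade reporting).
    """
    if post.n_draws < min_draws:
        raise ValueError(f"need >= {min_draws} retained draws, have {post.n_draws}")

    def conv(v: float) -> float:
        if round_years is None:
            return float(v)
        return float(np.round(v * 1000.0 / round_years) * round_years)

    rows = []
    for p, pid in enumerate(post.phase_ids):
        for kind, draws in (("start", post.starts[:, p]), ("end", post.ends[:, p])):
            row = {"phase": pid, "boundary": kind, "mean": conv(draws.mean())}
            for lev in sorted(levels):
                lo, hi = hpd_interval(draws, lev)
                row[f"hpd{int(round(lev * 100))}_lower"] = conv(lo)
                row[f"hpd{int(round(lev * 100))}_upper"] = conv(hi)
            rows.append(row)
    return pd.DataFrame(rows)
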