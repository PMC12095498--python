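"""Optical-age arithmetic: D_e / dose rate, and weighted combination of paired
quartz-OSL and K-feldspar-pIRIR ages.

Age uncertainties are kept as two components: the *unshared* (random) part,
independent between the two minerals of a sample, and the *shared* (systematic)
part common to both (dose-rate conversion factors, internal-K value, cosmic-ray
estimate). Only unshared errors weight the paired-age mean; the shared relative
error is re-added in quadrature to the combined uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DoseRate",
    "AgeEstimate",
    "compute_age",
    "combine_paired_ages",
    "ratio_consistency",
]


@dataclass(frozen=True)
class DoseRate:
    """Total environmental dose rate (Gy/ka) with its random/systematic split."""

    total: float
    random_se: float = 0.0
    systematic_se: float = 0.0

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("dose rate must be positive")
        if self.random_se < 0 or self.systematic_se < 0:
            raise ValueError("standard errors must be non-negative")


@dataclass(frozen=True)
class AgeEstimate:
    """An age in ka with unshared (random) and shared (systematic) errors."""

    age: float
    unshared_se: float
    shared_se: float
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.unshared_se < 0 or self.shared_se < 0:
            raise ValueError("standard errors must be non-negative")

    @property
    def total_se(self) -> float:
        return math.hypot(self.unshared_se, self.shared_se)


def compute_age(de: tuple[float, float], dr: DoseRate,
                sample_id: str | None = None) -> AgeEstimate:
    """Age = D_e / dose rate, with relative errors propagated in quadrature.

    The D_e error and the dose rate's random error feed the unshared component;
    the dose rate's systematic error feeds the shared component.
    """
    de_val, de_se = de
    if de_val <= 0 or de_se < 0:
        raise ValueError("D_e must be positive with non-negative se")
    age = de_val / dr.total
    unshared_rel = math.hypot(de_se / de_val, dr.random_se / dr.total)
    shared_rel = dr.systematic_se / dr.total
    return AgeEstimate(age=age, unshared_se=age * unshared_rel,
                       shared_se=age * shared_rel, sample_id=sample_id)


def combine_paired_ages(
    a_osl: AgeEstimate,
    a_pirir: AgeEstimate,
    shared_rel_override: float | None = None,
) -> AgeEstimate:
    """Inverse-variance weighted mean of a paired OSL/pIRIR age.

    Weights are the inverse squares of the *unshared* errors. The shared
    relative error added back in quadrature is the mean of the pair's shared
    relative errors, unless ``shared_rel_override`` is given (e.g. a
    dataset-average value such as 0.04).
    """
    if a_osl.sample_id is not None and a_pirir.sample_id is not None \
            and a_osl.sample_id != a_pirir.sample_id:
        raise ValueError(
            f"mismatched sample ids: {a_osl.sample_id!r} vs {a_pirir.sample_id!r}")
    if a_osl.unshared_se <= 0 or a_pirir.unshared_se <= 0:
        raise ValueError("unshared errors must be positive to weight the mean")
    w1 = a_osl.unshared_se**-2
    w2 = a_pirir.unshared_se**-2
    mean = (w1 * a_osl.age + w2 * a_pirir.age) / (w1 + w2)
    unshared = 1.0 / math.sqrt(w1 + w2)
    if shared_rel_override is not None:
        shared_rel = shared_rel_override
    else:
        shared_rel = 0.5 * (a_osl.shared_se / a_osl.age
                            + a_pirir.shared_se / a_pirir.age)
    return AgeEstimate(age=mean, unshared_se=unshared,
                       shared_se=mean * shared_rel, sample_id=a_osl.sample_id)


def ratio_consistency(
    pairs: list[tuple[AgeEstimate, AgeEstimate]],
) -> tuple[float, float, bool]:
    """Mean OSL/pIRIR age ratio across pairs with its standard error.

    Returns ``(mean ratio, se of mean, consistent)`` where ``consistent`` is
    true when the mean ratio lies within 1.96 standard errors of unity — the
    check that paired ages from the two minerals agree, as expected for
    sediments fully bleached by sunlight at deposition.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    ratios = []
    for osl, pirir in pairs:
        if pirir.age == 0:
            raise ValueError("zero pIRIR age")
        ratios.append(osl.age / pirir.age)
    r = np.asarray(ratios)
    mean = float(r.mean())
    sem = float(r.std(ddof=1) / math.sqrt(r.size))
    consistent = abs(mean - 1.0) <= 1.96 * sem
    return mean, sem, consistent
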