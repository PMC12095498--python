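"""Per-sample, per-family ancient-DNA authentication.

A family's fragments in a sample count as ancient only when (1) the family
holds at least 1% of all family-assigned fragments, (2) at least 10 assigned
fragments are putatively deaminated (terminal C-to-T at the 5' or 3' end), and
(3) the terminal C-to-T substitution frequency is significantly above 10% —
its 95% binomial confidence interval's lower bound exceeds 0.10 — at either
terminus (or both, configurable). Ancient DNA accumulates deamination damage;
modern contaminants do not, so their terminal substitution rates stay near the
sequencing-error floor and fail criterion 3.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .reads import AssignmentProfile, Fragment

__all__ = [
    "AuthenticationResult",
    "binomial_lower_bound",
    "authenticate_family",
    "select_best_reference",
]


@dataclass
class AuthenticationResult:
    sample_id: str
    family: str
    n_assigned: int
    family_fraction: float
    n_deaminated: int
    ct5: tuple[int, int, float]  # (k converted, n reference-C termini, lower bound)
    ct3: tuple[int, int, float]
    c1_abundance: bool
    c2_deam_count: bool
    c3_significance: bool

    @property
    def authenticated(self) -> bool:
        return self.c1_abundance and self.c2_deam_count and self.c3_significance


def binomial_lower_bound(k: int, n: int, conf: float = 0.95,
                         method: str = "clopper-pearson") -> float:
    """Lower bound of the two-sided binomial CI for k successes in n trials.

    Clopper-Pearson (the exact interval, matching R's ``binom.test``) by
    default; Wilson selectable. ``k == 0`` gives 0 by convention.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need n >= 1 and 0 <= k <= n")
    if k == 0:
        return 0.0
    alpha = 1.0 - conf
    if method == "clopper-pearson":
        return float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    if method == "wilson":
        lo, _ = proportion_confint(k, n, alpha=alpha, method="wilson")
        return float(lo)
    raise ValueError(f"unknown CI method {method!r}")


def select_best_reference(fragments: list[Fragment], family: str) -> str | None:
    """Genome of ``family`` with the most aligned fragments (tie: lexicographic
    smallest genome id, so the choice is stable across runs)."""
    counts: dict[str, int] = {}
    for f in fragments:
        a = f.alignment
        if a is not None and a.family == family:
            counts[a.genome] = counts.get(a.genome, 0) + 1
    if not counts:
        return None
    return min(counts, key=lambda g: (-counts[g], g))


def authenticate_family(
    profile: AssignmentProfile,
    family: str,
    fragments: list[Fragment],
    min_fraction: float = 0.01,
    min_deaminated: int = 10,
    freq_threshold: float = 0.10,
    conf: float = 0.95,
    termini: str = "either",
    ci_method: str = "clopper-pearson",
) -> AuthenticationResult:
    """Apply the three ancientness criteria to one family in one sample.

    ``fragments`` should already be restricted to the family's best reference
    genome (see :func:`select_best_reference`). Terminal substitution
    frequencies use fragments with a reference C at the terminus as the
    denominator. ``termini='either'`` requires the CI rule at one terminus;
    ``'both'`` at both.
    """
    if termini not in ("either", "both"):
        raise ValueError(f"unknown termini rule {termini!r}")
    fam_frags = [f for f in fragments
                 if f.alignment is not None and f.alignment.family == family]
    n_assigned = len(fam_frags)
    frac = profile.fraction(family)
    n_deam = sum(1 for f in fam_frags if f.deaminated)

    n5 = sum(1 for f in fam_frags if f.ref_c_5p)
    k5 = sum(1 for f in fam_frags if f.terminal_ct_5p)
    n3 = sum(1 for f in fam_frags if f.ref_c_3p)
    k3 = sum(1 for f in fam_frags if f.terminal_ct_3p)
    lb5 = binomial_lower_bound(k5, n5, conf, ci_method) if n5 else 0.0
    lb3 = binomial_lower_bound(k3, n3, conf, ci_method) if n3 else 0.0

    sig5 = lb5 > freq_threshold
    sig3 = lb3 > freq_threshold
    c3 = (sig5 or sig3) if termini == "either" else (sig5 and sig3)
    return AuthenticationResult(
        sample_id=profile.sample_id,
        family=family,
        n_assigned=n_assigned,
        family_fraction=frac,
        n_deaminated=n_deam,
        ct5=(k5, n5, lb5),
        ct3=(k3, n3, lb3),
        c1_abundance=frac >= min_fraction,
        c2_deam_count=n_deam >= min_deaminated,
        c3_significance=c3,
    )
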