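"""Mitochondrial group calls and hominin lineage assignment.

Groups (e.g. Denisovan, Neanderthal, ancient modern human; hyaenid haplogroups
A/D; cave vs brown bear) are called from fragments overlapping the group's
diagnostic positions: the call requires the derived state to be supported by
significantly more than 10% of informative sequences (95% binomial CI) and at
three or more unique diagnostic positions. Modern-human calls use deaminated
fragments only, to exclude present-day contamination.

Lineage assignment scores each hominin fragment by k-mers unique to one
lineage haplotype (an emulation of pseudoalignment with equivalence-class
ambiguity resolved to "unassigned"), pools Denisova 3 with 4 and Denisova 2
with 8, and calls pools holding at least 20% of the identified sequences —
for samples with at least 250 endogenous ancient hominin sequences, after
subtracting the modern-human contaminant estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import pandas as pd

from .authenticate import binomial_lower_bound
from .reads import Fragment, revcomp

__all__ = [
    "GroupCall",
    "LineageCall",
    "call_group",
    "estimate_contamination",
    "assign_lineage",
    "LINEAGE_POOLS",
]

LINEAGE_POOLS = {
    "Denisova3": "Denisova3/4",
    "Denisova4": "Denisova3/4",
    "Denisova2": "Denisova2/8",
    "Denisova8": "Denisova2/8",
    "Neanderthal": "Neanderthal",
    "ModernHuman": "ModernHuman",
}


@dataclass
class GroupCall:
    sample_id: str
    family: str
    group: str
    n_informative: int
    n_supporting: int
    support_fraction: float
    lower_bound: float
    n_unique_diag_positions_supported: int
    deaminated_only: bool
    conflicts: int = 0  # fragments also supporting another group's derived state

    @property
    def called(self) -> bool:
        return (self.lower_bound > 0.10
                and self.n_unique_diag_positions_supported >= 3)


@dataclass
class LineageCall:
    sample_id: str
    n_hominin_unique: int
    n_contaminant_est: int
    n_endogenous: int
    assigned_counts: dict = field(default_factory=dict)   # per lineage
    pooled_counts: dict = field(default_factory=dict)     # per pool
    shares: dict = field(default_factory=dict)            # pool -> share
    called: list = field(default_factory=list)
    eligible: bool = False


def _read_base_at(fragment: Fragment, pos: int, L: int) -> str | None:
    """Base the (strand-normalized) read shows at 1-based genome ``pos``."""
    a = fragment.alignment
    if a is None:
        return None
    off = (pos - a.start) % L
    if off >= len(fragment):
        return None
    read_fwd = fragment.sequence if a.strand == "+" else revcomp(fragment.sequence)
    return read_fwd[off]


def call_group(
    fragments: list[Fragment],
    diagnostic_table: pd.DataFrame,
    group: str,
    deaminated_only: bool = False,
    genome_length: int | None = None,
    sample_id: str = "sample",
    conf: float = 0.95,
) -> GroupCall:
    """Call one mitochondrial group from diagnostic-position support.

    Informative fragments overlap at least one of the group's diagnostic
    positions; supporting fragments carry the derived base at one of them.
    For the ModernHuman group only deaminated fragments are considered,
    regardless of ``deaminated_only``.
    """
    diag = diagnostic_table[diagnostic_table.group == group]
    if diag.pos.nunique() < 3:
        raise ValueError(f"group {group!r} has fewer than 3 diagnostic positions")
    family = diag.family.iloc[0]
    if group == "ModernHuman":
        deaminated_only = True
    pool = [f for f in fragments
            if f.alignment is not None and f.alignment.family == family]
    if deaminated_only:
        pool = [f for f in pool if f.deaminated]
    other = diagnostic_table[diagnostic_table.group != group]

    n_informative = n_supporting = conflicts = 0
    supported_positions = set()
    for f in sorted(pool, key=lambda fr: fr.id):
        gl = genome_length or _genome_length_hint(f)
        bases = {int(row.pos): _read_base_at(f, int(row.pos), gl)
                 for row in diag.itertuples()}
        hit = {p: b for p, b in bases.items() if b is not None}
        if not hit:
            continue
        n_informative += 1
        derived_at = [p for p, b in hit.items()
                      if b == diag.loc[diag.pos == p, "derived"].iloc[0]]
        if derived_at:
            n_supporting += 1
            supported_positions.update(derived_at)
            for row in other[other.family == family].itertuples():
                ob = _read_base_at(f, int(row.pos), gl)
                if ob is not None and ob == row.derived:
                    conflicts += 1
                    break
    frac = n_supporting / n_informative if n_informative else 0.0
    lb = (binomial_lower_bound(n_supporting, n_informative, conf)
          if n_informative else 0.0)
    return GroupCall(
        sample_id=sample_id, family=family, group=group,
        n_informative=n_informative, n_supporting=n_supporting,
        support_fraction=frac, lower_bound=lb,
        n_unique_diag_positions_supported=len(supported_positions),
        deaminated_only=deaminated_only, conflicts=conflicts,
    )


def _genome_length_hint(fragment: Fragment) -> int:
    # alignments never wrap more than once, so any large bound works when the
    # true circular length is unknown; callers should pass genome_length
    a = fragment.alignment
    return max(a.end, 10**9)


def estimate_contamination(
    hominin_fragments: list[Fragment],
    modern_diagnostics: pd.DataFrame,
    genome_length: int | None = None,
) -> int:
    """Count unique hominin fragments carrying the modern-human derived state
    at one or more modern-specific diagnostic positions.

    A fragment that also supports an archaic state elsewhere still counts as
    contaminant (a conservative rule for the endogenous-count subtraction).
    """
    if modern_diagnostics.empty:
        raise ValueError("modern-human diagnostic set must be non-empty")
    n = 0
    for f in hominin_fragments:
        if f.alignment is None:
            continue
        gl = genome_length or _genome_length_hint(f)
        for row in modern_diagnostics.itertuples():
            b = _read_base_at(f, int(row.pos), gl)
            if b is not None and b == row.derived:
                n += 1
                break
    return n


def _unique_kmers(haplotypes: dict, k: int) -> dict:
    """k-mers (both strands) occurring in exactly one lineage haplotype."""
    per_lin = {}
    for lin, seq in haplotypes.items():
        dbl = seq + seq[: k - 1]
        mers = {dbl[i:i + k] for i in range(len(seq))}
        mers |= {revcomp(m) for m in mers}
        per_lin[lin] = mers
    counts: dict[str, int] = {}
    for mers in per_lin.values():
        for m in mers:
            counts[m] = counts.get(m, 0) + 1
    return {lin: {m for m in mers if counts[m] == 1}
            for lin, mers in per_lin.items()}


def assign_lineage(
    hominin_fragments: list[Fragment],
    lineage_haplotypes: dict,
    k: int = 16,
    min_total: int = 250,
    min_share: float = 0.20,
    modern_diagnostics: pd.DataFrame | None = None,
    genome_length: int | None = None,
    sample_id: str = "sample",
    collapse_duplicates: bool = True,
) -> LineageCall:
    """Assign hominin fragments to specific mtDNA lineages by unique k-mers.

    Each fragment is scored by how many k-mers unique to each lineage it
    contains and assigned to the single top-scoring lineage (ties or no unique
    k-mer: unassigned). Pool shares are computed over identified (assigned)
    fragments. A sample is eligible for lineage identification only when its
    endogenous count (unique hominin fragments minus the contaminant estimate)
    reaches ``min_total``.
    """
    if len(lineage_haplotypes) < 2:
        raise ValueError("need at least 2 lineage haplotypes")
    if any(k >= len(s) for s in lineage_haplotypes.values()):
        raise ValueError("k must be smaller than the haplotype length")
    frags = [f for f in hominin_fragments if f.alignment is not None]
    if collapse_duplicates:
        seen = {}
        for f in frags:
            seen.setdefault(f.sequence, f)
        frags = list(seen.values())
    n_unique = len(frags)
    if modern_diagnostics is not None and not modern_diagnostics.empty:
        n_cont = estimate_contamination(frags, modern_diagnostics, genome_length)
    else:
        n_cont = 0
    n_endo = n_unique - n_cont
    if n_endo < 0:
        warn("contaminant estimate exceeds unique hominin count; clamping to 0",
             RuntimeWarning)
        n_endo = 0

    uniq = _unique_kmers(lineage_haplotypes, k)
    assigned: dict[str, int] = {lin: 0 for lin in lineage_haplotypes}
    for f in frags:
        if len(f) < k:
            continue
        mers = {f.sequence[i:i + k] for i in range(len(f) - k + 1)}
        scores = {lin: len(mers & uk) for lin, uk in uniq.items()}
        best = max(scores.values())
        if best == 0:
            continue
        top = [lin for lin, s in scores.items() if s == best]
        if len(top) == 1:
            assigned[top[0]] += 1

    pooled: dict[str, int] = {}
    for lin, cnt in assigned.items():
        pool = LINEAGE_POOLS.get(lin, lin)
        pooled[pool] = pooled.get(pool, 0) + cnt
    n_identified = sum(pooled.values())
    shares = {p: (c / n_identified if n_identified else 0.0)
              for p, c in pooled.items()}
    eligible = n_endo >= min_total
    called = ([p for p, s in sorted(shares.items()) if s >= min_share]
              if eligible else [])
    return LineageCall(
        sample_id=sample_id, n_hominin_unique=n_unique,
        n_contaminant_est=n_cont, n_endogenous=n_endo,
        assigned_counts=assigned, pooled_counts=pooled, shares=shares,
        called=called, eligible=eligible,
    )
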