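"""Fragment-level processing of mtDNA capture reads.

Short sediment-DNA fragments are aligned to a panel of circular mitochondrial
reference genomes by exact k-mer seeding plus ungapped extension, assigned to a
mammalian family only when every near-best hit falls in a single family, length
filtered, deduplicated (by sequence identity or by alignment coordinates), and
annotated for the terminal C-to-T substitutions characteristic of cytosine
deamination in ancient DNA.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

__all__ = [
    "Alignment",
    "Fragment",
    "AssignmentProfile",
    "PanelIndex",
    "filter_fragments",
    "deduplicate",
    "assign_family",
    "annotate_terminal_ct",
    "process_sample",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Alignment:
    """Ungapped placement of a fragment on a circular reference genome.

    ``start``/``end`` are 1-based inclusive on the forward reference strand;
    ``end`` may exceed the genome length when the fragment wraps the origin
    (position j of the aligned read sits at ``((start - 1 + j) mod L) + 1``).
    """

    family: str
    genome: str
    start: int
    end: int
    strand: str  # '+' | '-'
    n_mismatches: int
    identity: float
    score: int
    mapq: int


@dataclass
class Fragment:
    id: str
    sequence: str
    merged: bool = True
    duplicate_count: int = 1
    alignment: Alignment | None = None
    terminal_ct_5p: bool = False
    terminal_ct_3p: bool = False
    #: reference base is C at the read-strand 5'/3' terminus (the denominator
    #: for terminal substitution frequencies)
    ref_c_5p: bool = False
    ref_c_3p: bool = False
    truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def deaminated(self) -> bool:
        return self.terminal_ct_5p or self.terminal_ct_3p


@dataclass
class AssignmentProfile:
    """Per-sample counts of fragments assigned to each family."""

    sample_id: str
    counts: dict
    unassigned: int

    @property
    def total_assigned(self) -> int:
        return sum(self.counts.values())

    def fraction(self, family: str) -> float:
        tot = self.total_assigned
        return self.counts.get(family, 0) / tot if tot else 0.0


class PanelIndex:
    """Exact k-mer index over the (circular) genomes of a reference panel."""

    def __init__(self, panel, k: int = 16):
        if k < 4:
            raise ValueError("k must be at least 4")
        self.k = k
        self.panel = panel
        # genome id -> (family, sequence, doubled sequence)
        self.genomes: dict[str, tuple[str, str, str]] = {}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for family, genomes in panel.genomes.items():
            for gid, seq in genomes.items():
                dbl = seq + seq[: k - 1]
                self.genomes[gid] = (family, seq, dbl)
                for p in range(len(seq)):
                    self._index[dbl[p:p + k]].append((gid, p))

    def seeds(self, seq: str):
        """Candidate (genome, 0-based start) placements from exact k-mer hits."""
        k = self.k
        cands = set()
        for o in range(len(seq) - k + 1):
            for gid, p in self._index.get(seq[o:o + k], ()):
                L = len(self.genomes[gid][1])
                cands.add((gid, (p - o) % L))
        return cands

    def ref_segment(self, gid: str, start0: int, length: int) -> str:
        _, seq, _ = self.genomes[gid]
        L = len(seq)
        if start0 + length <= L:
            return seq[start0:start0 + length]
        return (seq + seq)[start0:start0 + length]


def _best_hits(frag_seq: str, index: PanelIndex):
    """Best ungapped alignment per genome, over both strands."""
    per_genome: dict[str, tuple[int, int, str]] = {}  # gid -> (mm, start0, strand)
    for strand, seq in (("+", frag_seq), ("-", revcomp(frag_seq))):
        for gid, start0 in index.seeds(seq):
            ref = index.ref_segment(gid, start0, len(seq))
            mm = sum(a != b for a, b in zip(seq, ref))
            cur = per_genome.get(gid)
            if cur is None or (mm, start0, strand) < cur:
                per_genome[gid] = (mm, start0, strand)
    return per_genome


def assign_family(fragment: Fragment, index: PanelIndex,
                  min_score: int = 25) -> Fragment:
    """Assign a fragment to a family via seed-and-extend alignment.

    The fragment is assigned only when all hits within one mismatch of the best
    fall in a single family (a conservativeness rule in the spirit of
    lowest-common-ancestor binning), and the uniqueness score — a Phred-scaled
    function of the score gap between the best hit and the best hit in any
    *other* family, capped at 60 — reaches ``min_score``. A fragment shorter
    than k is left unassigned.
    """
    m = len(fragment.sequence)
    if m < index.k:
        fragment.alignment = None
        return fragment
    hits = _best_hits(fragment.sequence, index)
    if not hits:
        fragment.alignment = None
        return fragment
    best_gid = min(hits, key=lambda g: (hits[g][0], g))
    best_mm = hits[best_gid][0]
    top_families = {index.genomes[g][0] for g, h in hits.items()
                    if h[0] <= best_mm + 1}
    family = index.genomes[best_gid][0]
    score = (m - best_mm) - best_mm
    other = [(len(fragment.sequence) - h[0]) - h[0]
             for g, h in hits.items() if index.genomes[g][0] != family]
    mapq = 60 if not other else max(0, min(60, 3 * (score - max(other))))
    if len(top_families) > 1 or mapq < min_score:
        fragment.alignment = None
        return fragment
    mm, start0, strand = hits[best_gid]
    fragment.alignment = Alignment(
        family=family, genome=best_gid, start=start0 + 1,
        end=start0 + m, strand=strand, n_mismatches=mm,
        identity=(m - mm) / m, score=score, mapq=mapq,
    )
    return fragment


def filter_fragments(fragments: list[Fragment], min_len: int = 35) -> list[Fragment]:
    """Keep aligned fragments of at least ``min_len`` bp (35 bp boundary
    inclusive); unaligned fragments are removed regardless of length."""
    return [f for f in fragments
            if f.alignment is not None and len(f) >= min_len]


def deduplicate(fragments: list[Fragment], mode: str = "sequence",
                min_count: int | None = None) -> list[Fragment]:
    """Collapse PCR duplicates.

    ``sequence`` mode (mammalian capture) collapses identical sequences and
    keeps only survivors seen at least ``min_count`` times (default 2).
    ``coordinate`` mode (human capture) collapses fragments sharing
    (genome, start, end, strand), default ``min_count`` 1. The first fragment
    of each key (input order) is the representative; ``duplicate_count`` sums
    the counts of the collapsed members, so deduplication is idempotent.
    """
    if mode not in ("sequence", "coordinate"):
        raise ValueError(f"unknown mode {mode!r}")
    if min_count is None:
        min_count = 2 if mode == "sequence" else 1
    groups: dict = {}
    for f in fragments:
        if mode == "sequence":
            key = f.sequence
        else:
            a = f.alignment
            key = (a.genome, a.start, a.end, a.strand) if a else ("?", f.id)
        if key in groups:
            groups[key].duplicate_count += f.duplicate_count
        else:
            groups[key] = replace(f)
    return [f for f in groups.values() if f.duplicate_count >= min_count]


def annotate_terminal_ct(fragment: Fragment, index: PanelIndex,
                         window: int = 1) -> Fragment:
    """Set terminal C-to-T flags from the strand-normalized alignment.

    The reference segment is rewritten onto the read's own strand, so a
    C-to-T on a reverse-strand read (G-to-A on the forward reference) is
    flagged like a forward one. Only positions whose reference base is C can
    be flagged; ``ref_c_5p``/``ref_c_3p`` record whether each terminus has a
    reference C within the window (the frequency denominator).
    """
    a = fragment.alignment
    if a is None:
        raise ValueError("fragment must be aligned before damage annotation")
    ref = index.ref_segment(a.genome, a.start - 1, len(fragment))
    if a.strand == "-":
        # the read maps to revcomp(ref); flip the reference instead so both
        # sit on the read's own strand
        ref = revcomp(ref)
    read = fragment.sequence
    m = len(read)
    w = min(window, m)
    fragment.ref_c_5p = any(ref[i] == "C" for i in range(w))
    fragment.ref_c_3p = any(ref[m - 1 - i] == "C" for i in range(w))
    fragment.terminal_ct_5p = any(
        ref[i] == "C" and read[i] == "T" for i in range(w))
    fragment.terminal_ct_3p = any(
        ref[m - 1 - i] == "C" and read[m - 1 - i] == "T" for i in range(w))
    return fragment


def process_sample(
    fragments: list[Fragment],
    index: PanelIndex,
    sample_id: str = "sample",
    mode: str = "sequence",
    min_len: int = 35,
    min_score: int = 25,
    min_count: int | None = None,
) -> tuple[AssignmentProfile, list[Fragment]]:
    """Full pipeline: align/assign, length-filter, deduplicate, annotate.

    Returns the per-family :class:`AssignmentProfile` (the unassigned count is
    the number of post-filter, post-dedup fragments without a family) and the
    surviving annotated fragments.
    """
    aligned = [assign_family(f, index, min_score=min_score) for f in fragments]
    kept = filter_fragments(aligned, min_len=min_len)
    unassigned_long = [f for f in aligned
                       if f.alignment is None and len(f) >= min_len]
    deduped = deduplicate(kept, mode=mode, min_count=min_count)
    for f in deduped:
        annotate_terminal_ct(f, index)
    counts: dict[str, int] = defaultdict(int)
    for f in deduped:
        counts[f.alignment.family] += 1
    return (
        AssignmentProfile(sample_id=sample_id, counts=dict(counts),
                          unassigned=len(unassigned_long)),
        deduped,
    )
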