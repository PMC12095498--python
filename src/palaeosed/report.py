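"""Layer- and site-level synthesis of the per-sample results.

Layer composition profiles average the *percentages* of fragments assigned to
each family across the layer's samples (an unweighted mean of per-sample
percentages, not a pool of counts, so a small sample counts as much as a large
one). Detection tables turn per-sample positivity flags into counts and
nearest-integer percentages. Haplogroup turnover scans layer profiles in
stratigraphic order for changes in the dominant called group of a taxon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "LayerProfile",
    "DetectionTable",
    "layer_family_profile",
    "detection_table",
    "haplogroup_turnover",
    "round_percent",
]


def round_percent(k: int, n: int) -> int:
    """Nearest-integer percentage, ties away from zero (so 12.5% -> 13%)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return int(math.floor(100.0 * k / n + 0.5))


@dataclass
class LayerProfile:
    layer_id: str
    family_percentages: dict  # family -> mean percentage across samples
    n_samples: int
    dominant_haplogroups: dict = field(default_factory=dict)  # taxon -> group


@dataclass
class DetectionTable:
    """Counts and rounded percentages of positive samples per grouping."""

    rows: list  # (label, n_samples, n_positive_fauna, n_positive_hominin)

    def as_records(self) -> list[dict]:
        out = []
        for label, n, kf, kh in self.rows:
            out.append({
                "group": label, "n_samples": n,
                "n_positive_fauna": kf, "pct_fauna": round_percent(kf, n),
                "n_positive_hominin": kh, "pct_hominin": round_percent(kh, n),
            })
        return out


def layer_family_profile(
    sample_counts: dict,
    layer_id: str = "layer",
    dominant_haplogroups: dict | None = None,
) -> LayerProfile:
    """Average per-sample family percentages for one layer.

    ``sample_counts`` maps sample id -> {family: assigned fragment count}.
    Samples with zero assigned fragments are excluded with a warning; each
    remaining sample's counts are turned into percentages (summing to 100)
    before the unweighted mean across samples.
    """
    usable = {}
    for sid, counts in sample_counts.items():
        tot = sum(counts.values())
        if tot == 0:
            warnings.warn(f"sample {sid!r} has no assigned fragments; excluded",
                          RuntimeWarning)
            continue
        usable[sid] = {fam: 100.0 * c / tot for fam, c in counts.items()}
    if not usable:
        raise ValueError(f"layer {layer_id!r} has no sample with assigned fragments")
    families = sorted({fam for pcts in usable.values() for fam in pcts})
    mean_pct = {
        fam: sum(pcts.get(fam, 0.0) for pcts in usable.values()) / len(usable)
        for fam in families
    }
    return LayerProfile(layer_id=layer_id, family_percentages=mean_pct,
                        n_samples=len(usable),
                        dominant_haplogroups=dominant_haplogroups or {})


def detection_table(sample_flags: dict, grouping: dict) -> DetectionTable:
    """Detection counts per grouping.

    ``sample_flags`` maps sample id -> (fauna_positive, hominin_positive);
    ``grouping`` maps grouping label -> list of sample ids.
    """
    rows = []
    for label, sids in grouping.items():
        n = len(sids)
        kf = sum(1 for s in sids if sample_flags[s][0])
        kh = sum(1 for s in sids if sample_flags[s][1])
        rows.append((label, n, kf, kh))
    return DetectionTable(rows=rows)


def haplogroup_turnover(
    layer_calls: list[tuple[str, dict]],
    taxon: str | None = None,
) -> tuple[list[tuple[str, str | None]], list[dict]]:
    """Dominant group per layer plus change-points, oldest to youngest.

    ``layer_calls`` is an ordered list of (layer id, {group: called support}),
    where support is the supporting-fragment count of *called* groups only;
    layers with no calls use an empty dict and are marked no-data. A
    change-point is flagged where the dominant group differs from the most
    recent layer with data; if no-data layers intervene the change-point is
    bracketed between the flanking data layers and flagged uncertain.
    """
    if sum(1 for _, calls in layer_calls if calls) < 2:
        raise ValueError("need calls in at least 2 layers")
    dominants: list[tuple[str, str | None]] = []
    for lid, calls in layer_calls:
        if calls:
            dom = max(sorted(calls), key=lambda g: calls[g])
        else:
            dom = None
        dominants.append((lid, dom))
    changes = []
    prev_layer = prev_dom = None
    gap = False
    for lid, dom in dominants:
        if dom is None:
            if prev_dom is not None:
                gap = True
            continue
        if prev_dom is not None and dom != prev_dom:
            changes.append({
                "layer": lid, "from_group": prev_dom, "to_group": dom,
                "after_layer": prev_layer, "uncertain": gap,
            })
        prev_layer, prev_dom, gap = lid, dom, False
    return dominants, changes
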