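"""Deletion-size computation, analysis-subgroup classification and
breakpoint-hotspot detection for 22q13 deletions.

Sizes use the 1-based inclusive convention (a terminal deletion starting at
position s spans qter - s + 1 bp).  The 10-group analysis classification
assigns each finding exactly one primary group (1-7) and overlay groups
8/9/10 from the additional-rearrangement flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CHR22_QTER, GeneticFinding

GROUP_NAMES = {
    1: "terminal deletion > threshold",
    2: "terminal deletion <= threshold",
    3: "interstitial deletion",
    4: "SHANK3 sequence variant",
    5: "ring 22",
    6: "unbalanced translocation",
    7: "mosaic deletion",
    8: "additional rearrangement at chr22",
    9: "additional rearrangement in other chromosomes",
    10: "any additional rearrangement",
}


def deletion_size(finding: GeneticFinding) -> int:
    """Deletion length in bp (1-based inclusive convention).

    Terminal deletions extend to the chr22 q terminus regardless of the
    recorded distal coordinate; interstitial ones use their own ends.
    """
    if finding.kind != "deletion" or finding.interval is None:
        raise ValueError(f"{finding.patient_id}: no deletion interval")
    iv = finding.interval
    if finding.terminal:
        size = CHR22_QTER - iv.start1 + 1
    else:
        size = iv.end1 - iv.start1 + 1
    if size <= 1:
        warnings.warn(f"{finding.patient_id}: degenerate deletion of {size} bp")
    return size


def classify_subgroup(finding: GeneticFinding, size_threshold_mb: float = 0.25) -> set[int]:
    """Analysis-group labels for one finding.

    Exactly one primary group among 1-7, with mechanism precedence
    ring 22 > unbalanced translocation > mosaic > interstitial >
    size-split terminal; overlays 8/9 from the additional-rearrangement
    flags and 10 = 8 or 9 (never on group 4, variant cases).
    """
    if finding.kind == "shank3_variant":
        return {4}

    mech = finding.mechanism
    if mech == "ring22":
        if finding.interval is not None and not finding.terminal:
            raise ValueError(f"{finding.patient_id}: ring 22 with interstitial interval")
        primary = 5
    elif mech in ("unbalanced_translocation_de_novo", "unbalanced_translocation_inherited"):
        primary = 6
    elif finding.mosaic_fraction is not None:
        primary = 7
    elif mech == "interstitial":
        if finding.terminal:
            raise ValueError(f"{finding.patient_id}: interstitial mechanism flagged terminal")
        primary = 3
    else:
        size_mb = deletion_size(finding) / 1e6
        primary = 1 if size_mb > size_threshold_mb else 2

    labels = {primary}
    if finding.additional_rearr_chr22:
        labels |= {8, 10}
    if finding.additional_rearr_other:
        labels |= {9, 10}
    return labels


def classify_cohort(findings: list[GeneticFinding], size_threshold_mb: float = 0.25) -> pd.DataFrame:
    rows = []
    for f in findings:
        labels = classify_subgroup(f, size_threshold_mb)
        primary = min(label for label in labels if label <= 7)
        rows.append(
            {
                "patient_id": f.patient_id,
                "size_bp": deletion_size(f) if f.kind == "deletion" else np.nan,
                "primary_group": primary,
                "overlay_groups": ",".join(str(g) for g in sorted(labels - {primary})),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BreakpointHotspot:
    window: tuple[int, int]  # 1-based inclusive span covered
    members: tuple[str, ...]
    side: str  # "5prime" or "3prime"

    @property
    def count(self) -> int:
        return len(self.members)


def _greedy_windows(
    positions: list[tuple[int, str]], window: int, min_count: int, side: str
) -> list[BreakpointHotspot]:
    """Greedy fixed-width window clustering.

    Candidate windows are anchored at breakpoints ([x, x + window]); the
    window covering most remaining breakpoints is emitted first (ties go to
    the smaller coordinate), its members removed, and so on while a window
    holds at least ``min_count`` members.
    """
    remaining = sorted(positions)
    hotspots = []
    while True:
        best = None
        pos = [p for p, _ in remaining]
        for i, (anchor, _) in enumerate(remaining):
            members = [(p, pid) for p, pid in remaining if anchor <= p <= anchor + window]
            if best is None or len(members) > len(best[1]):
                best = (anchor, members)
        if best is None or len(best[1]) < min_count:
            break
        anchor, members = best
        hotspots.append(
            BreakpointHotspot(
                window=(members[0][0], members[-1][0]),
                members=tuple(pid for _, pid in members),
                side=side,
            )
        )
        taken = {pid for _, pid in members}
        remaining = [(p, pid) for p, pid in remaining if pid not in taken]
    return hotspots


def breakpoint_hotspots(
    findings: list[GeneticFinding], window: int = 30_000, min_count: int = 3
) -> list[BreakpointHotspot]:
    """Recurrent-breakpoint windows among deletion cases.

    5' (proximal) breakpoints of all deletions and 3' (distal) breakpoints
    of interstitial deletions are clustered separately; results are sorted
    by member count descending then coordinate ascending.
    """
    dels = [f for f in findings if f.kind == "deletion" and f.interval is not None]
    if not dels:
        raise ValueError("no deletions with coordinates")
    five = [(f.interval.start1, f.patient_id) for f in dels]
    three = [(f.interval.end1, f.patient_id) for f in dels if not f.terminal]
    hits = _greedy_windows(five, window, min_count, "5prime")
    hits += _greedy_windows(three, window, min_count, "3prime")
    return sorted(hits, key=lambda h: (-h.count, h.window[0]))


def hotspots_to_bed(hotspots: list[BreakpointHotspot]) -> pd.DataFrame:
    """BED-style (0-based half-open) table of hotspot windows."""
    return pd.DataFrame(
        [
            {
                "chrom": "22",
                "start": h.window[0] - 1,
                "end": h.window[1],
                "name": f"{h.side}_hotspot",
                "score": h.count,
            }
            for h in hotspots
        ]
    )
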