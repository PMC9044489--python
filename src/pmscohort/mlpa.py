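"""MLPA probe-ratio normalization, dosage calling and mosaic-fraction
estimation.

Relative probe signals are formed by dividing each peak area by the sum of
the control-probe areas of the same run; each relative signal is then
divided by the matching relative signal of a reference run, so a normal
diploid probe sits near ratio 1.0 and a constitutional heterozygous
deletion near 0.5.

A post-zygotic mosaic deletion shifts the ratio only part-way: with a
fraction ``m`` of deleted cells in an otherwise diploid sample the expected
ratio is ``1 - m/2``, giving the inverse estimator ``m = 2 (1 - ratio)``.
Fractions below 15% are flagged as below the practical detection limit of
array-based dosage assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

MOSAIC_DETECTION_LIMIT = 0.15


@dataclass(frozen=True)
class ProbePeak:
    probe_id: str
    area: float
    is_control: bool = False
    chrom: Optional[str] = None
    position: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.area > 0):
            raise ValueError(f"probe {self.probe_id}: area must be > 0")


@dataclass
class MlpaRun:
    sample_id: str
    peaks: list[ProbePeak]

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.sample_id}: duplicate probe_id in run")
        if not any(p.is_control for p in self.peaks):
            raise ValueError(f"{self.sample_id}: run has no control probes")
        if all(p.is_control for p in self.peaks):
            raise ValueError(f"{self.sample_id}: run has no test probes")

    def control_sum(self) -> float:
        return sum(p.area for p in self.peaks if p.is_control)


@dataclass(frozen=True)
class DosageCall:
    probe_id: str
    ratio: float
    call: str  # deleted | normal | duplicated | indeterminate
    mosaic_fraction_est: Optional[float] = None
    below_detection: bool = False


def read_peak_table(path) -> dict[str, MlpaRun]:
    """Peak CSV (`sample_id, probe_id, chrom, position, is_control, area`)
    parsed into one run per sample."""
    df = pd.read_csv(path)
    runs = {}
    for sid, group in df.groupby("sample_id", sort=False):
        peaks = [
            ProbePeak(
                probe_id=row.probe_id,
                area=float(row.area),
                is_control=bool(int(row.is_control)),
                chrom=None if pd.isna(row.get("chrom")) else str(row.chrom),
                position=None if pd.isna(row.get("position")) else int(row.position),
            )
            for row in group.itertuples()
        ]
        runs[str(sid)] = MlpaRun(sample_id=str(sid), peaks=peaks)
    return runs


def normalize_run(sample: MlpaRun, reference: MlpaRun) -> dict[str, float]:
    """Dosage ratio per shared probe.

    ratio = (area_s / sum controls_s) / (area_r / sum controls_r).
    Probes absent from the reference are skipped with a warning.  Ratios are
    invariant under uniform rescaling of either run.
    """
    cs, cr = sample.control_sum(), reference.control_sum()
    if cs <= 0 or cr <= 0:
        raise ValueError("zero control-probe sum")
    ref_areas = {p.probe_id: p.area for p in reference.peaks}
    ratios = {}
    for peak in sample.peaks:
        if peak.probe_id not in ref_areas:
            warnings.warn(
                f"{sample.sample_id}: probe {peak.probe_id} missing in reference; skipped"
            )
            continue
        rel_s = peak.area / cs
        rel_r = ref_areas[peak.probe_id] / cr
        ratios[peak.probe_id] = rel_s / rel_r
    return ratios


def call_dosage(
    ratios: dict[str, float],
    lower: float = 0.70,
    upper: float = 1.30,
    guard: float = 0.02,
) -> list[DosageCall]:
    """Threshold-band dosage calls with an indeterminate guard band.

    Ratios within ``guard`` of either threshold are indeterminate; below
    the lower band the probe is deleted (with a mosaic-fraction estimate),
    above the upper band duplicated, otherwise normal.
    """
    calls = []
    for probe_id, ratio in ratios.items():
        if not np.isfinite(ratio) or ratio < 0:
            raise ValueError(f"probe {probe_id}: invalid ratio {ratio}")
        est = None
        below = False
        if abs(ratio - lower) <= guard or abs(ratio - upper) <= guard:
            call = "indeterminate"
        elif ratio < lower:
            call = "deleted"
            est, below = mosaic_fraction(min(ratio, 1.0))
        elif ratio > upper:
            call = "duplicated"
        else:
            call = "normal"
        calls.append(
            DosageCall(
                probe_id=probe_id,
                ratio=float(ratio),
                call=call,
                mosaic_fraction_est=est,
                below_detection=below,
            )
        )
    return calls


def mosaic_fraction(ratio: float) -> tuple[float, bool]:
    """Mosaic deleted-cell fraction implied by a dosage ratio <= 1.

    ``m = clamp(2 (1 - ratio), 0, 1)``: ratio 1.0 means no deleted cells,
    ratio 0.5 a constitutional heterozygous deletion.  Returns
    ``(m, below_detection)`` where the flag marks fractions under 15%.
    """
    if ratio > 1.0:
        raise ValueError(f"ratio {ratio} > 1 is on the duplication side")
    if ratio < 0:
        raise ValueError(f"ratio {ratio} < 0")
    m = min(max(2.0 * (1.0 - ratio), 0.0), 1.0)
    return m, m < MOSAIC_DETECTION_LIMIT


def estimate_region_mosaic(ratios: dict[str, float], probe_ids: list[str]) -> tuple[float, bool]:
    """Mosaic fraction from the mean ratio over a deleted probe region.

    Averaging first suppresses per-probe multiplicative noise before the
    ratio is inverted to a cell fraction.
    """
    values = [ratios[p] for p in probe_ids if p in ratios]
    if not values:
        raise ValueError("no ratios for requested probes")
    return mosaic_fraction(min(float(np.mean(values)), 1.0))


def calls_to_frame(calls: list[DosageCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "probe_id": c.probe_id,
                "ratio": c.ratio,
                "call": c.call,
                "mosaic_fraction_est": c.mosaic_fraction_est,
                "below_detection": c.below_detection,
            }
            for c in calls
        ]
    )
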