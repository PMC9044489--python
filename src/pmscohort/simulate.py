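"""Synthetic 22q13-deletion cohort generator.

Emulates the statistical structure of a large Phelan-McDermid cohort so
that every downstream stage (severity scoring, subgroup classification,
clustering, screens) is testable without patient-level data:

* mechanism drawn from the published mechanism partition of deletion cases
  (simple terminal : ring 22 : unbalanced translocations : interstitial);
* deletion size drawn from a 4-component Gaussian mixture whose weights,
  means and SDs match the published Ward cluster solution
  (64:66:29:28 at 0.52/3.39/6.10/8.27 Mb), truncated by resampling to the
  observed extremes (12 kb to 10.30 Mb);
* post-zygotic mosaicism as an independent overlay (rate 17/189, fraction
  uniform on the reported 10%-82% range);
* each clinical item Bernoulli with logistic size coupling
  ``P(present) = expit(logit(baseline) + slope * (size_mb - center))``
  followed by independent missingness masking.

One global seed governs a named substream per stage, so stages are
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import catalog as cat
from .cohort import (
    CHR22_QTER,
    Cohort,
    GeneticFinding,
    GenomicInterval,
    PatientPhenotype,
)

#: Logit slope magnitude (per Mb) applied to the size-linked items.  The
#: value is a documented calibration constant: with the default mixture it
#: puts the mean Pearson correlation between deletion size and the severity
#: score at ~0.33 across seeds (see docs/methods.md).
SIZE_SLOPE = 0.32

#: Size at which the logistic coupling is centred (Mb); close to the
#: mixture mean, so marginal prevalences stay at their baselines.
SIZE_CENTER_MB = 3.5

#: Largest deletion the generator will emit (Mb).
SIZE_CAP_MB = 10.30

_STREAMS = ("mechanism", "sizes", "items", "masking", "mosaic", "demographics", "overlays")


@dataclass
class GeneratorConfig:
    n_patients: int
    subgroup_proportions: dict[str, float]
    size_mixture: list[tuple[float, float, float]]  # (weight, mean Mb, sd Mb)
    min_size: float  # Mb
    feature_models: dict[str, tuple[float, float, float]]  # baseline, slope, missing_rate
    mosaic_rate: float
    mosaic_range: tuple[float, float]
    seed: int
    size_cap: float = SIZE_CAP_MB
    size_center: float = SIZE_CENTER_MB
    shank3_variant_prop: float = 0.0
    add22_rate: float = 0.0
    add_other_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        total = sum(self.subgroup_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subgroup_proportions sum to {total}, expected 1")
        wsum = sum(w for w, _, _ in self.size_mixture)
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {wsum}, expected 1")
        if any(sd <= 0 for _, _, sd in self.size_mixture):
            raise ValueError("mixture sds must be > 0")
        if not (0 < self.min_size < self.size_cap):
            raise ValueError("min_size must lie in (0, size_cap)")
        for fid, (base, _, miss) in self.feature_models.items():
            if not (0.0 < base < 1.0):
                raise ValueError(f"{fid}: baseline prevalence must lie in (0, 1)")
            if not (0.0 <= miss < 1.0):
                raise ValueError(f"{fid}: missing_rate must lie in [0, 1)")
        for rate, name in (
            (self.mosaic_rate, "mosaic_rate"),
            (self.shank3_variant_prop, "shank3_variant_prop"),
            (self.add22_rate, "add22_rate"),
            (self.add_other_rate, "add_other_rate"),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.mosaic_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("mosaic_range must satisfy 0 < lo <= hi <= 1")


@dataclass
class GroundTruth:
    """Latent per-patient state before missingness masking."""

    table: pd.DataFrame  # patient_id, kind, mechanism, size_mb, mosaic_fraction
    items: pd.DataFrame  # patient_id x feature_id, values present/absent


def default_calibration(seed: int = 0, n_patients: int = 189) -> GeneratorConfig:
    """Calibration matching the published microdeletion cohort.

    Mechanism proportions 144:20:8:5:12 over 189 deletion cases, the
    64:66:29:28 size mixture at 0.52/3.39/6.10/8.27 Mb, per-item
    prevalences and missingness from the descriptive tables, minimum size
    12 kb, mosaic overlay 17/189 on 10%-82%, and documented logistic size
    slopes on the size-linked items.
    """
    nd = 189.0
    proportions = {
        "simple_terminal": 144 / nd,
        "ring22": 20 / nd,
        "unbalanced_translocation_de_novo": 8 / nd,
        "unbalanced_translocation_inherited": 5 / nd,
        "interstitial": 12 / nd,
    }
    wtot = 64 + 66 + 29 + 28
    mixture = [
        (64 / wtot, 0.52, 0.51),
        (66 / wtot, 3.39, 0.77),
        (29 / wtot, 6.10, 0.69),
        (28 / wtot, 8.27, 0.74),
    ]
    prev = cat.default_prevalences()
    miss = cat.default_missing_rates()
    feature_models = {
        fid: (prev[fid], cat.SIZE_LINKED.get(fid, 0) * SIZE_SLOPE, miss[fid])
        for fid in prev
    }
    return GeneratorConfig(
        n_patients=n_patients,
        subgroup_proportions=proportions,
        size_mixture=mixture,
        min_size=0.012,
        feature_models=feature_models,
        mosaic_rate=17 / nd,
        mosaic_range=(0.10, 0.82),
        seed=seed,
        add22_rate=12 / nd,
        add_other_rate=28 / nd,
    )


def whole_cohort_calibration(seed: int = 0, n_patients: int = 210) -> GeneratorConfig:
    """Deletion calibration plus a 10% SHANK3 sequence-variant share."""
    config = default_calibration(seed=seed, n_patients=n_patients)
    config.shank3_variant_prop = 21 / 210
    return config


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _draw_sizes(rng: np.random.Generator, config: GeneratorConfig, n: int) -> np.ndarray:
    """Mixture sizes in Mb, truncated to [min_size, size_cap] by resampling."""
    weights = np.array([w for w, _, _ in config.size_mixture])
    means = np.array([m for _, m, _ in config.size_mixture])
    sds = np.array([s for _, _, s in config.size_mixture])
    out = np.empty(n)
    comp = rng.choice(len(weights), size=n, p=weights)
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.normal(means[comp[remaining]], sds[comp[remaining]])
        ok = (draw >= config.min_size) & (draw <= config.size_cap)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort and its ground truth; deterministic given config.seed."""
    rng = _streams(config.seed)
    n = config.n_patients
    pids = [f"SIM{i + 1:04d}" for i in range(n)]

    is_variant = rng["mechanism"].random(n) < config.shank3_variant_prop
    mech_names = sorted(config.subgroup_proportions)
    mech_probs = np.array([config.subgroup_proportions[m] for m in mech_names])
    mech_probs = mech_probs / mech_probs.sum()
    mechanisms = np.array(mech_names)[
        rng["mechanism"].choice(len(mech_names), size=n, p=mech_probs)
    ]
    mechanisms = np.where(is_variant, "shank3_variant", mechanisms)

    sizes_mb = _draw_sizes(rng["sizes"], config, n)
    sizes_mb[is_variant] = np.nan

    mosaic = rng["mosaic"].random(n) < config.mosaic_rate
    mosaic &= ~is_variant
    lo, hi = config.mosaic_range
    mosaic_fraction = np.where(mosaic, rng["mosaic"].uniform(lo, hi, size=n), np.nan)

    add22 = (rng["overlays"].random(n) < config.add22_rate) & ~is_variant
    add_other = (rng["overlays"].random(n) < config.add_other_rate) & ~is_variant

    # Demographics: female excess ~1.1:1; age at diagnosis inversely related
    # to size (small deletions are recognized later), evaluation age broad.
    demo = rng["demographics"]
    sex = np.where(demo.random(n) < 105 / 190, "female", "male")
    size_term = np.where(is_variant, 0.0, np.nan_to_num(sizes_mb) - config.size_center)
    age_dx = np.maximum(1.0, demo.normal(72.0 - 8.0 * size_term, 55.0))
    age_eval = np.maximum(0.5, demo.normal(12.44, 8.7, size=n))

    # Clinical items: logistic size coupling, then missingness masking.
    feature_ids = list(config.feature_models)
    base = np.array([config.feature_models[f][0] for f in feature_ids])
    slope = np.array([config.feature_models[f][1] for f in feature_ids])
    miss = np.array([config.feature_models[f][2] for f in feature_ids])
    size_for_items = np.where(is_variant, config.size_center, sizes_mb)
    eta = logit(base)[None, :] + slope[None, :] * (size_for_items - config.size_center)[:, None]
    p_present = expit(eta)
    true_items = rng["items"].random((n, len(feature_ids))) < p_present
    masked = rng["masking"].random((n, len(feature_ids))) < miss[None, :]

    phenotypes = []
    for i, pid in enumerate(pids):
        items = {}
        for j, fid in enumerate(feature_ids):
            if masked[i, j]:
                items[fid] = "missing"
            else:
                items[fid] = "present" if true_items[i, j] else "absent"
        phenotypes.append(
            PatientPhenotype(
                patient_id=pid,
                sex=str(sex[i]),
                age_dx_months=float(round(age_dx[i], 1)),
                age_eval_years=float(round(age_eval[i], 1)),
                items=items,
            )
        )

    findings = []
    for i, pid in enumerate(pids):
        if mechanisms[i] == "shank3_variant":
            findings.append(GeneticFinding(patient_id=pid, kind="shank3_variant"))
            continue
        size_bp = max(1, int(round(sizes_mb[i] * 1e6)))
        if mechanisms[i] == "interstitial":
            # Internal 22q13 segment: distal end retained, 150 kb - 2 Mb
            # of material left between the deletion and the q terminus.
            gap = int(rng["sizes"].integers(150_000, 2_000_000))
            end0 = CHR22_QTER - gap
            interval = GenomicInterval(start0=end0 - size_bp, end0=end0)
            terminal = False
        else:
            interval = GenomicInterval(start0=CHR22_QTER - size_bp, end0=CHR22_QTER)
            terminal = True
        findings.append(
            GeneticFinding(
                patient_id=pid,
                kind="deletion",
                interval=interval,
                terminal=terminal,
                mechanism=str(mechanisms[i]),
                mosaic_fraction=float(mosaic_fraction[i]) if mosaic[i] else None,
                additional_rearr_chr22=bool(add22[i]),
                additional_rearr_other=bool(add_other[i]),
            )
        )

    cohort = Cohort(catalog=cat.default_catalog(), phenotypes=phenotypes, findings=findings)
    truth_table = pd.DataFrame(
        {
            "patient_id": pids,
            "kind": np.where(is_variant, "shank3_variant", "deletion"),
            "mechanism": mechanisms,
            "size_mb": sizes_mb,
            "mosaic_fraction": mosaic_fraction,
        }
    )
    truth_items = pd.DataFrame(
        np.where(true_items, "present", "absent"), index=pids, columns=feature_ids
    )
    truth_items.index.name = "patient_id"
    return cohort, GroundTruth(table=truth_table, items=truth_items)
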