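"""Shared fixtures: tiny hand-built cohorts and the published-count fixture."""

from __future__ import annotations

import pytest

from pmscohort.cohort import (
    CHR22_QTER,
    ClinicalFeature,
    Cohort,
    GeneticFinding,
    GenomicInterval,
    PatientPhenotype,
)


def make_feature(fid, polarity="adverse", category="comorbidity"):
    return ClinicalFeature(feature_id=fid, label=fid.replace("_", " "), category=category, polarity=polarity)


def terminal_finding(pid, size_bp, mechanism="simple_terminal", **kw):
    start0 = CHR22_QTER - size_bp
    return GeneticFinding(
        patient_id=pid,
        kind="deletion",
        interval=GenomicInterval(start0=start0, end0=CHR22_QTER),
        terminal=True,
        mechanism=mechanism,
        **kw,
    )


@pytest.fixture
def tiny_cohort():
    catalog = [
        make_feature("hypotonia"),
        make_feature("seizures"),
        make_feature("sphincter_control", polarity="protective", category="development"),
    ]
    phenotypes = [
        PatientPhenotype("P1", "male", 24.0, 5.0,
                         {"hypotonia": "present", "seizures": "present", "sphincter_control": "present"}),
        PatientPhenotype("P2", "female", 60.0, 10.0,
                         {"hypotonia": "absent", "seizures": "missing", "sphincter_control": "absent"}),
        PatientPhenotype("P3", "unknown", None, None,
                         {"hypotonia": "present", "seizures": "absent", "sphincter_control": "missing"}),
    ]
    findings = [
        terminal_finding("P1", 3_500_000),
        terminal_finding("P2", 100_000),
        GeneticFinding(patient_id="P3", kind="shank3_variant"),
    ]
    return Cohort(catalog=catalog, phenotypes=phenotypes, findings=findings)


def counts_cohort(groups):
    """Cohort with one dummy feature and the requested finding composition.

    ``groups``: list of (count, kwargs-for-finding-constructor-or-None).
    """
    catalog = [make_feature("hypotonia")]
    phenotypes, findings = [], []
    idx = 0
    for count, spec in groups:
        for _ in range(count):
            idx += 1
            pid = f"C{idx:03d}"
            phenotypes.append(PatientPhenotype(pid, "unknown", None, None, {"hypotonia": "missing"}))
            if spec is None:
                findings.append(GeneticFinding(patient_id=pid, kind="shank3_variant"))
            else:
                findings.append(terminal_finding(pid, **spec) if "size_bp" in spec
                                else GeneticFinding(patient_id=pid, **spec))
    return Cohort(catalog=catalog, phenotypes=phenotypes, findings=findings)


@pytest.fixture
def table_counts_cohort():
    """210 patients with the published mechanism composition: 144 simple
    terminal + 20 ring + 13 translocation + 12 interstitial deletions (17
    mosaic, 12/28 additional-rearrangement overlays) and 21 variants."""
    mkint = lambda: GenomicInterval(start0=45_000_000, end0=46_000_000)
    groups = []
    # 17 mosaic overlays: 8 of the rings, 9 simple terminals
    groups.append((9, {"size_bp": 3_000_000, "mosaic_fraction": 0.4}))
    groups.append((135, {"size_bp": 3_000_000}))
    groups.append((8, {"size_bp": 3_000_000, "mechanism": "ring22", "mosaic_fraction": 0.3}))
    groups.append((12, {"size_bp": 3_000_000, "mechanism": "ring22"}))
    groups.append((8, {"size_bp": 3_000_000, "mechanism": "unbalanced_translocation_de_novo"}))
    groups.append((5, {"size_bp": 3_000_000, "mechanism": "unbalanced_translocation_inherited"}))
    groups.append(
        (12, {"kind": "deletion", "interval": mkint(), "mechanism": "interstitial"})
    )
    groups.append((21, None))
    cohort = counts_cohort(groups)
    # additional-rearrangement overlays on deletion cases: 12 chr22, 28 other
    dels = [f for f in cohort.findings if f.kind == "deletion"]
    for f in dels[:12]:
        f.additional_rearr_chr22 = True
    for f in dels[12:40]:
        f.additional_rearr_other = True
    return cohort
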