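"""Core cohort data model: clinical feature catalog, per-patient phenotypes and
genetic findings, with TSV readers/writers and cohort-level count summaries.

Phenotype items are ternary-coded (``present`` / ``absent`` / ``missing``):
denominators in a Phelan-McDermid cohort vary per item because not every
feature is evaluable in every patient, so a blank cell must never be read as
"absent".  Genomic coordinates are accepted 1-based inclusive (the clinical
reporting convention) and stored 0-based half-open; everything emitted is
1-based inclusive again.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

#: GRCh37 length of chromosome 22 (q terminus coordinate, 1-based).
CHR22_QTER = 51_304_566

#: A deletion whose distal end lies within this many bp of the q terminus is
#: treated as terminal even when the input row does not flag it.
TERMINAL_TOLERANCE_BP = 100_000

PRESENT = "present"
ABSENT = "absent"
MISSING = "missing"
TERNARY = frozenset({PRESENT, ABSENT, MISSING})

CATEGORIES = frozenset({"development", "speech", "comorbidity", "dysmorphic", "behavior"})
POLARITIES = frozenset({"adverse", "protective"})
SEXES = frozenset({"male", "female", "unknown"})
KINDS = frozenset({"deletion", "shank3_variant"})
MECHANISMS = frozenset(
    {
        "simple_terminal",
        "ring22",
        "unbalanced_translocation_de_novo",
        "unbalanced_translocation_inherited",
        "interstitial",
    }
)


class CohortValidationError(ValueError):
    """Raised when an input table violates the cohort data contract."""


@dataclass(frozen=True)
class ClinicalFeature:
    """One catalog entry: a clinical item that can be scored per patient.

    ``polarity`` states whether presence of the item is adverse (the usual
    case: seizures, lymphedema, ...) or protective (ability to make
    sentences, sphincter control, walking by 15 months).
    """

    feature_id: str
    label: str
    category: str
    polarity: str
    hpo_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CohortValidationError(
                f"feature {self.feature_id!r}: unknown category {self.category!r}"
            )
        if self.polarity not in POLARITIES:
            raise CohortValidationError(
                f"feature {self.feature_id!r}: unknown polarity {self.polarity!r}"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """Chr22 interval stored 0-based half-open."""

    start0: int
    end0: int
    chrom: str = "22"

    @classmethod
    def from_1based(cls, start1: int, end1: int, chrom: str = "22") -> "GenomicInterval":
        return cls(start0=int(start1) - 1, end0=int(end1), chrom=chrom)

    @property
    def start1(self) -> int:
        return self.start0 + 1

    @property
    def end1(self) -> int:
        return self.end0

    def __len__(self) -> int:
        return self.end0 - self.start0


@dataclass
class PatientPhenotype:
    patient_id: str
    sex: str = "unknown"
    age_dx_months: Optional[float] = None
    age_eval_years: Optional[float] = None
    items: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CohortValidationError(f"{self.patient_id}: invalid sex {self.sex!r}")
        for age, name in ((self.age_dx_months, "age_dx_months"), (self.age_eval_years, "age_eval_years")):
            if age is not None and not (age == age and 0 <= age < float("inf")):
                raise CohortValidationError(f"{self.patient_id}: {name} must be finite and >= 0")
        for fid, state in self.items.items():
            if state not in TERNARY:
                raise CohortValidationError(
                    f"{self.patient_id}: item {fid!r} has invalid state {state!r}"
                )


@dataclass
class GeneticFinding:
    """A patient's 22q13 finding: a deletion interval or a SHANK3 variant.

    Additional rearrangements (on chr22 or elsewhere) are overlay booleans on
    the same record rather than extra rows, because analysis groups them as
    overlays on deletion cases.
    """

    patient_id: str
    kind: str
    interval: Optional[GenomicInterval] = None
    terminal: bool = False
    mechanism: Optional[str] = None
    mosaic_fraction: Optional[float] = None
    includes_shank3: bool = True
    additional_rearr_chr22: bool = False
    additional_rearr_other: bool = False
    variant_annotation: Optional[dict] = None

    def __post_init__(self) -> None:
        pid = self.patient_id
        if self.kind not in KINDS:
            raise CohortValidationError(f"{pid}: invalid kind {self.kind!r}")
        if self.kind == "deletion":
            if self.interval is None:
                raise CohortValidationError(f"{pid}: deletion requires coordinates")
            if self.mechanism not in MECHANISMS:
                raise CohortValidationError(f"{pid}: invalid mechanism {self.mechanism!r}")
            iv = self.interval
            if not (0 <= iv.start0 < iv.end0):
                raise CohortValidationError(
                    f"{pid}: malformed interval [{iv.start1}, {iv.end1}]"
                )
            if iv.end0 > CHR22_QTER:
                raise CohortValidationError(
                    f"{pid}: interval end {iv.end1} exceeds chr22 length {CHR22_QTER}"
                )
            # Auto-promote near-telomeric deletions to terminal.
            if iv.end0 >= CHR22_QTER - TERMINAL_TOLERANCE_BP:
                self.terminal = True
        else:
            if self.interval is not None:
                raise CohortValidationError(f"{pid}: shank3_variant must not carry an interval")
        if self.mosaic_fraction is not None and not (0.0 < self.mosaic_fraction <= 1.0):
            raise CohortValidationError(
                f"{pid}: mosaic_fraction {self.mosaic_fraction} outside (0, 1]"
            )


@dataclass
class Cohort:
    catalog: list[ClinicalFeature]
    phenotypes: list[PatientPhenotype]
    findings: list[GeneticFinding]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [f.feature_id for f in self.catalog]
        if len(ids) != len(set(ids)):
            raise CohortValidationError("duplicate feature_id in catalog")
        pids = [p.patient_id for p in self.phenotypes]
        if len(pids) != len(set(pids)):
            dupes = sorted({p for p in pids if pids.count(p) > 1})
            raise CohortValidationError(f"duplicate patient_id(s): {dupes}")
        known = set(ids)
        pid_set = set(pids)
        for pheno in self.phenotypes:
            unknown = set(pheno.items) - known
            if unknown:
                raise CohortValidationError(
                    f"{pheno.patient_id}: unknown feature_id(s) {sorted(unknown)}"
                )
        for finding in self.findings:
            if finding.patient_id not in pid_set:
                raise CohortValidationError(
                    f"finding for {finding.patient_id} has no phenotype row"
                )

    @property
    def n_patients(self) -> int:
        return len(self.phenotypes)

    def feature(self, feature_id: str) -> ClinicalFeature:
        for f in self.catalog:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def finding_for(self, patient_id: str) -> Optional[GeneticFinding]:
        for f in self.findings:
            if f.patient_id == patient_id:
                return f
        return None


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

_PHENO_FIXED = ["patient_id", "sex", "age_dx_months", "age_eval_years"]
_FINDINGS_COLS = [
    "patient_id", "kind", "chrom", "start", "end", "terminal", "mechanism",
    "mosaic_fraction", "add22", "addOther", "annotation_json",
]
_CATALOG_COLS = ["feature_id", "label", "hpo_id", "category", "polarity"]


def _cell_to_state(cell) -> str:
    if pd.isna(cell) or str(cell).strip() == "":
        return MISSING
    token = str(cell).strip()
    if token in ("1", "1.0", PRESENT):
        return PRESENT
    if token in ("0", "0.0", ABSENT):
        return ABSENT
    raise CohortValidationError(f"invalid phenotype cell {cell!r} (expected 1/0/blank)")


def read_catalog(path) -> list[ClinicalFeature]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = set(_CATALOG_COLS) - set(df.columns)
    if missing_cols:
        raise CohortValidationError(f"catalog missing columns {sorted(missing_cols)}")
    out = []
    for _, row in df.iterrows():
        hpo = row["hpo_id"]
        out.append(
            ClinicalFeature(
                feature_id=row["feature_id"],
                label=row["label"],
                hpo_id=None if pd.isna(hpo) or hpo == "" else hpo,
                category=row["category"],
                polarity=row["polarity"],
            )
        )
    return out


def read_phenotypes(path, catalog: list[ClinicalFeature]) -> list[PatientPhenotype]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    feature_cols = [c for c in df.columns if c not in _PHENO_FIXED]
    known = {f.feature_id for f in catalog}
    unknown = set(feature_cols) - known
    if unknown:
        raise CohortValidationError(f"phenotype table has unknown feature_id(s) {sorted(unknown)}")
    out = []
    for _, row in df.iterrows():
        items = {fid: _cell_to_state(row[fid]) for fid in feature_cols}
        out.append(
            PatientPhenotype(
                patient_id=row["patient_id"],
                sex=row["sex"] if not pd.isna(row["sex"]) else "unknown",
                age_dx_months=None if pd.isna(row["age_dx_months"]) else float(row["age_dx_months"]),
                age_eval_years=None if pd.isna(row["age_eval_years"]) else float(row["age_eval_years"]),
                items=items,
            )
        )
    return out


def _parse_bool(cell) -> bool:
    if pd.isna(cell):
        return False
    return str(cell).strip().lower() in ("1", "true", "yes")


def read_findings(path) -> list[GeneticFinding]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for idx, row in df.iterrows():
        kind = row["kind"]
        interval = None
        if not pd.isna(row.get("start")) and str(row.get("start")).strip() != "":
            try:
                start1, end1 = int(float(row["start"])), int(float(row["end"]))
            except (TypeError, ValueError) as exc:
                raise CohortValidationError(
                    f"row {idx} ({row['patient_id']}): malformed coordinates"
                ) from exc
            interval = GenomicInterval.from_1based(start1, end1, chrom=str(row.get("chrom", "22")))
        ann = row.get("annotation_json")
        mosaic = row.get("mosaic_fraction")
        out.append(
            GeneticFinding(
                patient_id=row["patient_id"],
                kind=kind,
                interval=interval,
                terminal=_parse_bool(row.get("terminal")),
                mechanism=None if pd.isna(row.get("mechanism")) else row["mechanism"],
                mosaic_fraction=None if pd.isna(mosaic) or str(mosaic) == "" else float(mosaic),
                additional_rearr_chr22=_parse_bool(row.get("add22")),
                additional_rearr_other=_parse_bool(row.get("addOther")),
                variant_annotation=None if pd.isna(ann) or str(ann) == "" else json.loads(ann),
            )
        )
    return out


def read_cohort(phenotype_path, findings_path, catalog_path) -> Cohort:
    """Read and validate the three cohort tables.

    Blank phenotype cells map to ``missing``, never to ``absent``.
    """
    catalog = read_catalog(catalog_path)
    phenotypes = read_phenotypes(phenotype_path, catalog)
    findings = read_findings(findings_path)
    return Cohort(catalog=catalog, phenotypes=phenotypes, findings=findings)


def write_cohort(cohort: Cohort, phenotype_path, findings_path, catalog_path) -> None:
    cat = pd.DataFrame(
        [
            {
                "feature_id": f.feature_id,
                "label": f.label,
                "hpo_id": f.hpo_id or "",
                "category": f.category,
                "polarity": f.polarity,
            }
            for f in cohort.catalog
        ],
        columns=_CATALOG_COLS,
    )
    cat.to_csv(catalog_path, sep="\t", index=False)

    state_to_cell = {PRESENT: "1", ABSENT: "0", MISSING: ""}
    feature_ids = [f.feature_id for f in cohort.catalog]
    rows = []
    for p in cohort.phenotypes:
        row = {
            "patient_id": p.patient_id,
            "sex": p.sex,
            "age_dx_months": "" if p.age_dx_months is None else repr(p.age_dx_months),
            "age_eval_years": "" if p.age_eval_years is None else repr(p.age_eval_years),
        }
        for fid in feature_ids:
            row[fid] = state_to_cell[p.items.get(fid, MISSING)]
        rows.append(row)
    pd.DataFrame(rows, columns=_PHENO_FIXED + feature_ids).to_csv(
        phenotype_path, sep="\t", index=False
    )

    frows = []
    for f in cohort.findings:
        frows.append(
            {
                "patient_id": f.patient_id,
                "kind": f.kind,
                "chrom": f.interval.chrom if f.interval else "",
                "start": f.interval.start1 if f.interval else "",
                "end": f.interval.end1 if f.interval else "",
                "terminal": int(f.terminal),
                "mechanism": f.mechanism or "",
                "mosaic_fraction": "" if f.mosaic_fraction is None else repr(f.mosaic_fraction),
                "add22": int(f.additional_rearr_chr22),
                "addOther": int(f.additional_rearr_other),
                "annotation_json": json.dumps(f.variant_annotation) if f.variant_annotation else "",
            }
        )
    pd.DataFrame(frows, columns=_FINDINGS_COLS).to_csv(findings_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cohort-level summaries
# ---------------------------------------------------------------------------

def _pct(count: int, denom: int) -> float:
    return round(100.0 * count / denom, 1)


def summarize_counts(cohort: Cohort) -> pd.DataFrame:
    """Mechanism-group counts and percentages.

    Deletion subgroups use the number of deletion cases as denominator; the
    variant share uses the whole cohort, mirroring how such cohorts are
    tabulated.  Post-zygotic mosaicism and additional rearrangements are
    overlays counted across deletion cases.
    """
    if cohort.n_patients == 0:
        raise CohortValidationError("empty cohort")
    dels = [f for f in cohort.findings if f.kind == "deletion"]
    variants = [f for f in cohort.findings if f.kind == "shank3_variant"]
    n, nd = cohort.n_patients, len(dels)

    rows = [("deletions", len(dels), n)]
    if nd:
        mech_counts = {
            "simple_terminal": sum(f.mechanism == "simple_terminal" for f in dels),
            "ring22": sum(f.mechanism == "ring22" for f in dels),
            "unbalanced_translocations": sum(
                f.mechanism in ("unbalanced_translocation_de_novo", "unbalanced_translocation_inherited")
                for f in dels
            ),
            "interstitial": sum(f.mechanism == "interstitial" for f in dels),
        }
        rows += [(name, c, nd) for name, c in mech_counts.items()]
        rows.append(("postzygotic_mosaic", sum(f.mosaic_fraction is not None for f in dels), nd))
        rows.append(
            (
                "additional_rearrangements",
                sum(f.additional_rearr_chr22 or f.additional_rearr_other for f in dels),
                nd,
            )
        )
        rows.append(("additional_rearr_chr22", sum(f.additional_rearr_chr22 for f in dels), nd))
        rows.append(("additional_rearr_other", sum(f.additional_rearr_other for f in dels), nd))
    rows.append(("shank3_variants", len(variants), n))

    return pd.DataFrame(
        [
            {"group": g, "count": c, "denominator": d, "percent": _pct(c, d)}
            for g, c, d in rows
        ]
    )
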