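"""Parental origin of a 22q13 deletion from STR segregation in trios.

At a marker inside the deletion the proband is hemizygous: the single
retained allele must come from one parent, so the *other* parent
contributed the deleted chromosome.  A retained allele seen only in the
mother implies a paternal deletion, only in the father a maternal one,
in both parents the marker is uninformative, and in neither a Mendelian
inconsistency (genotyping error or non-paternity).

The default panel is six highly polymorphic markers within and around
SHANK3: D22S1169, D22S1149, D22S444, D22S1170, D22S295, D22S1141.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

DEFAULT_PANEL = ("D22S1169", "D22S1149", "D22S444", "D22S1170", "D22S295", "D22S1141")

PATERNAL = "paternal_deletion"
MATERNAL = "maternal_deletion"
UNINFORMATIVE = "uninformative"
INCONSISTENT = "inconsistent"


@dataclass
class Trio:
    proband_id: str
    # marker -> hemizygous proband allele (repeat length)
    proband: dict[str, int] = field(default_factory=dict)
    mother: dict[str, frozenset[int]] = field(default_factory=dict)
    father: dict[str, frozenset[int]] = field(default_factory=dict)


@dataclass
class OriginCall:
    proband_id: str
    per_marker: dict[str, str]
    consensus: str  # paternal | maternal | uninformative | conflict


def marker_origin(
    proband_allele: int, mother: frozenset[int], father: frozenset[int]
) -> str:
    """Verdict for one intra-deletion marker (proband hemizygous)."""
    if not mother and not father:
        warnings.warn("empty parental genotypes; marker uninformative")
        return UNINFORMATIVE
    in_mother = proband_allele in mother
    in_father = proband_allele in father
    if in_mother and in_father:
        return UNINFORMATIVE
    if in_mother:
        return PATERNAL
    if in_father:
        return MATERNAL
    return INCONSISTENT


def trio_consensus(trio: Trio, min_markers: int = 1) -> OriginCall:
    """Consensus parental origin over a trio's typed markers.

    Paternal iff at least ``min_markers`` paternal-deletion markers and no
    maternal ones (and symmetrically); both directions present means
    conflict.  Inconsistent markers are reported but excluded from the
    consensus.
    """
    if not trio.proband:
        raise ValueError(f"{trio.proband_id}: no markers typed")
    per_marker = {}
    for marker, allele in trio.proband.items():
        per_marker[marker] = marker_origin(
            allele,
            trio.mother.get(marker, frozenset()),
            trio.father.get(marker, frozenset()),
        )
    n_pat = sum(v == PATERNAL for v in per_marker.values())
    n_mat = sum(v == MATERNAL for v in per_marker.values())
    if n_pat and n_mat:
        consensus = "conflict"
    elif n_pat >= min_markers:
        consensus = "paternal"
    elif n_mat >= min_markers:
        consensus = "maternal"
    else:
        consensus = "uninformative"
    return OriginCall(proband_id=trio.proband_id, per_marker=per_marker, consensus=consensus)


def cohort_origin_summary(calls: list[OriginCall]) -> pd.DataFrame:
    """Counts and percentages of parental origin across trios.

    Paternal/maternal percentages are over informative trios; the
    noninformative share is over all trios.
    """
    if not calls:
        raise ValueError("no origin calls")
    n = len(calls)
    n_pat = sum(c.consensus == "paternal" for c in calls)
    n_mat = sum(c.consensus == "maternal" for c in calls)
    n_inf = n_pat + n_mat
    n_non = sum(c.consensus in ("uninformative", "conflict") for c in calls)
    rows = [
        ("paternal", n_pat, n_inf),
        ("maternal", n_mat, n_inf),
        ("noninformative", n_non, n),
    ]
    return pd.DataFrame(
        [
            {
                "origin": name,
                "count": count,
                "denominator": denom,
                "percent": round(100.0 * count / denom, 1) if denom else float("nan"),
            }
            for name, count, denom in rows
        ]
    )


def read_trio_table(path) -> list[Trio]:
    """Trio TSV: `trio_id  person  marker  allele1  allele2` with person in
    {proband, mother, father}; markers where the proband shows two alleles
    are outside the deletion and excluded."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    trios = []
    for tid, group in df.groupby("trio_id", sort=False):
        trio = Trio(proband_id=str(tid))
        for row in group.itertuples():
            a1 = None if pd.isna(row.allele1) or row.allele1 == "" else int(float(row.allele1))
            a2 = None
            if hasattr(row, "allele2") and not (pd.isna(row.allele2) or row.allele2 == ""):
                a2 = int(float(row.allele2))
            alleles = frozenset(a for a in (a1, a2) if a is not None)
            if row.person == "proband":
                if a1 is not None and a2 is None:
                    trio.proband[row.marker] = a1
                # two proband alleles: marker outside the deletion, skip
            elif row.person == "mother":
                trio.mother[row.marker] = alleles
            elif row.person == "father":
                trio.father[row.marker] = alleles
            else:
                raise ValueError(f"trio {tid}: unknown person {row.person!r}")
        trios.append(trio)
    return trios
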