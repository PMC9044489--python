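"""Laboratory-management decision engine for suspected Phelan-McDermid
syndrome.

Encodes the diagnostic pathway as a deterministic rule cascade over the
case's phenotype flags and test results:

* chromosome microarray (CMA) is the first-tier test in patients with
  intellectual disability, autism or congenital malformations;
* a terminal 22q13 deletion on CMA requires karyotyping to rule out a ring
  chromosome 22, and parental FISH when an unbalanced or balanced
  translocation is suspected;
* a diagnosis first made by MLPA or FISH still requires CMA to complete it
  (deletion size, gene content, additional rearrangements);
* suspected low-grade mosaicism calls for FISH on the proband;
* a confirmed ring 22 triggers an NF2 tumor-surveillance advisory
  (biallelic NF2 loss risk);
* when the full cytogenetic and molecular workup is negative but the
  phenotype still suggests the syndrome, exome or panel sequencing with
  extensive SHANK3 analysis is recommended.

Every emitted action carries the rule that produced it, and any state with
no further action resolves to an explicit terminal ("diagnosis complete" /
"workup exhausted"): the cascade has no dead ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

TESTS = ("CMA", "MLPA", "FISH", "karyotype", "exome_or_panel")
RESULTS = frozenset(
    {
        "not_done",
        "normal",
        "terminal_deletion",
        "interstitial_deletion",
        "mosaic_suspected",
        "translocation_suspected",
        "ring22_confirmed",
        "shank3_variant",
        "negative",
    }
)

#: Results that settle a test (re-running it is never recommended).
CONCLUSIVE = frozenset(
    {"normal", "negative", "terminal_deletion", "interstitial_deletion",
     "ring22_confirmed", "shank3_variant"}
)
POSITIVE = frozenset(
    {"terminal_deletion", "interstitial_deletion", "ring22_confirmed",
     "shank3_variant", "translocation_suspected", "mosaic_suspected"}
)


class CaseStateError(ValueError):
    """Contradictory or invalid case state."""


@dataclass
class CaseState:
    intellectual_disability: bool = False
    asd: bool = False
    congenital_malformations: bool = False
    pms_features: bool = False
    tests_done: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for test in TESTS:
            self.tests_done.setdefault(test, "not_done")
        unknown = set(self.tests_done) - set(TESTS)
        if unknown:
            raise CaseStateError(f"unknown tests {sorted(unknown)}")
        for test, result in self.tests_done.items():
            if result not in RESULTS:
                raise CaseStateError(f"{test}: unknown result {result!r}")
        if not (
            self.intellectual_disability
            or self.asd
            or self.congenital_malformations
            or self.pms_features
        ):
            raise CaseStateError("no phenotype flag set; pathway not triggered")
        if self._any_result("ring22_confirmed") and (
            self.tests_done["CMA"] == "not_done"
            and self.tests_done["karyotype"] == "not_done"
        ):
            raise CaseStateError(
                "ring 22 cannot be confirmed without CMA or karyotype"
            )

    def _any_result(self, result: str) -> bool:
        return any(r == result for r in self.tests_done.values())

    def result(self, test: str) -> str:
        return self.tests_done[test]


@dataclass(frozen=True)
class Recommendation:
    actions: tuple[tuple[str, str], ...]  # (action, rationale)

    @property
    def action_names(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.actions)


def _pending(state: CaseState, test: str) -> bool:
    return state.result(test) not in CONCLUSIVE


def next_actions(state: CaseState) -> Recommendation:
    """Ordered test recommendations for a case state.

    Deterministic; confirmatory cytogenetics (karyotype/FISH) are ordered
    before sequencing when several rules fire.
    """
    actions: list[tuple[str, str]] = []

    def add(action: str, rationale: str) -> None:
        if action not in (a for a, _ in actions):
            actions.append((action, rationale))

    all_not_done = all(r == "not_done" for r in state.tests_done.values())
    if all_not_done:
        add("CMA", "CMA is the first-tier test in ID/ASD/congenital-malformation referrals")
        return Recommendation(tuple(actions))

    # A diagnosis first established by MLPA or FISH still needs CMA.
    if state.result("CMA") == "not_done" and (
        state.result("MLPA") in POSITIVE or state.result("FISH") in POSITIVE
    ):
        add("CMA", "CMA remains mandatory to complete a diagnosis first made by MLPA/FISH")

    # Terminal deletions: karyotype to rule out ring 22.
    if state.result("CMA") == "terminal_deletion" and _pending(state, "karyotype"):
        add("karyotype", "terminal 22q13 deletions need karyotyping to rule out r(22)")

    # Translocation suspicion: parental FISH.
    if state._any_result("translocation_suspected"):
        add("parental_FISH", "parental FISH is mandatory on suspicion of an unbalanced or balanced translocation")

    # Mosaic suspicion: FISH on the proband.
    if state._any_result("mosaic_suspected") and _pending(state, "FISH"):
        add("FISH_proband", "low-grade mosaicism may be detected by FISH in the proband")

    # Ring 22 confirmed: tumor-surveillance advisory.
    if state._any_result("ring22_confirmed"):
        add(
            "NF2_tumor_surveillance",
            "r(22) carries an increased nervous-system tumor risk from biallelic NF2 loss",
        )

    # Exhausted negative workup with a suggestive phenotype: sequence SHANK3.
    performed = [r for r in state.tests_done.values() if r != "not_done"]
    all_negative = bool(performed) and all(r in ("normal", "negative") for r in performed)
    if (
        all_negative
        and state.pms_features
        and state.result("exome_or_panel") == "not_done"
    ):
        add(
            "exome_or_panel_SHANK3",
            "negative cytogenetic/molecular workup with PMS features: exome or panel with extensive SHANK3 analysis",
        )

    if not actions:
        if any(r in POSITIVE for r in state.tests_done.values()):
            add("diagnosis_complete", "genetic diagnosis established; no further laboratory testing indicated")
        else:
            add("workup_exhausted", "no pathway rule applies; clinical re-evaluation advised")
    return Recommendation(tuple(actions))
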