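"""Default clinical-feature catalog for 22q13 deletion (Phelan-McDermid)
cohorts, with the published microdeletion-cohort frequencies used to
calibrate the synthetic generator.

Each row is ``(feature_id, label, category, polarity, n_present,
n_evaluated)`` where the counts are the microdeletion-group frequencies of
the descriptive tables (denominators vary per item because not every item
was evaluable in every patient).  Three-level items are decomposed into
binary ones (speech into no-words / ability-to-make-sentences, growth into
the two extreme centile bands), giving 61 items in total — the size of the
per-feature regression screens run on this catalog.

``SIZE_LINKED`` lists the items whose prevalence the generator couples to
deletion size (the items reported to correlate with size), with the sign of
the logit slope: +1 means larger deletions make the item more likely.
"""

from __future__ import annotations

from .cohort import ClinicalFeature

# feature_id, label, category, polarity, n_present, n_evaluated
DEFAULT_FEATURES: list[tuple[str, str, str, str, int, int]] = [
    # development
    ("intellectual_disability", "Intellectual disability", "development", "adverse", 181, 189),
    ("developmental_delay", "Developmental delay", "development", "adverse", 139, 187),
    ("hypotonia", "Hypotonia", "development", "adverse", 142, 187),
    ("regressions", "Regressions", "development", "adverse", 90, 188),
    ("walk_le_15m", "Walk independently by 15 months", "development", "protective", 50, 189),
    ("sphincter_control", "Sphincter control", "development", "protective", 26, 187),
    # speech
    ("speech_delay", "Delayed or absent speech", "speech", "adverse", 184, 189),
    ("no_words", "No words", "speech", "adverse", 65, 181),
    ("ability_sentences", "Ability to make sentences", "speech", "protective", 46, 181),
    # comorbidity
    ("seizures", "Seizures", "comorbidity", "adverse", 58, 187),
    ("high_pain_threshold", "High pain threshold", "comorbidity", "adverse", 125, 187),
    ("decreased_perspiration", "Decreased perspiration", "comorbidity", "adverse", 99, 187),
    ("cardiac_anomalies", "Cardiac anomalies", "comorbidity", "adverse", 30, 189),
    ("ophthalmologic_anomalies", "Ophthalmologic anomalies", "comorbidity", "adverse", 41, 187),
    ("renal_urogenital_anomalies", "Renal and urogenital anomalies", "comorbidity", "adverse", 42, 188),
    ("lip_palate_abnormalities", "Lip/palate abnormalities", "comorbidity", "adverse", 17, 188),
    ("sleeping_disorders", "Sleeping disorders", "comorbidity", "adverse", 45, 187),
    ("skin_anomalies", "Skin anomalies", "comorbidity", "adverse", 42, 188),
    ("recurrent_infections", "Recurrent infections", "comorbidity", "adverse", 30, 187),
    ("herniae", "Herniae", "comorbidity", "adverse", 12, 187),
    ("obesity", "Obesity", "comorbidity", "adverse", 4, 188),
    ("hearing_problems", "Hearing problems", "comorbidity", "adverse", 20, 187),
    ("lymphedema", "Lymphedema", "comorbidity", "adverse", 18, 187),
    ("gastrointestinal_problems", "Gastrointestinal problems", "comorbidity", "adverse", 34, 187),
    ("brain_mri_abnormal", "Abnormal brain MRI", "comorbidity", "adverse", 36, 95),
    ("growth_gt_95", "Growth centile >95th", "comorbidity", "adverse", 60, 188),
    ("growth_lt_3", "Growth centile <3rd", "comorbidity", "adverse", 23, 188),
    # dysmorphic
    ("microcephaly", "Microcephaly", "dysmorphic", "adverse", 37, 188),
    ("macrocephaly", "Macrocephaly", "dysmorphic", "adverse", 49, 188),
    ("dolichocephaly", "Dolichocephaly", "dysmorphic", "adverse", 38, 188),
    ("flat_midface", "Flat midface", "dysmorphic", "adverse", 26, 187),
    ("epicanthal_folds", "Epicanthal folds", "dysmorphic", "adverse", 54, 188),
    ("strabismus", "Strabismus", "dysmorphic", "adverse", 49, 187),
    ("ptosis", "Ptosis", "dysmorphic", "adverse", 34, 187),
    ("long_eyelashes", "Long eyelashes", "dysmorphic", "adverse", 107, 187),
    ("full_eyebrow", "Full eyebrow", "dysmorphic", "adverse", 74, 187),
    ("full_puffy_eyelids", "Full/puffy eyelids", "dysmorphic", "adverse", 43, 187),
    ("deep_set_eyes", "Deep set eyes", "dysmorphic", "adverse", 44, 187),
    ("wide_nasal_bridge", "Wide nasal bridge", "dysmorphic", "adverse", 105, 187),
    ("bulbous_nose", "Bulbous nose", "dysmorphic", "adverse", 108, 187),
    ("ear_anomalies", "Ear anomalies", "dysmorphic", "adverse", 86, 188),
    ("full_puffy_cheeks", "Full/puffy cheeks", "dysmorphic", "adverse", 42, 187),
    ("widely_spaced_teeth", "Widely spaced teeth/malocclusion", "dysmorphic", "adverse", 88, 187),
    ("pointed_chin", "Pointed chin", "dysmorphic", "adverse", 109, 187),
    ("toe_syndactyly", "2/3 toe syndactyly", "dysmorphic", "adverse", 51, 187),
    ("large_fleshy_hands", "Large, fleshy hands", "dysmorphic", "adverse", 101, 187),
    ("fifth_finger_clinodactyly", "Fifth finger clinodactyly", "dysmorphic", "adverse", 35, 187),
    ("hypoplastic_nails", "Hypoplastic/dysplastic nails", "dysmorphic", "adverse", 76, 187),
    # behavior
    ("behavior_abnormalities", "Behavior abnormalities", "behavior", "adverse", 148, 187),
    ("poor_visual_contact", "Poor visual contact", "behavior", "adverse", 106, 187),
    ("biting", "Biting", "behavior", "adverse", 70, 186),
    ("very_sensitive_touch", "Very sensitive to touch", "behavior", "adverse", 61, 187),
    ("uncontrolled_laughter", "Uncontrolled laughter", "behavior", "adverse", 69, 187),
    ("impulsive", "Impulsive", "behavior", "adverse", 97, 187),
    ("excessive_yelling", "Excessive yelling", "behavior", "adverse", 69, 186),
    ("hair_pulling", "Hair pulling", "behavior", "adverse", 42, 187),
    ("skin_picking", "Skin picking", "behavior", "adverse", 43, 187),
    ("nonstop_crying", "Nonstop crying", "behavior", "adverse", 26, 187),
    ("aggressive_behavior", "Aggressive behavior", "behavior", "adverse", 36, 187),
    ("tongue_thrusting", "Tongue thrusting, sticking out", "behavior", "adverse", 62, 187),
    ("abnormal_emotional_response", "Abnormal emotional response", "behavior", "adverse", 98, 187),
]

#: Reference size of the microdeletion group behind the counts above.
N_DELETION_COHORT = 189

#: Items coupled to deletion size in the generator, with logit-slope sign.
#: Adverse items on this list become more frequent with larger deletions
#: (+1); protective items and microcephaly (reported in small deletions
#: only) become less frequent (-1).
SIZE_LINKED: dict[str, int] = {
    "ability_sentences": -1,
    "sphincter_control": -1,
    "microcephaly": -1,
    "lymphedema": +1,
    "macrocephaly": +1,
    "renal_urogenital_anomalies": +1,
    "seizures": +1,
    "brain_mri_abnormal": +1,
    "deep_set_eyes": +1,
    "growth_gt_95": +1,
    "herniae": +1,
    "abnormal_emotional_response": +1,
    "toe_syndactyly": +1,
    "epicanthal_folds": +1,
}


def default_catalog() -> list[ClinicalFeature]:
    """The 61-item default catalog."""
    return [
        ClinicalFeature(feature_id=fid, label=label, category=cat, polarity=pol)
        for fid, label, cat, pol, _, _ in DEFAULT_FEATURES
    ]


def default_prevalences() -> dict[str, float]:
    """Per-item baseline prevalence among evaluated patients."""
    return {fid: n_yes / n_tot for fid, _, _, _, n_yes, n_tot in DEFAULT_FEATURES}


def default_missing_rates() -> dict[str, float]:
    """Per-item missingness relative to the reference deletion cohort size."""
    return {
        fid: max(0.0, 1.0 - n_tot / N_DELETION_COHORT)
        for fid, _, _, _, _, n_tot in DEFAULT_FEATURES
    }
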