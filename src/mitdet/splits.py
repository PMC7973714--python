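"""Patient-disjoint cross-validation bookkeeping for the public mitosis benchmarks.

The TUPAC16 auxiliary dataset (73 patients) is split so that no patient
appears in more than one of train/validation/test; the MITOS12 and MITOS14
training patients augment the training set only.  The split below is the
published benchmark split, stored verbatim so experiment code can assert
patient disjointness instead of trusting it.
"""

from __future__ import annotations

__all__ = [
    "TUPAC16_TRAIN_PATIENTS",
    "TUPAC16_VALIDATION_PATIENTS",
    "TUPAC16_TEST_PATIENTS",
    "split_summary",
    "check_patient_disjoint",
]

TUPAC16_TRAIN_PATIENTS = (
    1, 2, 3, 5, 7, 8, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 22, 23, 24,
    25, 28, 33, 34, 35, 37, 38, 40, 42, 44, 47, 49, 51, 52, 54, 59, 61, 64,
    68, 69, 70, 72,
)

TUPAC16_VALIDATION_PATIENTS = (4, 6, 9, 21, 26, 29, 31, 39, 46, 48, 56, 65, 67, 73)

TUPAC16_TEST_PATIENTS = (27, 30, 32, 36, 41, 43, 45, 50, 53, 55, 57, 58, 60, 62, 63, 66, 71)


def split_summary() -> dict:
    """Patient counts per split; raises if the split is not patient-disjoint."""
    check_patient_disjoint(
        TUPAC16_TRAIN_PATIENTS, TUPAC16_VALIDATION_PATIENTS, TUPAC16_TEST_PATIENTS
    )
    return {
        "train": len(TUPAC16_TRAIN_PATIENTS),
        "validation": len(TUPAC16_VALIDATION_PATIENTS),
        "test": len(TUPAC16_TEST_PATIENTS),
        "total": len(TUPAC16_TRAIN_PATIENTS)
        + len(TUPAC16_VALIDATION_PATIENTS)
        + len(TUPAC16_TEST_PATIENTS),
    }


def check_patient_disjoint(*groups) -> None:
    seen: set = set()
    for g in groups:
        s = set(g)
        if len(s) != len(tuple(g)):
            raise ValueError("duplicate patient within a split")
        if seen & s:
            raise ValueError(f"patients appear in multiple splits: {sorted(seen & s)}")
        seen |= s
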