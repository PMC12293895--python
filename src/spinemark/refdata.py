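"""Published reference-cohort values.

Reported figures from the multicenter lumbar-radiograph study this
toolkit operationalizes: per-rater malposition tallies, per-rater
weighted-F1 scores under global and local cutoffs, the case-exclusion
flow, the sample-size inputs, and the per-level optimal cutoff angles.

They serve two purposes: (a) inputs to the arithmetic self-checks
(`spinemark repro` and the test suite recompute every derived figure —
column totals, ratios, means — from these cells), and (b) defaults for
the simulator's latent rater cutoffs.
"""

from __future__ import annotations

import pandas as pd

#: Sample-size formula inputs: 99% confidence, maximal-variance
#: proportion, 3% margin of error.
SAMPLE_SIZE_PARAMS = {"z": 2.576, "p": 0.5, "e": 0.03}

#: Cases retrieved from the radiology archive before exclusions.
REFERENCE_INITIAL_CASES = 3605

#: Ordered exclusion steps (reason, count) applied to the archive pull.
REFERENCE_EXCLUSIONS: list[tuple[str, int]] = [
    ("fracture", 137),
    ("metal instrumentation", 122),
    ("severe degenerative change", 560),
    ("lumbar sacralization", 426),
    ("sacral lumbarization", 324),
    ("poor image quality", 36),
]

#: Per-rater malposition tallies. Each rater read 400 cases x 5 levels
#: (n = 2000 vertebrae) except rotation, which excludes L5 (n = 1600).
REFERENCE_RATER_TALLIES = pd.DataFrame(
    {
        "flexion": [985, 451, 945, 52, 192],
        "extension": [44, 102, 131, 34, 144],
        "right_bending": [320, 147, 358, 188, 62],
        "left_bending": [453, 195, 365, 216, 63],
        "right_rotation": [170, 60, 202, 101, 74],
        "left_rotation": [171, 253, 391, 210, 113],
    },
    index=["R1", "R2", "R3", "R4", "R5"],
)

#: Per-rater weighted F1 under the global (shared) and local (per-rater)
#: optimal cutoffs, by malposition type.
REFERENCE_F1_SCORES = pd.DataFrame(
    {
        ("global", "sagittal"): [0.81, 0.76, 0.72, 0.80, 0.70],
        ("global", "coronal"): [0.93, 0.91, 0.67, 0.86, 0.88],
        ("global", "axial"): [0.72, 0.75, 0.52, 0.73, 0.82],
        ("local", "sagittal"): [0.89, 0.78, 0.79, 0.95, 0.81],
        ("local", "coronal"): [0.94, 0.91, 0.70, 0.86, 0.94],
        ("local", "axial"): [0.73, 0.76, 0.55, 0.74, 0.84],
    },
    index=["R1", "R2", "R3", "R4", "R5"],
)
REFERENCE_F1_SCORES.columns = pd.MultiIndex.from_tuples(
    REFERENCE_F1_SCORES.columns, names=["regime", "type"])

#: Reported column means +- SD of REFERENCE_F1_SCORES (2 decimals).
REFERENCE_F1_MEANS = {
    ("global", "sagittal"): 0.76, ("global", "coronal"): 0.85,
    ("global", "axial"): 0.71, ("local", "sagittal"): 0.84,
    ("local", "coronal"): 0.87, ("local", "axial"): 0.72,
}

#: Per-level optimal cutoff angles (degrees), L1..L5.  Flexion is
#: diagnosed below the flexion value, extension above the extension
#: value (one signed scale); bending and rotation are magnitudes.
REFERENCE_CUTOFFS: dict[str, tuple[float, ...]] = {
    "flexion": (0.64, 3.56, 5.29, 8.90, 8.53),
    "extension": (10.46, 14.95, 17.61, 20.76, 24.47),
    "lateral_bending": (2.21, 2.10, 1.92, 2.06, 2.31),
    "rotation": (9.49, 5.19, 4.59, 5.87, 7.13),
}

#: Reported sacral-rotation screen cutoff (Q3 + 1.5 IQR of the cohort's
#: r values); context only — it depends on the unavailable cohort.
REFERENCE_SACRAL_CUTOFF = 0.0886
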