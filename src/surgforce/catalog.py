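"""Fixed vocabularies: task labels, experience levels, the 37-feature catalogue.

The feature catalogue is closed and ordered; every feature extraction returns
exactly these names in exactly this order.  Units: ``duration``,
``cycle_length``, ``acf_first_min_time`` and ``acf_first_zero_time`` are in
seconds; force moments, peaks and shift magnitudes are in Newtons (variance
shifts in N^2); everything else is dimensionless.
"""

from __future__ import annotations

TASKS: tuple[str, ...] = (
    "Retracting",
    "Manipulation",
    "Dissecting",
    "Pulling",
    "Coagulation",
)

EXPERIENCE_LEVELS: tuple[str, ...] = ("Expert", "Novice")

EVENT_FLAGS: frozenset[str] = frozenset(
    {"high_force_error", "low_force_error", "bleeding", "repeat_task"}
)

#: The 37 segment features, in canonical order.
FEATURE_CATALOG: tuple[str, ...] = (
    "duration",
    "mean",
    "max",
    "min",
    "range",
    "median",
    "sd",
    "cv",
    "mean_ci95_halfwidth",
    "skewness",
    "skewness_2se",
    "kurtosis",
    "kurtosis_2se",
    "shapiro_w",
    "shapiro_p",
    "peak_value",
    "peak_count",
    "d1_sd",
    "flat_spots",
    "dominant_freq",
    "cycle_length",
    "trend",
    "fluctuation",
    "spikiness",
    "linearity",
    "stability",
    "lumpiness",
    "curvature",
    "max_mean_shift",
    "max_var_shift",
    "max_kl_shift",
    "kpss_stat",
    "spectral_entropy",
    "acf_first_min_time",
    "acf_first_zero_time",
    "acf_e1",
    "acf_e10",
)

#: Features dropped by the fixed model-subset rule, leaving the 25 retained
#: for skill modelling (they showed no useful group separation in screening).
FIXED_SUBSET_EXCLUSIONS: tuple[str, ...] = (
    "duration",
    "min",
    "cv",
    "skewness",
    "skewness_2se",
    "d1_sd",
    "peak_count",
    "cycle_length",
    "spikiness",
    "kpss_stat",
    "acf_first_zero_time",
    "acf_e10",
)

#: Metadata columns carried alongside features in a feature table.
METADATA_COLUMNS: tuple[str, ...] = (
    "segment_id",
    "case_id",
    "task",
    "surgeon_id",
    "experience",
)
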