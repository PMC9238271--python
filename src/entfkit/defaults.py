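"""All method constants in one place, overridable per run.

Values mirror the validated assay settings: MRM retention-time windows
and acceptance thresholds, Transwell geometry, alignment gap penalties
and importance multipliers, and the scan's class count.
"""

from __future__ import annotations

DEFAULTS: dict = {
    "detection": {
        "ratio_bounds": [2.0, 4.0],
        "sn_threshold": 3.0,
        "loq_pm": 100.0,
        "rt_windows": {
            "LC1MS1": [4.25, 4.45],
            "LC2MS1": [4.85, 4.95],
            "LC1MS2": [3.40, 3.50],
            "LC1MS3": [4.13, 4.16],
        },
        "hr_tolerance": {"LC1MS2": 0.05, "LC1MS3": 0.005},
        "min_daughters": {"LC1MS2": 4, "LC1MS3": 2},
        "min_isotopes": {"LC1MS2": 3, "LC1MS3": 4},
    },
    "kinetics": {
        "transwell_area_cm2": 1.12,
        "donor_conc_mol_per_cm3": 1e-9,
        "receiver_volume_ul": 1500.0,
        "sample_volume_ul": 300.0,
        "pk_breakpoint_min": 30.0,
        "exposure_window_min": 1440.0,
        "endogenous_conc_nm": 0.329,
    },
    "alignment": {
        "gap_open": 10.0,
        "gap_extend": 0.5,
        "rank_multipliers": {"1": 3, "2": 2},
        "rank1_positions": [1, 2, 10],
        "rank2_positions": [3, 9],
    },
    "alascan": {"k_classes": 5, "scale": "root-probit"},
    "qpcr": {"lod_copies_per_g": 1e5, "dilution_range": [1e1, 1e7]},
}
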