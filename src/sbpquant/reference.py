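"""Published reference values from the motivating clinical study.

The quantification method was developed on an in-vivo confocal
cohort of 20 healthy volunteers and 18 type-2 diabetic patients with
neuropathy.  The raw images of that study were never deposited, but
its printed per-group summaries (normalised to 1 mm² of corneal
surface) and the individual clinical values of the diabetic group
are reproducible inputs for the statistics layer: they drive the
summary-statistics Welch tests, the unit-consistency checks and the
simulated-cohort discriminant analysis.

All values are stored exactly as printed.
"""

from __future__ import annotations

N_HEALTHY = 20
N_DIABETIC = 18

#: Per-group (mean, sd) of the normalised morphometric parameters.
#: Lengths in µm per mm², density in µm of fibre per µm² (the scale on
#: which a healthy plexus is ~0.02), counts per mm².
GROUP_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    "control": {
        "component_pixels": (52863.8, 19766.0),
        "skeleton_pixels": (16469.7, 5430.3),
        "component_ratio_pct": (5.7, 2.1),
        "single_nerve_fibres": (302.2, 148.9),
        "fibres_per_component": (8.8, 6.5),
        "total_fibre_length_um": (19961.3, 6552.9),
        "avg_single_fibre_length_um": (74.8, 26.0),
        "fibre_density_um_per_um2": (0.02, 0.007),
        "n_connectivity_points": (21.8, 9.9),
        "n_branches": (141.9, 85.7),
        "homogeneity": (0.009, 0.004),
    },
    "diabetic": {
        "component_pixels": (21756.6, 8363.2),
        "skeleton_pixels": (5223.6, 2060.1),
        "component_ratio_pct": (2.4, 0.9),
        "single_nerve_fibres": (78.1, 53.2),
        "fibres_per_component": (3.4, 3.5),
        "total_fibre_length_um": (6223.1, 2419.2),
        "avg_single_fibre_length_um": (95.8, 42.0),
        "fibre_density_um_per_um2": (0.006, 0.002),
        "n_connectivity_points": (5.8, 5.8),
        "n_branches": (25.3, 28.6),
        "homogeneity": (0.014, 0.005),
    },
}

#: The two predictors that suffice for the published discriminant
#: separation of the groups.
DISCRIMINANT_VARIABLES = ("component_ratio_pct", "fibre_density_um_per_um2")

#: Individual clinical values of the 18 diabetic-neuropathy patients
#: (diabetes duration in years, HbA1c in %, neuropathy scores in points).
DIABETES_DURATION_YRS = [12, 24, 6, 24, 28, 22, 14, 6, 37, 18, 1, 9, 3, 11, 7, 27, 10, 14]
HBA1C_PCT = [8.7, 8.7, 11.0, 8.4, 9.9, 11.2, 5.5, 7.3, 8.7, 7.9, 7.1, 7.6, 7.2, 7.2, 5.2, 9.7, 8.8, 7.6]
NSS_PTS = [7, 10, 4, 7, 5, 10, 9, 9, 7, 7, 8, 8, 7, 4, 8, 10, 3, 5]
NDS_PTS = [4, 10, 4, 8, 6, 8, 9, 8, 8, 10, 9, 8, 6, 3, 9, 8, 4, 10]
RETINOPATHY = ["NDR", "DR", "NDR", "DR", "DR", "DR", "NDR", "NDR", "DR",
               "DR", "NDR", "NDR", "NDR", "NDR", "NDR", "DR", "NDR", "NDR"]
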