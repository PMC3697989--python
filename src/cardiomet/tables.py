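"""Published group-level endpoints of the fructose / low-intensity-training study.

Each entry maps an endpoint to per-group ``(mean, sem)`` pairs for the
control (C), sedentary fructose (F) and fructose-trained (FT) groups,
with n = 8 animals per group.  These numbers parameterize the synthetic
cohort generator and serve as inputs to the percent-change arithmetic;
they are group summaries, not per-animal data.
"""

from __future__ import annotations

import math

GROUPS = ("C", "F", "FT")

#: Number of animals per group in the study design.
N_PER_GROUP = 8

#: D-fructose concentration in the drinking water, g/L.
FRUCTOSE_G_PER_L = 100.0

#: Insulin bolus for the tolerance test, U/kg i.p.
INSULIN_DOSE_U_PER_KG = 0.75

#: Blood-glucose sampling times of the insulin tolerance test, minutes.
ITT_TIMES_MIN = (0.0, 4.0, 8.0, 12.0, 16.0)

#: endpoint -> group -> (mean, SEM).  Units in the comment per row.
ENDPOINTS: dict[str, dict[str, tuple[float, float]]] = {
    # -- metabolic (final evaluation) --
    "glycemia": {"C": (84, 5), "F": (76, 4), "FT": (88, 3)},          # mg/dL
    "triglycerides": {"C": (96, 4), "F": (240, 6), "FT": (160, 10)},  # mg/dL
    "kitt": {"C": (5.0, 0.3), "F": (2.8, 0.3), "FT": (3.5, 0.1)},     # %/min
    "wat": {"C": (3.2, 0.1), "F": (6.1, 0.2), "FT": (3.1, 0.2)},      # g
    "body_weight": {"C": (440, 9), "F": (438, 10), "FT": (446, 11)},  # g
    "chow": {"C": (13.1, 0.2), "F": (8.2, 0.4), "FT": (9.1, 0.3)},    # g/day
    "fluid": {"C": (17.7, 0.4), "F": (39.1, 1.4), "FT": (38.7, 1.0)}, # mL/day
    # -- hemodynamics --
    "sap": {"C": (122, 2), "F": (151, 3), "FT": (142, 2)},            # mmHg
    "dap": {"C": (95, 2), "F": (118, 3), "FT": (112, 4)},             # mmHg
    "map": {"C": (111, 3), "F": (140, 6), "FT": (125, 5)},            # mmHg
    "hr": {"C": (325, 12), "F": (344, 10), "FT": (352, 4)},           # bpm
    "tr": {"C": (3.23, 0.42), "F": (1.91, 0.12), "FT": (2.55, 0.11)}, # bpm/mmHg
    "br": {"C": (-1.71, 0.12), "F": (-1.32, 0.11), "FT": (-1.41, 0.08)},
    "sap_var": {"C": (23.5, 2.6), "F": (41.9, 6.5), "FT": (21.7, 4.4)},  # mmHg^2
    "sap_lf": {"C": (3.0, 0.5), "F": (8.1, 0.6), "FT": (3.4, 0.6)},   # mmHg^2
    # -- right atrium ANP granules --
    "nv_granules": {"C": (22.1, 2.3), "F": (10.8, 1.4), "FT": (18.7, 1.5)},
    "vv_granules": {"C": (5.3, 0.6), "F": (3.7, 0.6), "FT": (4.8, 0.5)},   # %
    "granule_area": {"C": (1785, 40), "F": (2030, 66), "FT": (1754, 35)},  # nm^2
    "vv_mitochondria": {"C": (25.8, 2.1), "F": (14.1, 1.2), "FT": (32.7, 1.9)},
    "vv_myofibrils": {"C": (23.9, 2.1), "F": (23.1, 1.9), "FT": (23.7, 2.3)},
    # -- left ventricle --
    "heart_weight": {"C": (1.31, 0.04), "F": (1.42, 0.01), "FT": (1.25, 0.03)},
    "htw_bw": {"C": (2.8, 0.1), "F": (3.4, 0.1), "FT": (2.7, 0.1)},   # x10^-3
    "myocyte_area": {"C": (479, 18), "F": (588, 22), "FT": (674, 48)},  # um^2
    "nv_myocytes": {"C": (6.3, 0.3), "F": (9.7, 0.3), "FT": (8.0, 0.5)},  # /mm^2
    "nv_capillaries": {"C": (5.4, 0.3), "F": (3.9, 0.1), "FT": (5.2, 0.2)},
    "lv_vv_collagen": {"C": (7.7, 0.8), "F": (13.7, 1.5), "FT": (8.7, 1.5)},  # %
    "vv_myocytes": {"C": (73.2, 1.8), "F": (81.4, 1.2), "FT": (74.8, 1.6)},
    "vv_capillaries": {"C": (3.6, 0.5), "F": (3.1, 0.3), "FT": (3.6, 0.4)},
    # -- ascending aorta --
    "aorta_area": {"C": (0.71, 0.04), "F": (0.96, 0.02), "FT": (0.65, 0.01)},  # mm^2
    "aorta_diameter": {"C": (0.95, 0.02), "F": (1.15, 0.05), "FT": (0.86, 0.04)},  # mm
    "imt": {"C": (158.1, 0.7), "F": (177.3, 3.1), "FT": (153.4, 1.1)},  # um
    "aorta_vv_collagen": {"C": (1.51, 0.22), "F": (7.92, 0.61), "FT": (1.92, 0.04)},
    "elastic_lamellae": {"C": (13.3, 0.1), "F": (10.4, 0.3), "FT": (12.5, 0.2)},
    "cwt": {"C": (62, 3), "F": (81, 5), "FT": (61, 5)},               # mmHg*mm
}


def group_mean(endpoint: str, group: str) -> float:
    return ENDPOINTS[endpoint][group][0]


def group_sem(endpoint: str, group: str) -> float:
    return ENDPOINTS[endpoint][group][1]


def group_sd(endpoint: str, group: str, n: int = N_PER_GROUP) -> float:
    """Between-animal SD implied by a published SEM (SD = SEM * sqrt(n))."""
    return ENDPOINTS[endpoint][group][1] * math.sqrt(n)
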