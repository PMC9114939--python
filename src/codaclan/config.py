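"""Study-area constants, island gazetteer and reference scale table.

Everything here is a plain module-level constant so that analyses are
reproducible from the package alone; all of it can be overridden through
function arguments in the analysis modules.
"""

#: (lat, lon) origin of the local planar projection, mid Lesser Antilles.
STUDY_ORIGIN = (14.5, -61.0)

EARTH_RADIUS_KM = 6371.0

#: Island centroids (lat, lon) used to attach an island label to sightings.
ISLAND_GAZETTEER = {
    "St. Kitts & Nevis": (17.30, -62.73),
    "Antigua": (17.07, -61.80),
    "Guadeloupe": (16.17, -61.60),
    "Dominica": (15.42, -61.35),
    "Martinique": (14.64, -61.02),
    "St. Lucia": (13.91, -60.97),
    "St. Vincent": (13.25, -61.19),
    "Grenada": (12.11, -61.68),
}

#: Published Eastern Tropical Pacific scale summaries used as the comparison
#: reference by :func:`codaclan.movement_spatial.compare_scales`.
ETP_REFERENCE = {
    "n_vocal_clans": 5.0,
    "mean_social_unit_size": 12.2,       # mean of Regular 13.6 and Plus-One 10.7
    "mean_group_size": 30.4,
    "displacement_3h_km": 10.5,          # mean of Regular 10.2 and Plus-One 10.7
    "displacement_6h_km": 18.1,          # mean of Regular 16.8 and Plus-One 19.4
    "daily_rms_km": 50.0,
    "yearly_rms_km": 1000.0,
    "max_female_displacement_km": 5000.0,
    "range_km": 1500.0,
}

#: Default thresholds of the identity-coda clan delineation.
IDCALL_DEFAULTS = {"u_min": 0.05, "prevalence_min": 0.5, "out_max": 0.05}

#: Default robustness-sweep grid (3 x 3 x 3 threshold combinations).
SWEEP_GRID_DEFAULT = {
    "u_min": (0.03, 0.05, 0.10),
    "prevalence_min": (0.4, 0.5, 0.6),
    "out_max": (0.03, 0.05, 0.10),
    "similarity_mode": ("bhattacharyya",),
}

PHOTO_QUALITY_MIN = 3
ASSOCIATION_WINDOW_HOURS = 2.0
CODA_MIN_CLICKS = 3
CODA_MAX_CLICKS = 11
REPERTOIRE_MIN_CODAS = 25

#: Displacement samples implying a faster speed indicate a track error.
SPEED_GUARD_KMH = 12.0
#: Survey vessel cruise speed, four knots.
CRUISE_SPEED_KMH = 7.408

#: Default lag-bin edges (days) for the RMS-displacement likelihood.
DEFAULT_LAG_BIN_EDGES = (1, 2, 5, 10, 30, 90, 180, 365, 500)
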