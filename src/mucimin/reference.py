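"""Reference experimental values for the A. muciniphila minimal-medium study.

These constants are the measured study conditions that parameterise the
synthetic-data generators and against which the analysis stages are
benchmarked: specific growth rates on CP medium + 6 g/l L-threonine +
25 mM total sugar, NagB Michaelis constants from triplicate initial-rate
assays, and the fermentation acetate:propionate yield ratios.
"""

from __future__ import annotations

#: specific growth rates mu (1/h) and across-replicate SD per sugar condition
GROWTH_RATES = {
    "GlcNAc/Glc": (0.122, 0.036),
    "GlcNAc": (0.056, 0.023),
    "GalNAc": (0.084, 0.014),
    "GlcN/Glc": (0.005, 0.004),
    "GlcN": (0.0, 0.002),
    "Fru": (0.0, 0.0),
    "Glc": (0.0, 0.0),
}

#: NagB Km (mM) mean +/- SD without activator (n = 3)
KM_VALUES = {
    "Fru6P": (5.5, 0.9),
    "NH4": (41.3, 12.8),
    "GlcN6P": (2.4, 0.2),
}

#: acetate:propionate molar production ratios per condition
SCFA_RATIOS = {
    "GlcNAc/Glc": 1.0,  # 1:1
    "GlcNAc": 1.75,  # mid of the observed 1.5:1 - 2:1 band
    "GalNAc": 1.75,
    "Glc/GlcN": 0.5,  # 1:2
}

#: genome-scale model v2 dimensions (reactions, metabolites)
MODEL_V2_COUNTS = (748, 737)

#: growth optima (a.u.) reported for the genome-scale v2 model per medium
MODEL_V2_AU = {
    "glucose_glcn": 0.0,
    "glcn": 0.0,
    "glcnac": 0.09,
    "glcnac_glucose": 0.13,
    "galnac": 0.09,
    "glucose": 0.0,
}

#: y/n growth pattern of the curated (v2-like) model across the six media
MODEL_V2_PATTERN = {
    "glucose_glcn": False,
    "glcn": False,
    "glcnac": True,
    "glcnac_glucose": True,
    "galnac": True,
    "glucose": False,
}

#: y/n growth pattern of the original (v1-like, GlmS-containing) model
MODEL_V1_PATTERN = {
    "glucose_glcn": True,
    "glcn": False,
    "glcnac": True,
    "glcnac_glucose": True,
    "galnac": True,
    "glucose": True,
}

#: acetate:propionate exchange-flux ratio the genome-scale model predicts on GlcNAc
MODEL_SCFA_RATIO = 1.25  # 5:4

#: order of the media as tabulated
MEDIA_ORDER = (
    "glucose_glcn", "glcn", "glcnac", "glcnac_glucose", "galnac", "glucose",
)
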