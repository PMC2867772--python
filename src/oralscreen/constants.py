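"""Documented reference constants from the original clinical study.

The clinical image set this pipeline was designed around is not publicly
deposited, so the operating points and AUC values reported for it cannot be
recomputed here.  They are retained as metadata — embedded in reports for
comparison, never used as algorithm defaults.
"""

#: Consensus clinical impression counts of the measured sites, by
#: (category, confounder) cell.  These drive the synthetic generator's
#: default dataset composition.
CLINICAL_SITE_COUNTS = {
    ("Normal", "none"): 222,
    ("LowRisk", "none"): 30,
    ("HighRisk", "none"): 22,
    ("Cancer", "none"): 37,
    ("Normal", "melanosis"): 8,
    ("LowRisk", "melanosis"): 22,
    ("HighRisk", "melanosis"): 0,
    ("Cancer", "melanosis"): 0,
    ("Normal", "osf"): 2,
    ("LowRisk", "osf"): 8,
    ("HighRisk", "osf"): 0,
    ("Cancer", "osf"): 0,
}

#: Q-point operating points reported for the two headline features on the
#: original clinical data (thresholds on the normalized-feature scale;
#: sensitivity/specificity as fractions).
REFERENCE_OPERATING_POINTS = {
    "norm_mfi_b": {"threshold": 0.86, "sensitivity": 0.92, "specificity": 0.84},
    "norm_mfi_ratio_rg": {"threshold": 1.11, "sensitivity": 0.90, "specificity": 0.87},
}

#: Top-five feature AUCs reported on the original clinical data.
REFERENCE_TOP5_AUC = {
    "norm_mfi_g": 0.91,
    "norm_mfi_b": 0.91,
    "norm_mfi_ratio_rg": 0.90,
    "norm_mfi_gray": 0.89,
    "norm_mfi_r": 0.85,
}

#: Normalized red/green MFI threshold reported by an independent
#: multispectral-microscope study at comparable excitation, documented for
#: cross-device comparison only.
EXTERNAL_RG_THRESHOLD = 1.09
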