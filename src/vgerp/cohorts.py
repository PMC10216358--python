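"""Reference synthetic study configurations.

These are the cohort designs the package's validation studies run on: a
patient-vs-control discrimination cohort with strongly diminished late ERP
components in the patient group, a matched null cohort with no group
effect, a three-group design whose prodromal group sits between patients
and controls, and a small noise-only cohort for significance-level
calibration.

Group sizes in the discrimination and generalization designs follow the
clinical layout the pipeline targets (11 robust normal elderly, 15 AD,
15 prodromal AD; 72 trials per condition at 250 Hz).  The spatial/spectral
grid is reduced to three midline-ish channels, two word conditions and two
bands, which keeps a full study inside interactive run times without
changing any of the statistical properties being validated (t-test
calibration, separability, group intermediacy are all grid-size
invariant).

The ERP effect structure mirrors the word-repetition phenomenology the
pipeline is built around: an N400-like negative deflection (~400 ms) and a
P600-like positive deflection (~600 ms), both strongly diminished in the
patient group and partially diminished in the prodromal group.
"""

from __future__ import annotations

from .synth import ERPComponent, SyntheticConfig

__all__ = [
    "STUDY_CHANNELS",
    "STUDY_CONDITIONS",
    "STUDY_BANDS",
    "CALIBRATION_BANDS",
    "discrimination_study",
    "null_study",
    "generalization_study",
    "calibration_study",
]

STUDY_CHANNELS = ("Fz", "Cz", "Pz")
STUDY_CONDITIONS = ("NC", "OC")
STUDY_BANDS = ("raw", "delta")
CALIBRATION_BANDS = ("raw", "alpha")


def _erp_components(ad_scale_n400, ad_scale_p600, pad_scale_n400=None, pad_scale_p600=None):
    n400_scale = {"AD": ad_scale_n400}
    p600_scale = {"AD": ad_scale_p600}
    if pad_scale_n400 is not None:
        n400_scale["pAD"] = pad_scale_n400
    if pad_scale_p600 is not None:
        p600_scale["pAD"] = pad_scale_p600
    return (
        ERPComponent(0.4, 0.10, -5.0, n400_scale),
        ERPComponent(0.6, 0.12, 8.0, p600_scale),
    )


def discrimination_study(seed: int = 0) -> SyntheticConfig:
    """Two-group cohort with large diminished-ERP effects in the AD group."""
    return SyntheticConfig(
        n_subjects_per_group={"AD": 15, "RNE": 11},
        n_trials=72,
        channels=STUDY_CHANNELS,
        conditions=STUDY_CONDITIONS,
        erp_components=_erp_components(0.15, 0.1),
        noise_sd=10.0,
        trial_jitter_sd=0.01,
        seed=seed,
    )


def null_study(seed: int = 0) -> SyntheticConfig:
    """Same layout and components as the discrimination study, but with
    identical amplitudes in both groups (no class signal)."""
    return SyntheticConfig(
        n_subjects_per_group={"AD": 15, "RNE": 11},
        n_trials=72,
        channels=STUDY_CHANNELS,
        conditions=STUDY_CONDITIONS,
        erp_components=_erp_components(1.0, 1.0),
        noise_sd=10.0,
        trial_jitter_sd=0.01,
        seed=seed,
    )


def generalization_study(seed: int = 0) -> SyntheticConfig:
    """Three groups; the prodromal group's component amplitudes sit halfway
    between patients and controls (relatively preserved N400, compromised
    P600)."""
    return SyntheticConfig(
        n_subjects_per_group={"AD": 15, "pAD": 15, "RNE": 11},
        n_trials=72,
        channels=STUDY_CHANNELS,
        conditions=STUDY_CONDITIONS,
        erp_components=_erp_components(0.15, 0.1, pad_scale_n400=0.7, pad_scale_p600=0.45),
        noise_sd=10.0,
        trial_jitter_sd=0.01,
        seed=seed,
    )


def calibration_study(seed: int = 0) -> SyntheticConfig:
    """Small noise-only cohort for significance-level calibration runs.

    Ten subjects per group, eight trials, no planted effects; trial count
    does not influence the null distribution of the group comparison, so it
    is kept low for speed.
    """
    return SyntheticConfig(
        n_subjects_per_group={"AD": 10, "RNE": 10},
        n_trials=8,
        channels=STUDY_CHANNELS,
        conditions=STUDY_CONDITIONS,
        erp_components=(),
        noise_sd=10.0,
        seed=seed,
    )
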