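import numpy as np
import pandas as pd
import pytest

from globinscreen import synthcohort


@pytest.fixture(scope="session")
def panel():
    return synthcohort.GlobinPanel()


@pytest.fixture
def clean_acq():
    """Artefact-free acquisition: no noise, no baseline, no drift."""
    return synthcohort.AcquisitionModel(
        noise_sd=0.0, baseline_amplitude=0.0, calibration_shift_ppm=0.0
    )


@pytest.fixture(scope="session")
def profiles():
    return synthcohort.default_profiles()


def make_truth_feature_table(
    n_per_class, profiles=None, seed=0, cv=None, label_map=None
):
    """Feature table drawn directly from the abundance generator (no spectra).

    Fast stand-in for end-to-end tables in model-level tests: the 6 intensity
    features are the true abundances and the ratio/diff features follow.
    """
    profiles = profiles or synthcohort.default_profiles()
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for class_name in sorted(n_per_class):
        prof = profiles[class_name]
        if cv is not None:
            import dataclasses

            prof = dataclasses.replace(prof, between_sample_cv=cv)
        for _ in range(n_per_class[class_name]):
            i += 1
            ab = synthcohort._draw_abundances(prof, rng)
            a, b, g = ab["alpha"], ab["beta"], ab["gamma"]
            label, genotype = synthcohort.CLASS_TO_LABELS[class_name]
            rows.append(
                {
                    "sample_id": f"t{seed}_{i:04d}",
                    "class_label": label,
                    "genotype_group": genotype,
                    "alpha_1p": a,
                    "beta_1p": b,
                    "gamma_1p": g,
                    "alpha_2p": a,
                    "beta_2p": b,
                    "gamma_2p": g,
                    "ratio_ab_1p": a / b if b > 0 else np.nan,
                    "ratio_ab_2p": a / b if b > 0 else np.nan,
                    "diff_ab_1p": a - b,
                    "diff_ab_2p": a - b,
                }
            )
    return pd.DataFrame(rows)
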