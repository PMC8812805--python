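"""Synthetic MALDI-TOF blood-spectrum cohorts with chain-imbalance structure.

The forward model places one Gaussian peak per (species, charge) slot at
m/z = (M + z*proton)/z, scaled by the sample's drawn chain abundance, on top
of a decaying exponential baseline with additive Gaussian noise, and injects
an optional multiplicative calibration error on the m/z axis. Disease classes
perturb chain abundances (e.g. beta deficit in beta-thalassaemia) and the
gamma chain rises to compensate a beta deficit, which propagates into the
simulated Hb F covariate. Ground truth is recorded per sample so every
downstream stage can be checked against the generator.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .spectra_io import Spectrum

PROTON_MASS = 1.00728  # Da

#: Apex height of a unit-abundance peak before charge partitioning.
PEAK_HEIGHT_SCALE = 100.0

CLASS_NAMES = ("control", "alpha_thal", "beta_thal", "alphabeta_compound")

#: class_name -> (class_label, genotype_group)
CLASS_TO_LABELS = {
    "control": ("control", "none"),
    "alpha_thal": ("thalassaemia", "alpha"),
    "beta_thal": ("thalassaemia", "beta"),
    "alphabeta_compound": ("thalassaemia", "alphabeta"),
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclasses.dataclass
class GlobinPanel:
    """Reference masses of the globin chains and the spiked internal standard.

    Globin neutral average masses default to canonical human chain values;
    the internal standard is myoglobin at 16,952 Da. ``mz_ref`` gives the
    reference m/z of a z-charged ion, (M + z*proton)/z.
    """

    species_masses: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "alpha": 15126.4,
            "beta": 15867.2,
            "gamma": 15995.3,
            "internal_standard": 16952.0,
        }
    )
    proton_mass: float = PROTON_MASS
    charges: tuple[int, ...] = (1, 2)
    match_window_ppm: float = 3000.0

    def __post_init__(self) -> None:
        for name, mass in self.species_masses.items():
            if mass <= 0:
                raise ConfigurationError(f"species {name!r} has nonpositive mass {mass}")
        if "internal_standard" not in self.species_masses:
            raise ConfigurationError("panel must define an internal_standard mass")
        m_is = self.species_masses["internal_standard"]
        min_sep = 2.0 * self.match_window_ppm * 1e-6 * m_is
        for name, mass in self.species_masses.items():
            if name == "internal_standard":
                continue
            if abs(mass - m_is) <= min_sep:
                raise ConfigurationError(
                    f"internal standard mass {m_is} too close to {name} ({mass}); "
                    f"separation must exceed {min_sep:.1f} Da"
                )
        if any((int(z) != z or z < 1) for z in self.charges):
            raise ConfigurationError("charge states must be positive integers")
        self.charges = tuple(int(z) for z in self.charges)

    @property
    def globin_species(self) -> tuple[str, ...]:
        return tuple(s for s in self.species_masses if s != "internal_standard")

    def mz_ref(self, species: str, charge: int) -> float:
        mass = self.species_masses[species]
        return (mass + charge * self.proton_mass) / charge


@dataclasses.dataclass
class DiseaseProfile:
    """Expected chain abundances and covariate links for one disease class.

    Abundances are relative to the internal standard (fixed at 1).
    ``hbf_link`` maps gamma abundance to simulated Hb F (%); ``hb_link``
    maps alpha+beta abundance to simulated blood Hb (g/L).
    ``gamma_beta_coupling`` raises the gamma expectation when beta falls
    below its healthy reference, producing the Hb F correlation structure.
    """

    class_name: str
    mean_abundance: dict[str, float]
    between_sample_cv: float = 0.10
    hbf_link: float = 25.0
    hb_link: float = 35.0
    gamma_beta_coupling: float = 1.0

    BETA_REFERENCE = 1.0  # healthy beta abundance anchoring gamma compensation

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ConfigurationError(
                f"unknown class {self.class_name!r}; expected one of {CLASS_NAMES}"
            )
        for name, mean in self.mean_abundance.items():
            if mean < 0:
                raise ConfigurationError(f"abundance of {name!r} is negative: {mean}")
        if self.between_sample_cv < 0:
            raise ConfigurationError("between_sample_cv must be nonnegative")
        if self.class_name == "control":
            a = self.mean_abundance.get("alpha", 0.0)
            b = self.mean_abundance.get("beta", 0.0)
            if b == 0 or not 0.9 <= a / b <= 1.1:
                raise ConfigurationError("control profile must have alpha/beta ~= 1")
            if self.mean_abundance.get("gamma", 0.0) > 0.05:
                raise ConfigurationError("control profile must have near-zero gamma")


@dataclasses.dataclass
class AcquisitionModel:
    """Instrument artefact model: axis, peak width, baseline, noise, drift."""

    mz_range: tuple[float, float] = (2000.0, 20000.0)
    sampling_step: float = 1.0
    peak_sigma: float = 8.0  # Th at charge 1+; scaled by 1/z at higher charge
    charge2_fraction: float = 0.3
    baseline_amplitude: float = 500.0
    baseline_decay: float = 3000.0  # Th
    noise_sd: float = 1.0
    calibration_shift_ppm: float = 0.0

    def __post_init__(self) -> None:
        low, high = self.mz_range
        if not low < high:
            raise ConfigurationError(f"mz_range must satisfy low < high, got {self.mz_range}")
        if self.sampling_step <= 0:
            raise ConfigurationError("sampling_step must be positive")
        if self.peak_sigma <= 0:
            raise ConfigurationError("peak_sigma must be positive")
        if not 0.0 <= self.charge2_fraction <= 1.0:
            raise ConfigurationError("charge2_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")

    def axis(self) -> np.ndarray:
        low, high = self.mz_range
        n = int(np.floor((high - low) / self.sampling_step)) + 1
        return low + self.sampling_step * np.arange(n)


@dataclasses.dataclass
class SampleRecord:
    """Manifest row: labels, clinical covariates and simulation ground truth."""

    sample_id: str
    cohort_id: str
    class_label: str
    genotype_group: str
    clinical: dict[str, float]
    truth: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.class_label == "control" and self.genotype_group != "none":
            raise ConfigurationError("control samples must have genotype_group 'none'")
        if self.truth is not None and any(
            v < 0 for k, v in self.truth.items() if k != "ratio_ab"
        ):
            raise ConfigurationError("truth abundances must be nonnegative")

    def as_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            "cohort_id": self.cohort_id,
            "class_label": self.class_label,
            "genotype_group": self.genotype_group,
            "hb_g_l": self.clinical.get("hb_g_l"),
            "hbf_pct": self.clinical.get("hbf_pct"),
            "hba2_pct": self.clinical.get("hba2_pct"),
        }
        if self.truth is not None:
            for key, val in self.truth.items():
                row[f"truth_{key}"] = val
        return row


def default_profiles() -> dict[str, DiseaseProfile]:
    """Default disease profiles for the four simulated classes."""
    return {
        "control": DiseaseProfile(
            "control", {"alpha": 1.0, "beta": 1.0, "gamma": 0.02}
        ),
        "alpha_thal": DiseaseProfile(
            "alpha_thal", {"alpha": 0.55, "beta": 1.0, "gamma": 0.05}
        ),
        "beta_thal": DiseaseProfile(
            "beta_thal", {"alpha": 1.0, "beta": 0.5, "gamma": 0.30}
        ),
        "alphabeta_compound": DiseaseProfile(
            "alphabeta_compound", {"alpha": 0.6, "beta": 0.5, "gamma": 0.30}
        ),
    }


def _draw_abundances(
    profile: DiseaseProfile, rng: np.random.Generator
) -> dict[str, float]:
    cv = profile.between_sample_cv

    def draw(mean: float) -> float:
        if mean <= 0:
            return 0.0
        return max(0.0, float(rng.normal(mean, cv * mean)))

    alpha = draw(profile.mean_abundance.get("alpha", 0.0))
    beta = draw(profile.mean_abundance.get("beta", 0.0))
    gamma_mean = profile.mean_abundance.get("gamma", 0.0)
    if gamma_mean > 0 and profile.gamma_beta_coupling != 0:
        # gamma compensates a beta deficit relative to the healthy reference
        ratio = profile.BETA_REFERENCE / max(beta, 0.05)
        gamma_mean = gamma_mean * ratio**profile.gamma_beta_coupling
    gamma = draw(gamma_mean)
    return {"alpha": alpha, "beta": beta, "gamma": gamma, "internal_standard": 1.0}


def _draw_clinical(
    profile: DiseaseProfile, abundances: Mapping[str, float], rng: np.random.Generator
) -> dict[str, float]:
    hb = max(
        0.0,
        50.0
        + profile.hb_link * (abundances["alpha"] + abundances["beta"])
        + float(rng.normal(0.0, 5.0)),
    )
    hbf = max(0.0, profile.hbf_link * abundances["gamma"] + float(rng.normal(0.0, 0.5)))
    hba2 = max(0.0, float(rng.normal(2.7, 0.4)))
    return {"hb_g_l": hb, "hbf_pct": hbf, "hba2_pct": hba2}


def simulate_spectrum(
    panel: GlobinPanel,
    profile: DiseaseProfile,
    acq: AcquisitionModel,
    seed: int,
    sample_id: str = "sample",
    cohort_id: str = "cohort",
) -> tuple[Spectrum, SampleRecord]:
    """Simulate one spectrum and its ground-truth sample record.

    Identical (configuration, seed) pairs give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    abundances = _draw_abundances(profile, rng)

    low, high = acq.mz_range
    mz = acq.axis()
    signal = np.zeros_like(mz)
    shift = 1.0 + acq.calibration_shift_ppm * 1e-6
    for species, abundance in abundances.items():
        if abundance <= 0:
            continue
        for z in panel.charges:
            centre_true = panel.mz_ref(species, z)
            if not low <= centre_true <= high:
                raise ConfigurationError(
                    f"peak centre {centre_true:.1f} for ({species}, {z}+) lies outside "
                    f"the acquisition m/z range {acq.mz_range}"
                )
            centre = centre_true * shift
            frac = acq.charge2_fraction if z == 2 else 1.0 - acq.charge2_fraction
            if frac <= 0:
                continue
            height = abundance * PEAK_HEIGHT_SCALE * frac
            sigma = acq.peak_sigma / z
            signal += height * np.exp(-0.5 * ((mz - centre) / sigma) ** 2)

    baseline = acq.baseline_amplitude * np.exp(-mz / acq.baseline_decay)
    intensity = signal + baseline
    if acq.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, acq.noise_sd, size=mz.size)
    intensity = np.clip(intensity, 0.0, None)

    clinical = _draw_clinical(profile, abundances, rng)
    class_label, genotype_group = CLASS_TO_LABELS[profile.class_name]
    truth = {
        "alpha": abundances["alpha"],
        "beta": abundances["beta"],
        "gamma": abundances["gamma"],
        "ratio_ab": (
            abundances["alpha"] / abundances["beta"] if abundances["beta"] > 0 else np.nan
        ),
    }
    record = SampleRecord(
        sample_id=sample_id,
        cohort_id=cohort_id,
        class_label=class_label,
        genotype_group=genotype_group,
        clinical=clinical,
        truth=truth,
    )
    return Spectrum(mz, intensity, sample_id=sample_id), record


def simulate_cohort(
    panel: GlobinPanel,
    profiles: Sequence[DiseaseProfile] | Mapping[str, DiseaseProfile],
    n_per_class: Mapping[str, int],
    acq: AcquisitionModel,
    seed: int,
    cohort_id: str = "cohort",
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Simulate a cohort with exact per-class counts and a shuffled manifest.

    Returns the spectra (aligned with manifest rows) and the manifest table.
    """
    if isinstance(profiles, Mapping):
        by_class = dict(profiles)
    else:
        by_class = {p.class_name: p for p in profiles}
    unknown = set(n_per_class) - set(by_class)
    if unknown:
        raise ConfigurationError(f"n_per_class refers to unknown classes {sorted(unknown)}")
    total = sum(int(n) for n in n_per_class.values())
    if total <= 0:
        raise ConfigurationError("n_per_class requests zero samples in total")

    rng = np.random.default_rng(seed)
    items: list[tuple[Spectrum, SampleRecord]] = []
    counter = 0
    for class_name in sorted(n_per_class):
        profile = by_class[class_name]
        for _ in range(int(n_per_class[class_name])):
            counter += 1
            sample_seed = int(rng.integers(0, 2**63 - 1))
            sid = f"{cohort_id}_s{counter:04d}"
            items.append(
                simulate_spectrum(
                    panel, profile, acq, seed=sample_seed, sample_id=sid, cohort_id=cohort_id
                )
            )
    order = rng.permutation(len(items))
    spectra = [items[i][0] for i in order]
    manifest = pd.DataFrame([items[i][1].as_row() for i in order]).reset_index(drop=True)
    return spectra, manifest
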