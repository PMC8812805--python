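"""Screening feature construction from normalised peak assignments.

For one sample the feature vector has exactly ten slots: the normalised
intensities of the three globin chains at charge 1+ and 2+, the alpha/beta
intensity ratio per charge, and the alpha minus beta difference per charge.
Slots whose inputs are absent are masked, never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Optional

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .specproc import PeakAssignment

logger = logging.getLogger(__name__)

#: Canonical feature column order (also the tie-break order for ranking).
FEATURE_NAMES: tuple[str, ...] = (
    "alpha_1p",
    "beta_1p",
    "gamma_1p",
    "alpha_2p",
    "beta_2p",
    "gamma_2p",
    "ratio_ab_1p",
    "ratio_ab_2p",
    "diff_ab_1p",
    "diff_ab_2p",
)

#: Manifest columns carried alongside the features when assembling a table.
LABEL_COLUMNS: tuple[str, ...] = ("class_label", "cohort_id", "genotype_group")


class FeatureError(ValueError):
    """Raised on malformed feature-table inputs (duplicates, empty manifest)."""


@dataclass
class FeatureVector:
    """The 10 named screening features for one sample.

    ``values`` maps each feature name to a float, or ``None`` when masked.
    """

    values: dict[str, Optional[float]]
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            self.values = {name: self.values.get(name) for name in FEATURE_NAMES}

    @property
    def mask(self) -> dict[str, bool]:
        """True where the feature is present (unmasked)."""
        return {k: v is not None for k, v in self.values.items()}

    @property
    def n_unmasked(self) -> int:
        return sum(v is not None for v in self.values.values())

    def as_row(self) -> dict[str, float]:
        return {k: (math.nan if v is None else float(v)) for k, v in self.values.items()}


def compute_features(assignments: Iterable["PeakAssignment"]) -> FeatureVector:
    """Build the 10-slot feature vector from one sample's normalised assignments.

    Ratio features are masked when the beta denominator is absent or zero;
    difference features require both operands. Missing slots raise QC flags
    but never abort the sample.
    """
    norm: dict[tuple[str, int], float] = {}
    for a in assignments:
        if a.species == "internal_standard":
            continue
        if a.intensity_norm is None:
            raise FeatureError(
                f"assignment ({a.species}, {a.charge}+) has no normalised intensity; "
                "run normalisation first"
            )
        norm[(a.species, a.charge)] = a.intensity_norm

    values: dict[str, Optional[float]] = {}
    flags: list[str] = []
    for charge in (1, 2):
        for species in ("alpha", "beta", "gamma"):
            name = f"{species}_{charge}p"
            values[name] = norm.get((species, charge))
            if values[name] is None:
                flags.append(f"slot_missing:{name}")
    for charge in (1, 2):
        a = norm.get(("alpha", charge))
        b = norm.get(("beta", charge))
        ratio_name, diff_name = f"ratio_ab_{charge}p", f"diff_ab_{charge}p"
        if a is not None and b is not None and b > 0:
            values[ratio_name] = a / b
        else:
            values[ratio_name] = None
            flags.append(f"{ratio_name}_undefined")
        if a is not None and b is not None:
            values[diff_name] = a - b
        else:
            values[diff_name] = None
            flags.append(f"{diff_name}_undefined")
    ordered = {name: values[name] for name in FEATURE_NAMES}
    return FeatureVector(values=ordered, qc_flags=tuple(flags))


def assemble_feature_table(
    manifest: pd.DataFrame,
    vectors: Mapping[str, Optional[FeatureVector]],
) -> pd.DataFrame:
    """Row-align feature vectors with the manifest into one table.

    ``vectors`` maps sample_id to its FeatureVector, or ``None`` for samples
    that failed QC; those are excluded and the count logged. Masked features
    become NaN in the table.
    """
    if len(manifest) == 0:
        raise FeatureError("empty manifest")
    ids = manifest["sample_id"]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique().tolist())
        raise FeatureError(f"duplicate sample_id values in manifest: {dupes}")

    rows = []
    n_failed = 0
    for _, mrow in manifest.iterrows():
        sid = mrow["sample_id"]
        vec = vectors.get(sid)
        if vec is None:
            n_failed += 1
            continue
        row: dict = {"sample_id": sid}
        for col in LABEL_COLUMNS:
            if col in manifest.columns:
                row[col] = mrow[col]
        row.update(vec.as_row())
        rows.append(row)
    if n_failed:
        logger.info("excluded %d QC-failed samples from feature table", n_failed)
    if not rows:
        raise FeatureError("no samples passed QC; feature table would be empty")
    return pd.DataFrame(rows).reset_index(drop=True)
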