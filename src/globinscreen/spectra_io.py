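"""On-disk artefacts: ASCII spectra, manifest CSVs, feature tables, reports.

Spectra are two-column whitespace-delimited text (m/z, intensity), one file
per acquisition, with ``#`` comment lines. Tables are UTF-8 comma-separated
with a header row. Model reports are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .globin_features import FEATURE_NAMES

logger = logging.getLogger(__name__)

MANIFEST_REQUIRED_COLUMNS = ("sample_id", "class_label")


class FormatError(ValueError):
    """A spectrum file violates the two-column ASCII dialect."""


class SchemaError(ValueError):
    """A table is missing mandatory columns or is otherwise malformed."""


@dataclasses.dataclass
class Spectrum:
    """One acquisition: a strictly increasing m/z axis with nonnegative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be one-dimensional")
        if self.mz.shape != self.intensity.shape:
            raise ValueError(
                f"length mismatch: {self.mz.size} m/z values vs "
                f"{self.intensity.size} intensities"
            )
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")

    def __len__(self) -> int:
        return int(self.mz.size)

    def copy(self) -> "Spectrum":
        return Spectrum(self.mz.copy(), self.intensity.copy(), self.sample_id)


def read_spectrum(path: str | Path, sample_id: Optional[str] = None) -> Spectrum:
    """Parse a two-column ASCII spectrum file into a validated :class:`Spectrum`.

    Lines starting with ``#`` and blank lines are skipped. Out-of-order rows
    are sorted (with a warning), duplicate m/z values are intensity-averaged,
    and negative intensities are clipped to zero (baseline-subtracted vendor
    exports can contain them).
    """
    path = Path(path)
    mzs: list[float] = []
    intens: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected at least 2 columns, got {len(parts)}"
                )
            try:
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric value in {parts[:2]!r}"
                ) from exc
    if len(mzs) < 10:
        raise FormatError(f"{path}: only {len(mzs)} data rows; at least 10 required")

    mz = np.asarray(mzs)
    intensity = np.asarray(intens)
    if np.any(np.diff(mz) < 0):
        logger.warning("%s: m/z values out of order; sorting", path)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
    if np.any(np.diff(mz) == 0):
        uniq, inverse = np.unique(mz, return_inverse=True)
        summed = np.bincount(inverse, weights=intensity)
        counts = np.bincount(inverse)
        mz, intensity = uniq, summed / counts
        logger.warning("%s: duplicate m/z values averaged", path)
    if np.any(intensity < 0):
        logger.warning("%s: negative intensities clipped to zero", path)
        intensity = np.clip(intensity, 0.0, None)
    if not np.any(intensity > 0):
        raise FormatError(f"{path}: all intensities are zero")
    return Spectrum(mz, intensity, sample_id=sample_id or path.stem)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as two-column whitespace-delimited ASCII text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"sample_id: {spectrum.sample_id}\nm/z intensity"
    np.savetxt(
        path,
        np.column_stack([spectrum.mz, spectrum.intensity]),
        fmt="%.10g",
        header=header,
    )
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest CSV, validating the mandatory columns."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in MANIFEST_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: manifest missing mandatory columns {missing}")
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    missing = [c for c in MANIFEST_REQUIRED_COLUMNS if c not in manifest.columns]
    if missing:
        raise SchemaError(f"manifest missing mandatory columns {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)
    return path


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a feature table CSV (one row per sample, 10 feature columns)."""
    missing = [c for c in ("sample_id", *FEATURE_NAMES) if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing columns {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.10g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in ("sample_id", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: feature table missing columns {missing}")
    return df


def write_model_report(reports: Sequence, path: str | Path) -> Path:
    """Serialise model reports (dataclasses or dicts) as a JSON array."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [
        dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        for r in reports
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def config_hash(config: dict) -> str:
    """Stable sha256 of a JSON-serialisable configuration mapping."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def write_run_record(out_dir: str | Path, config: dict, seed: int) -> Path:
    """Write a ``run.json`` provenance record (config hash, seed, versions)."""
    import sklearn

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "config_sha256": config_hash(config),
        "seed": int(seed),
        "versions": {
            "globinscreen": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    path = out_dir / "run.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
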