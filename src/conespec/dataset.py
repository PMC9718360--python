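"""The spectral dataset container: (wavelength, irradiance, amplitude) triplets.

A ``SpectralDataset`` holds the points from one eye/recording or, after
pooling, a cumulative dataset combining many per-eye max-normalized
datasets.  Columns follow the package CSV convention:
``wavelength_nm, log_irradiance, amplitude, is_replicate, eye_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectralDataset", "pool"]

COLUMNS = ["wavelength_nm", "log_irradiance", "amplitude", "is_replicate", "eye_id"]


@dataclass
class SpectralDataset:
    wavelength_nm: np.ndarray
    log_irradiance: np.ndarray
    amplitude: np.ndarray
    is_replicate: np.ndarray | None = None
    eye_id: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.log_irradiance = np.asarray(self.log_irradiance, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        n = self.wavelength_nm.size
        if self.log_irradiance.size != n or self.amplitude.size != n:
            raise ValueError("column lengths differ")
        if self.is_replicate is None:
            self.is_replicate = np.zeros(n, dtype=bool)
        else:
            self.is_replicate = np.asarray(self.is_replicate, dtype=bool)
        if self.eye_id is None:
            self.eye_id = np.zeros(n, dtype=int)
        else:
            self.eye_id = np.asarray(self.eye_id)
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be nonnegative")

    @property
    def n_points(self) -> int:
        return int(self.wavelength_nm.size)

    @property
    def n_eyes(self) -> int:
        return int(np.unique(self.eye_id).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelength_nm,
                "log_irradiance": self.log_irradiance,
                "amplitude": self.amplitude,
                "is_replicate": self.is_replicate,
                "eye_id": self.eye_id,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "SpectralDataset":
        return cls(
            wavelength_nm=df["wavelength_nm"].to_numpy(),
            log_irradiance=df["log_irradiance"].to_numpy(),
            amplitude=df["amplitude"].to_numpy(),
            is_replicate=df["is_replicate"].to_numpy() if "is_replicate" in df else None,
            eye_id=df["eye_id"].to_numpy() if "eye_id" in df else None,
            metadata=dict(metadata or {}),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectralDataset":
        return cls.from_frame(pd.read_csv(path))

    def normalized(self) -> "SpectralDataset":
        """Amplitudes divided by the dataset maximum (stored in metadata)."""
        peak = float(self.amplitude.max()) if self.n_points else 0.0
        if peak <= 0:
            raise ValueError("cannot normalize: maximal amplitude is not positive")
        meta = dict(self.metadata)
        meta["max_amplitude"] = peak
        return SpectralDataset(
            self.wavelength_nm,
            self.log_irradiance,
            self.amplitude / peak,
            self.is_replicate,
            self.eye_id,
            meta,
        )


def pool(datasets: list[SpectralDataset]) -> SpectralDataset:
    """Concatenate per-eye datasets into a cumulative dataset.

    Eyes are re-labelled 0..k-1 in input order so each contributes its own
    point count with equal per-point weight (datasets should already be
    max-normalized so normalization weights eyes equally).
    """
    if not datasets:
        raise ValueError("nothing to pool")
    parts, eye_ids = [], []
    for i, ds in enumerate(datasets):
        parts.append(ds)
        eye_ids.append(np.full(ds.n_points, i))
    return SpectralDataset(
        wavelength_nm=np.concatenate([d.wavelength_nm for d in parts]),
        log_irradiance=np.concatenate([d.log_irradiance for d in parts]),
        amplitude=np.concatenate([d.amplitude for d in parts]),
        is_replicate=np.concatenate([d.is_replicate for d in parts]),
        eye_id=np.concatenate(eye_ids),
        metadata={"n_datasets": len(datasets)},
    )
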