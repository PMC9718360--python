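"""Preprocessing of raw cone-PIII ERG sweeps into amplitudes and waveform metrics.

The aspartate-isolated cone-PIII response is a hyperpolarizing trough at
light onset followed by a repolarizing peak after offset.  The pipeline is:
average the four replicate sweeps of each condition, boxcar filter (17 ms,
one 60-Hz line cycle), extract the trough-to-peak amplitude within 850 ms
of stimulus onset, run a stability check on the late-run replicates, and
max-normalize the per-eye dataset.  Latency metrics (ON-trough, OFF-peak)
are measured on the grand-mean waveform of a whole spectral dataset, where
noise interferes least with extrema timing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import SpectralDataset

__all__ = [
    "WaveformRecord",
    "AmplitudeRecord",
    "WaveformMetrics",
    "StabilityResult",
    "average_sweeps",
    "boxcar_filter",
    "trough_to_peak",
    "dataset_metrics",
    "stability_check",
    "normalize_dataset",
]


@dataclass
class WaveformRecord:
    """One digitized sweep (or averaged sweep) with stimulus timing."""

    samples: np.ndarray
    rate: float = 2000.0
    onset_index: int = 0
    offset_index: int | None = None
    wavelength_nm: float | None = None
    log_irradiance: float | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.offset_index is not None:
            if not (0 <= self.onset_index < self.offset_index < self.samples.size):
                raise ValueError("need onset_index < offset_index < trace length")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.rate


@dataclass(frozen=True)
class AmplitudeRecord:
    wavelength_nm: float
    log_irradiance: float
    amplitude_uv: float
    is_replicate: bool = False

    def __post_init__(self):
        if self.amplitude_uv < 0:
            raise ValueError("amplitude must be nonnegative")


@dataclass(frozen=True)
class WaveformMetrics:
    dataset_vmax_uv: float
    on_trough_latency_ms: float
    off_peak_latency_ms: float


@dataclass(frozen=True)
class StabilityResult:
    accept: bool
    ratios: tuple[float, ...]
    tol_fraction: float


def _check_aligned(sweeps: list[WaveformRecord]) -> None:
    first = sweeps[0]
    for s in sweeps[1:]:
        if (
            s.n_samples != first.n_samples
            or s.rate != first.rate
            or s.onset_index != first.onset_index
            or s.offset_index != first.offset_index
        ):
            raise ValueError("sweeps have mismatched length or timing")
        if (
            s.wavelength_nm != first.wavelength_nm
            or s.log_irradiance != first.log_irradiance
        ):
            raise ValueError("sweeps come from different stimulus conditions")


def average_sweeps(sweeps: list[WaveformRecord]) -> WaveformRecord:
    """Pointwise mean of replicate sweeps of one condition."""
    if not sweeps:
        raise ValueError("no sweeps to average")
    _check_aligned(sweeps)
    mean = np.mean([s.samples for s in sweeps], axis=0)
    return replace(sweeps[0], samples=mean)


def boxcar_filter(w: WaveformRecord, width_ms: float = 17.0) -> WaveformRecord:
    """Centered moving average of one line-frequency cycle (34 samples at 2 kHz).

    Edges use a truncated window (no padding); metrics are taken far from
    the trace edges so the edge policy is immaterial in practice.
    """
    window = int(round(width_ms * w.rate / 1000.0))
    if window < 1:
        raise ValueError("filter width is below one sample")
    left = (window - 1) // 2
    right = window // 2
    kernel = np.ones(window)
    sums = np.convolve(w.samples, kernel, mode="full")
    counts = np.convolve(np.ones(w.n_samples), kernel, mode="full")
    # output index i covers samples [i-left, i+right] -> full-conv index i+right
    sl = slice(right, right + w.n_samples)
    out = sums[sl] / counts[sl]
    return replace(w, samples=out)


def trough_to_peak(w: WaveformRecord, window_ms: float = 850.0) -> float:
    """Trough-to-peak amplitude within ``window_ms`` after stimulus onset.

    Computed as the maximum rise max_{i <= j} (v_j - v_i) inside the window,
    so the trough always precedes the peak it is paired with; equals the
    depth-plus-height of a clean biphasic PIII response and 0 for flat or
    monotonically falling traces.
    """
    n = int(round(window_ms * w.rate / 1000.0))
    start = w.onset_index
    if start + n > w.n_samples:
        raise ValueError("analysis window extends past the end of the trace")
    seg = w.samples[start : start + n]
    return float(np.max(seg - np.minimum.accumulate(seg)))


def dataset_metrics(
    records: list[WaveformRecord],
    amplitude_window_ms: float = 850.0,
) -> WaveformMetrics:
    """Waveform metrics of a whole spectral dataset.

    ON-trough latency = time from stimulus onset to the minimum of the
    grand-mean waveform between onset and offset; OFF-peak latency = time
    from offset to the maximum after offset.  ``dataset_vmax`` is the
    largest trough-to-peak amplitude among the records.
    """
    if not records:
        raise ValueError("no records")
    _check_timing = records[0]
    if _check_timing.offset_index is None:
        raise ValueError("records need onset and offset indices")
    for r in records[1:]:
        if (
            r.n_samples != _check_timing.n_samples
            or r.onset_index != _check_timing.onset_index
            or r.offset_index != _check_timing.offset_index
            or r.rate != _check_timing.rate
        ):
            raise ValueError("records are not aligned")
    grand = np.mean([r.samples for r in records], axis=0)
    rate = _check_timing.rate
    on, off = _check_timing.onset_index, _check_timing.offset_index
    trough_idx = on + int(np.argmin(grand[on : off + 1]))
    peak_idx = off + int(np.argmax(grand[off:]))
    vmax = max(trough_to_peak(r, amplitude_window_ms) for r in records)
    return WaveformMetrics(
        dataset_vmax_uv=float(vmax),
        on_trough_latency_ms=(trough_idx - on) * 1000.0 / rate,
        off_peak_latency_ms=(peak_idx - off) * 1000.0 / rate,
    )


def stability_check(
    pairs: list[tuple[float, float]],
    tol_fraction: float = 0.25,
    floor: float = 1e-9,
) -> StabilityResult:
    """Accept or reject a dataset by replicate amplitude drift.

    ``pairs`` are (original, replicate) amplitudes of the stability
    conditions; the dataset is rejected if any fractional drift
    |replicate - original| / max(original, floor) exceeds ``tol_fraction``.
    """
    if not pairs:
        raise ValueError("need at least one (original, replicate) pair")
    ratios = tuple(
        abs(rep - orig) / max(orig, floor) for orig, rep in pairs
    )
    return StabilityResult(
        accept=all(r <= tol_fraction for r in ratios),
        ratios=ratios,
        tol_fraction=tol_fraction,
    )


def normalize_dataset(
    records: list[AmplitudeRecord] | SpectralDataset,
    eye_id=0,
    metadata: dict | None = None,
) -> SpectralDataset:
    """Max-normalize one eye's amplitudes into a SpectralDataset.

    The pre-normalization maximum is stored in ``metadata['max_amplitude']``
    so absolute scale is recoverable.
    """
    if isinstance(records, SpectralDataset):
        ds = records
    else:
        ds = SpectralDataset(
            wavelength_nm=[r.wavelength_nm for r in records],
            log_irradiance=[r.log_irradiance for r in records],
            amplitude=[r.amplitude_uv for r in records],
            is_replicate=[r.is_replicate for r in records],
            eye_id=np.full(len(records), eye_id),
            metadata=dict(metadata or {}),
        )
    return ds.normalized()
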