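"""Synthetic spectral datasets and raw waveforms with known ground truth.

The generator emulates the statistical structure the fitting pipeline
assumes: a known cone combination (the "truth") generates amplitudes over
the standard 9-wavelength x 7-irradiance protocol, additive Gaussian
amplitude noise (truncated at zero) is applied, per-eye datasets are
max-normalized and pooled into a cumulative dataset.  Raw sweeps are
smooth biphasic traces (gamma-kernel ON trough, delayed gamma-kernel OFF
peak) whose trough-to-peak amplitude equals the scenario's predicted
amplitude, plus white trace noise — enough structure to exercise every
preprocessing stage, with no pretence of modelling phototransduction.

Scenario presets sketch qualitative cone-amplitude profiles (a larval
wild-type-like hexachromat, a red-dichromat adult, a red-shifted
tetrachromat); their Vm values are illustrative, not calibrated to any
recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import SpectralDataset, pool
from .model import ModelParams, predict_log
from .protocol import Condition, StimulusProtocol, default_protocol
from .templates import ConeCatalog, build_default_catalog
from .waveform import WaveformRecord

__all__ = [
    "WaveformKinetics",
    "SimulationScenario",
    "simulate_dataset",
    "simulate_waveforms",
    "simulate_cumulative",
    "simulate_adaptation_series",
    "normalize_truth",
    "wt_larva_like",
    "red_dichromat_adult_like",
    "red_shifted_tetrachromat_like",
]


@dataclass(frozen=True)
class WaveformKinetics:
    """Shape parameters of the synthetic biphasic cone-PIII trace."""

    trough_latency_ms: float = 135.0
    off_peak_latency_ms: float = 310.0
    trough_fraction: float = 0.7  # share of trough-to-peak depth in the ON trough
    noise_sd_trace_uv: float = 0.0
    rate_hz: float = 2000.0
    pre_ms: float = 100.0
    flash_ms: float = 300.0
    post_ms: float = 1100.0
    shape_order: float = 4.0


@dataclass(frozen=True)
class SimulationScenario:
    truth: ModelParams
    catalog: ConeCatalog
    protocol: StimulusProtocol = field(default_factory=default_protocol)
    noise_sd: float = 0.02
    n_datasets: int = 1
    seed: int = 0
    amplitude_scale_uv: float = 100.0
    kinetics: WaveformKinetics = field(default_factory=WaveformKinetics)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")


def normalize_truth(
    params: ModelParams, catalog: ConeCatalog, protocol: StimulusProtocol
) -> ModelParams:
    """Rescale truth Vm so the maximum predicted amplitude over the protocol is 1.

    Fitted Vm are expressed in per-dataset max-normalized units, so a truth
    scaled this way is directly comparable to what the fitter recovers.
    """
    conds = protocol.conditions()
    wl = np.array([c.wavelength_nm for c in conds])
    log_i = np.array([c.log_irradiance for c in conds])
    peak = float(np.max(predict_log(params, catalog, wl, log_i)))
    if peak <= 0:
        raise ValueError("truth predicts no response anywhere on the protocol")
    vm = {lbl: v / peak for lbl, v in params.vm.items()}
    return ModelParams(subset=params.subset, vm=vm, log_k_uv=params.log_k_uv)


def simulate_dataset(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    eye_id: int = 0,
) -> SpectralDataset:
    """One eye's 70-row spectral dataset: truth predictions plus amplitude noise.

    Amplitudes are ``predict(truth) + N(0, noise_sd)`` truncated at zero;
    replicate rows re-draw noise on their paired condition so the stability
    check sees realistic drift.  Deterministic for a given scenario seed.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    conds = scenario.protocol.conditions()
    wl = np.array([c.wavelength_nm for c in conds])
    log_i = np.array([c.log_irradiance for c in conds])
    clean = np.asarray(predict_log(scenario.truth, scenario.catalog, wl, log_i))
    noisy = clean + rng.normal(0.0, scenario.noise_sd, size=clean.shape)
    noisy = np.clip(noisy, 0.0, None)
    return SpectralDataset(
        wavelength_nm=wl,
        log_irradiance=log_i,
        amplitude=noisy,
        is_replicate=np.array([c.is_replicate for c in conds]),
        eye_id=np.full(len(conds), eye_id),
        metadata={"seed": scenario.seed, "noise_sd": scenario.noise_sd},
    )


def _gamma_kernel(t_ms: np.ndarray, peak_ms: float, order: float) -> np.ndarray:
    """Smooth unimodal kernel, zero for t<=0, peak value 1 at t = peak_ms."""
    out = np.zeros_like(t_ms)
    pos = t_ms > 0
    u = t_ms[pos] / peak_ms
    out[pos] = u**order * np.exp(order * (1.0 - u))
    return out


def simulate_waveforms(
    scenario: SimulationScenario,
    condition: Condition,
    rng: np.random.Generator | None = None,
) -> list[WaveformRecord]:
    """Four raw sweeps for one condition, 2 kHz, biphasic PIII shape.

    The noiseless trace's trough-to-peak amplitude equals the scenario's
    predicted amplitude for the condition (in uV after amplitude scaling).
    """
    rng = rng or np.random.default_rng(scenario.seed)
    kin = scenario.kinetics
    rate = kin.rate_hz
    n_pre = int(round(kin.pre_ms * rate / 1000.0))
    n_flash = int(round(kin.flash_ms * rate / 1000.0))
    n_post = int(round(kin.post_ms * rate / 1000.0))
    n_total = n_pre + n_flash + n_post
    t_ms = np.arange(n_total) * 1000.0 / rate
    onset_ms = n_pre * 1000.0 / rate
    offset_ms = (n_pre + n_flash) * 1000.0 / rate

    amp_norm = float(
        predict_log(
            scenario.truth,
            scenario.catalog,
            condition.wavelength_nm,
            condition.log_irradiance,
        )
    )
    amp_uv = amp_norm * scenario.amplitude_scale_uv
    depth = kin.trough_fraction * amp_uv
    height = (1.0 - kin.trough_fraction) * amp_uv
    clean = -depth * _gamma_kernel(t_ms - onset_ms, kin.trough_latency_ms, kin.shape_order)
    clean += height * _gamma_kernel(t_ms - offset_ms, kin.off_peak_latency_ms, kin.shape_order)

    sweeps = []
    for _ in range(condition.sweep_count):
        noise = (
            rng.normal(0.0, kin.noise_sd_trace_uv, size=n_total)
            if kin.noise_sd_trace_uv > 0
            else 0.0
        )
        sweeps.append(
            WaveformRecord(
                samples=clean + noise,
                rate=rate,
                onset_index=n_pre,
                offset_index=n_pre + n_flash,
                wavelength_nm=condition.wavelength_nm,
                log_irradiance=condition.log_irradiance,
            )
        )
    return sweeps


def simulate_cumulative(scenario: SimulationScenario) -> SpectralDataset:
    """Pooled cumulative dataset of ``n_datasets`` per-eye max-normalized datasets.

    Every eye contributes exactly one full 70-row dataset; eye draws are
    independent streams spawned from the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    eyes = []
    for i in range(scenario.n_datasets):
        child = np.random.default_rng(rng.integers(0, 2**31 - 1))
        ds = simulate_dataset(scenario, rng=child, eye_id=i)
        eyes.append(ds.normalized())
    out = pool(eyes)
    out.metadata.update({"seed": scenario.seed, "noise_sd": scenario.noise_sd})
    return out


def simulate_adaptation_series(
    wavelength_nm: float,
    background: str,
    log_sigma: float,
    rng: np.random.Generator,
    vmax: float = 1.0,
    exponent: float = 1.0,
    log_irradiance_grid=None,
    n_per_point: int = 30,
    amplitude_sd: float = 0.02,
):
    """Mean +/- SE irradiance-response points for one adapting background.

    Emulates how adaptation data are tabulated: at each irradiance the
    amplitude is the mean over ``n_per_point`` eyes, each eye's amplitude
    being the Hill-function truth plus additive Gaussian noise of SD
    ``amplitude_sd`` (the same noise model as the spectral generator), so
    the stored SE is amplitude_sd/sqrt(n).  Default grid: seven 0.5-log
    steps around ``log_sigma`` (the protocol's 3-log-unit ladder).
    """
    from .adaptation import AdaptationSeries, _hill_log

    if log_irradiance_grid is None:
        log_irradiance_grid = log_sigma + np.arange(-1.5, 1.51, 0.5)
    grid = np.asarray(log_irradiance_grid, dtype=float)
    clean = _hill_log(grid, vmax, exponent, log_sigma)
    draws = clean[:, None] + rng.normal(0.0, amplitude_sd, size=(grid.size, n_per_point))
    draws = np.clip(draws, 0.0, None)
    return AdaptationSeries(
        wavelength_nm=wavelength_nm,
        background=background,
        log_irradiance=grid,
        amplitude=draws.mean(axis=1),
        se=np.full(grid.size, amplitude_sd / np.sqrt(n_per_point)),
        n=np.full(grid.size, n_per_point),
    )


# ---------------------------------------------------------------------------
# scenario presets (illustrative Vm profiles, not calibrated measurements)


def _preset(subset, vm, log_k_uv, catalog=None, **kwargs) -> SimulationScenario:
    catalog = catalog or build_default_catalog()
    protocol = kwargs.pop("protocol", default_protocol())
    truth = normalize_truth(
        ModelParams(subset=subset, vm=vm, log_k_uv=log_k_uv), catalog, protocol
    )
    return SimulationScenario(truth=truth, catalog=catalog, protocol=protocol, **kwargs)


def wt_larva_like(**kwargs) -> SimulationScenario:
    """Six-cone hexachromat with a strong UV signal and dominant mid/long amplitudes."""
    return _preset(
        subset=("UV", "B1", "B2", "G1", "G4", "R2"),
        vm={"UV": 0.40, "B1": 0.12, "B2": 0.18, "G1": 0.14, "G4": 0.20, "R2": 0.55},
        log_k_uv=4.2,
        **kwargs,
    )


def red_dichromat_adult_like(**kwargs) -> SimulationScenario:
    """Two red cones only, the long-peak class dominant."""
    return _preset(
        subset=("R2", "R1"),
        vm={"R2": 0.45, "R1": 0.80},
        log_k_uv=4.25,
        **kwargs,
    )


def red_shifted_tetrachromat_like(**kwargs) -> SimulationScenario:
    """Blue/green remnants plus strong red signals."""
    return _preset(
        subset=("B1", "G1", "R2", "R1"),
        vm={"B1": 0.15, "G1": 0.20, "R2": 0.35, "R1": 0.75},
        log_k_uv=4.25,
        **kwargs,
    )
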