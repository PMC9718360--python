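"""The saturable-summation cone spectral model.

The net cone-PIII photovoltage is modelled as a linear sum of Hill-type
(exponent 1) contributions from the cone classes in a chosen subset S:

    V(wl, I) = sum_{i in S}  Vm_i * I*A_i(wl) / (I*A_i(wl) + k_i)

where A_i is the peak-normalized absorbance of cone i at wavelength wl,
I is linear irradiance (quanta um^-2 s^-1), Vm_i the saturation amplitude
of cone i (in dataset-normalized units), and k_i its semi-saturation
irradiance at the absorbance peak.  Off peak the effective semi-saturation
is k_i / A_i(wl) — sensitivity falls in inverse proportion to absorbance.
Only one semi-saturation is free: k_i = 10**(log_k_uv + delta_i), with the
per-class offsets delta_i taken from the catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SpectralDataset  # noqa: F401  (re-export: the fitting currency)
from .templates import ConeCatalog

__all__ = ["ModelParams", "SpectralDataset", "predict", "predict_log", "predict_curve", "spectral_sensitivity"]

DEFAULT_QUANTAL_LEVELS = (3.4, 4.0, 4.6)


@dataclass(frozen=True)
class ModelParams:
    """A cone subset with its saturation amplitudes and shared UV semi-saturation."""

    subset: tuple[str, ...]
    vm: dict[str, float]
    log_k_uv: float

    def __post_init__(self):
        if not self.subset:
            raise ValueError("subset must be nonempty")
        if set(self.subset) != set(self.vm):
            raise ValueError("vm keys must match subset labels")
        if any(v < 0 for v in self.vm.values()):
            raise ValueError("all Vm must be nonnegative")
        if not np.isfinite(self.log_k_uv):
            raise ValueError("log_k_uv must be finite")

    def vm_vector(self, order: tuple[str, ...] | None = None) -> np.ndarray:
        order = order or self.subset
        return np.array([self.vm[lbl] for lbl in order])


def _components(params: ModelParams, catalog: ConeCatalog, wl, irradiance):
    """Per-cone Hill responses, shape (n_points, n_subset)."""
    wl = np.atleast_1d(np.asarray(wl, dtype=float))
    irr = np.atleast_1d(np.asarray(irradiance, dtype=float))
    if np.any(irr < 0):
        raise ValueError("irradiance must be nonnegative")
    wl, irr = np.broadcast_arrays(wl, irr)
    idx = [catalog.index(lbl) for lbl in params.subset]
    a = catalog.absorbance_matrix(wl.ravel())[:, idx]
    k = 10.0 ** (params.log_k_uv + catalog.delta_log_k[idx])
    x = irr.ravel()[:, None] * a
    return x / (x + k), wl.shape


def predict(params: ModelParams, catalog: ConeCatalog, wl, irradiance):
    """Predicted amplitude at wavelength(s) ``wl`` and *linear* irradiance(s)."""
    h, shape = _components(params, catalog, wl, irradiance)
    v = (h @ params.vm_vector()).reshape(shape)
    if np.isscalar(wl) and np.isscalar(irradiance):
        return float(v[0])
    return v


def predict_log(params: ModelParams, catalog: ConeCatalog, wl, log_irradiance):
    """Predicted amplitude with irradiance given in log10 units (protocol convention)."""
    if np.isscalar(log_irradiance):
        return predict(params, catalog, wl, 10.0 ** float(log_irradiance))
    log_i = np.asarray(log_irradiance, dtype=float)
    return predict(params, catalog, wl, np.power(10.0, log_i))


def predict_curve(
    params: ModelParams,
    catalog: ConeCatalog,
    wl: float,
    log_irradiance_grid,
) -> np.ndarray:
    """Irradiance-response curve at one wavelength over a log-irradiance grid."""
    grid = np.asarray(log_irradiance_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty irradiance grid")
    return np.asarray(predict_log(params, catalog, np.full(grid.shape, wl), grid))


def spectral_sensitivity(
    params: ModelParams,
    catalog: ConeCatalog,
    wl_grid,
    constant_quantal_levels=DEFAULT_QUANTAL_LEVELS,
) -> pd.DataFrame:
    """Constant-quantal spectra: modelled amplitude across wavelength at fixed quantal irradiance.

    Returns a tidy frame with columns ``level`` (log10 quanta um^-2 s^-1),
    ``wavelength_nm`` and ``amplitude``.
    """
    wl_grid = np.asarray(wl_grid, dtype=float)
    rows = []
    for level in constant_quantal_levels:
        amp = np.asarray(
            predict_log(params, catalog, wl_grid, np.full(wl_grid.shape, level))
        )
        rows.append(
            pd.DataFrame(
                {"level": level, "wavelength_nm": wl_grid, "amplitude": amp}
            )
        )
    return pd.concat(rows, ignore_index=True)
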