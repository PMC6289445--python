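"""Modified Beer-Lambert law (MBLL) conversion between optical density and
chromophore concentration changes.

Continuous-wave fNIRS measures attenuation changes ΔA(t, λ) of near-infrared
light at two wavelengths.  Under the MBLL these are linear in the underlying
concentration changes of oxygenated (HbO) and deoxygenated (HbR) hemoglobin::

    ΔA(t, λi) = l · d(λi) · [ α_HbO(λi) ΔC_HbO(t) + α_HbR(λi) ΔC_HbR(t) ]

with `l` the emitter-detector distance (mm), `d` the differential path length
factor (DPF, dimensionless) and `α` extinction coefficients in µM⁻¹ mm⁻¹, so
concentrations come out in µM.  Conversion solves this 2×2 system per sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ExtinctionTable",
    "PathSpec",
    "mbll_convert",
    "forward_optical_density",
    "MBLLConverter",
    "default_extinction_table",
    "default_path_spec",
]

_COND_LIMIT = 1e8


def _load_defaults() -> dict:
    with resources.files("fnirsvmd.data").joinpath("extinction_760_830.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ExtinctionTable:
    """Extinction coefficients α_HbX(λi), µM⁻¹ mm⁻¹, for two wavelengths.

    ``alpha`` is a 2×2 matrix with rows indexed by wavelength and columns by
    chromophore ``(HbO, HbR)``: ``alpha[i, 0] = α_HbO(λi)``.
    """

    wavelengths: tuple[float, float] = (760.0, 830.0)
    alpha: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.alpha is None:
            d = _load_defaults()
            a = np.column_stack([d["alpha_uM_mm"]["hbo"], d["alpha_uM_mm"]["hbr"]])
            object.__setattr__(self, "alpha", a)
        a = np.asarray(self.alpha, dtype=float)
        if a.shape != (2, 2):
            raise ValueError(f"alpha must be 2x2, got shape {a.shape}")
        object.__setattr__(self, "alpha", a)
        if self.wavelengths[0] == self.wavelengths[1]:
            raise ValueError("wavelengths must be distinct")
        if np.linalg.cond(a) > _COND_LIMIT:
            raise ValueError(
                "extinction matrix for wavelengths "
                f"{self.wavelengths[0]:g}/{self.wavelengths[1]:g} nm is singular or "
                f"ill-conditioned (condition number > {_COND_LIMIT:g})"
            )


@dataclass(frozen=True)
class PathSpec:
    """Photon path geometry: distance `l` (mm) and DPF `d`.

    ``d`` may be a scalar (applied to both wavelengths) or a pair, one per
    wavelength.
    """

    l: float = 30.0
    d: float | tuple[float, float] = 6.0

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError("emitter-detector distance l must be > 0")
        d = np.atleast_1d(np.asarray(self.d, dtype=float))
        if d.size not in (1, 2) or np.any(d <= 0):
            raise ValueError("DPF d must be a positive scalar or pair")

    @property
    def ld(self) -> np.ndarray:
        """Per-wavelength effective path length l·d, shape (2,)."""
        d = np.atleast_1d(np.asarray(self.d, dtype=float))
        return self.l * (np.repeat(d, 2) if d.size == 1 else d)


def default_extinction_table() -> ExtinctionTable:
    return ExtinctionTable()


def default_path_spec() -> PathSpec:
    d = _load_defaults()
    return PathSpec(l=d["emitter_detector_distance_mm"], d=d["dpf"])


def mbll_convert(
    dA: np.ndarray,
    extinction: ExtinctionTable | None = None,
    path: PathSpec | None = None,
) -> np.ndarray:
    """Convert optical-density changes to concentration changes (µM).

    Parameters
    ----------
    dA
        Optical-density changes with the two wavelengths on the last axis,
        any leading shape (e.g. ``(n_channels, n_times, 2)``).
    extinction, path
        Extinction table and path geometry; tabulated 760/830 nm defaults
        are used when omitted.

    Returns
    -------
    Array of the same shape with ``(ΔHbO, ΔHbR)`` on the last axis.
    """
    extinction = extinction or ExtinctionTable()
    path = path or default_path_spec()
    dA = np.asarray(dA, dtype=float)
    if dA.shape[-1] != 2:
        raise ValueError("dA must have the two wavelengths on its last axis")
    scaled = dA / path.ld  # broadcast per wavelength
    # Solve alpha @ [hbo, hbr] = dA/(l d) for each sample.
    return np.linalg.solve(extinction.alpha, scaled[..., None]).squeeze(-1)


def forward_optical_density(
    conc: np.ndarray,
    extinction: ExtinctionTable | None = None,
    path: PathSpec | None = None,
) -> np.ndarray:
    """Forward MBLL: concentration changes (µM) → optical-density changes.

    ``conc`` carries ``(ΔHbO, ΔHbR)`` on its last axis.  Exact inverse of
    :func:`mbll_convert` for the same table and path.
    """
    extinction = extinction or ExtinctionTable()
    path = path or default_path_spec()
    conc = np.asarray(conc, dtype=float)
    if conc.shape[-1] != 2:
        raise ValueError("conc must have (HbO, HbR) on its last axis")
    return (extinction.alpha @ conc[..., None]).squeeze(-1) * path.ld


class MBLLConverter(BaseEstimator, TransformerMixin):
    """Stateless transformer applying the MBLL to a multichannel OD matrix.

    Input is ``(n_times, 2 * n_channels)`` with columns ordered
    ``ch01_od<λ1>, ch01_od<λ2>, ch02_od<λ1>, ...`` (the repo CSV dialect);
    output has columns ``ch01_hbo, ch01_hbr, ...`` in µM.
    """

    def __init__(self, extinction: ExtinctionTable | None = None, path: PathSpec | None = None):
        self.extinction = extinction
        self.path = path

    def fit(self, X, y=None):  # noqa: D102 -- stateless
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] % 2:
            raise ValueError("X must be (n_times, 2 * n_channels)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] % 2:
            raise ValueError("X must be (n_times, 2 * n_channels)")
        n_t, n2 = X.shape
        pairs = X.reshape(n_t, n2 // 2, 2)  # (time, channel, wavelength)
        conc = mbll_convert(pairs, self.extinction, self.path)
        return conc.reshape(n_t, n2)

    def inverse_transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n_t, n2 = X.shape
        pairs = X.reshape(n_t, n2 // 2, 2)
        od = forward_optical_density(pairs, self.extinction, self.path)
        return od.reshape(n_t, n2)
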