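"""Length-based natural-mortality models.

Two alternatives capture model uncertainty in natural mortality:

* ``constant`` — a single fixed rate (default 0.4 / year) for every length
  and year, with no process uncertainty; the convention of many
  age-structured assessments.
* ``gislason`` — mortality declines with length as m(len) = k (Linf/len)^1.5
  (Gislason's second estimator), rescaled so that its mean over the most
  exploited lengths (15-60 cm by default) equals Jensen's second estimator
  m = 1.5 k.  Process uncertainty enters by evaluating the curve at each
  draw of the growth-parameter ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .growth import GrowthEnsemble, GrowthParams

__all__ = [
    "MortalityCurve",
    "constant_m",
    "gislason_m",
    "jensen_scale",
    "build_mortality_ensemble",
    "MORTALITY_MODELS",
]

MORTALITY_MODELS = ("constant", "gislason")
DEFAULT_CONSTANT_M = 0.4
DEFAULT_JENSEN_WINDOW = (15.0, 60.0)
GISLASON_EXPONENT = 1.5
JENSEN_FACTOR = 1.5


@dataclass(frozen=True)
class MortalityCurve:
    """Natural mortality by length class, one row per iteration.

    ``m`` has shape (n_iterations, n_lengths); the constant model carries a
    single pseudo-iteration with zero across-iteration variance.
    """

    lengths: np.ndarray  # length-class midpoints, cm
    m: np.ndarray  # (iter, length) rates, 1/year
    model_id: str

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        m = np.atleast_2d(np.asarray(self.m, dtype=float))
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "m", m)
        if self.model_id not in MORTALITY_MODELS:
            raise ValueError(f"unknown mortality model {self.model_id!r}")
        if m.shape[1] != lengths.size:
            raise ValueError("m and lengths disagree on the number of classes")
        if m.size and not np.all(m > 0):
            raise ValueError("all mortality rates must be positive")

    @property
    def n_iterations(self) -> int:
        return self.m.shape[0]

    def iteration(self, i: int) -> np.ndarray:
        """Mortality-at-length for iteration i (constant model broadcasts)."""
        if self.n_iterations == 1:
            return self.m[0]
        return self.m[i]


def constant_m(lengths: np.ndarray, value: float = DEFAULT_CONSTANT_M) -> MortalityCurve:
    """Flat mortality: every length class gets ``value``, no variance."""
    if not value > 0:
        raise ValueError("mortality value must be positive")
    lengths = np.asarray(lengths, dtype=float)
    return MortalityCurve(lengths=lengths, m=np.full((1, lengths.size), value), model_id="constant")


def gislason_m(length, p: GrowthParams):
    """Gislason's second estimator: m(len) = k * (linf / len)^1.5."""
    length_arr = np.asarray(length, dtype=float)
    if np.any(length_arr <= 0):
        raise ValueError("length must be positive")
    out = p.k * (p.linf / length_arr) ** GISLASON_EXPONENT
    return float(out) if np.isscalar(length) else out


def jensen_scale(
    curve: MortalityCurve,
    k: float | np.ndarray,
    window: tuple[float, float] = DEFAULT_JENSEN_WINDOW,
) -> MortalityCurve:
    """Rescale so the window-mean mortality equals Jensen's 1.5 k.

    The unweighted arithmetic mean of m over length classes whose midpoint
    lies in the closed interval ``window`` is forced to 1.5 k per iteration;
    the shape of the curve (ratios between lengths) is unchanged.  ``k`` may
    be a scalar or one value per iteration.
    """
    lo, hi = window
    in_window = (curve.lengths >= lo) & (curve.lengths <= hi)
    if not np.any(in_window):
        raise ValueError(f"window {window} does not intersect the length grid")
    window_mean = curve.m[:, in_window].mean(axis=1)
    k_arr = np.broadcast_to(np.asarray(k, dtype=float), window_mean.shape)
    scale = JENSEN_FACTOR * k_arr / window_mean
    return MortalityCurve(lengths=curve.lengths, m=curve.m * scale[:, None], model_id=curve.model_id)


def build_mortality_ensemble(
    model_id: str,
    lengths: np.ndarray,
    growth: GrowthEnsemble | None = None,
    constant_value: float = DEFAULT_CONSTANT_M,
    jensen_window: tuple[float, float] = DEFAULT_JENSEN_WINDOW,
) -> MortalityCurve:
    """Natural-mortality curves for every growth iteration.

    ``gislason`` produces one Jensen-scaled curve per growth draw (process
    uncertainty inherited from the growth ensemble); ``constant`` produces a
    single deterministic curve.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("length grid must be non-empty")
    if model_id == "constant":
        return constant_m(lengths, constant_value)
    if model_id == "gislason":
        if growth is None or len(growth) == 0:
            raise ValueError("gislason model requires a non-empty growth ensemble")
        params = growth.as_array()
        linf = params[:, 0][:, None]
        k = params[:, 1]
        raw = k[:, None] * (linf / lengths[None, :]) ** GISLASON_EXPONENT
        curve = MortalityCurve(lengths=lengths, m=raw, model_id="gislason")
        return jensen_scale(curve, k, jensen_window)
    raise ValueError(f"unknown mortality model {model_id!r}")
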