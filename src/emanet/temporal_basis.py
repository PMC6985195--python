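"""Temporal design matrix: polynomial recovery trends and diurnal cycles.

Seven columns: linear, quadratic, cubic trends on elapsed time, plus a
sine and cosine term for each of a 24-hr (diurnal) and 12-hr (ultradian)
cycle, so that cycle amplitude and phase are both free parameters.  The
trend axis is hours since the person's first observation; the cycle axis
is actual clock time-of-day.  Because each frequency carries both a sine
and a cosine term, the fitted cyclic variance is invariant to any phase
shift of the clock, and the cubic trend span is invariant to affine
re-parameterization of elapsed time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BASIS_COLUMNS", "TemporalBasis", "build_basis", "standardize_basis"]

BASIS_COLUMNS: tuple[str, ...] = (
    "trend_linear",
    "trend_quadratic",
    "trend_cubic",
    "sin24",
    "cos24",
    "sin12",
    "cos12",
)


@dataclass
class TemporalBasis:
    """The n_obs x k temporal design matrix with its provenance.

    ``X`` is raw (unstandardized) unless ``center``/``scale`` are set, in
    which case each column has been affinely mapped to mean 0, SD 1 and
    the mapping recorded for back-transformation of coefficients.
    """

    columns: tuple[str, ...]
    X: np.ndarray
    t: np.ndarray  # elapsed hours since anchor
    clock: np.ndarray  # time-of-day in hours, [0, 24)
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    dropped: tuple[str, ...] = field(default=())

    @property
    def standardized(self) -> bool:
        return self.center is not None

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=list(self.columns))


def build_basis(timestamps, anchor=None) -> TemporalBasis:
    """Build the raw 7-column basis aligned to observation timestamps.

    Parameters
    ----------
    timestamps:
        Strictly increasing datetimes.
    anchor:
        Zero point of elapsed time; defaults to the first timestamp.
        Must not lie after it.
    """
    ts = pd.DatetimeIndex(timestamps)
    if len(ts) == 0:
        raise ValueError("no timestamps")
    if len(ts) > 1 and not (np.diff(ts.asi8) > 0).all():
        raise ValueError("timestamps must be strictly increasing")
    anchor = pd.Timestamp(anchor) if anchor is not None else ts[0]
    if anchor > ts[0]:
        raise ValueError("anchor must not be after the first timestamp")

    t = (ts.asi8 - anchor.value) / 3.6e12  # ns -> hours
    clock = (
        ts.hour.to_numpy()
        + ts.minute.to_numpy() / 60.0
        + ts.second.to_numpy() / 3600.0
    )
    w24 = 2.0 * np.pi * clock / 24.0
    w12 = 2.0 * np.pi * clock / 12.0
    X = np.column_stack(
        [t, t**2, t**3, np.sin(w24), np.cos(w24), np.sin(w12), np.cos(w12)]
    )
    return TemporalBasis(columns=BASIS_COLUMNS, X=X, t=t, clock=clock)


def standardize_basis(b: TemporalBasis) -> TemporalBasis:
    """Center and scale every column to mean 0, SD 1.

    Raw trend columns span wildly different magnitudes (t^3 in hours
    reaches ~1.1e8 over 20 days), which would make a shared L1 penalty
    meaningless; standardization puts all seven on a common scale.
    Zero-variance columns (e.g. sin24 when every prompt falls at the same
    clock time) are dropped with a warning recorded in ``dropped``.
    """
    if b.standardized:
        return b
    if b.X.shape[0] < 2:
        raise ValueError("need at least 2 observations to standardize")
    mu = b.X.mean(axis=0)
    sd = b.X.std(axis=0, ddof=0)
    keep = sd > 1e-12
    dropped = tuple(c for c, k in zip(b.columns, keep) if not k)
    if dropped:
        import warnings

        warnings.warn(
            f"dropping zero-variance basis column(s): {dropped}", stacklevel=2
        )
    X = (b.X[:, keep] - mu[keep]) / sd[keep]
    return TemporalBasis(
        columns=tuple(c for c, k in zip(b.columns, keep) if k),
        X=X,
        t=b.t,
        clock=b.clock,
        center=mu[keep],
        scale=sd[keep],
        dropped=dropped,
    )
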