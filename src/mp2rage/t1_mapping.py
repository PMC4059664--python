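"""Lookup-table T1 mapping from the uniform MP2RAGE image.

For a fixed protocol the uniform-image intensity is a smooth function of
T1 (computed with the forward signal model at nominal B1+), strictly
monotone over the physiological range, so it can be inverted by a dense
1-D lookup table with piecewise-linear interpolation.  T1 maps must be
derived from the *uniform* image: feeding robust-image intensities through
this table is biased wherever the signal power is not much larger than
beta (background, CSF, poor-B1 regions).

An optional 2-D table (intensity x B1+) is provided for users with a
measured transmit-field map; by default mapping assumes nominal B1+ = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .combination import uniform_combination
from .signal_model import AcquisitionProtocol, TissueProperties, mp2rage_signals

__all__ = ["T1LookupTable", "build_lut", "build_lut_2d", "t1_from_uniform"]

DEFAULT_T1_MIN = 0.1
DEFAULT_T1_MAX = 6.0
DEFAULT_T1_STEP = 0.005


@dataclass(frozen=True)
class T1LookupTable:
    """Monotone map between uniform-image intensity and T1 (seconds)."""

    t1_grid: np.ndarray
    s_values: np.ndarray
    monotone_slice: slice
    protocol: AcquisitionProtocol
    b1plus: float = 1.0

    @property
    def monotone_range(self) -> Tuple[float, float]:
        """Maximal T1 interval (s) on which intensity is strictly monotone."""
        t = self.t1_grid[self.monotone_slice]
        return float(t[0]), float(t[-1])

    @property
    def attainable(self) -> Tuple[float, float]:
        """Intensity interval invertible by this table."""
        s = self.s_values[self.monotone_slice]
        return float(s.min()), float(s.max())


def _longest_monotone_run(s: np.ndarray) -> slice:
    """Index slice of the longest strictly monotone run of ``s``.

    A run end that abuts a curvature reversal is trimmed by one node: the
    continuous extremum lies inside the neighboring grid cell, so intensities
    of T1 values just inside that cell could fall outside the tabulated
    (attainable) interval and the inversion guarantee would not hold there.
    """
    sign = np.sign(np.diff(s))
    best_len, best_start = 0, 0
    start = 0
    for i in range(1, len(sign) + 1):
        if i == len(sign) or sign[i] != sign[start] or sign[i] == 0:
            if sign[start] != 0 and i - start > best_len:
                best_len, best_start = i - start, start
            start = i
    if best_len == 0:
        raise ValueError("uniform intensity is nowhere strictly monotone in T1")
    lo, hi = best_start, best_start + best_len + 1
    if lo > 0 and hi - lo > 2:
        lo += 1
    if hi < len(s) and hi - lo > 2:
        hi -= 1
    return slice(lo, hi)


def build_lut(
    protocol: AcquisitionProtocol,
    t1_grid: Optional[Sequence[float]] = None,
    b1plus: float = 1.0,
) -> T1LookupTable:
    """Tabulate uniform intensity over a T1 grid and locate the monotone range.

    Default grid covers 0.1-6.0 s at 5 ms spacing.  Raises if the grid is
    not strictly increasing or the response is nowhere monotone.
    """
    if t1_grid is None:
        t1_grid = np.arange(
            DEFAULT_T1_MIN, DEFAULT_T1_MAX + DEFAULT_T1_STEP / 2, DEFAULT_T1_STEP
        )
    t1_grid = np.asarray(t1_grid, dtype=float)
    if t1_grid.ndim != 1 or t1_grid.size < 2:
        raise ValueError("t1_grid must be a 1-D grid of at least 2 points")
    if not np.all(np.diff(t1_grid) > 0):
        raise ValueError("t1_grid must be strictly increasing")
    s1, s2 = mp2rage_signals(protocol, TissueProperties(t1=t1_grid), b1plus=b1plus)
    s_values = uniform_combination(s1, s2)
    mono = _longest_monotone_run(s_values)
    return T1LookupTable(
        t1_grid=t1_grid,
        s_values=s_values,
        monotone_slice=mono,
        protocol=protocol,
        b1plus=float(b1plus),
    )


def build_lut_2d(
    protocol: AcquisitionProtocol,
    t1_grid: Optional[Sequence[float]] = None,
    b1_grid: Sequence[float] = (0.6, 0.8, 1.0, 1.2, 1.4),
) -> list:
    """One lookup table per B1+ value (off by default in the CLI)."""
    return [build_lut(protocol, t1_grid, b1plus=b) for b in b1_grid]


def t1_from_uniform(
    u,
    lut,
    b1plus=None,
    clamp: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Invert uniform-image intensities to T1 (seconds).

    Returns ``(t1, valid)``.  Intensities outside the attainable range are
    flagged invalid and set to NaN rather than silently clamped (they mark
    background noise or inversion-artifact voxels); pass ``clamp=True`` to
    clamp to the table ends instead.  If ``lut`` is a list of tables built
    by :func:`build_lut_2d`, ``b1plus`` selects the nearest table per voxel.
    """
    u = np.asarray(u, dtype=float)
    if isinstance(lut, (list, tuple)):
        if b1plus is None:
            raise ValueError("a B1+ map is required with a 2-D lookup table")
        b1map = np.broadcast_to(np.asarray(b1plus, dtype=float), u.shape)
        b1s = np.array([l.b1plus for l in lut])
        idx = np.argmin(np.abs(b1map[..., None] - b1s), axis=-1)
        t1 = np.full(u.shape, np.nan)
        valid = np.zeros(u.shape, dtype=bool)
        for k, table in enumerate(lut):
            sel = idx == k
            if np.any(sel):
                t1k, vk = t1_from_uniform(u[sel], table, clamp=clamp)
                t1[sel] = t1k
                valid[sel] = vk
        return t1, valid

    s = lut.s_values[lut.monotone_slice]
    t = lut.t1_grid[lut.monotone_slice]
    if s[0] > s[-1]:  # np.interp needs ascending x
        s, t = s[::-1], t[::-1]
    lo, hi = lut.attainable
    valid = (u >= lo) & (u <= hi)
    t1 = np.interp(np.clip(u, lo, hi), s, t)
    if not clamp:
        t1 = np.where(valid, t1, np.nan)
    return np.asarray(t1, dtype=float), np.asarray(valid)
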