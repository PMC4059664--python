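"""Steady-state forward model of the MP2RAGE signal.

MP2RAGE interleaves one adiabatic inversion with two rapid gradient-echo
(GRE) readout trains per repetition cycle, yielding two volumes (GRE_TI1,
GRE_TI2) with different inversion times.  Because each cycle is a fixed
sequence of *affine* operations on the longitudinal magnetization Mz
(inversion, free T1 relaxation over the gap times, and cosine scaling plus
relaxation for every low-flip-angle excitation), the steady state is the
fixed point of a single affine map and can be written in closed form.

The model tracks only Mz in units of the equilibrium magnetization M0.
Transverse history is ignored (perfect spoiling), which is the standard
approximation for spoiled GRE trains.  The signal of each volume is read at
the excitation in the middle of its train, where the center of k-space is
acquired under linear (sequential) phase-encode ordering.

All functions broadcast over numpy arrays, so a whole volume of tissue
parameters and B1 fields can be simulated in one vectorized call.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import yaml

__all__ = [
    "AcquisitionProtocol",
    "TissueProperties",
    "ProtocolError",
    "cycle_fixed_point",
    "mp2rage_signals",
]

_DEG = np.pi / 180.0

ArrayLike = Union[float, np.ndarray]


class ProtocolError(ValueError):
    """Raised when acquisition timing parameters are inconsistent."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and flip-angle parameters of one MP2RAGE protocol.

    Units: all times in seconds, flip angles in degrees, voxel size in mm.
    ``ti1``/``ti2`` are defined to the *center* of each readout train;
    ``n_readout`` is the number of excitations per train (the inner
    phase-encode loop, here the 240-line phase-encode dimension under
    linear ordering).  The defaults reproduce a typical 7T whole-brain
    protocol: TR 6 s, echo spacing 6.5 ms, TE 2.89 ms, flip angles 4deg/5deg,
    TI 0.8/2.7 s, matrix 256x240x176, voxel 1.0x1.0x1.2 mm.
    """

    tr_mp2rage: float = 6.0
    tr_readout: float = 6.5e-3
    te: float = 2.89e-3
    ti1: float = 0.8
    ti2: float = 2.7
    alpha1: float = 4.0
    alpha2: float = 5.0
    n_readout: int = 240
    inversion_efficiency: float = 0.96
    matrix: Tuple[int, int, int] = (256, 240, 176)
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.2)

    def __post_init__(self) -> None:
        if not (0.0 < self.ti1 < self.ti2 < self.tr_mp2rage):
            raise ProtocolError(
                f"need 0 < ti1 < ti2 < tr_mp2rage, got "
                f"ti1={self.ti1}, ti2={self.ti2}, tr={self.tr_mp2rage}"
            )
        if self.tr_readout <= 0 or self.n_readout < 1:
            raise ProtocolError("tr_readout must be > 0 and n_readout >= 1")
        if not (0.0 <= self.inversion_efficiency <= 1.0):
            raise ProtocolError("inversion_efficiency must lie in [0, 1]")
        if len(self.matrix) != 3 or any(int(m) <= 0 for m in self.matrix):
            raise ProtocolError("matrix must be 3 positive integers")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ProtocolError("voxel_size must be 3 positive lengths (mm)")
        for name, gap in (("ta", self.ta), ("tb", self.tb), ("tc", self.tc)):
            if gap < 0:
                raise ProtocolError(
                    f"negative gap time {name}={gap:.6g} s: readout trains "
                    "do not fit between the inversion times"
                )

    # Gap times between inversion / trains / end of cycle, with the train
    # contrast anchored at its center (linear ordering).
    @property
    def ta(self) -> float:
        return self.ti1 - (self.n_readout / 2.0) * self.tr_readout

    @property
    def tb(self) -> float:
        return self.ti2 - self.ti1 - self.n_readout * self.tr_readout

    @property
    def tc(self) -> float:
        return self.tr_mp2rage - self.ti2 - (self.n_readout / 2.0) * self.tr_readout

    @classmethod
    def default(cls) -> "AcquisitionProtocol":
        return cls()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["matrix"] = list(self.matrix)
        d["voxel_size"] = list(self.voxel_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        d = dict(d)
        if "matrix" in d:
            d["matrix"] = tuple(int(m) for m in d["matrix"])
        if "voxel_size" in d:
            d["voxel_size"] = tuple(float(v) for v in d["voxel_size"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class TissueProperties:
    """Per-voxel (or scalar) tissue parameters.

    ``t1`` in seconds, ``pd`` in arbitrary proton-density units, ``t2star``
    (seconds) optional -- it only scales both readouts by the same factor
    exp(-TE/T2*) and therefore cancels in the image combination.
    Fields may be numpy arrays of a common shape.
    """

    t1: ArrayLike
    pd: ArrayLike = 1.0
    t2star: Optional[ArrayLike] = None

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.t1) > 0):
            raise ValueError("t1 must be strictly positive")
        if not np.all(np.asarray(self.pd) >= 0):
            raise ValueError("pd must be nonnegative")


# ---------------------------------------------------------------------------
# Affine maps on Mz.  Each map is a pair (m, b) meaning Mz -> m*Mz + b, with
# Mz in units of M0.  Composition: apply f1 then f2 -> (m2*m1, m2*b1 + b2).
# ---------------------------------------------------------------------------


def _relax(t: float, t1: ArrayLike) -> Tuple[np.ndarray, np.ndarray]:
    e = np.exp(-t / np.asarray(t1, dtype=float))
    return e, 1.0 - e


def _train(
    n: int, alpha_deg: float, b1plus: ArrayLike, t1: ArrayLike, tr: float
) -> Tuple[np.ndarray, np.ndarray]:
    """n excitation/relaxation steps of a GRE train as one affine map.

    One step is Mz -> Mz*cos(alpha*b1+)*E + (1 - E) with E = exp(-tr/T1);
    the n-fold composition has a geometric-series offset, guarded against
    the cos*E -> 1 degeneracy.
    """
    t1 = np.asarray(t1, dtype=float)
    e = np.exp(-tr / t1)
    ce = np.cos(alpha_deg * _DEG * np.asarray(b1plus, dtype=float)) * e
    m = ce**n
    denom = 1.0 - ce
    safe = np.abs(denom) > 1e-12
    denom_safe = np.where(safe, denom, 1.0)
    b = np.where(safe, (1.0 - e) * (1.0 - m) / denom_safe, n * (1.0 - e))
    return m, b


def _compose(*maps: Tuple[np.ndarray, np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    """Compose affine maps applied left to right."""
    m_tot: ArrayLike = 1.0
    b_tot: ArrayLike = 0.0
    for m, b in maps:
        m_tot = m * m_tot
        b_tot = m * b_tot + b
    return np.asarray(m_tot), np.asarray(b_tot)


def _cycle_maps(
    protocol: AcquisitionProtocol,
    t1: ArrayLike,
    b1plus: ArrayLike,
    inversion_efficiency: Optional[ArrayLike],
):
    eff = (
        protocol.inversion_efficiency
        if inversion_efficiency is None
        else np.asarray(inversion_efficiency, dtype=float)
    )
    inv = (-eff * np.ones_like(np.asarray(t1, dtype=float)), 0.0)
    return [
        inv,
        _relax(protocol.ta, t1),
        _train(protocol.n_readout, protocol.alpha1, b1plus, t1, protocol.tr_readout),
        _relax(protocol.tb, t1),
        _train(protocol.n_readout, protocol.alpha2, b1plus, t1, protocol.tr_readout),
        _relax(protocol.tc, t1),
    ]


def cycle_fixed_point(
    protocol: AcquisitionProtocol,
    tissue: TissueProperties,
    b1plus: ArrayLike = 1.0,
    inversion_efficiency: Optional[ArrayLike] = None,
) -> np.ndarray:
    """Steady-state longitudinal magnetization at the start of a cycle.

    The full cycle (inversion, TA, train 1, TB, train 2, TC) is an affine
    map Mz -> m*Mz + b; the steady state is its fixed point b / (1 - m).
    Returned in units of M0.  For physical inputs every factor of m has
    magnitude <= 1 with at least one strict, so |m| < 1.
    """
    m, b = _compose(*_cycle_maps(protocol, tissue.t1, b1plus, inversion_efficiency))
    return b / (1.0 - m)


def mp2rage_signals(
    protocol: AcquisitionProtocol,
    tissue: TissueProperties,
    b1plus: ArrayLike = 1.0,
    b1minus: ArrayLike = 1.0,
    phase: ArrayLike = 0.0,
    inversion_efficiency: Optional[ArrayLike] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Complex signals of the two GRE readouts at their k-space centers.

    Starting from the steady state, Mz is propagated to just before the
    center excitation (index n_readout//2) of each train; the signal is

        s_i = pd * b1minus * sin(alpha_i * b1plus) * Mz_center_i
              * exp(i*phase) [* exp(-te/t2star)]

    The sign of Mz is preserved: at short TI1 long-T1 tissue is still
    inverted and s1 is negative -- this sign carries the T1 information the
    uniform combination exploits.  Receive field, proton density, phase and
    T2* decay multiply both signals identically.
    """
    t1 = np.asarray(tissue.t1, dtype=float)
    pd = np.asarray(tissue.pd, dtype=float)
    b1p = np.asarray(b1plus, dtype=float)
    half = protocol.n_readout // 2
    rest = protocol.n_readout - half

    mz_ss = cycle_fixed_point(protocol, tissue, b1plus, inversion_efficiency)

    maps = _cycle_maps(protocol, t1, b1p, inversion_efficiency)
    inv, relax_ta = maps[0], maps[1]

    # Just before the center pulse of train 1.
    m1, b1 = _compose(
        inv,
        relax_ta,
        _train(half, protocol.alpha1, b1p, t1, protocol.tr_readout),
    )
    mz_c1 = m1 * mz_ss + b1

    # Continue through the rest of train 1, the TB gap, and half of train 2.
    m2, b2 = _compose(
        _train(rest, protocol.alpha1, b1p, t1, protocol.tr_readout),
        _relax(protocol.tb, t1),
        _train(half, protocol.alpha2, b1p, t1, protocol.tr_readout),
    )
    mz_c2 = m2 * mz_c1 + b2

    common = pd * np.asarray(b1minus, dtype=float) * np.exp(1j * np.asarray(phase))
    if tissue.t2star is not None:
        common = common * np.exp(-protocol.te / np.asarray(tissue.t2star, dtype=float))

    s1 = common * np.sin(protocol.alpha1 * _DEG * b1p) * mz_c1
    s2 = common * np.sin(protocol.alpha2 * _DEG * b1p) * mz_c2
    return np.asarray(s1, dtype=complex), np.asarray(s2, dtype=complex)
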