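"""Frequency-domain gait features.

One cycle's two informative signals — the sagittal acceleration magnitude
``A_sag = sqrt(A_x^2 + A_y^2)`` and the sagittal angular velocity ``G_z`` —
are Hann-windowed, zero-padded to ``2**n_exp`` samples and Fourier
transformed. Because both are real, the spectrum is conjugate-symmetric and
only the first ``2**(n_exp-1)`` bins carry information; their magnitudes and
phases form four half-spectra (``M_sag``, ``P_sag``, ``M_z``, ``P_z``). The
feature vector keeps the first ``n_orders`` bins of each, concatenated in
that order, for ``4 * n_orders`` features per cycle. Low-order bins carry
almost all of the energy of these slow quasi-periodic movements, which is
what makes the truncation cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import GaitCycle

#: Magnitudes below this are treated as numerically zero and get phase 0.
ZERO_MAGNITUDE = 1e-12


def sagittal_magnitude(ax, ay) -> np.ndarray:
    """Elementwise sagittal-plane acceleration magnitude sqrt(ax^2 + ay^2).

    Both inputs are 1-D arrays in m/s^2 of equal length; the result is
    nonnegative by construction.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    if ax.shape != ay.shape:
        raise ValueError(f"ax and ay must have equal shape, got {ax.shape} vs {ay.shape}")
    return np.hypot(ax, ay)


def hann_window(length: int, include_endpoints: bool = False) -> np.ndarray:
    """Hann window coefficients of the given length.

    The default is the endpoint-free symmetric form
    ``w_k = 0.5 * (1 - cos(2*pi*k / (L+1)))`` for ``k = 1..L`` (no zero
    samples at the ends), the dialect used by numerical packages that call
    it "hanning". ``include_endpoints=True`` selects the periodic-analysis
    variant whose first and last coefficients are exactly zero.
    """
    if length < 1:
        raise ValueError(f"window length must be >= 1, got {length}")
    if include_endpoints:
        if length == 1:
            return np.ones(1)
        k = np.arange(length)
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (length - 1)))
    k = np.arange(1, length + 1)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (length + 1)))


def window_and_pad(signal, n_exp: int, include_endpoints: bool = False) -> np.ndarray:
    """Hann-window a signal and right-pad it with zeros to length ``2**n_exp``.

    Raises if the signal is empty or longer than ``2**n_exp`` — silently
    truncating would corrupt the spectrum, so the caller must raise
    ``n_exp`` instead.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError(f"signal must be 1-D, got shape {signal.shape}")
    if signal.size == 0:
        raise ValueError("signal must be non-empty")
    if n_exp < 1:
        raise ValueError(f"n_exp must be >= 1, got {n_exp}")
    size = 2 ** n_exp
    if signal.size > size:
        raise ValueError(
            f"signal length {signal.size} exceeds 2**n_exp = {size}; "
            f"use n_exp >= {int(math.ceil(math.log2(signal.size)))}"
        )
    out = np.zeros(size)
    out[: signal.size] = signal * hann_window(signal.size, include_endpoints)
    return out


@dataclass(frozen=True)
class SpectralComponents:
    """One-sided magnitude/phase spectra of a cycle's two signals.

    Each vector has length ``2**(n_exp-1)`` (bins 0 .. 2**(n_exp-1)-1 of the
    ``2**n_exp``-point FFT); magnitudes are nonnegative, phases lie in
    (-pi, pi] and are fixed at 0 for numerically-zero bins.
    """

    m_sag: np.ndarray
    p_sag: np.ndarray
    m_z: np.ndarray
    p_z: np.ndarray
    n_exp: int

    @property
    def n_bins(self) -> int:
        return 2 ** (self.n_exp - 1)


def _one_sided(spectrum: np.ndarray, n_exp: int) -> tuple[np.ndarray, np.ndarray]:
    half = spectrum[: 2 ** (n_exp - 1)]
    magnitude = np.abs(half)
    phase = np.arctan2(half.imag, half.real)
    phase[magnitude < ZERO_MAGNITUDE] = 0.0
    phase[phase == -np.pi] = np.pi  # canonical range (-pi, pi]
    return magnitude, phase


def spectral_components(
    asag, gz, n_exp: int = 5, include_endpoints: bool = False
) -> SpectralComponents:
    """Windowed one-sided FFT magnitude and phase of A_sag and G_z."""
    fa = np.fft.fft(window_and_pad(asag, n_exp, include_endpoints))
    fg = np.fft.fft(window_and_pad(gz, n_exp, include_endpoints))
    m_sag, p_sag = _one_sided(fa, n_exp)
    m_z, p_z = _one_sided(fg, n_exp)
    return SpectralComponents(m_sag=m_sag, p_sag=p_sag, m_z=m_z, p_z=p_z, n_exp=n_exp)


def extract_features(
    cycle: GaitCycle,
    n_exp: int = 5,
    n_orders: int = 6,
    skip_dc: bool = False,
    include_endpoints: bool = False,
) -> np.ndarray:
    """The 4*n_orders spectral feature vector of one gait cycle.

    Concatenates the first ``n_orders`` bins of ``M_sag``, ``P_sag``,
    ``M_z`` and ``P_z`` in that order. ``skip_dc=True`` starts at bin 1
    instead of the DC bin.
    """
    half = 2 ** (n_exp - 1)
    offset = 1 if skip_dc else 0
    if not 1 <= n_orders <= half - offset:
        raise ValueError(
            f"n_orders must be in [1, {half - offset}] for n_exp={n_exp}"
            f"{' with skip_dc' if skip_dc else ''}, got {n_orders}"
        )
    comp = spectral_components(cycle.asag, cycle.gz, n_exp, include_endpoints)
    sl = slice(offset, offset + n_orders)
    return np.concatenate([comp.m_sag[sl], comp.p_sag[sl], comp.m_z[sl], comp.p_z[sl]])


def min_padding_exponent(cycles: Iterable[GaitCycle], floor: int = 5) -> int:
    """Smallest padding exponent >= floor that fits every cycle."""
    longest = max((c.n_samples for c in cycles), default=1)
    return max(floor, int(math.ceil(math.log2(max(longest, 1)))))


def feature_matrix(
    cycles: Sequence[GaitCycle],
    n_orders: int = 6,
    n_exp: int | None = None,
    skip_dc: bool = False,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Feature matrix and label vector for a list of labeled cycles.

    When ``n_exp`` is None, the smallest exponent >= 5 that fits the longest
    cycle is used for every cycle so all rows share one spectral grid.

    Returns
    -------
    X : ndarray of shape (n_cycles, 4*n_orders)
    y : ndarray of int class codes (0 where a cycle carries no label)
    n_exp : the padding exponent actually used
    """
    if len(cycles) == 0:
        raise ValueError("no cycles given")
    if n_exp is None:
        n_exp = min_padding_exponent(cycles)
    X = np.vstack(
        [extract_features(c, n_exp=n_exp, n_orders=n_orders, skip_dc=skip_dc) for c in cycles]
    )
    y = np.array([int(c.label) if c.label is not None else 0 for c in cycles])
    return X, y, n_exp
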