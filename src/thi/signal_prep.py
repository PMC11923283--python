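"""Sensor-array preprocessing: grouping, low-pass, normalization, selection.

The chain mirrors a typical multichannel (e.g. resting-state EEG) protocol:
average sensors within spatial groups, zero-phase low-pass so forward finite
differences are meaningful, rescale each channel to unit sample standard
deviation (monomials of different degrees stay comparable in magnitude, which
keeps STLSQ thresholding well conditioned), difference, and finally keep the
samples closest to the channel-wise median — which implicitly tunes the
Taylor sampling-box size and sets the base point to the median.

A band-limited synthetic multichannel generator with optional planted
pairwise/triadic couplings makes the whole chain testable without any
external recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .dynamics import TimeSeries, finite_difference

__all__ = ["PrepConfig", "group_channels", "lowpass", "normalize_std",
           "select_near_median", "synth_multichannel", "preprocess"]


@dataclass
class PrepConfig:
    """groups: partition of the input channels; lowpass_hz < Nyquist;
    n_keep: samples retained nearest the median after differencing."""

    groups: Optional[List[List[int]]] = None
    lowpass_hz: float = 5.0
    sample_rate_hz: float = 160.0
    normalize: bool = True
    n_keep: int = 1000
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.lowpass_hz < self.sample_rate_hz / 2:
            raise ValueError("need 0 < lowpass_hz < sample_rate_hz / 2")
        if self.filter_order < 1 or self.n_keep < 1:
            raise ValueError("filter_order and n_keep must be positive")


def group_channels(raw: np.ndarray, groups: Sequence[Sequence[int]]) -> np.ndarray:
    """Average channels within each group: column j = mean over group j."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    C = raw.shape[1]
    flat = [c for g in groups for c in g]
    if sorted(flat) != list(range(C)):
        raise ValueError("groups must partition all channels exactly once")
    out = np.empty((raw.shape[0], len(groups)))
    for j, g in enumerate(groups):
        out[:, j] = raw[:, list(g)].mean(axis=1)
    return out


def lowpass(ts: np.ndarray, lowpass_hz: float, sample_rate_hz: float,
            filter_order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the time axis."""
    if not 0 < lowpass_hz < sample_rate_hz / 2:
        raise ValueError("cutoff must lie strictly below the Nyquist frequency")
    sos = sps.butter(filter_order, lowpass_hz, btype="low", fs=sample_rate_hz,
                     output="sos")
    return sps.sosfiltfilt(sos, np.atleast_2d(np.asarray(ts, float)), axis=0)


def normalize_std(ts: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Rescale each column to unit sample standard deviation (mean untouched)."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    stds = ts.std(axis=0, ddof=ddof)
    if np.any(stds == 0):
        bad = np.nonzero(stds == 0)[0].tolist()
        raise ValueError(f"zero-variance column(s) {bad} cannot be normalized")
    return ts / stds


def select_near_median(ts: TimeSeries, n_keep: int) -> TimeSeries:
    """Keep the ``n_keep`` rows closest (Euclidean) to the channel-wise median.

    Ties break by time order; rows keep their precomputed derivatives; the
    base point becomes the median vector.
    """
    if n_keep > ts.n_samples:
        raise ValueError(f"n_keep={n_keep} exceeds available samples {ts.n_samples}")
    m = np.median(ts.X, axis=0)
    d = np.linalg.norm(ts.X - m, axis=1)
    order = np.argsort(d, kind="stable")[:n_keep]
    order = np.sort(order)  # retained rows stay in time order
    return TimeSeries(
        X=ts.X[order],
        t=None if ts.t is None else ts.t[order],
        Xdot=None if ts.Xdot is None else ts.Xdot[order],
        base_point=m,
        series_lengths=[n_keep],
    )


def preprocess(raw: np.ndarray, cfg: PrepConfig) -> TimeSeries:
    """Full chain: group → low-pass → normalize → forward-difference →
    near-median selection."""
    M = np.atleast_2d(np.asarray(raw, dtype=float))
    if cfg.groups is not None:
        M = group_channels(M, cfg.groups)
    M = lowpass(M, cfg.lowpass_hz, cfg.sample_rate_hz, cfg.filter_order)
    if cfg.normalize:
        M = normalize_std(M)
    dt = 1.0 / cfg.sample_rate_hz
    X, Xdot, lengths = finite_difference(M, dt)
    t = np.arange(X.shape[0]) * dt
    ts = TimeSeries(X=X, t=t, Xdot=Xdot, series_lengths=lengths)
    return select_near_median(ts, min(cfg.n_keep, ts.n_samples))


def synth_multichannel(g: int, K: int, bandwidth_hz: float,
                       sample_rate_hz: float,
                       mixing: Optional[Sequence[Tuple[int, Sequence[int], float]]] = None,
                       seed: int = 0, n_tones: int = 20) -> np.ndarray:
    """Band-limited, unit-variance synthetic multichannel signal.

    Each channel is a sum of ``n_tones`` random-phase sinusoids with
    frequencies drawn in [0.05, 0.8] x ``bandwidth_hz`` — the upper margin
    keeps the band clear of a Butterworth filter's roll-off at the nominal
    cutoff, so a low-pass at ``bandwidth_hz`` leaves the signal nearly
    unchanged.  ``mixing`` plants directed
    interactions ``(target, sources, strength)``: the running integral of the
    source product is added to the target, so the target's derivative carries
    the monomial Π x_src with the given strength — a known ground truth for
    the inference chain.  All channels are rescaled to unit variance at the
    end.
    """
    if g < 1 or K < 2 or bandwidth_hz <= 0 or sample_rate_hz <= 0:
        raise ValueError("dimensions and rates must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(K) / sample_rate_hz
    base = np.zeros((K, g))
    for c in range(g):
        freqs = rng.uniform(0.05 * bandwidth_hz, 0.8 * bandwidth_hz, n_tones)
        phases = rng.uniform(0, 2 * np.pi, n_tones)
        amps = rng.uniform(0.5, 1.0, n_tones)
        base[:, c] = (amps[None, :] * np.sin(
            2 * np.pi * freqs[None, :] * t[:, None] + phases[None, :])).sum(axis=1)
    base /= base.std(axis=0, ddof=1)
    out = base.copy()
    if mixing:
        for target, sources, strength in mixing:
            prod = np.ones(K)
            for s in sources:
                prod *= base[:, s]
            integ = cumulative_trapezoid(prod, t, initial=0.0)
            out[:, target] = out[:, target] + strength * integ
    return out / out.std(axis=0, ddof=1)
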