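"""Moving-window entropic Emergence, Self-organization and Complexity (ESC).

A univariate series of acoustic-parameter values is discretized into ``l``
global states and scanned with a rolling window of the same length ``l``.
For the window ending at time ``t``, with within-window state frequencies
``p_i``:

* emergence          ``E_t = K * (-sum_i p_i log2 p_i)``,
* self-organization  ``S_t = 1 - E_t``,
* complexity         ``C_t = 4 * E_t * S_t``.

With ``K = 1 / log2(l)`` the emergence is Shannon entropy normalized by its
window maximum, so ``0 <= E <= 1``: E = 0 for a fully repetitive
(deterministic) window and E = 1 when every observation occupies a distinct
state.  C peaks at 1 when order and novelty balance (E = S = 0.5).
A base-10 normalization (``K = 1 / log10(l)``, entropy still in bits) is
available behind the ``k_base`` switch for sensitivity checks; note it does
not bound E by 1.

The scan yields series of length ``n - l``: of the ``n - l + 1`` full
windows the first is dropped, so a 39-value series with ``l = 8`` gives 31
emergence values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscretizationSpec:
    """How to discretize a continuous series into ``l`` states.

    ``l`` is both the number of states and the rolling-window length;
    windows of 4 and 6 are noise-sensitive on short call series, so the
    default is 8.  Binning is global over the whole series (per-window
    binning of continuous data would make every state unique and E
    identically 1): ``equal_width_global`` splits the observed range into
    ``l`` equal bins, ``equal_frequency_global`` uses empirical quantiles.
    """

    l: int = 8
    binning: Literal["equal_width_global", "equal_frequency_global"] = "equal_width_global"
    k_base: Literal["log2", "log10"] = "log2"

    def __post_init__(self):
        if self.l < 2:
            raise ValueError("l must be >= 2")


@dataclass
class ESCSeries:
    """Aligned moving emergence/self-organization/complexity series.

    ``mE[t]`` is the emergence of the window ending at original index
    ``l + 1 + t`` (0-based arrays); all three series have length
    ``n - l``.
    """

    mE: np.ndarray
    mS: np.ndarray
    mC: np.ndarray
    l: int
    k_base: str = "log2"
    parameter: str = ""

    def __len__(self) -> int:
        return len(self.mE)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(1, len(self.mE) + 1),
                "mE": self.mE,
                "mS": self.mS,
                "mC": self.mC,
            }
        )


def discretize_series(x: Sequence[float], spec: DiscretizationSpec) -> np.ndarray:
    """Map each value to a state in 1..l using global bins.

    Bins are half-open except the last (closed), so the series maximum
    lands in state ``l``.  A constant series maps entirely to state 1.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.isfinite(arr).all():
        raise ValueError("series contains NaN or infinite values")
    if len(arr) == 0:
        raise ValueError("series is empty")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        logger.info("constant series: all values mapped to state 1")
        return np.ones(len(arr), dtype=int)
    if spec.binning == "equal_width_global":
        edges = np.linspace(lo, hi, spec.l + 1)
    elif spec.binning == "equal_frequency_global":
        qs = np.linspace(0, 1, spec.l + 1)
        edges = np.quantile(arr, qs)
        edges = np.maximum.accumulate(edges)  # ties may collapse bins
    else:
        raise ValueError(f"unknown binning {spec.binning!r}")
    states = np.digitize(arr, edges[1:-1], right=False) + 1
    return np.minimum(states, spec.l)


def window_esc(states: Sequence[int], l: int, k_base: str = "log2") -> tuple[float, float, float]:
    """(E, S, C) of a single window of exactly ``l`` states.

    Uses the 0*log(0) = 0 convention; state labels are arbitrary (any
    bijective relabeling leaves the result unchanged).
    """
    states = np.asarray(states)
    if len(states) != l:
        raise ValueError(f"window length {len(states)} != l={l}")
    _, counts = np.unique(states, return_counts=True)
    p = counts / l
    h_bits = float(-(p * np.log2(p)).sum()) + 0.0  # normalize -0.0
    k = 1.0 / math.log2(l) if k_base == "log2" else 1.0 / math.log10(l)
    e = k * h_bits
    s = 1.0 - e
    c = 4.0 * e * s
    return e, s, c


def moving_esc(
    x: Sequence[float],
    spec: DiscretizationSpec | None = None,
    parameter: str = "",
) -> ESCSeries:
    """Moving ESC series for one parameter series.

    Discretizes globally, then slides a length-``l`` window one step at a
    time.  The output has length ``n - l``: the window ending at position
    ``l`` (the first full window) is dropped, keeping the windows ending at
    positions ``l + 1 .. n``.
    """
    spec = spec or DiscretizationSpec()
    if len(x) <= spec.l:
        raise ValueError(f"series length {len(x)} must exceed l={spec.l}")
    states = discretize_series(x, spec)
    n, l = len(states), spec.l
    windows = np.lib.stride_tricks.sliding_window_view(states, l)[1:]
    mE = np.empty(len(windows))
    mS = np.empty(len(windows))
    mC = np.empty(len(windows))
    for i, w in enumerate(windows):
        mE[i], mS[i], mC[i] = window_esc(w, l, spec.k_base)
    assert len(mE) == n - l
    return ESCSeries(mE=mE, mS=mS, mC=mC, l=l, k_base=spec.k_base, parameter=parameter)


def window_length_report(
    x: Sequence[float],
    lengths: Sequence[int] = (4, 6, 8),
    binning: str = "equal_width_global",
) -> pd.DataFrame:
    """Stability diagnostic across candidate window lengths.

    For each candidate ``l`` reports the emergence series' variance and
    mean absolute first difference — shorter windows react more noisily on
    short call series, which is why 8 is the default.
    """
    rows = []
    for l in lengths:
        esc = moving_esc(x, DiscretizationSpec(l=l, binning=binning))
        diffs = np.abs(np.diff(esc.mE)) if len(esc) > 1 else np.array([0.0])
        rows.append((l, len(esc), float(np.var(esc.mE)), float(diffs.mean())))
    return pd.DataFrame(rows, columns=["l", "length", "mE_variance", "mE_mean_abs_diff"])


def esc_table(
    sequences,
    spec: DiscretizationSpec | None = None,
    parameters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format ESC table over call sequences and acoustic parameters.

    One row per (subject, session, parameter, t); sequences shorter than
    ``l + 1`` calls are skipped with a log message.
    """
    from .io import PARAMETERS

    spec = spec or DiscretizationSpec()
    parameters = parameters or PARAMETERS
    frames = []
    for seq in sequences:
        for param in parameters:
            if len(seq) <= spec.l:
                logger.warning(
                    "sequence %s/%s too short for l=%d; skipped",
                    seq.subject, seq.session, spec.l,
                )
                break
            esc = moving_esc(seq.param(param), spec, parameter=param)
            frame = esc.to_frame()
            frame.insert(0, "session", seq.session)
            frame.insert(0, "subject", seq.subject)
            frame.insert(2, "parameter", param)
            frame["l"] = spec.l
            frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["subject", "session", "parameter", "t", "mE", "mS", "mC", "l"]
        )
    return pd.concat(frames, ignore_index=True)
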