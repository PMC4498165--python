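"""Lagged pairwise correlations between simultaneously recorded units.

Rates are binned at 1 s, slow co-fluctuations (slower than ~100 s) are
removed with a zero-phase 0.01-Hz high-pass so correlations reflect the
~1-s timescale, and Pearson r is computed at integer-bin lags up to
+/-20 s.  The zero-lag p-value uses the standard t distribution of the
correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import butter, sosfiltfilt

from .config import PairCorrConfig
from .ratedyn import RateSeries


def detrend_rate(series: RateSeries, cutoff: float = 0.01,
                 order: int = 2) -> RateSeries:
    """High-pass the rate timecourse above ``cutoff`` Hz (zero phase).

    Removes components slower than ~1/cutoff seconds; the output is
    approximately zero-mean.  Values are allowed to be negative afterwards,
    so the result is stored de-meaned rather than as a physical rate.
    """
    fs = 1.0 / series.bin_width
    if series.n_bins <= 2.0 / (cutoff * series.bin_width):
        raise ValueError(
            f"series too short for a {cutoff} Hz high-pass: need more than "
            f"{2.0 / cutoff:.0f} s of data"
        )
    sos = butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, series.rates)
    out = RateSeries.__new__(RateSeries)      # bypass >=0 invariant
    out.bin_width = series.bin_width
    out.start_times = series.start_times
    out.rates = filtered
    return out


@dataclass
class PairCorrelation:
    unit_a: str
    unit_b: str
    lags: np.ndarray           # seconds, symmetric about 0
    r: np.ndarray              # Pearson r at each lag
    r_zero: float
    p_zero: float
    peak_lag: float            # lag of max |r|
    significant: bool


def lagged_correlation(rate_a: RateSeries, rate_b: RateSeries,
                       config: Optional[PairCorrConfig] = None,
                       unit_a: str = "a", unit_b: str = "b") -> PairCorrelation:
    """Pearson r(tau) between two aligned rate series at integer-bin lags.

    Positive lag means unit_b's series is delayed relative to unit_a's, so
    r(tau) for (A, B) equals r(-tau) for (B, A).
    """
    config = config or PairCorrConfig()
    if rate_a.bin_width != rate_b.bin_width:
        raise ValueError("bin widths differ")
    if (rate_a.n_bins != rate_b.n_bins
            or not np.allclose(rate_a.start_times, rate_b.start_times)):
        raise ValueError("series spans are not aligned")
    a, b = rate_a.rates, rate_b.rates
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input; correlation undefined")
    max_shift = int(round(config.max_lag_s / rate_a.bin_width))
    lags = np.arange(-max_shift, max_shift + 1) * rate_a.bin_width
    r = np.empty(lags.size)
    for i, shift in enumerate(range(-max_shift, max_shift + 1)):
        if shift >= 0:
            x, y = a[: a.size - shift or None], b[shift:]
        else:
            x, y = a[-shift:], b[: shift]
        r[i] = np.corrcoef(x, y)[0, 1] if x.std() > 0 and y.std() > 0 else np.nan
    r_zero = float(r[max_shift])
    n = a.size
    t = r_zero * np.sqrt((n - 2) / max(1e-300, 1.0 - r_zero ** 2))
    p_zero = float(2 * stats.t.sf(abs(t), n - 2))
    peak = float(lags[np.nanargmax(np.abs(r))])
    return PairCorrelation(unit_a, unit_b, lags, r, r_zero, p_zero, peak,
                           p_zero < config.alpha)


def pairwise_correlations(series_by_unit: dict,
                          config: Optional[PairCorrConfig] = None,
                          detrend: bool = True) -> List[PairCorrelation]:
    """All unit pairs: detrend (0.01-Hz high-pass) then lag-correlate."""
    config = config or PairCorrConfig()
    prepared = {}
    for uid, series in series_by_unit.items():
        prepared[uid] = (detrend_rate(series, config.highpass_hz,
                                      config.filter_order)
                         if detrend else series)
    out = []
    for ua, ub in combinations(sorted(prepared), 2):
        try:
            out.append(lagged_correlation(prepared[ua], prepared[ub],
                                          config, ua, ub))
        except ValueError:
            continue     # zero-variance unit: undefined, skipped
    return out


def correlation_table(pairs: List[PairCorrelation]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        for lag, r in zip(p.lags, p.r):
            rows.append({"unit_a": p.unit_a, "unit_b": p.unit_b,
                         "lag_s": lag, "r": r, "r_zero": p.r_zero,
                         "p_zero_lag": p.p_zero, "peak_lag": p.peak_lag,
                         "significant": p.significant})
    cols = ["unit_a", "unit_b", "lag_s", "r", "r_zero", "p_zero_lag",
            "peak_lag", "significant"]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
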