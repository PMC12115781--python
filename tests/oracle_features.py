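"""Independent brute-force reference for windowing, window features and lags.

Everything here is written with explicit Python loops and the ``math``
module only, so it shares no code path with the vectorized implementation
it is used to check.  Peak prominence and width follow the standard
topographic definitions (walk outwards to the next higher point, take the
minimum on each side; width measured at peak height minus a fraction of the
prominence, with linear interpolation at the crossings, bounded by the
prominence bases).  Plateau-free signals are assumed (random continuous
inputs have no ties).
"""

import math


def oracle_windows(n, size, step):
    """All [start, stop) windows by literal enumeration."""
    out = []
    start = 0
    while start + size <= n:
        out.append((start, start + size))
        start += step
    return out


def _mean(xs):
    return sum(xs) / len(xs)


def _std(xs):
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / len(xs))


def _skew(xs):
    m = _mean(xs)
    m2 = sum((x - m) ** 2 for x in xs) / len(xs)
    if m2 == 0:
        return 0.0
    m3 = sum((x - m) ** 3 for x in xs) / len(xs)
    return m3 / m2**1.5


def _kurtosis_excess(xs):
    m = _mean(xs)
    m2 = sum((x - m) ** 2 for x in xs) / len(xs)
    if m2 == 0:
        return 0.0
    m4 = sum((x - m) ** 4 for x in xs) / len(xs)
    return m4 / m2**2 - 3.0


def _rms_first_diff(xs):
    diffs = [(xs[i + 1] - xs[i]) ** 2 for i in range(len(xs) - 1)]
    return math.sqrt(sum(diffs) / len(diffs))


def _local_maxima(xs):
    return [i for i in range(1, len(xs) - 1) if xs[i - 1] < xs[i] > xs[i + 1]]


def _prominence(xs, peak):
    """Topographic prominence and its left/right base indices."""
    left_min, left_base = xs[peak], peak
    i = peak
    while i >= 0 and xs[i] <= xs[peak]:
        if xs[i] < left_min:
            left_min, left_base = xs[i], i
        i -= 1
    right_min, right_base = xs[peak], peak
    i = peak
    while i < len(xs) and xs[i] <= xs[peak]:
        if xs[i] < right_min:
            right_min, right_base = xs[i], i
        i += 1
    return xs[peak] - max(left_min, right_min), left_base, right_base


def _width(xs, peak, prominence, left_base, right_base, rel_height):
    height = xs[peak] - rel_height * prominence
    i = peak
    while left_base < i and height < xs[i]:
        i -= 1
    left_ip = float(i)
    if xs[i] < height:
        left_ip += (height - xs[i]) / (xs[i + 1] - xs[i])
    i = peak
    while i < right_base and height < xs[i]:
        i += 1
    right_ip = float(i)
    if xs[i] < height:
        right_ip -= (height - xs[i]) / (xs[i - 1] - xs[i])
    return right_ip - left_ip


def oracle_peak_features(xs, prominence_threshold, rel_height, rate):
    """(count, total prominence, total duration in s) of one EDA window."""
    count, total_prom, total_width = 0, 0.0, 0.0
    for peak in _local_maxima(xs):
        prom, lb, rb = _prominence(xs, peak)
        if prom >= prominence_threshold:
            count += 1
            total_prom += prom
            total_width += _width(xs, peak, prom, lb, rb, rel_height)
    return count, total_prom, total_width / rate


def oracle_window_features(eda, hr, temp, size, step, prominence, rel_height, rate=4.0):
    """Rows of the 19 current-window features (dict per window)."""
    rows = []
    for start, stop in oracle_windows(len(eda), size, step):
        e, h, t = list(eda[start:stop]), list(hr[start:stop]), list(temp[start:stop])
        peaks, amp, dur = oracle_peak_features(e, prominence, rel_height, rate)
        row = {
            "EDA_Min": min(e), "EDA_Max": max(e), "EDA_Mean": _mean(e), "EDA_Std": _std(e),
            "EDA_Skew": _skew(e), "EDA_Kurtosis": _kurtosis_excess(e),
            "EDA_Peaks": float(peaks), "EDA_Amplitude": amp, "EDA_Duration": dur,
            "HR_Min": min(h), "HR_Max": max(h), "HR_Mean": _mean(h), "HR_Std": _std(h),
            "HR_RMS": _rms_first_diff(h),
            "TEMP_Min": min(t), "TEMP_Max": max(t), "TEMP_Mean": _mean(t), "TEMP_Std": _std(t),
            "TEMP_RMS": _rms_first_diff(t),
        }
        rows.append(row)
    return rows


def oracle_add_lags(rows, max_lag):
    """Lag stacking by literal shifting; drops the first max_lag rows."""
    out = []
    for i in range(max_lag, len(rows)):
        row = dict(rows[i])
        for k in range(1, max_lag + 1):
            for sig in ("EDA", "HR", "TEMP"):
                row[f"{sig}_Mean_lag{k}"] = rows[i - k][f"{sig}_Mean"]
        out.append(row)
    return out
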