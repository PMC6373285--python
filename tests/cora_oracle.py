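"""Literal brute-force CORA reimplementation used as an independent oracle.

Everything here is written with explicit per-sample Python loops and an
exhaustive shift scan, deliberately sharing no code with the package's
vectorised implementation.
"""

import math


def brute_corridor(ref, test, cfg):
    y = max(abs(v) for v in ref)
    inner, outer = cfg.a0 * y, cfg.b0 * y
    total = 0.0
    for r, t in zip(ref, test):
        err = abs(t - r)
        if err <= inner:
            s = 1.0
        elif err >= outer:
            s = 0.0
        else:
            s = ((outer - err) / (outer - inner)) ** cfg.k_c
        total += s
    return 10.0 * total / len(ref)


def _corr_at(ref, test, lag):
    num = d1 = d2 = 0.0
    n = len(ref)
    for i in range(n):
        j = i + lag
        if 0 <= j < n:
            num += ref[i] * test[j]
            d1 += ref[i] * ref[i]
            d2 += test[j] * test[j]
    if d1 == 0.0 or d2 == 0.0:
        return 0.0
    return num / math.sqrt(d1 * d2)


def brute_phase(ref, test, cfg, dt):
    n = len(ref)
    max_lag = int(math.floor(cfg.max_shift_fraction * (n - 1)))
    best_r, best_lag = -math.inf, 0
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda m: (abs(m), m)):
        r = _corr_at(ref, test, lag)
        if r > best_r + 1e-15:
            best_r, best_lag = r, lag
    shift = best_lag * dt
    t_len = (n - 1) * dt
    lo, hi = cfg.d_min * t_len, cfg.d_max * t_len
    if abs(shift) <= lo:
        p = 10.0
    elif abs(shift) >= hi:
        p = 0.0
    else:
        p = 10.0 * (hi - abs(shift)) / (hi - lo)
    return shift, p


def brute_shape(ref, test, shift, cfg, dt):
    lag = int(round(shift / dt))
    r = _corr_at(ref, test, lag)
    return 10.0 * max(0.0, r) ** cfg.k_V


def brute_size(ref, test, shift, cfg, dt):
    lag = int(round(shift / dt))
    n = len(ref)
    a = [ref[i] for i in range(n) if 0 <= i + lag < n]
    b = [test[i + lag] for i in range(n) if 0 <= i + lag < n]
    area_a = sum(0.5 * dt * (a[i] ** 2 + a[i + 1] ** 2) for i in range(len(a) - 1))
    area_b = sum(0.5 * dt * (b[i] ** 2 + b[i + 1] ** 2) for i in range(len(b) - 1))
    big, small = max(area_a, area_b), min(area_a, area_b)
    return 10.0 * (small / big) ** cfg.k_G
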