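"""CORA biofidelity rating of time-history pairs.

CORA (CORrelation and Analysis) scores the agreement of an evaluated signal
against a reference signal with four components on a 0-10 scale:

* ``C1`` corridor rating: fraction of samples inside an inner/outer corridor
  built from the reference peak;
* ``V`` shape: normalised cross-correlation after phase alignment;
* ``G`` size: ratio of squared-signal areas;
* ``P`` phase: penalty on the correlation-maximising time shift.

The overall biofidelity rating ``B`` is the (weighted, default equal) mean of
the four, and maps to a five-level classification from Unacceptable to
Excellent. Per-case scores aggregate over channels, and cross-case summaries
aggregate per-case scores, both as unweighted means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .signals import SignalCurve, align_pair

__all__ = [
    "CoraConfig",
    "RatingComponents",
    "BiofidelityReport",
    "corridor_rating",
    "phase_rating",
    "shape_rating",
    "size_rating",
    "combine_components",
    "rate_pair",
    "rate_channels",
    "aggregate_cases",
    "classify_biofidelity",
]

#: classification bins: label, lower edge (inclusive), upper edge (exclusive;
#: the top bin includes 10). The Fair/Good boundary is 6.5.
CLASSIFICATION_BINS = (
    ("Unacceptable", 0.0, 2.6),
    ("Marginal", 2.6, 4.5),
    ("Fair", 4.5, 6.5),
    ("Good", 6.5, 8.6),
    ("Excellent", 8.6, 10.0),
)


@dataclass(frozen=True)
class CoraConfig:
    """Rating parameters.

    The corridor half-widths are fractions of the reference peak ``Y``:
    inner ``a0*Y``, outer ``b0*Y``. Phase tolerances ``d_min``/``d_max`` are
    fractions of the evaluation-window length; the shift search is bounded by
    ``max_shift_fraction`` of the window. Defaults follow common published
    CORA practice; all are exposed because the method's authority defines the
    structure, not the constants.
    """

    eval_window: tuple[float, float] | None = None
    a0: float = 0.05
    b0: float = 0.5
    k_c: float = 2.0
    k_V: float = 1.0
    k_G: float = 1.0
    d_min: float = 0.01
    d_max: float = 0.12
    max_shift_fraction: float = 0.2
    component_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if not 0 < self.a0 < self.b0:
            raise ValueError("corridor fractions must satisfy 0 < a0 < b0")
        if not 0 <= self.d_min < self.d_max <= 1:
            raise ValueError("phase fractions must satisfy 0 <= d_min < d_max <= 1")
        w = np.asarray(self.component_weights, float)
        if w.size != 4 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("component_weights must be 4 non-negative values summing to 1")


@dataclass(frozen=True)
class RatingComponents:
    """The four CORA sub-scores and the overall rating, each in [0, 10]."""

    V: float
    G: float
    P: float
    C1: float
    B: float

    def __post_init__(self) -> None:
        for name in ("V", "G", "P", "C1", "B"):
            v = getattr(self, name)
            if not 0.0 <= v <= 10.0 + 1e-12:
                raise ValueError(f"component {name}={v} outside [0, 10]")

    def rounded(self, ndigits: int = 2) -> "RatingComponents":
        """Half-even rounding for report display (table precision)."""
        r = lambda x: float(np.round(x, ndigits))
        return RatingComponents(r(self.V), r(self.G), r(self.P), r(self.C1), r(self.B))


@dataclass
class BiofidelityReport:
    """Per-channel and per-case ratings plus classification."""

    per_channel: list[tuple[str, RatingComponents]]
    per_case: RatingComponents
    classification: str

    def to_dict(self) -> dict:
        return {
            "per_channel": [
                {"channel": lbl, **asdict(rc)} for lbl, rc in self.per_channel
            ],
            "per_case": asdict(self.per_case),
            "classification": self.classification,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ----------------------------------------------------------------------
# component ratings (curves must already share a grid; see align_pair)
# ----------------------------------------------------------------------

def _check_aligned(ref: SignalCurve, test: SignalCurve) -> None:
    if ref.times.size != test.times.size or not np.allclose(
        ref.times, test.times, rtol=0, atol=1e-12 * max(1.0, abs(ref.times[-1]))
    ):
        raise ValueError("curves must be aligned on a common grid (use align_pair)")


def corridor_rating(ref: SignalCurve, test: SignalCurve, config: CoraConfig) -> float:
    """Corridor score ``C1`` in [0, 10].

    With ``Y = max |ref|``, samples within the inner corridor ``a0*Y`` score
    1, beyond the outer corridor ``b0*Y`` score 0, and in between
    ``((outer - |err|)/(outer - inner))**k_c``; C1 is 10x their mean.
    """
    _check_aligned(ref, test)
    y = float(np.max(np.abs(ref.values)))
    if y == 0.0:
        raise ValueError("degenerate reference: flat zero signal has no corridor")
    inner = config.a0 * y
    outer = config.b0 * y
    err = np.abs(test.values - ref.values)
    s = np.clip((outer - err) / (outer - inner), 0.0, 1.0) ** config.k_c
    s[err <= inner] = 1.0
    return 10.0 * float(np.mean(s))


def phase_rating(
    ref: SignalCurve, test: SignalCurve, config: CoraConfig
) -> tuple[float, float]:
    """Phase score ``P`` and the detected shift in seconds.

    The shift maximising the normalised cross-correlation is searched over
    integer-sample lags within ``max_shift_fraction`` of the window length;
    ties break toward the smallest ``|shift|``. A positive shift means the
    test curve lags the reference. ``P`` is 10 for ``|shift| <= d_min*T``,
    0 for ``|shift| >= d_max*T`` and linear in between (``T`` = window
    length).

    Returns ``(shift_seconds, P)``.
    """
    _check_aligned(ref, test)
    n = ref.times.size
    if n < 3:
        raise ValueError("phase rating needs a window of at least 3 samples")
    dt = ref.sample_interval
    t_len = ref.duration
    max_lag = int(np.floor(config.max_shift_fraction * (n - 1)))
    best_r, best_lag = -np.inf, 0
    # ordered by |lag| so the first strict maximum wins ties toward zero shift
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda m: (abs(m), m)):
        r = _xcorr_at_lag(ref.values, test.values, lag)
        if r > best_r + 1e-15:
            best_r, best_lag = r, lag
    shift = best_lag * dt
    lo, hi = config.d_min * t_len, config.d_max * t_len
    if abs(shift) <= lo:
        p = 10.0
    elif abs(shift) >= hi:
        p = 0.0
    else:
        p = 10.0 * (hi - abs(shift)) / (hi - lo)
    return shift, p


def _xcorr_at_lag(ref: np.ndarray, test: np.ndarray, lag: int) -> float:
    """Normalised (non-centred) cross-correlation of ref[i] with test[i+lag]."""
    n = ref.size
    if lag >= 0:
        a, b = ref[: n - lag], test[lag:]
    else:
        a, b = ref[-lag:], test[: n + lag]
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0.0:
        return 0.0
    return float(np.sum(a * b) / denom)


def _shift_overlap(ref: SignalCurve, test: SignalCurve, shift: float):
    """Overlapping sample arrays after undoing an integer-sample shift."""
    dt = ref.sample_interval
    lag = int(round(shift / dt))
    n = ref.times.size
    if abs(lag) >= n - 1:
        raise ValueError("shift exceeds the evaluation window")
    if lag >= 0:
        return ref.values[: n - lag], test.values[lag:]
    return ref.values[-lag:], test.values[: n + lag]


def shape_rating(
    ref: SignalCurve, test: SignalCurve, shift: float, config: CoraConfig
) -> float:
    """Shape score ``V = 10 * max(0, r)**k_V`` at the aligned position."""
    _check_aligned(ref, test)
    a, b = _shift_overlap(ref, test, shift)
    if np.all(a == 0.0) or np.all(b == 0.0):
        raise ValueError("zero-variance signal in window: shape undefined")
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    r = float(np.sum(a * b) / denom)
    return 10.0 * max(0.0, r) ** config.k_V


def size_rating(
    ref: SignalCurve, test: SignalCurve, shift: float, config: CoraConfig
) -> float:
    """Size score from squared-signal areas after phase alignment.

    ``G = 10 * (min(A_ref, A_test) / max(A_ref, A_test))**k_G`` with
    ``A_x`` the trapezoidal integral of ``x(t)^2`` over the overlap.
    """
    _check_aligned(ref, test)
    a, b = _shift_overlap(ref, test, shift)
    dt = ref.sample_interval
    area_a = float(np.trapezoid(a * a, dx=dt))
    area_b = float(np.trapezoid(b * b, dx=dt))
    if area_a == 0.0 and area_b == 0.0:
        raise ValueError("both signals have zero area: size undefined")
    ratio = min(area_a, area_b) / max(area_a, area_b)
    return 10.0 * ratio ** config.k_G


def combine_components(
    v: float, g: float, p: float, c1: float, config: CoraConfig | None = None
) -> float:
    """Overall rating ``B``: weighted mean of (V, G, P, C1), default equal."""
    w = (0.25, 0.25, 0.25, 0.25) if config is None else config.component_weights
    return float(w[0] * v + w[1] * g + w[2] * p + w[3] * c1)


def rate_pair(
    ref: SignalCurve, test: SignalCurve, config: CoraConfig | None = None
) -> RatingComponents:
    """Full per-channel rating of ``test`` against ``ref``."""
    config = config or CoraConfig()
    r, t = align_pair(ref, test, config.eval_window)
    c1 = corridor_rating(r, t, config)
    shift, p = phase_rating(r, t, config)
    v = shape_rating(r, t, shift, config)
    g = size_rating(r, t, shift, config)
    b = combine_components(v, g, p, c1, config)
    return RatingComponents(v, g, p, c1, b)


def rate_channels(
    pairs: Iterable[tuple[str, SignalCurve, SignalCurve]],
    config: CoraConfig | None = None,
) -> BiofidelityReport:
    """Rate several channels and aggregate into a per-case report."""
    per_channel = [(lbl, rate_pair(ref, test, config)) for lbl, ref, test in pairs]
    per_case = aggregate_cases([rc for _, rc in per_channel])
    return BiofidelityReport(per_channel, per_case, classify_biofidelity(per_case.B))


def aggregate_cases(cases: Sequence[RatingComponents]) -> RatingComponents:
    """Unweighted component-wise mean over cases (the table 'Average' row)."""
    if len(cases) == 0:
        raise ValueError("cannot aggregate an empty list of cases")
    arr = np.array([[c.V, c.G, c.P, c.C1, c.B] for c in cases], float)
    m = arr.mean(axis=0)
    return RatingComponents(*m)


def classify_biofidelity(b: float) -> str:
    """Map an overall rating to its five-level classification label."""
    if not 0.0 <= b <= 10.0:
        raise ValueError(f"B={b} outside [0, 10]")
    for label, lo, hi in CLASSIFICATION_BINS:
        if lo <= b < hi:
            return label
    return "Excellent"  # b == 10.0
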