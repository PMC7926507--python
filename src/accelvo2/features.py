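"""Per-minute feature extraction for triaxial acceleration windows.

Each one-minute window of a session contributes 55 variables: for each of
the four channels (the three orthogonal axes X, Y, Z and the resultant
vector RV) thirteen statistics are computed —

* dispersion: sample standard deviation (``SD``) and variance (``VAR``);
* distribution shape: the 10th/25th/50th/75th/90th percentiles
  (``P10`` … ``P90``) and the interquartile range (``75-25``);
* temporal dynamics: the lag-one autocorrelation (``DYN``);
* multi-resolution energy: Euclidean norms of the level-1 and level-2
  detail coefficients and the level-2 approximation coefficients of a
  two-level Daubechies-2 discrete wavelet transform (``ND1``, ``ND2``,
  ``NA2``);
* irregularity: sample entropy with pattern length m = 2 and tolerance
  r = 0.3 × SD of the window (``SAMPEN``);

plus the three zero-lag Pearson cross-correlations between the axes
(``XCORR_XY``, ``XCORR_YZ``, ``XCORR_XZ``), for 4 × 13 + 3 = 55.

Feature names follow the ``{channel}_{stat}`` scheme (e.g. ``RV_75-25``,
``Y_VAR``) so published predictive equations can be evaluated by name
lookup.  Features split into a *linear* class (SD, VAR, percentiles, IQR;
32 features) and a *nonlinear* class (DYN, wavelet norms, SAMPEN,
cross-correlations; 23 features).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

CHANNELS = ("X", "Y", "Z", "RV")

#: Per-channel statistics, in canonical order.
CHANNEL_STATS = (
    "SD", "VAR", "P10", "P25", "P50", "P75", "P90", "75-25",
    "DYN", "ND1", "ND2", "NA2", "SAMPEN",
)

LINEAR_STATS = frozenset({"SD", "VAR", "P10", "P25", "P50", "P75", "P90", "75-25"})
NONLINEAR_STATS = frozenset({"DYN", "ND1", "ND2", "NA2", "SAMPEN"})

CROSS_CORRELATIONS = ("XCORR_XY", "XCORR_YZ", "XCORR_XZ")

#: All 55 canonical feature names.  The order here is the canonical order
#: used for column layout and for deterministic tie-breaking in model
#: selection: channels X, Y, Z, RV each with their 13 statistics, then the
#: three cross-correlations.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{stat}" for ch in CHANNELS for stat in CHANNEL_STATS
) + CROSS_CORRELATIONS

FEATURE_INDEX: dict[str, int] = {name: i for i, name in enumerate(FEATURE_NAMES)}

#: Metadata columns appended after the 55 features in tabular output.
TABLE_META_COLUMNS = ("label", "type", "vo2", "participant_id")


def feature_class_map() -> dict[str, str]:
    """Map each of the 55 feature names to its class, ``linear`` or
    ``nonlinear``.

    Linear: SD, VAR, the five percentiles and the IQR per channel (32).
    Nonlinear: DYN, ND1, ND2, NA2, SAMPEN per channel plus the three
    cross-correlations (23).
    """
    cmap: dict[str, str] = {}
    for ch in CHANNELS:
        for stat in CHANNEL_STATS:
            cmap[f"{ch}_{stat}"] = "linear" if stat in LINEAR_STATS else "nonlinear"
    for name in CROSS_CORRELATIONS:
        cmap[name] = "nonlinear"
    return cmap


def canonical_sort(names) -> list[str]:
    """Sort feature names into the canonical order."""
    return sorted(names, key=FEATURE_INDEX.__getitem__)


@dataclass
class MinuteWindow:
    """One 60-second, four-channel slab of acceleration with its label and
    the minute-averaged oxygen uptake observed over the same interval.

    ``rv`` must equal the per-sample Euclidean norm of ``(x, y, z)``.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    rv: np.ndarray
    label: str
    type: str
    vo2: float
    participant_id: str
    start_s: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.rv = np.asarray(self.rv, dtype=float)
        n = len(self.x)
        if not (len(self.y) == len(self.z) == len(self.rv) == n):
            raise ValueError("window channels must have equal lengths")
        if n < 4:
            raise ValueError(
                f"window needs >= 4 samples for a level-2 wavelet transform, got {n}"
            )
        if not np.allclose(self.rv, np.sqrt(self.x**2 + self.y**2 + self.z**2)):
            raise ValueError("rv channel is not the Euclidean norm of (x, y, z)")

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {"X": self.x, "Y": self.y, "Z": self.z, "RV": self.rv}

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class FeatureVector:
    """The 55 named variables of one window plus carried-through metadata."""

    values: dict[str, float]
    label: str
    type: str
    vo2: float
    participant_id: str

    def __post_init__(self) -> None:
        if set(self.values) != set(FEATURE_NAMES):
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature vector must have exactly the 55 canonical keys; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# per-channel statistics


def dispersion_stats(s: np.ndarray) -> dict[str, float]:
    """Sample (n−1 denominator) variance and standard deviation."""
    s = np.asarray(s, dtype=float)
    if s.size < 2:
        raise ValueError("dispersion_stats needs at least 2 samples")
    var = float(np.var(s, ddof=1))
    return {"SD": math.sqrt(var), "VAR": var}


def percentile_stats(s: np.ndarray) -> dict[str, float]:
    """10/25/50/75/90th percentiles (linear interpolation between order
    statistics) and the interquartile range ``75-25``."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("percentile_stats needs a non-empty series")
    p10, p25, p50, p75, p90 = np.percentile(s, [10, 25, 50, 75, 90])
    return {
        "P10": float(p10), "P25": float(p25), "P50": float(p50),
        "P75": float(p75), "P90": float(p90), "75-25": float(p75 - p25),
    }


def _pearson(a: np.ndarray, b: np.ndarray, what: str) -> float:
    """Pearson r with the degenerate-window convention: a constant input
    yields 0 with a logged warning rather than NaN."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        log.warning("%s: constant series, correlation reported as 0", what)
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def lag_one_correlation(s: np.ndarray) -> float:
    """Lag-one autocorrelation: Pearson r between s[:-1] and s[1:]."""
    s = np.asarray(s, dtype=float)
    if s.size < 3:
        raise ValueError("lag_one_correlation needs at least 3 samples")
    return _pearson(s[:-1], s[1:], "lag_one_correlation")


def cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-lag Pearson correlation between two equally long channels."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("cross_correlation needs equal-length series")
    if a.size < 2:
        raise ValueError("cross_correlation needs at least 2 samples")
    return _pearson(a, b, "cross_correlation")


def wavelet_norms(s: np.ndarray, wavelet: str = "db2", level: int = 2) -> dict[str, float]:
    """Euclidean norms of the detail and deepest approximation coefficients
    of a multi-level DWT with periodized boundary handling.

    With the default Daubechies-2 wavelet at level 2 the transform is
    orthonormal under periodization for lengths divisible by 4 (one-minute
    windows at any whole samples-per-minute rate divisible by 4 qualify), so
    ND1² + ND2² + NA2² then equals the signal energy up to round-off.  Other
    lengths are padded internally by the transform and conserve energy only
    approximately.
    """
    s = np.asarray(s, dtype=float)
    if s.size < 2**level:
        raise ValueError(
            f"wavelet_norms needs at least {2**level} samples for level {level}, got {s.size}"
        )
    coeffs = pywt.wavedec(s, wavelet, mode="periodization", level=level)
    approx, details = coeffs[0], coeffs[1:]  # details: [cD_level, ..., cD1]
    out: dict[str, float] = {}
    for lev, cd in zip(range(level, 0, -1), details):
        out[f"ND{lev}"] = float(np.linalg.norm(cd))
    out[f"NA{level}"] = float(np.linalg.norm(approx))
    return out


def sample_entropy(s: np.ndarray, m: int = 2, r_coeff: float = 0.3) -> float:
    """Sample entropy SampEn(m, r) with tolerance r = r_coeff × SD(s).

    SampEn = −ln(A/B), where B counts pairs of distinct m-length templates
    whose Chebyshev distance is ≤ r and A counts the same for (m+1)-length
    templates; both counts run over the first n−m template start positions
    and self-matches are excluded.  Degenerate conventions: a constant
    window returns 0; if no (m+1)-template pairs match, the standard cap
    −ln(2 / ((n−m−1)(n−m))) is returned.  Pair counting uses a KD-tree in
    the Chebyshev metric, which is exactly equivalent to the quadratic
    template scan.
    """
    s = np.asarray(s, dtype=float)
    n = s.size
    if n < m + 2:
        raise ValueError(f"sample_entropy needs at least m + 2 = {m + 2} samples")
    sd = float(np.std(s, ddof=1))
    if sd == 0.0:
        log.warning("sample_entropy: constant series, returning 0")
        return 0.0
    r = r_coeff * sd

    def _pairs(width: int) -> int:
        tmpl = np.lib.stride_tricks.sliding_window_view(s, width)[: n - m]
        tree = cKDTree(tmpl)
        ordered = tree.count_neighbors(tree, r, p=np.inf)
        return int(ordered - len(tmpl)) // 2

    b = _pairs(m)
    a = _pairs(m + 1)
    if a == 0 or b == 0:
        log.warning(
            "sample_entropy: no template matches at length %d; returning the "
            "standard cap", m + 1 if b else m,
        )
        return -math.log(2.0 / ((n - m - 1) * (n - m)))
    return -math.log(a / b)


# ---------------------------------------------------------------------------
# window-level extraction


def channel_features(s: np.ndarray, m: int = 2, r_coeff: float = 0.3,
                     wavelet: str = "db2") -> dict[str, float]:
    """The 13 statistics of one channel, keyed by bare statistic name."""
    out: dict[str, float] = {}
    out.update(dispersion_stats(s))
    out.update(percentile_stats(s))
    out["DYN"] = lag_one_correlation(s)
    out.update(wavelet_norms(s, wavelet=wavelet, level=2))
    out["SAMPEN"] = sample_entropy(s, m=m, r_coeff=r_coeff)
    return out


def compute_features(w: MinuteWindow, names, m: int = 2, r_coeff: float = 0.3,
                     wavelet: str = "db2") -> dict[str, float]:
    """Compute only the named features of a window.

    Statistics are evaluated lazily per group (dispersion, percentiles,
    lag-one, wavelet, sample entropy, cross-correlation), so e.g. evaluating
    a three-term published equation on a window never pays for sample
    entropy.  Returns a name → value mapping covering exactly ``names``.
    """
    names = list(names)
    unknown = [n for n in names if n not in FEATURE_INDEX]
    if unknown:
        raise KeyError(f"unknown feature names: {unknown}")
    chans = w.channels
    out: dict[str, float] = {}
    groups = {
        "dispersion": ("SD", "VAR"),
        "percentile": ("P10", "P25", "P50", "P75", "P90", "75-25"),
    }
    for name in names:
        if name in out:
            continue
        if name in CROSS_CORRELATIONS:
            pair = name.split("_")[1]  # "XY", "YZ" or "XZ"
            out[name] = cross_correlation(chans[pair[0]], chans[pair[1]])
            continue
        ch, stat = name.split("_", 1)
        s = chans[ch]
        if stat in groups["dispersion"]:
            out.update({f"{ch}_{k}": v for k, v in dispersion_stats(s).items()})
        elif stat in groups["percentile"]:
            out.update({f"{ch}_{k}": v for k, v in percentile_stats(s).items()})
        elif stat == "DYN":
            out[name] = lag_one_correlation(s)
        elif stat in ("ND1", "ND2", "NA2"):
            out.update({f"{ch}_{k}": v for k, v in wavelet_norms(s, wavelet=wavelet).items()})
        elif stat == "SAMPEN":
            out[name] = sample_entropy(s, m=m, r_coeff=r_coeff)
    return {n: out[n] for n in names}


def extract_features(w: MinuteWindow, m: int = 2, r_coeff: float = 0.3,
                     wavelet: str = "db2") -> FeatureVector:
    """Compute all 55 features of a window.

    Deterministic for a fixed input; channel-level errors are re-raised with
    the window's identity (participant, label, start time) attached.
    """
    values: dict[str, float] = {}
    try:
        for ch, s in w.channels.items():
            stats = channel_features(s, m=m, r_coeff=r_coeff, wavelet=wavelet)
            for stat, v in stats.items():
                values[f"{ch}_{stat}"] = v
        values["XCORR_XY"] = cross_correlation(w.x, w.y)
        values["XCORR_YZ"] = cross_correlation(w.y, w.z)
        values["XCORR_XZ"] = cross_correlation(w.x, w.z)
    except ValueError as exc:
        raise ValueError(
            f"feature extraction failed for window participant={w.participant_id} "
            f"label={w.label!r} start={w.start_s:g}s: {exc}"
        ) from exc
    return FeatureVector(values=values, label=w.label, type=w.type,
                         vo2=w.vo2, participant_id=w.participant_id)


def features_table(windows, m: int = 2, r_coeff: float = 0.3,
                   wavelet: str = "db2") -> pd.DataFrame:
    """Extract features for a sequence of windows into a table.

    Columns are the 55 canonical feature names in canonical order followed
    by ``label``, ``type``, ``vo2`` and ``participant_id``; one row per
    window.
    """
    rows = []
    for w in windows:
        fv = extract_features(w, m=m, r_coeff=r_coeff, wavelet=wavelet)
        row = {name: fv.values[name] for name in FEATURE_NAMES}
        row.update(label=fv.label, type=fv.type, vo2=fv.vo2,
                   participant_id=fv.participant_id)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + list(TABLE_META_COLUMNS))
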