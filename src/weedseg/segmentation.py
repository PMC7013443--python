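"""RGNIR vegetation index, histogram prefix statistics, multi-level Otsu
thresholding and the binary vegetation mask.

The RGNIR index is a normalised-green-style colour index for a modified RGB
camera whose blue channel carries a combined NIR + green response:

    RGNIR = beta*(Gc - gc) / (alpha*(Rc + rc) + beta*(Gc - gc) + gamma*(Bc - bc)) + L

with per-channel background corrections (gc, rc, bc) captured in a black-box
condition, channel weights alpha/beta/gamma in [0, 1] and a soil-adjusted
additive constant L.  Note the asymmetric "+rc" in the denominator, which is
kept as the default (``red_correction_sign="plus"``); the symmetric
subtraction is available via ``red_correction_sign="minus"``.

Segmentation quantises the index image to 8 bits, histograms it and picks
thresholds maximising between-class variance (multi-level Otsu), with class
statistics obtained in O(1) per candidate from prefix sums over the histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IndexWeights",
    "BackgroundCorrection",
    "IndexImage",
    "DegenerateHistogramError",
    "compute_rgnir",
    "quantise_index",
    "prefix_stats",
    "multi_otsu",
    "between_class_variance",
    "vegetation_mask",
]


@dataclass
class IndexWeights:
    """Channel weights and soil constant of the RGNIR index."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    L: float = 0.0
    red_correction_sign: str = "plus"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.red_correction_sign not in ("plus", "minus"):
            raise ValueError("red_correction_sign must be 'plus' or 'minus'")


@dataclass
class BackgroundCorrection:
    """Per-channel background correction: scalar or full-resolution array, [0, 255]."""

    rc: float | np.ndarray = 0.0
    gc: float | np.ndarray = 0.0
    bc: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        for name in ("rc", "gc", "bc"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < 0) or np.any(v > 255):
                raise ValueError(f"background correction {name} outside [0, 255]")
            setattr(self, name, v if v.ndim else float(v))


@dataclass
class IndexImage:
    """Real-valued RGNIR index image with provenance back to its source frame."""

    values: np.ndarray
    source_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("index image must be finite everywhere")


class DegenerateHistogramError(ValueError):
    """Histogram has too few populated bins to support the requested thresholds."""


def _check_bg_shape(bg_val, shape, name: str) -> np.ndarray:
    arr = np.asarray(bg_val, dtype=float)
    if arr.ndim and arr.shape != shape:
        raise ValueError(
            f"background correction {name} shape {arr.shape} != frame shape {shape}"
        )
    return arr


def compute_rgnir(frame, bg: BackgroundCorrection, w: IndexWeights) -> IndexImage:
    """Evaluate the RGNIR index per pixel in signed float arithmetic.

    Pixels with a zero denominator (no measurable reflectance) evaluate to the
    soil baseline ``L``.
    """
    shape = frame.shape
    rc = _check_bg_shape(bg.rc, shape, "rc")
    gc = _check_bg_shape(bg.gc, shape, "gc")
    bc = _check_bg_shape(bg.bc, shape, "bc")

    r = frame.red.astype(float)
    g = frame.green.astype(float)
    b = frame.blue.astype(float)

    num = w.beta * (g - gc)
    red_term = (r + rc) if w.red_correction_sign == "plus" else (r - rc)
    den = w.alpha * red_term + num + w.gamma * (b - bc)

    out = np.full(shape, w.L, dtype=float)
    ok = den != 0
    out[ok] = num[ok] / den[ok] + w.L
    return IndexImage(values=out, source_index=frame.index)


def quantise_index(img: IndexImage) -> tuple[np.ndarray, np.ndarray]:
    """Min–max scale the index image onto [0, 255] (round half-up) and histogram it.

    A constant image maps to all zeros.  Min–max scaling is monotone, so the
    Otsu class structure of the index is preserved.  Returns (uint8 image,
    256-bin histogram).
    """
    v = img.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        q = np.zeros(v.shape, dtype=np.uint8)
    else:
        q = np.floor(255.0 * (v - lo) / (hi - lo) + 0.5).astype(np.uint8)
    hist = np.bincount(q.ravel(), minlength=256).astype(np.int64)
    return q, hist


def prefix_stats(hist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative counts and cumulative first moments of a 256-bin histogram.

    ``counts[k] = sum_{i<=k} hist[i]`` and ``moments[k] = sum_{i<=k} i*hist[i]``.
    These prefix sums give every class's weight and mean in O(1), which is what
    makes the exhaustive multi-Otsu search cheap.
    """
    h = np.asarray(hist, dtype=np.int64)
    if h.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.any(h < 0):
        raise ValueError("histogram counts must be non-negative")
    counts = np.cumsum(h)
    moments = np.cumsum(np.arange(256, dtype=np.int64) * h)
    return counts, moments


def _class_score_table(hist: np.ndarray) -> np.ndarray:
    """S[lo, hi] = M^2 / W for the intensity class [lo, hi] (0 when empty).

    Maximising the between-class variance sum(W_k mu_k^2) - mu_T^2 is
    equivalent to maximising sum_k M_k^2 / W_k, M_k and W_k the class first
    moment and weight.
    """
    counts, moments = prefix_stats(hist)
    cc = np.concatenate([[0], counts])  # cc[i] = sum of bins < i
    cm = np.concatenate([[0], moments])
    lo = np.arange(256)[:, None]
    hi = np.arange(256)[None, :]
    W = (cc[hi + 1] - cc[lo]).astype(float)
    M = (cm[hi + 1] - cm[lo]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(W > 0, M * M / np.maximum(W, 1), 0.0)
    S[hi < lo] = 0.0
    return S


def between_class_variance(hist: np.ndarray, thresholds: tuple[int, ...]) -> float:
    """Between-class variance of the partition [0,t1], (t1,t2], ..., (tn,255].

    Reported as sum_k W_k (mu_k - mu_T)^2 / N, comparable across partitions.
    """
    h = np.asarray(hist, dtype=np.int64)
    n = int(h.sum())
    if n == 0:
        return 0.0
    edges = [0] + [t + 1 for t in thresholds] + [256]
    mu_t = float((np.arange(256) * h).sum()) / n
    var = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        w = float(h[a:b].sum())
        if w > 0:
            mu = float((np.arange(a, b) * h[a:b]).sum()) / w
            var += w * (mu - mu_t) ** 2
    return var / n


def _enumerate_best(S: np.ndarray, n: int) -> tuple[int, ...]:
    """Exhaustive search over strictly increasing threshold tuples, n <= 3.

    The flat argmax of the (C-ordered) objective tensor is the lexicographically
    smallest maximiser.
    """
    if n == 1:
        t = np.arange(255)
        total = S[0, t] + S[t + 1, 255]
        return (int(np.argmax(total)),)
    if n == 2:
        t1 = np.arange(255)[:, None]
        t2 = np.arange(255)[None, :]
        total = S[0, t1] + S[t1 + 1, np.maximum(t2, t1)] + S[t2 + 1, 255]
        total = np.where(t2 > t1, total, -np.inf)
        flat = int(np.argmax(total))
        return (flat // 255, flat % 255)
    # n == 3: ~16.6M candidates, still fine vectorised
    t = np.arange(255)
    a = S[0, t]  # (t1,)
    b = S[t[:, None] + 1, np.maximum(t[None, :], t[:, None])]  # (t1, t2) -> class (t1, t2]
    c = S[t[:, None] + 1, np.maximum(t[None, :], t[:, None])]  # (t2, t3)
    d = S[t + 1, 255]  # (t3,)
    total = (
        a[:, None, None]
        + b[:, :, None]
        + c[None, :, :]
        + d[None, None, :]
    )
    t1 = t[:, None, None]
    t2 = t[None, :, None]
    t3 = t[None, None, :]
    total = np.where((t2 > t1) & (t3 > t2), total, -np.inf)
    flat = int(np.argmax(total))
    return (flat // (255 * 255), (flat // 255) % 255, flat % 255)


def _dp_best(S: np.ndarray, n: int) -> tuple[int, ...]:
    """Suffix dynamic programme for larger n; lexicographically smallest on ties."""
    n_classes = n + 1
    # F[m][s] = best score splitting bins [s, 255] into m classes
    F = np.full((n_classes + 1, 257), -np.inf)
    F[1, :256] = S[np.arange(256), 255]
    F[0, 256] = 0.0
    for m in range(2, n_classes + 1):
        for s in range(256 - m, -1, -1):
            ends = np.arange(s, 256 - m + 1)
            F[m, s] = np.max(S[s, ends] + F[m - 1, ends + 1])
    best = F[n_classes, 0]
    thresholds: list[int] = []
    s = 0
    remaining = n_classes
    acc = 0.0
    for _ in range(n):
        for t in range(s, 256 - (remaining - 1)):
            cand = acc + S[s, t] + F[remaining - 1, t + 1]
            if np.isclose(cand, best, rtol=1e-12, atol=1e-9):
                thresholds.append(t)
                acc += S[s, t]
                s = t + 1
                remaining -= 1
                break
    return tuple(thresholds)


def multi_otsu(hist: np.ndarray, n_thresholds: int = 2) -> tuple[int, ...]:
    """Thresholds maximising between-class variance (multi-level Otsu).

    Classes are the intensity ranges [0,t1], (t1,t2], ..., (tn,255].  The
    search is exhaustive over all strictly increasing tuples, with class
    statistics from prefix sums; ties break to the lexicographically smallest
    tuple.  Supports 1–4 thresholds.
    """
    if not (1 <= n_thresholds <= 4):
        raise ValueError("n_thresholds must be in 1..4")
    h = np.asarray(hist, dtype=np.int64)
    if np.count_nonzero(h) < n_thresholds + 1:
        raise DegenerateHistogramError(
            f"histogram has {np.count_nonzero(h)} populated bins; "
            f"need at least {n_thresholds + 1} for {n_thresholds} thresholds"
        )
    S = _class_score_table(h)
    if n_thresholds <= 3:
        return _enumerate_best(S, n_thresholds)
    return _dp_best(S, n_thresholds)


def select_vegetation_classes(hist: np.ndarray, thresholds: tuple[int, ...]) -> set[int]:
    """Classes on the bright side of the widest inter-class separation.

    The plant/soil boundary is the threshold whose adjacent class means are
    furthest apart: the index gap between soil and vegetation dwarfs any
    within-population split the extra Otsu levels introduce.  Falls back to
    the top class when means are degenerate.
    """
    h = np.asarray(hist, dtype=np.int64)
    edges = [0] + [t + 1 for t in thresholds] + [256]
    means = []
    for a, b in zip(edges[:-1], edges[1:]):
        w = h[a:b].sum()
        means.append(float((np.arange(a, b) * h[a:b]).sum()) / w if w else np.nan)
    means_arr = np.array(means)
    # gaps between consecutive non-empty class means
    gaps = []
    prev = None
    for k, m in enumerate(means_arr):
        if np.isnan(m):
            continue
        if prev is not None:
            gaps.append((m - means_arr[prev], k))
        prev = k
    if not gaps:
        return {len(thresholds)}
    _, split = max(gaps)
    return set(range(split, len(thresholds) + 1))


def vegetation_mask(
    quantised: np.ndarray,
    thresholds: tuple[int, ...],
    vegetation_classes: set[int] | None = None,
) -> np.ndarray:
    """Binary mask of pixels whose Otsu class is a vegetation class.

    Class 0 is [0, t1] (inclusive upper bound); by default the top (brightest)
    class is vegetation, since the green-normalised index scores plants high.
    """
    thresholds = tuple(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    n_classes = len(thresholds) + 1
    if vegetation_classes is None:
        vegetation_classes = {n_classes - 1}
    bad = [c for c in vegetation_classes if not (0 <= c < n_classes)]
    if bad:
        raise ValueError(f"invalid vegetation class indices {bad} for {n_classes} classes")
    classes = np.digitize(quantised, thresholds, right=True)
    return np.isin(classes, sorted(vegetation_classes))
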