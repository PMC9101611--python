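"""Co-occurrence and run-length texture statistics.

Five per-ROI statistics are computed on the quantized level array:

* ``Entropy``  = -sum_{i,j} p(i,j) log p(i,j), the Shannon entropy of the
  gray-level co-occurrence matrix (GLCM) at a fixed pixel displacement;
* ``DifEntrp`` = -sum_m q(m) log q(m), the entropy of the difference
  histogram q(m) = sum_{|i-j|=m} p(i,j);
* ``LngREmph`` = sum_{i,k} k^2 r(i,k) / sum_{i,k} r(i,k), the long-run
  emphasis of the run-length matrix (RLM) -- the second-moment-weighted
  mean run length, large for images with extended uniform regions such as
  the solid dark patches of invasive melanoma;
* ``TI`` = Entropy / LngREmph and ``BI`` = DifEntrp / LngREmph, ratios of
  structural diversity to uniform longitudinal structure (texture index
  and bone index).

The GLCM is accumulated symmetrically (both pair orders) in the Haralick
convention, at displacement distance 5 along the four canonical directions;
runs are scanned along the same four directions with no length cap.  Each
feature is aggregated over directions by its configured reducer
(arithmetic mean by default) and TI/BI are derived from the aggregated
values per ROI.  Entropies use the natural logarithm by default; the base
only rescales Entropy/DifEntrp/TI/BI globally and leaves group orderings
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from lesiontex.imaging_io import GroupLabel, Lighting
from lesiontex.preprocess import QuantizedROI

_NORM_TOL = 1e-8


class Direction(str, Enum):
    """Scan direction for run decomposition (and the matching GLCM offset)."""

    HORIZONTAL = "horizontal"  # offset (0, d)
    VERTICAL = "vertical"      # offset (d, 0)
    DIAG45 = "diag45"          # offset (d, -d): runs along anti-diagonals
    DIAG135 = "diag135"        # offset (d, d): runs along main diagonals


def offsets_for_distance(d: int) -> dict[Direction, tuple[int, int]]:
    """The four canonical pixel displacements at grid distance ``d``."""
    return {
        Direction.HORIZONTAL: (0, d),
        Direction.VERTICAL: (d, 0),
        Direction.DIAG135: (d, d),
        Direction.DIAG45: (d, -d),
    }


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric, normalized joint distribution p(i, j) of level pairs.

    ``p[i-1, j-1]`` is the probability that a pixel pair at displacement
    ``offset`` (counted in both orders) has levels ``(i, j)``.
    """

    p: np.ndarray
    offset: tuple[int, int]
    ng: int
    pair_count: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if p.shape != (self.ng, self.ng):
            raise ValueError(f"p must be {self.ng}x{self.ng}, got {p.shape}")
        object.__setattr__(self, "p", p)

    def difference_histogram(self) -> np.ndarray:
        """q(m) = sum_{|i-j|=m} p(i,j) for m = 0 .. Ng-1."""
        i = np.arange(self.ng)
        m = np.abs(i[:, None] - i[None, :])
        return np.bincount(m.ravel(), weights=self.p.ravel(), minlength=self.ng)


@dataclass(frozen=True)
class RunLengthMatrix:
    """Counts r(i, k) of maximal runs of level i with length k."""

    r: np.ndarray
    direction: Direction
    ng: int
    nr: int

    def __post_init__(self) -> None:
        r = np.asarray(self.r)
        if r.shape != (self.ng, self.nr):
            raise ValueError(f"r must be {self.ng}x{self.nr}, got {r.shape}")
        object.__setattr__(self, "r", r.astype(np.int64))

    @property
    def total_runs(self) -> int:
        return int(self.r.sum())


@dataclass(frozen=True)
class FeatureVector:
    """The five per-ROI texture statistics with provenance.

    ``TI * LngREmph == Entropy`` and ``BI * LngREmph == DifEntrp`` hold by
    construction (TI/BI are derived from the direction-aggregated values).
    ``per_direction`` keeps the unaggregated values for inspection.
    """

    lngremph: float
    entropy: float
    difentrp: float
    ti: float
    bi: float
    source_id: str = ""
    lighting: Lighting = Lighting.POLARIZED
    group_label: GroupLabel = GroupLabel.UNKNOWN
    origin: tuple[int, int] = (0, 0)
    per_direction: dict = field(default_factory=dict, repr=False)


@dataclass(frozen=True)
class TextureConfig:
    """Feature-extraction settings.

    Attributes
    ----------
    distance
        Pixel displacement of the co-occurrence pairs (default 5).
    log_base
        ``None`` for natural log (default) or a numeric base (e.g. 10);
        a global scale factor on the two entropies and both indices.
    reducer
        How per-direction values are aggregated: ``"mean"`` (default),
        ``"min"`` or ``"max"``.
    """

    distance: int = 5
    log_base: float | None = None
    reducer: str = "mean"

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.reducer not in ("mean", "min", "max"):
            raise ValueError(f"unknown reducer {self.reducer!r}")

    @property
    def log_factor(self) -> float:
        return 1.0 if self.log_base is None else 1.0 / math.log(self.log_base)

    def reduce(self, values: list[float]) -> float:
        if self.reducer == "mean":
            return float(np.mean(values))
        return float(min(values) if self.reducer == "min" else max(values))


def compute_glcm(q: QuantizedROI, offset: tuple[int, int]) -> CooccurrenceMatrix:
    """Build the symmetric normalized co-occurrence matrix at ``offset``.

    Every in-bounds ordered pixel pair ``(x, x + offset)`` is counted in
    both orders, then counts are normalized to sum to 1.  By symmetry the
    result is identical for ``offset`` and ``-offset``.
    """
    dr, dc = int(offset[0]), int(offset[1])
    h, w = q.levels.shape
    if (dr, dc) == (0, 0):
        raise ValueError("offset must be nonzero")
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"offset {offset} leaves no valid pair in a {h}x{w} ROI")
    lv = q.levels
    # canonicalize to dr >= 0 (symmetric accumulation makes sign irrelevant)
    if dr < 0:
        dr, dc = -dr, -dc
    rows_a = slice(0, h - dr)
    rows_b = slice(dr, h)
    if dc >= 0:
        a = lv[rows_a, 0 : w - dc]
        b = lv[rows_b, dc:w]
    else:
        a = lv[rows_a, -dc:w]
        b = lv[rows_b, 0 : w + dc]
    if a.size == 0:
        raise ValueError(f"offset {offset} leaves no valid pair in a {h}x{w} ROI")
    ng = q.ng
    flat = (a.ravel() - 1) * ng + (b.ravel() - 1)
    counts = np.bincount(flat, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    counts = counts + counts.T  # both pair orders
    pair_count = int(2 * a.size)
    return CooccurrenceMatrix(counts / pair_count, offset=(int(offset[0]), int(offset[1])),
                              ng=ng, pair_count=pair_count)


def _check_normalized(m: CooccurrenceMatrix) -> None:
    total = float(m.p.sum())
    if m.pair_count <= 0 or abs(total - 1.0) > _NORM_TOL or np.any(m.p < 0):
        raise ValueError(f"co-occurrence matrix is not normalized (sum={total})")


def _shannon(p: np.ndarray, log_base: float | None) -> float:
    p = p[p > 0]
    h = float(-np.sum(p * np.log(p)))
    return h if log_base is None else h / math.log(log_base)


def glcm_entropy(m: CooccurrenceMatrix, log_base: float | None = None) -> float:
    """Entropy of the co-occurrence distribution; zero terms contribute 0."""
    _check_normalized(m)
    return _shannon(m.p, log_base)


def glcm_difference_entropy(m: CooccurrenceMatrix, log_base: float | None = None) -> float:
    """Entropy of the gray-level difference histogram induced by the GLCM."""
    _check_normalized(m)
    return _shannon(m.difference_histogram(), log_base)


_SENTINEL = 0  # levels are >= 1, so 0 terminates every line


def _lines_for_direction(levels: np.ndarray, direction: Direction) -> list[np.ndarray]:
    if direction == Direction.HORIZONTAL:
        return [levels]
    if direction == Direction.VERTICAL:
        return [levels.T]
    a = np.fliplr(levels) if direction == Direction.DIAG45 else levels
    h, w = a.shape
    return [a.diagonal(k) for k in range(-(h - 1), w)]


def compute_rlm(q: QuantizedROI, direction: Direction | str) -> RunLengthMatrix:
    """Decompose the ROI into maximal runs along ``direction``.

    Each scan line is split into maximal segments of constant level;
    ``r[i-1, k-1]`` counts runs of level ``i`` and length ``k``.  No length
    cap is applied: ``Nr`` equals the ROI side, so a fully uniform line is
    a single run (the melanoma dark-patch signal must not be truncated).
    """
    direction = Direction(direction)
    lv = q.levels
    nr = max(lv.shape)
    pieces: list[np.ndarray] = []
    for block in _lines_for_direction(lv, direction):
        if block.ndim == 2:
            # append a sentinel column so runs cannot cross row boundaries
            sep = np.full((block.shape[0], 1), _SENTINEL, dtype=block.dtype)
            pieces.append(np.hstack([block, sep]).ravel())
        else:
            pieces.append(block)
            pieces.append(np.array([_SENTINEL], dtype=block.dtype))
    seq = np.concatenate(pieces)
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [seq.size - 1]])
    values = seq[starts]
    lengths = ends - starts + 1
    keep = values != _SENTINEL
    values, lengths = values[keep], lengths[keep]
    flat = (values - 1) * nr + (lengths - 1)
    r = np.bincount(flat, minlength=q.ng * nr).reshape(q.ng, nr)
    return RunLengthMatrix(r, direction=direction, ng=q.ng, nr=nr)


def long_run_emphasis(rlm: RunLengthMatrix) -> float:
    """Second-moment-weighted mean run length; >= 1, equality iff all runs
    have length 1."""
    total = rlm.total_runs
    if total == 0:
        raise ValueError("run-length matrix has no runs")
    k = np.arange(1, rlm.nr + 1, dtype=np.float64)
    return float((k * k * rlm.r.sum(axis=0)).sum() / total)


def compute_indices(entropy: float, difentrp: float, lngremph: float) -> tuple[float, float]:
    """Texture index and bone index: the two entropies over long-run emphasis."""
    if lngremph <= 0:
        raise ValueError(f"LngREmph must be positive, got {lngremph}")
    return entropy / lngremph, difentrp / lngremph


def feature_vector(q: QuantizedROI, cfg: TextureConfig | None = None) -> FeatureVector:
    """Compute the five texture statistics of a quantized ROI.

    Entropy and DifEntrp are evaluated at the four distance-``d`` offsets,
    LngREmph along the four run directions; each is aggregated by the
    configured reducer, then TI and BI are derived from the aggregates.
    """
    cfg = cfg or TextureConfig()
    offsets = offsets_for_distance(cfg.distance)
    per_dir: dict[str, dict[str, float]] = {}
    ent, dif, lre = [], [], []
    for direction, offset in offsets.items():
        m = compute_glcm(q, offset)
        e = glcm_entropy(m, cfg.log_base)
        de = glcm_difference_entropy(m, cfg.log_base)
        lr = long_run_emphasis(compute_rlm(q, direction))
        per_dir[direction.value] = {"entropy": e, "difentrp": de, "lngremph": lr}
        ent.append(e)
        dif.append(de)
        lre.append(lr)
    entropy = cfg.reduce(ent)
    difentrp = cfg.reduce(dif)
    lngremph = cfg.reduce(lre)
    ti, bi = compute_indices(entropy, difentrp, lngremph)
    return FeatureVector(
        lngremph=lngremph,
        entropy=entropy,
        difentrp=difentrp,
        ti=ti,
        bi=bi,
        source_id=q.source_id,
        lighting=q.lighting,
        group_label=q.group_label,
        origin=q.origin,
        per_direction=per_dir,
    )
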