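"""Density profiles along the membrane normal and their statistics.

Every membrane metric in this package is defined on a binned number-density
profile n(z) of some particle selection, with z measured from the bilayer
midplane.  Profiles are computed per frame and then averaged, so that the
frame dimension is available for resampling: the bootstrap used for
intercept/peak uncertainties resamples frames with replacement, and the
block-average estimator for autocorrelated observables splits frames into
contiguous blocks.  All intervals are 95% two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import AnalysisError, InterceptError, NoDistinctPeakError, SelectionError

DEFAULT_BIN_WIDTH = 0.1  # nm; resolves ~0.3-0.5 nm head-group peaks
DEFAULT_N_BOOT = 100
DEFAULT_N_BLOCKS = 5
CONFIDENCE = 0.95


@dataclass
class IntervalEstimate:
    """A value with a 95% interval and the method that produced it.

    ``method`` is "bootstrap" (percentile over frame resamples), "block"
    (Student-t over contiguous block means) or "exact" (degenerate).  ``n``
    is the number of resamples or blocks.  The interval is widened, if
    necessary, to contain the point estimate (a percentile interval from a
    skewed resampling distribution can otherwise exclude it).
    """

    value: float
    lower: float
    upper: float
    method: str
    n: int

    def __post_init__(self):
        self.lower = min(float(self.lower), float(self.value))
        self.upper = max(float(self.upper), float(self.value))
        self.value = float(self.value)

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class DensityProfile:
    """Binned mean number density (particles/nm^3) along z.

    ``per_frame_density`` (frame x bin) is retained so downstream statistics
    can resample frames without touching raw coordinates again.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    selection_label: str
    n_frames: int
    per_frame_density: np.ndarray | None = None
    mean_area: float = float("nan")
    metadata: dict = field(default_factory=dict)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_tsv(self, path) -> None:
        """Two-column TSV (bin_center_nm, density_per_nm3)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# bin_center_nm\tdensity_per_nm3\n")
            for c, d in zip(self.centers, self.density):
                fh.write(f"{c:.6f}\t{d:.8g}\n")


def _selection_label(sel) -> str:
    if callable(sel):
        return getattr(sel, "__name__", "callable")
    return ",".join(f"{k}={v}" for k, v in sel.items())


def symmetric_edges(half_extent: float, bin_width: float) -> np.ndarray:
    """Bin edges of exactly ``bin_width`` covering [-H, H] with an edge at 0."""
    nb = int(math.ceil(half_extent / bin_width))
    return np.arange(-nb, nb + 1) * bin_width


def density_profile(ens, sel, bin_width: float = DEFAULT_BIN_WIDTH) -> DensityProfile:
    """Number-density profile of a selection along z, averaged over frames.

    The binned range symmetrically covers the tallest box in the ensemble.
    Densities are normalised per frame by the frame's lateral area times the
    bin width, so sum(density * bin_volume) equals the mean selection count
    per frame when the lateral area is constant.
    """
    if bin_width <= 0:
        raise AnalysisError("bin_width must be positive")
    sub = ens.select(sel)
    if len(sub) == 0:
        raise SelectionError(f"empty selection: {_selection_label(sel)}")
    edges = symmetric_edges(ens.boxes[:, 2].max() / 2.0, bin_width)
    nbins = len(edges) - 1
    frame_idx = sub["frame"].to_numpy()
    z = sub["z"].to_numpy(dtype=float)
    bins = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, nbins - 1)
    counts = np.zeros((ens.n_frames, nbins))
    np.add.at(counts, (frame_idx, bins), 1.0)
    areas = ens.boxes[:, 0] * ens.boxes[:, 1]
    per_frame = counts / (areas[:, None] * bin_width)
    return DensityProfile(
        bin_edges=edges,
        density=per_frame.mean(axis=0),
        selection_label=_selection_label(sel),
        n_frames=ens.n_frames,
        per_frame_density=per_frame,
        mean_area=float(areas.mean()),
    )


def folded_profile(ens, sel, bin_width: float = DEFAULT_BIN_WIDTH) -> DensityProfile:
    """Density profile of |z|: the two leaflets folded about the midplane.

    Metrics defined relative to a single leaflet's reference peak (e.g.
    insertion depths relative to the glycerol backbone) are computed on
    folded profiles and thereby averaged over leaflets.
    """
    if bin_width <= 0:
        raise AnalysisError("bin_width must be positive")
    sub = ens.select(sel)
    if len(sub) == 0:
        raise SelectionError(f"empty selection: {_selection_label(sel)}")
    half = ens.boxes[:, 2].max() / 2.0
    nbins = int(math.ceil(half / bin_width))
    edges = np.arange(nbins + 1) * bin_width
    frame_idx = sub["frame"].to_numpy()
    z = np.abs(sub["z"].to_numpy(dtype=float))
    bins = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, nbins - 1)
    counts = np.zeros((ens.n_frames, nbins))
    np.add.at(counts, (frame_idx, bins), 1.0)
    areas = ens.boxes[:, 0] * ens.boxes[:, 1]
    per_frame = counts / (2.0 * areas[:, None] * bin_width)
    return DensityProfile(
        bin_edges=edges,
        density=per_frame.mean(axis=0),
        selection_label="|z| " + _selection_label(sel),
        n_frames=ens.n_frames,
        per_frame_density=per_frame,
        mean_area=float(areas.mean()),
        metadata={"folded": True},
    )


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


def _refine_peak(centers: np.ndarray, density: np.ndarray) -> float:
    """Peak z via argmax plus a 3-point parabolic vertex refinement."""
    i = int(np.argmax(density))
    if i == 0 or i == len(density) - 1:
        return float(centers[i])
    y0, y1, y2 = density[i - 1], density[i], density[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the bin centre
        return float(centers[i])
    offset = 0.5 * (y0 - y2) / denom
    offset = float(np.clip(offset, -0.5, 0.5))
    return float(centers[i] + offset * (centers[1] - centers[0]))


def _search_mask(centers: np.ndarray, search) -> np.ndarray:
    lo, hi = search
    mask = (centers >= lo) & (centers <= hi)
    if mask.sum() < 3:
        raise AnalysisError("search interval must overlap at least 3 bins")
    return mask


def peak_z(profile: DensityProfile, search) -> float:
    """Point estimate of the peak location; raises on flat profiles."""
    mask = _search_mask(profile.centers, search)
    dens = profile.density[mask]
    top = dens.max()
    if top <= 0:
        raise NoDistinctPeakError("no distinct peak: profile empty in region")
    near_top = dens >= top * (1.0 - 1e-9)
    if near_top.sum() > len(dens) / 2:
        raise NoDistinctPeakError("no distinct peak: profile flat in search region")
    return _refine_peak(profile.centers[mask], dens)


def peak_location(
    profile: DensityProfile,
    search,
    n_boot: int = DEFAULT_N_BOOT,
    seed=None,
    rng=None,
) -> IntervalEstimate:
    """Peak z with a percentile bootstrap interval over frame resamples."""
    value = peak_z(profile, search)
    if profile.per_frame_density is None:
        return IntervalEstimate(value, value, value, "exact", 0)
    rng = _rng(seed, rng)
    mask = _search_mask(profile.centers, search)
    centers = profile.centers[mask]
    per_frame = profile.per_frame_density[:, mask]
    nf = per_frame.shape[0]
    draws = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, nf, size=nf)
        draws[b] = _refine_peak(centers, per_frame[idx].mean(axis=0))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return IntervalEstimate(value, lo, hi, "bootstrap", n_boot)


# ---------------------------------------------------------------------------
# Intercepts
# ---------------------------------------------------------------------------


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-bin moving average with edge replication.

    Used only while bracketing profile crossings, to suppress single-bin
    noise crossings; reported profiles are never smoothed.
    """
    padded = np.r_[y[0], y, y[-1]]
    return np.convolve(padded, np.full(3, 1.0 / 3.0), mode="valid")


def _single_crossing(centers: np.ndarray, diff: np.ndarray, search) -> float:
    """z where the (smoothed) difference changes sign exactly once."""
    mask = _search_mask(centers, search)
    c = centers[mask]
    d = _smooth3(diff)[mask]
    sign = np.sign(d)
    # treat exact zeros as belonging to the previous sign
    for i in range(len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1] if i else 1.0
    change = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(change) == 0:
        raise InterceptError("profiles do not cross in region", candidates=())
    if len(change) > 1:
        zs = [
            float(c[i] + (c[i + 1] - c[i]) * d[i] / (d[i] - d[i + 1])) for i in change
        ]
        raise InterceptError(
            f"multiple profile crossings in region at z = "
            f"{', '.join(f'{z:.3f}' for z in zs)}",
            candidates=zs,
        )
    i = int(change[0])
    return float(c[i] + (c[i + 1] - c[i]) * d[i] / (d[i] - d[i + 1]))


def profile_intercept(
    a: DensityProfile,
    b: DensityProfile,
    search,
    n_boot: int = DEFAULT_N_BOOT,
    seed=None,
    rng=None,
) -> IntervalEstimate:
    """z where two profiles cross, with a frame-bootstrap interval.

    The two profiles must share bin edges and come from the same frames (they
    are resampled jointly).  Crossing bracketing uses a light 3-bin moving
    average; the crossing itself is linear interpolation between bin centres,
    so piecewise-linear profiles are resolved exactly.
    """
    if a.bin_edges.shape != b.bin_edges.shape or not np.allclose(
        a.bin_edges, b.bin_edges
    ):
        raise AnalysisError("profiles must share bin edges")
    value = _single_crossing(a.centers, a.density - b.density, search)
    if a.per_frame_density is None or b.per_frame_density is None:
        return IntervalEstimate(value, value, value, "exact", 0)
    if a.per_frame_density.shape[0] != b.per_frame_density.shape[0]:
        raise AnalysisError("profiles must cover the same frames")
    rng = _rng(seed, rng)
    nf = a.per_frame_density.shape[0]
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, nf, size=nf)
        d = a.per_frame_density[idx].mean(axis=0) - b.per_frame_density[idx].mean(
            axis=0
        )
        try:
            draws.append(_single_crossing(a.centers, d, search))
        except InterceptError:
            continue
    if len(draws) < 2:
        return IntervalEstimate(value, value, value, "bootstrap", n_boot)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return IntervalEstimate(value, lo, hi, "bootstrap", n_boot)


# ---------------------------------------------------------------------------
# Generic uncertainty machinery
# ---------------------------------------------------------------------------


def _rng(seed, rng):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def bootstrap_scalar(
    ens,
    functional,
    n_boot: int = DEFAULT_N_BOOT,
    seed=None,
    rng=None,
) -> IntervalEstimate:
    """Percentile bootstrap of an ensemble->scalar functional over frames.

    Frames are resampled with replacement (resample size = n_frames); the
    interval is the 2.5/97.5 percentile of the functional over ``n_boot``
    resamples, and the value is the functional on the full ensemble.
    Deterministic given ``seed``.
    """
    if n_boot < 2:
        raise AnalysisError("n_boot must be at least 2")
    rng = _rng(seed, rng)
    value = float(functional(ens))
    nf = ens.n_frames
    draws = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, nf, size=nf)
        draws[b] = functional(ens.resample_frames(idx))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return IntervalEstimate(value, lo, hi, "bootstrap", n_boot)


def bootstrap_series(
    series,
    func=np.mean,
    n_boot: int = DEFAULT_N_BOOT,
    seed=None,
    rng=None,
) -> IntervalEstimate:
    """Percentile bootstrap of a statistic of a per-frame scalar series."""
    if n_boot < 2:
        raise AnalysisError("n_boot must be at least 2")
    x = np.asarray(series, dtype=float)
    rng = _rng(seed, rng)
    value = float(func(x))
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    draws = np.array([func(x[row]) for row in idx])
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return IntervalEstimate(value, lo, hi, "bootstrap", n_boot)


def block_slices(n: int, n_blocks: int) -> list[slice]:
    """Contiguous equal blocks; remainder frames appended to the last block."""
    size = n // n_blocks
    out = []
    for b in range(n_blocks):
        start = b * size
        stop = (b + 1) * size if b < n_blocks - 1 else n
        out.append(slice(start, stop))
    return out


def block_average(series, n_blocks: int = DEFAULT_N_BLOCKS) -> IntervalEstimate:
    """Block-averaging interval for a (possibly autocorrelated) series.

    The value is the grand mean; the interval is mean +/- t(0.975, B-1) *
    sd(block means)/sqrt(B) with B contiguous blocks.  Block averaging
    inflates the interval relative to the naive i.i.d. standard error when
    the series is positively autocorrelated on sub-block time scales.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2 * n_blocks:
        raise AnalysisError(
            f"series of length {len(x)} too short for {n_blocks} blocks"
        )
    means = np.array([x[s].mean() for s in block_slices(len(x), n_blocks)])
    value = float(x.mean())
    half = (
        stats.t.ppf(0.5 + CONFIDENCE / 2, n_blocks - 1)
        * means.std(ddof=1)
        / math.sqrt(n_blocks)
    )
    return IntervalEstimate(value, value - half, value + half, "block", n_blocks)


def t_interval_from_blocks(value: float, block_values) -> IntervalEstimate:
    """Student-t interval around ``value`` from per-block re-estimates.

    Used by metrics (thickness, order parameters) whose point estimate is a
    nonlinear function of the whole ensemble: the metric is re-evaluated on
    each contiguous block and the spread of the block values sets the width.
    """
    bv = np.asarray(block_values, dtype=float)
    n = len(bv)
    if n < 2:
        return IntervalEstimate(value, value, value, "block", n)
    half = stats.t.ppf(0.5 + CONFIDENCE / 2, n - 1) * bv.std(ddof=1) / math.sqrt(n)
    return IntervalEstimate(value, value - half, value + half, "block", n)
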