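"""Statistics for single-cell filament fluorescence traces.

Implements the analysis battery applied to cells-by-time fluorescence
matrices from filamentous cyanobacteria: the synchronization index R (the
variance of the cross-cell mean over the mean per-cell variance), the spatial
autocorrelation of a filament snapshot, the coefficient-of-variation time
course, a binomial-partitioning division null, division-phase histograms,
cell-averaged power spectra, complex coherence versus cell distance, and a
position-reshuffling control.  Population (divisor N) variance conventions
are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .stochastic import SpectrumResult
from .filament import CoherenceResult

__all__ = [
    "FilamentTraces", "SyncResult", "AutocorrResult", "DivisionPhaseHistogram",
    "sync_index", "spatial_autocorr", "average_autocorr", "cv2_series",
    "binomial_partition_null", "detect_minima", "division_phase_histogram",
    "avg_power_spectrum", "coherence_estimate", "reshuffle_control",
]


@dataclass
class FilamentTraces:
    """Fluorescence matrix (cells x timepoints) with positions and lineage.

    values may contain NaN for cells that left the field of view; statistics
    operate on complete-case windows.  lineage, when present, is a DataFrame
    with columns (cell_id, parent_id, division_time_hr).
    """

    values: np.ndarray
    time_hr: np.ndarray
    positions: np.ndarray | None = None
    cell_ids: np.ndarray | None = None
    filament_id: str = "f0"
    lineage: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time_hr = np.asarray(self.time_hr, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x time)")
        if self.values.shape[1] != self.time_hr.size:
            raise ValueError("time grid does not match values")
        if np.any(np.diff(self.time_hr) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.nanmin(self.values) < 0:
            raise ValueError("fluorescence must be non-negative")
        if self.positions is None:
            self.positions = np.arange(self.values.shape[0])
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.values.shape[0])

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def window(self, t0: float, t1: float) -> "FilamentTraces":
        keep = (self.time_hr >= t0) & (self.time_hr <= t1)
        return FilamentTraces(values=self.values[:, keep],
                              time_hr=self.time_hr[keep],
                              positions=self.positions, cell_ids=self.cell_ids,
                              filament_id=self.filament_id, lineage=self.lineage)

    def in_position_order(self) -> "FilamentTraces":
        order = np.argsort(self.positions)
        return FilamentTraces(values=self.values[order],
                              time_hr=self.time_hr,
                              positions=self.positions[order],
                              cell_ids=self.cell_ids[order],
                              filament_id=self.filament_id, lineage=self.lineage)


@dataclass(frozen=True)
class SyncResult:
    R: float
    n_cells: int
    window_hr: tuple[float, float]
    mode: str


@dataclass(frozen=True)
class AutocorrResult:
    lags: np.ndarray
    g: np.ndarray
    n_averaged: int = 1


@dataclass(frozen=True)
class DivisionPhaseHistogram:
    bin_edges: np.ndarray       # on [0, 2*pi]
    counts: np.ndarray
    n_divisions: int
    n_excluded: int


def _pvar(x, axis=None):
    """Population variance (divisor N)."""
    return np.var(x, axis=axis, ddof=0)


# ---------------------------------------------------------------------------
# synchronization index

def sync_index(traces: FilamentTraces | np.ndarray, *,
               cells: np.ndarray | None = None,
               window_hr: tuple[float, float] | None = None,
               mode: str = "contiguous",
               sqrt: bool = False) -> SyncResult:
    """Synchronization index R = Var_t(mu(t)) / mean_i Var_t(f_i(t)).

    mu(t) is the across-cell mean at each time.  R = 1 for identical
    non-constant traces and ~1/N for N independent cells of equal variance.
    ``sqrt=True`` returns the standard-deviation-ratio variant instead of
    the variance ratio.  The caller is responsible for choosing a window
    spanning a full oscillation; ``window_hr`` restricts the time range.
    """
    if isinstance(traces, FilamentTraces):
        tr = traces if window_hr is None else traces.window(*window_hr)
        f = tr.values
        t0, t1 = tr.time_hr[0], tr.time_hr[-1]
    else:
        f = np.asarray(traces, dtype=float)
        t0, t1 = 0.0, float(f.shape[1] - 1)
        if window_hr is not None:
            raise ValueError("window_hr requires a FilamentTraces input")
    if cells is not None:
        f = f[np.asarray(cells)]
    ok = ~np.any(np.isnan(f), axis=0)
    f = f[:, ok]
    if f.shape[0] < 2:
        raise ValueError("sync_index requires at least 2 cells")
    per_cell = _pvar(f, axis=1)
    denom = per_cell.mean()
    if denom == 0:
        raise ValueError("all traces constant: R undefined (0/0)")
    R = _pvar(f.mean(axis=0)) / denom
    if sqrt:
        R = float(np.sqrt(R))
    return SyncResult(R=float(R), n_cells=f.shape[0],
                      window_hr=(float(t0), float(t1)), mode=mode)


def select_cells(n_cells: int, mode: str, rng: np.random.Generator, *,
                 group_size: int = 9, spacing: int = 10) -> np.ndarray:
    """Cell-selection protocols for R: 'contiguous' picks a random run of
    ``group_size`` cells; 'separated' picks cells ``spacing+1`` apart."""
    if mode == "contiguous":
        k = min(group_size, n_cells)
        start = rng.integers(0, n_cells - k + 1)
        return np.arange(start, start + k)
    if mode == "separated":
        start = rng.integers(0, min(spacing + 1, n_cells))
        return np.arange(start, n_cells, spacing + 1)
    raise ValueError(f"unknown selection mode {mode!r}")


def sync_index_across_filaments(filaments: list[FilamentTraces], seed: int, *,
                                n_repeats: int = 3,
                                window_hr: tuple[float, float] | None = None) -> SyncResult:
    """One random cell per filament, repeated and averaged (inter-filament R)."""
    rng = np.random.default_rng(seed)
    Rs = []
    for _ in range(n_repeats):
        rows = []
        for tr in filaments:
            trw = tr if window_hr is None else tr.window(*window_hr)
            rows.append(trw.values[rng.integers(0, trw.n_cells)])
        Rs.append(sync_index(np.array(rows), mode="across_filaments").R)
    t0, t1 = window_hr if window_hr is not None else (filaments[0].time_hr[0],
                                                      filaments[0].time_hr[-1])
    return SyncResult(R=float(np.mean(Rs)), n_cells=len(filaments),
                      window_hr=(float(t0), float(t1)), mode="across_filaments")


# ---------------------------------------------------------------------------
# spatial autocorrelation

def spatial_autocorr(snapshot: np.ndarray, max_lag: int = 30) -> AutocorrResult:
    """Spatial autocorrelation g_k = c_k / c_0 of a per-cell snapshot,
    with c_k = (1/N) sum_{i=1}^{N-k} (f_i - fbar)(f_{i+k} - fbar).

    The divisor is N at every lag and fbar is the overall mean, so g_0 = 1
    exactly and |g_k| <= 1.
    """
    f = np.asarray(snapshot, dtype=float)
    N = f.size
    if N <= max_lag:
        raise ValueError(f"need more than max_lag={max_lag} cells, got {N}")
    fbar = f.mean()
    d = f - fbar
    c0 = np.dot(d, d) / N
    if c0 == 0:
        raise ValueError("zero-variance snapshot")
    g = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        g[k] = np.dot(d[: N - k], d[k:]) / N / c0
    return AutocorrResult(lags=np.arange(max_lag + 1), g=g)


def average_autocorr(results: list[AutocorrResult]) -> AutocorrResult:
    g = np.mean([r.g for r in results], axis=0)
    return AutocorrResult(lags=results[0].lags, g=g,
                          n_averaged=sum(r.n_averaged for r in results))


def fit_correlation_length(res: AutocorrResult, max_fit_lag: int = 8) -> float:
    """Least-squares exponential decay length (cells) of g_k over small lags."""
    k = res.lags[1:max_fit_lag + 1]
    g = res.g[1:max_fit_lag + 1]
    pos = g > 0.02
    if pos.sum() < 2:
        return 0.0
    slope = np.polyfit(k[pos], np.log(g[pos]), 1)[0]
    return float(-1.0 / slope) if slope < 0 else np.inf


# ---------------------------------------------------------------------------
# coefficient of variation

def cv2_series(traces: FilamentTraces | np.ndarray) -> np.ndarray:
    """CV^2(t) = across-cell variance / squared mean, population convention.

    Time points with zero mean are returned as NaN (flagged, not fatal).
    """
    f = traces.values if isinstance(traces, FilamentTraces) else np.asarray(traces, float)
    mu = f.mean(axis=0)
    var = _pvar(f, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(mu > 0, var / mu ** 2, np.nan)
    return out


# ---------------------------------------------------------------------------
# binomial partitioning null

def binomial_partition_null(snapshot: np.ndarray, generations: int = 3,
                            seed: int = 0, *, quantum: float = 1.0,
                            max_lag: int = 30):
    """Division-inheritance null for the spatial autocorrelation.

    For each of ``generations`` rounds the cell order is reshuffled and every
    cell of value n is replaced by two adjacent daughters Binomial(n, 1/2)
    and n - Binomial(n, 1/2), multiplied by two to conserve the mean.  The
    per-round reshuffle disperses sibling blocks, so inheritance alone leaves
    correlation only between immediate sisters — the null decorrelates by
    the second neighbour.  Returns (simulated filament values, its
    AutocorrResult).  Values are converted to integer molecule counts via
    ``quantum``.
    """
    x = np.asarray(snapshot, dtype=float)
    if np.any(x < 0):
        raise ValueError("snapshot values must be non-negative")
    rng = np.random.default_rng(seed)
    counts = np.round(x / quantum).astype(np.int64)
    counts = counts[rng.permutation(counts.size)]
    for _ in range(generations):
        counts = counts[rng.permutation(counts.size)]
        left = rng.binomial(counts, 0.5)
        right = counts - left
        counts = np.empty(2 * counts.size, dtype=np.int64)
        counts[0::2] = 2 * left
        counts[1::2] = 2 * right
    values = counts.astype(float) * quantum
    return values, spatial_autocorr(values, max_lag=min(max_lag, values.size - 1))


# ---------------------------------------------------------------------------
# division phases

def detect_minima(mu: np.ndarray, time_hr: np.ndarray, *,
                  smooth_hr: float = 5.0, min_separation_hr: float = 12.0) -> np.ndarray:
    """Times of local minima of the mean trace, after a centred moving
    average of width ``smooth_hr``, with a minimum peak separation."""
    dt = float(np.median(np.diff(time_hr)))
    w = max(1, int(round(smooth_hr / dt)))
    kernel = np.ones(w) / w
    sm = np.convolve(mu, kernel, mode="same")
    dist = max(1, int(round(min_separation_hr / dt)))
    idx, _ = signal.find_peaks(-sm, distance=dist)
    return time_hr[idx]


def division_phase_histogram(division_times_hr: np.ndarray,
                             minima_times_hr: np.ndarray,
                             n_bins: int = 12) -> DivisionPhaseHistogram:
    """Phase of division events along the circadian cycle.

    Phase 0 and 2*pi are two consecutive minima of the (mean) oscillation; a
    division at time t in cycle [t_k, t_{k+1}) gets phase
    2*pi*(t - t_k)/(t_{k+1} - t_k).  Divisions outside any complete cycle are
    excluded and counted.
    """
    m = np.sort(np.asarray(minima_times_hr, dtype=float))
    if m.size < 2:
        raise ValueError("need at least two detected minima")
    phases = []
    excluded = 0
    for t in np.asarray(division_times_hr, dtype=float):
        k = np.searchsorted(m, t, side="right") - 1
        if k < 0 or k >= m.size - 1:
            excluded += 1
            continue
        phases.append(2.0 * np.pi * (t - m[k]) / (m[k + 1] - m[k]))
    edges = np.linspace(0.0, 2.0 * np.pi, n_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    return DivisionPhaseHistogram(bin_edges=edges, counts=counts,
                                  n_divisions=len(phases), n_excluded=excluded)


# ---------------------------------------------------------------------------
# spectra and coherence

def avg_power_spectrum(traces: FilamentTraces, *, discard_initial_hr: float = 24.0,
                       detrend: str = "mean",
                       min_duration_hr: float = 96.0) -> SpectrumResult:
    """Per-cell periodogram averaged across all cells of a filament."""
    tr = traces.window(discard_initial_hr, np.inf)
    t = tr.time_hr
    if t[-1] - t[0] < min_duration_hr:
        raise ValueError("traces too short after discard")
    dt = float(np.median(np.diff(t)))
    det = "constant" if detrend == "mean" else "linear"
    psds = []
    for row in tr.values:
        if np.any(np.isnan(row)):
            continue
        f, p = signal.periodogram(row, fs=1.0 / dt, detrend=det, window="boxcar")
        psds.append(p)
    keep = f > 0
    return SpectrumResult(freq_per_hr=f[keep],
                          psd=np.mean(psds, axis=0)[keep],
                          provenance="periodogram", n_averaged=len(psds),
                          units="a.u.^2 hr")


def coherence_estimate(traces: FilamentTraces, frequency_per_hr: float | None = None,
                       *, segment_cells: int = 35, d_max: int = 10,
                       discard_initial_hr: float = 24.0,
                       detrend: str = "mean") -> CoherenceResult:
    """Complex coherence versus cell distance at a stated frequency.

    Within each non-overlapping segment of ``segment_cells`` cells (in
    position order), the cross-periodogram F_i(w) conj(F_{i+d}(w)) is averaged
    over all cell pairs at distance d and normalized by the averaged
    auto-periodogram, so coherence(0) = 1 exactly.  If ``frequency_per_hr``
    is None the peak of the cell-averaged spectrum is used; otherwise the
    nearest frequency bin is taken.
    """
    tr = traces.in_position_order().window(discard_initial_hr, np.inf)
    f = tr.values
    n_cells, nt = f.shape
    if n_cells < segment_cells:
        raise ValueError(f"need at least segment_cells={segment_cells} cells")
    dt = float(np.median(np.diff(tr.time_hr)))
    if detrend == "mean":
        f = f - f.mean(axis=1, keepdims=True)
    else:
        f = signal.detrend(f, axis=1, type="linear")
    F = np.fft.rfft(f, axis=1)
    freqs = np.fft.rfftfreq(nt, d=dt)
    if frequency_per_hr is None:
        power = np.mean(np.abs(F) ** 2, axis=0)
        power[0] = 0.0
        k = int(np.argmax(power))
    else:
        k = int(np.argmin(np.abs(freqs - frequency_per_hr)))
    Fk = F[:, k]
    num = np.zeros(d_max + 1, dtype=complex)
    den = 0.0
    n_pairs = np.zeros(d_max + 1)
    n_segments = n_cells // segment_cells
    for s in range(n_segments):
        seg = Fk[s * segment_cells:(s + 1) * segment_cells]
        den += np.sum(np.abs(seg) ** 2)
        for d in range(d_max + 1):
            if d >= segment_cells:
                continue
            prods = seg[: segment_cells - d] * np.conj(seg[d:])
            num[d] += prods.sum()
            n_pairs[d] += prods.size
    den /= n_segments * segment_cells
    vals = (num / np.maximum(n_pairs, 1)) / den
    vals[0] = 1.0 + 0j   # exact by self-normalization
    return CoherenceResult(distances=np.arange(d_max + 1), values=vals,
                           freq_per_hr=float(freqs[k]), provenance="estimated",
                           n_averaged=n_segments)


def reshuffle_control(traces: FilamentTraces, seed: int) -> FilamentTraces:
    """Randomly permute cell positions, preserving each trace — the control
    that flattens genuinely spatial structure (autocorrelation, coherence)
    while leaving position-blind statistics (R, CV^2, spectra) unchanged."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(traces.n_cells)
    return FilamentTraces(values=traces.values[perm], time_hr=traces.time_hr,
                          positions=np.arange(traces.n_cells),
                          cell_ids=traces.cell_ids[perm],
                          filament_id=traces.filament_id, lineage=traces.lineage)
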