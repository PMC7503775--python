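"""Chromatographic preprocessing chain for UPLC-PDA profiles.

The stages, in order, are:

1. normalization of every trace by its sample mass,
2. baseline removal by numerical differentiation (a baseline that is
   locally linear contributes only a constant to the derivative, so it
   never has to be estimated explicitly),
3. retention-time alignment by correlation optimized warping (COW)
   against a reference trace, with the Pearson correlation as the
   segment similarity measure,
4. peak detection on the profile of the second derivative smoothed by a
   cubic regression spline, keeping maximal concave (negative second
   derivative) runs and discarding length-1 or low-intensity ones,
5. construction of common peaks across chromatograms by interval
   addition (union of overlapping intervals) with a minimum-support
   threshold ``c1``,
6. integration of the rectified differentiated signal per common peak,
7. merging of the two detection wavelengths into a single metabolite
   table, summing peak pairs that carry the same metabolite name.

All interval indices are half-open and 0-based on the aligned grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline

from .containers import Chromatogram, ChromatogramSet, CommonPeak, PeakInterval

__all__ = [
    "normalize_by_mass",
    "remove_baseline_by_differentiation",
    "cow_align",
    "CowResult",
    "smooth_second_derivative",
    "detect_peaks",
    "build_common_peaks",
    "integrate_peaks",
    "match_peaks_by_rt",
    "merge_wavelengths",
    "run_preprocessing",
    "PreprocessResult",
]

logger = logging.getLogger(__name__)


def normalize_by_mass(chrom: Chromatogram) -> Chromatogram:
    """Divide every intensity by the extracted sample mass (mg)."""
    if not (chrom.sample_mass > 0):
        raise ValueError("sample_mass must be positive")
    return chrom.with_intensity(chrom.intensity / chrom.sample_mass)


def remove_baseline_by_differentiation(chrom: Chromatogram | np.ndarray) -> np.ndarray:
    """First finite-difference derivative of intensity w.r.t. grid index.

    Central differences in the interior, one-sided at the ends.  A
    constant baseline maps to zero and a linear one to a constant, so
    the slowly varying baseline never needs explicit estimation.
    """
    y = chrom.intensity if isinstance(chrom, Chromatogram) else np.asarray(chrom, float)
    if y.size < 3:
        raise ValueError("need at least 3 grid points to differentiate")
    return np.gradient(y)


# ---------------------------------------------------------------------------
# correlation optimized warping


@dataclass
class CowResult:
    """Outcome of a COW alignment of one signal to a reference."""

    warped: np.ndarray
    ref_nodes: np.ndarray  # segment boundary indices on the reference grid
    signal_nodes: np.ndarray  # matched (possibly shifted) indices on the signal
    score: float  # sum of per-segment Pearson correlations

    @property
    def shifts(self) -> np.ndarray:
        return self.signal_nodes - self.ref_nodes

    def warp_path(self) -> list[tuple[int, float]]:
        return list(zip(self.ref_nodes.tolist(), self.signal_nodes.tolist()))


def _segment_correlations(
    signal: np.ndarray,
    ref_seg: np.ndarray,
    x_prev: np.ndarray,
    x_cur: np.ndarray,
) -> np.ndarray:
    """Pearson correlation of ref_seg with the signal stretch
    [x_prev, x_cur] resampled to len(ref_seg) points, for every
    (prev, cur) node pair.  Degenerate (constant) stretches score 0.
    """
    m1 = ref_seg.size
    frac = np.linspace(0.0, 1.0, m1)
    pos = x_prev[:, None, None] + (
        x_cur[None, :, None] - x_prev[:, None, None]
    ) * frac[None, None, :]
    vals = np.interp(pos.ravel(), np.arange(signal.size), signal).reshape(pos.shape)
    vc = vals - vals.mean(axis=2, keepdims=True)
    rc = ref_seg - ref_seg.mean()
    rnorm = np.sqrt(np.sum(rc * rc))
    vnorm = np.sqrt(np.sum(vc * vc, axis=2))
    denom = vnorm * rnorm
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, np.einsum("pqm,m->pq", vc, rc) / np.where(denom > 0, denom, 1.0), 0.0)
    return corr


def cow_align(
    signal: np.ndarray,
    reference: np.ndarray,
    segment_len: int,
    slack: int,
) -> CowResult:
    """Align ``signal`` to ``reference`` by correlation optimized warping.

    The reference is split into segments of roughly ``segment_len``
    points; each interior segment boundary of the signal may shift by at
    most ``slack`` points.  A dynamic program finds the monotone,
    endpoint-fixing piecewise-linear warp maximizing the sum of
    per-segment Pearson correlations; the warped signal is produced by
    linear interpolation.  The optimum is exact over this warp class.
    """
    signal = np.asarray(signal, dtype=float)
    reference = np.asarray(reference, dtype=float)
    n = signal.size
    if reference.size != n:
        raise ValueError("signal and reference must have the same length")
    if not (2 <= segment_len < n):
        raise ValueError(f"segment_len must be in [2, {n}), got {segment_len}")
    if not (0 <= slack < segment_len):
        raise ValueError(f"slack must be in [0, segment_len), got {slack}")

    n_seg = max(1, int(round((n - 1) / segment_len)))
    bounds = np.round(np.linspace(0, n - 1, n_seg + 1)).astype(int)

    # candidate shifts ordered by |u| so argmax tie-breaks toward the
    # smallest displacement (identity warp wins when scores tie)
    u_all = np.array(sorted(range(-slack, slack + 1), key=lambda u: (abs(u), u)))

    def node_candidates(i: int) -> np.ndarray:
        if i == 0 or i == n_seg:
            return np.array([bounds[i]])
        x = bounds[i] + u_all
        return x[(x >= 1) & (x <= n - 2)]

    prev_x = node_candidates(0)
    prev_score = np.zeros(prev_x.size)
    back: list[np.ndarray] = []
    xs: list[np.ndarray] = [prev_x]
    for i in range(1, n_seg + 1):
        cur_x = node_candidates(i)
        ref_seg = reference[bounds[i - 1] : bounds[i] + 1]
        corr = _segment_correlations(signal, ref_seg, prev_x, cur_x)
        total = prev_score[:, None] + corr
        valid = (cur_x[None, :] - prev_x[:, None]) >= 1  # monotone
        total = np.where(valid, total, -np.inf)
        choice = np.argmax(total, axis=0)
        prev_score = total[choice, np.arange(cur_x.size)]
        back.append(choice)
        prev_x = cur_x
        xs.append(cur_x)

    # backtrack from the fixed right endpoint
    idx = int(np.argmax(prev_score))
    score = float(prev_score[idx])
    nodes = [int(xs[-1][idx])]
    for i in range(n_seg - 1, -1, -1):
        idx = int(back[i][idx])
        nodes.append(int(xs[i][idx]))
    nodes.reverse()
    signal_nodes = np.array(nodes)

    # piecewise-linear resampling of the signal onto the reference grid
    pos = np.empty(n)
    for i in range(n_seg):
        b0, b1 = bounds[i], bounds[i + 1]
        t = np.arange(b0, b1 + 1)
        pos[b0 : b1 + 1] = signal_nodes[i] + (
            (signal_nodes[i + 1] - signal_nodes[i]) * (t - b0) / (b1 - b0)
        )
    warped = np.interp(pos, np.arange(n), signal)
    return CowResult(warped=warped, ref_nodes=bounds, signal_nodes=signal_nodes, score=score)


# ---------------------------------------------------------------------------
# peak detection


def smooth_second_derivative(
    signal: np.ndarray, n_knots: int = 520
) -> np.ndarray:
    """Smoothed second derivative of the original trace.

    ``signal`` is the already-differentiated (first-derivative) trace; a
    cubic spline with ``n_knots`` uniformly spaced knots is fitted by
    least squares and its analytic first derivative evaluated on the
    grid — i.e. the second derivative of the underlying chromatogram,
    smoothed.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n_knots < 4:
        raise ValueError("need at least 4 knots")
    if n_knots >= n:
        raise ValueError(f"n_knots ({n_knots}) must be < signal length ({n})")
    x = np.arange(n, dtype=float)
    knots = np.linspace(0.0, n - 1.0, n_knots)
    spline = LSQUnivariateSpline(x, signal, knots[1:-1], k=3)
    return spline.derivative()(x)


def detect_peaks(
    d2_profile: np.ndarray,
    signal: np.ndarray,
    intensity_tolerance: float = 0.0005,
) -> list[PeakInterval]:
    """Peak intervals from a smoothed second-derivative profile.

    Candidate peaks are maximal runs where the profile is negative
    (concave regions of the original trace).  Runs of length 1 are
    discarded, as are runs whose maximum absolute differentiated-signal
    value stays below ``intensity_tolerance``.  The apex is placed at
    the most concave point.
    """
    d2 = np.asarray(d2_profile, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if d2.shape != signal.shape:
        raise ValueError("profile and signal must have the same length")
    if not np.all(np.isfinite(d2)):
        raise ValueError("non-finite second-derivative profile")
    neg = d2 < 0
    # run boundaries of the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([False], neg, [False])).astype(int)))
    starts, ends = edges[0::2], edges[1::2]
    peaks = []
    for s, e in zip(starts, ends):
        if e - s < 2:  # length-1 peaks are artifacts
            continue
        if np.max(np.abs(signal[s:e])) < intensity_tolerance:
            continue
        apex = s + int(np.argmin(d2[s:e]))
        peaks.append(PeakInterval(int(s), int(e), apex))
    return peaks


# ---------------------------------------------------------------------------
# common peaks


def build_common_peaks(
    per_sample_intervals: dict[str, list[PeakInterval]],
    c1: int,
) -> list[CommonPeak]:
    """Merge individual peak intervals across samples into common peaks.

    Overlapping intervals are united (transitive closure of overlap,
    "interval addition"); each merged interval's support is the number
    of distinct samples contributing, and merged intervals supported by
    fewer than ``c1`` chromatograms are dropped.
    """
    if c1 < 1:
        raise ValueError("c1 must be >= 1")
    n_samples = len(per_sample_intervals)
    if c1 > n_samples:
        warnings.warn(
            f"c1={c1} exceeds the number of samples ({n_samples}); "
            "no common peak can qualify",
            stacklevel=2,
        )
    entries = sorted(
        (iv.start_idx, iv.end_idx, iv.apex_idx, sid)
        for sid, ivs in per_sample_intervals.items()
        for iv in ivs
    )
    merged: list[CommonPeak] = []
    cur: list[tuple[int, int, int, str]] = []
    cur_end = -1

    def flush() -> None:
        if not cur:
            return
        start = cur[0][0]
        end = max(e for _s, e, _a, _sid in cur)
        support = len({sid for _s, _e, _a, sid in cur})
        apex = int(np.median([a for _s, _e, a, _sid in cur]))
        if support >= c1:
            merged.append(
                CommonPeak(PeakInterval(start, end, apex), support=support)
            )

    for s, e, a, sid in entries:
        if cur and s < cur_end:  # overlap (half-open intervals)
            cur.append((s, e, a, sid))
            cur_end = max(cur_end, e)
        else:
            flush()
            cur = [(s, e, a, sid)]
            cur_end = e
    flush()
    return [
        CommonPeak(cp.interval, cp.support, peak_id=f"P{i + 1:03d}")
        for i, cp in enumerate(merged)
    ]


def integrate_peaks(
    signals: dict[str, np.ndarray],
    common_peaks: list[CommonPeak],
    dx: float = 1.0,
) -> pd.DataFrame:
    """Integrate the rectified differentiated signal per sample per peak.

    The value is the trapezoidal integral of ``max(signal, 0)`` over the
    peak interval with spacing ``dx``.  With ``dx=1`` (index spacing)
    and a derivative-per-index signal, the value of a clean peak equals
    its height (the cumulative rise from baseline to apex), which is
    monotone in true peak area for a fixed peak shape.
    """
    out = {}
    for sid, sig in signals.items():
        sig = np.asarray(sig, dtype=float)
        row = {}
        for cp in common_peaks:
            iv = cp.interval
            if iv.start_idx < 0 or iv.end_idx > sig.size:
                raise IndexError(
                    f"peak {cp.peak_id} interval [{iv.start_idx}, {iv.end_idx}) "
                    f"outside grid of length {sig.size}"
                )
            seg = np.maximum(sig[iv.start_idx : iv.end_idx], 0.0)
            row[cp.peak_id] = float(np.trapezoid(seg, dx=dx))
        out[sid] = row
    table = pd.DataFrame.from_dict(out, orient="index")
    table.index.name = "sample_id"
    return table


# ---------------------------------------------------------------------------
# wavelength merging


def match_peaks_by_rt(
    peaks_a: list[CommonPeak],
    peaks_b: list[CommonPeak],
    rt: np.ndarray,
) -> dict[str, list[str]]:
    """Name map pairing common peaks across two wavelengths by interval overlap.

    Peaks whose index intervals overlap on the shared aligned grid get
    the same name (the apex retention time of the first wavelength's
    peak); unmatched peaks are named by their own apex.  This emulates
    assigning one metabolite name to the pair of absorption maxima of
    the same compound.
    """
    rt = np.asarray(rt, dtype=float)

    def label(cp: CommonPeak) -> str:
        return f"RT{rt[cp.interval.apex_idx]:.3f}"

    name_map: dict[str, list[str]] = {}
    used_b: set[str] = set()
    for pa in peaks_a:
        match = None
        for pb in peaks_b:
            if pb.peak_id not in used_b and pa.interval.overlaps(pb.interval):
                match = pb
                break
        name_map[f"a:{pa.peak_id}"] = [label(pa)]
        if match is not None:
            used_b.add(match.peak_id)
            name_map[f"b:{match.peak_id}"] = [label(pa)]
    for pb in peaks_b:
        if pb.peak_id not in used_b:
            name_map[f"b:{pb.peak_id}"] = [label(pb)]
    return name_map


def merge_wavelengths(
    peak_table_280: pd.DataFrame,
    peak_table_330: pd.DataFrame,
    name_map: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Merge the per-wavelength peak tables into one metabolite table.

    ``name_map`` maps wavelength-qualified peak ids (``"a:P001"`` for
    the first table, ``"b:P001"`` for the second) to lists of metabolite
    names.  Variables sharing a name across wavelengths are summed into
    one variable; co-eluting peaks keep a multi-name ``"X;Y"`` label;
    unmapped peaks pass through under their own qualified id.
    """
    if set(peak_table_280.index) != set(peak_table_330.index):
        raise ValueError("peak tables must share the same sample set")
    name_map = name_map or {}

    for prefix, table in (("a", peak_table_280), ("b", peak_table_330)):
        seen: dict[str, str] = {}
        for col in table.columns:
            names = name_map.get(f"{prefix}:{col}")
            if not names:
                continue
            label = ";".join(names)
            if label in seen:
                raise ValueError(
                    f"name {label!r} maps to peaks {seen[label]} and {col} "
                    f"within the same wavelength"
                )
            seen[label] = col

    columns: dict[str, pd.Series] = {}
    provenance: dict[str, list[str]] = {}
    for prefix, table in (("a", peak_table_280), ("b", peak_table_330)):
        aligned = table.loc[sorted(table.index)]
        for col in table.columns:
            qid = f"{prefix}:{col}"
            names = name_map.get(qid)
            label = ";".join(names) if names else qid
            if label in columns:
                columns[label] = columns[label] + aligned[col]
            else:
                columns[label] = aligned[col].copy()
            provenance.setdefault(label, []).append(qid)
    merged = pd.DataFrame(columns)
    merged.index.name = "sample_id"
    merged.attrs["provenance"] = provenance
    return merged


# ---------------------------------------------------------------------------
# full chain


@dataclass
class PreprocessResult:
    """Outputs of the preprocessing chain."""

    table: pd.DataFrame  # design columns + metabolite variables
    common_peaks: dict[int, list[CommonPeak]] = field(default_factory=dict)
    peak_meta: pd.DataFrame | None = None  # peak_id, wavelength, rt bounds, support
    counts: dict[str, int] = field(default_factory=dict)


def run_preprocessing(config, chromatogram_set: ChromatogramSet) -> PreprocessResult:
    """Run the full chain on a chromatogram set.

    ``config`` must expose ``cow_segment_len``, ``cow_slack``,
    ``spline_knots``, ``peak_tolerance`` and either ``c1`` (absolute
    count) or ``c1_fraction`` (fraction of chromatograms).  The COW
    reference is the pointwise median of the mass-normalized,
    differentiated traces per wavelength.
    """
    if len(chromatogram_set) == 0:
        raise ValueError("empty chromatogram set")
    wavelengths = chromatogram_set.wavelengths
    lengths = {c.n_points for c in chromatogram_set}
    if len(lengths) != 1:
        raise ValueError(f"all chromatograms must share grid length, got {lengths}")

    design = chromatogram_set.design.set_index("sample_id")
    per_wl_tables: dict[int, pd.DataFrame] = {}
    common: dict[int, list[CommonPeak]] = {}
    counts: dict[str, int] = {}
    rt_grid = chromatogram_set.chromatograms[0].rt

    for wl in wavelengths:
        chroms = chromatogram_set.by_wavelength(wl)
        deriv = {}
        for c in chroms:
            deriv[c.sample_id] = remove_baseline_by_differentiation(
                normalize_by_mass(c)
            )
        ref = np.median(np.vstack(list(deriv.values())), axis=0)
        warped = {
            sid: cow_align(sig, ref, config.cow_segment_len, config.cow_slack).warped
            for sid, sig in deriv.items()
        }
        intervals = {}
        for sid, sig in warped.items():
            d2 = smooth_second_derivative(sig, n_knots=config.spline_knots)
            intervals[sid] = detect_peaks(d2, sig, config.peak_tolerance)
        n_individual = sum(len(v) for v in intervals.values())
        c1 = getattr(config, "c1", None)
        if c1 is None:
            c1 = max(1, int(np.ceil(config.c1_fraction * len(chroms))))
        common[wl] = build_common_peaks(intervals, c1=c1)
        per_wl_tables[wl] = integrate_peaks(warped, common[wl])
        counts[f"individual_peaks_{wl}"] = n_individual
        counts[f"common_peaks_{wl}"] = len(common[wl])
        logger.info(
            "wavelength %d nm: %d individual peaks, %d common peaks (c1=%d)",
            wl, n_individual, len(common[wl]), c1,
        )

    if len(wavelengths) == 2:
        wa, wb = wavelengths
        name_map = match_peaks_by_rt(common[wa], common[wb], rt_grid)
        merged = merge_wavelengths(per_wl_tables[wa], per_wl_tables[wb], name_map)
    elif len(wavelengths) == 1:
        merged = per_wl_tables[wavelengths[0]].copy()
        merged.attrs["provenance"] = {c: [f"a:{c}"] for c in merged.columns}
    else:
        raise ValueError("expected one or two wavelengths")
    counts["variables"] = merged.shape[1]

    meta_rows = []
    for wl in wavelengths:
        for cp in common[wl]:
            meta_rows.append(
                {
                    "peak_id": cp.peak_id,
                    "wavelength": wl,
                    "start_rt": rt_grid[cp.interval.start_idx],
                    "end_rt": rt_grid[min(cp.interval.end_idx, rt_grid.size - 1)],
                    "apex_rt": rt_grid[cp.interval.apex_idx],
                    "support": cp.support,
                }
            )
    peak_meta = pd.DataFrame(meta_rows)

    table = design.join(merged, how="inner")
    table.attrs["provenance"] = merged.attrs.get("provenance", {})
    table.attrs["design_columns"] = [c for c in design.columns]
    return PreprocessResult(
        table=table.reset_index(),
        common_peaks=common,
        peak_meta=peak_meta,
        counts=counts,
    )
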