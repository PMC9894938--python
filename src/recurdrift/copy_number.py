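"""Binned-coverage copy-number chain for paired tumor samples.

The chain starts from total coverage in fixed-width genomic bins (10 kb by
default) with a GC fraction per bin:

1. a robust locally-weighted regression of coverage on GC captures the
   sample-specific GC bias; coverage is rescaled by the fitted curve so the
   sample's median coverage is preserved;
2. adjusted coverage is converted to log2 ratios against a matched normal
   on the same bin grid when one exists, otherwise against the sample's own
   median adjusted coverage, and the ratios are median-centered;
3. the centered track is partitioned per chromosome by a simplified
   circular binary segmentation: recursively find the contiguous arc
   maximizing the two-sample t statistic against its complement, accept the
   split when its permutation p-value beats ``alpha``, and finally merge
   adjacent segments whose means are closer than a small epsilon;
4. segment means are mapped to genes through exon overlap (averaging across
   segments), and paired gain/loss calls are made from the per-gene delta
   CN(recurrence) - CN(primary).

Per-gene CN is reported on the relative copy-ratio scale ``2**mean_log2``
(diploid baseline 1), the scale on which the gain/loss thresholds +-0.75
and the minimum-CN rule of 0.5 operate; the centered log2 scale is
available via ``scale="log2"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

_T_CAP = 1e12  # stands in for an infinite t (zero within-arc variance)


class CopyNumberError(ValueError):
    pass


@dataclass(frozen=True)
class CoverageBin:
    """One fixed-width coverage bin (0-based half-open) with its GC fraction."""

    chrom: str
    start: int
    end: int
    gc: float
    coverage: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CopyNumberError(f"empty bin {self.chrom}:{self.start}-{self.end}")
        if not 0.0 <= self.gc <= 1.0:
            raise CopyNumberError(f"GC fraction {self.gc} outside [0, 1]")
        if self.coverage < 0:
            raise CopyNumberError("negative coverage")


def bins_to_frame(bins: Sequence[CoverageBin]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "gc": [b.gc for b in bins],
            "coverage": [b.coverage for b in bins],
        }
    )
    for chrom, grp in df.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise CopyNumberError(f"overlapping bins on {chrom}")
    return df


class GCModel:
    """Fitted GC -> expected-coverage curve, evaluated by interpolation."""

    def __init__(self, gc_grid: np.ndarray, fitted: np.ndarray, iterations: int, bandwidth: float):
        order = np.argsort(gc_grid)
        self.gc_grid = np.asarray(gc_grid, dtype=float)[order]
        self.fitted = np.asarray(fitted, dtype=float)[order]
        self.iterations = iterations
        self.bandwidth = bandwidth

    def __call__(self, gc) -> np.ndarray:
        return np.interp(np.asarray(gc, dtype=float), self.gc_grid, self.fitted)


def fit_gc_model(bins: Sequence[CoverageBin], bandwidth: float = 0.3, iterations: int = 3) -> GCModel:
    """Robust local-linear regression of bin coverage on GC fraction.

    Uses locally weighted regression with ``iterations`` bisquare
    re-weighting passes, so isolated high-coverage outliers (e.g. true
    amplifications) barely perturb the bias curve.  A degenerate GC range
    (all bins equal) falls back to a flat curve at the median coverage.
    """
    cov = np.array([b.coverage for b in bins], dtype=float)
    gc = np.array([b.gc for b in bins], dtype=float)
    positive = cov > 0
    if positive.sum() < 50:
        raise CopyNumberError("GC model needs at least 50 bins with positive coverage")
    if np.ptp(gc[positive]) == 0:
        warnings.warn("degenerate GC range; fitting a flat GC model", stacklevel=2)
        med = float(np.median(cov[positive]))
        return GCModel(np.array([gc[positive][0]]), np.array([med]), 0, bandwidth)
    smoothed = lowess(cov[positive], gc[positive], frac=bandwidth, it=iterations, return_sorted=True)
    grid, fitted = smoothed[:, 0], smoothed[:, 1]
    # collapse duplicate gc values (np.interp needs an increasing grid)
    uniq, idx = np.unique(grid, return_index=True)
    fitted = np.array([fitted[grid == u].mean() for u in uniq])
    return GCModel(uniq, fitted, iterations, bandwidth)


def adjust_coverage(bins: Sequence[CoverageBin], model: GCModel) -> np.ndarray:
    """Rescale coverage by the GC curve, preserving the sample's median.

    adjusted = coverage * median(fitted over bins) / fitted(gc); bins whose
    fitted expectation is non-positive are masked (NaN) and stay excluded
    from every downstream step.
    """
    cov = np.array([b.coverage for b in bins], dtype=float)
    fitted = model([b.gc for b in bins])
    ok = fitted > 0
    med_fit = float(np.median(fitted[ok])) if ok.any() else math.nan
    adjusted = np.full(len(bins), np.nan)
    adjusted[ok] = cov[ok] * med_fit / fitted[ok]
    return adjusted


@dataclass
class Log2RatioTrack:
    """Median-centered per-bin log2 coverage ratios for one sample."""

    sample_id: str
    bins: pd.DataFrame  # chrom, start, end
    log2: np.ndarray  # NaN = masked bin
    reference_mode: str  # matched_normal | self_median


def compute_log2_ratios(
    bins: Sequence[CoverageBin],
    tumor_adjusted: np.ndarray,
    reference_adjusted: Optional[np.ndarray] = None,
    sample_id: str = "",
) -> Log2RatioTrack:
    """log2(tumor / reference) per bin, median-centered.

    The reference is the matched normal's adjusted coverage on the same bin
    grid when supplied, otherwise the median of the tumor's own adjusted
    coverage.  Bins with zero/invalid denominator or masked coverage stay
    NaN.
    """
    tumor_adjusted = np.asarray(tumor_adjusted, dtype=float)
    if reference_adjusted is not None:
        reference_adjusted = np.asarray(reference_adjusted, dtype=float)
        if reference_adjusted.shape != tumor_adjusted.shape:
            raise CopyNumberError("tumor and reference tracks use different bin grids")
        denom = reference_adjusted
        mode = "matched_normal"
    else:
        finite = np.isfinite(tumor_adjusted)
        denom = np.full_like(tumor_adjusted, np.nanmedian(tumor_adjusted[finite]))
        mode = "self_median"
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(tumor_adjusted / denom)
    log2[~np.isfinite(log2)] = np.nan
    finite = np.isfinite(log2)
    if finite.any():
        log2 = log2 - np.median(log2[finite])
    frame = bins_to_frame(bins)[["chrom", "start", "end"]]
    return Log2RatioTrack(sample_id, frame, log2, mode)


@dataclass(frozen=True)
class CNSegment:
    chrom: str
    start: int
    end: int
    mean_log2: float
    n_bins: int


def _max_arc_stats(X: np.ndarray, min_bins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise max two-sample |t| over contiguous arcs vs their complement.

    X is (rows, n).  An arc [i, j) is valid when both it and its complement
    hold >= min_bins values and it does not strand a fragment shorter than
    min_bins at either end.  Returns (stat, i, j) per row; zero-variance
    splits with distinct means score a large finite cap.
    """
    P, n = X.shape
    csum = np.zeros((P, n + 1))
    csum[:, 1:] = np.cumsum(X, axis=1)
    total = csum[:, -1]
    sumsq = (X**2).sum(axis=1)
    best = np.zeros(P)
    best_i = np.zeros(P, dtype=int)
    best_j = np.full(P, n, dtype=int)
    dof = max(n - 2, 1)
    for w in range(min_bins, n - min_bins + 1):
        starts = np.arange(n - w + 1)
        valid = ((starts == 0) | (starts >= min_bins)) & (
            (starts + w == n) | (n - starts - w >= min_bins)
        )
        if not valid.any():
            continue
        s1 = csum[:, w:] - csum[:, : n - w + 1]
        s2 = total[:, None] - s1
        n1, n2 = w, n - w
        m_diff = s1 / n1 - s2 / n2
        ss_within = np.maximum(sumsq[:, None] - s1**2 / n1 - s2**2 / n2, 0.0)
        denom = np.sqrt(ss_within / dof * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(m_diff) / denom
        t = np.where(np.isnan(t), 0.0, t)
        t = np.minimum(t, _T_CAP)
        t[:, ~valid] = -np.inf
        arg = np.argmax(t, axis=1)
        row_max = t[np.arange(P), arg]
        upd = row_max > best
        best_i[upd] = arg[upd]
        best_j[upd] = arg[upd] + w
        best[upd] = row_max[upd]
    return best, best_i, best_j


def _split_significant(
    x: np.ndarray, observed: float, alpha: float, n_perm: int, min_bins: int, rng: np.random.Generator
) -> bool:
    """Permutation test of the max-arc statistic with early stopping.

    p = (1 + #{perm stat >= observed}) / (1 + n_perm); stops as soon as the
    exceedance count rules out p < alpha.
    """
    max_exceed = alpha * (1 + n_perm) - 1  # accept split iff exceed < this
    if max_exceed <= 0:
        return False
    exceed = 0
    done = 0
    batch = 100
    while done < n_perm:
        m = min(batch, n_perm - done)
        perms = np.array([rng.permutation(x) for _ in range(m)])
        stats, _, _ = _max_arc_stats(perms, min_bins)
        exceed += int((stats >= observed).sum())
        done += m
        if exceed >= max_exceed:
            return False
    return (1 + exceed) / (1 + n_perm) < alpha


def _segment_values(
    x: np.ndarray, alpha: float, n_perm: int, min_bins: int, rng: np.random.Generator
) -> list[int]:
    """Recursive change-point search on one chromosome's finite values.

    Returns sorted interior breakpoints (indices into x).
    """
    breaks: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 * min_bins:
            return
        stat, i, j = _max_arc_stats(seg[None, :], min_bins)
        observed = float(stat[0])
        if observed <= 0:
            return
        if not _split_significant(seg, observed, alpha, n_perm, min_bins, rng):
            return
        i0, j0 = int(i[0]), int(j[0])
        cuts = [c for c in (i0, j0) if 0 < c < n]
        for c in cuts:
            breaks.append(lo + c)
        edges = [0] + cuts + [n]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(lo + a, lo + b)

    recurse(0, len(x))
    return sorted(set(breaks))


def segment_track(
    track: Log2RatioTrack,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_bins: int = 5,
    seed: int = 0,
    merge_epsilon: float = 0.2,
) -> list[CNSegment]:
    """Simplified circular binary segmentation of a centered log2 track.

    Each chromosome is segmented independently on its finite bins; adjacent
    segments whose means differ by less than ``merge_epsilon`` are merged.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    segments: list[CNSegment] = []
    df = track.bins.copy()
    df["log2"] = track.log2
    for chrom in df["chrom"].unique():
        sub = df[df["chrom"] == chrom].sort_values("start")
        finite = sub[np.isfinite(sub["log2"])]
        if len(finite) == 0:
            continue
        x = finite["log2"].to_numpy()
        breaks = _segment_values(x, alpha, n_perm, min_bins, rng)
        edges = [0] + breaks + [len(x)]
        chrom_segments = []
        for a, b in zip(edges[:-1], edges[1:]):
            chrom_segments.append((a, b, float(np.mean(x[a:b]))))
        chrom_segments = _merge_adjacent(chrom_segments, x, merge_epsilon)
        starts = finite["start"].to_numpy()
        ends = finite["end"].to_numpy()
        for a, b, mean in chrom_segments:
            segments.append(CNSegment(str(chrom), int(starts[a]), int(ends[b - 1]), mean, b - a))
    return segments


def _merge_adjacent(
    segs: list[tuple[int, int, float]], x: np.ndarray, epsilon: float
) -> list[tuple[int, int, float]]:
    merged = list(segs)
    changed = True
    while changed and len(merged) > 1:
        changed = False
        for k in range(len(merged) - 1):
            a1, b1, m1 = merged[k]
            a2, b2, m2 = merged[k + 1]
            if abs(m1 - m2) < epsilon:
                merged[k : k + 2] = [(a1, b2, float(np.mean(x[a1:b2])))]
                changed = True
                break
    return merged


@dataclass(frozen=True)
class GeneCN:
    """Per-gene copy number on the scale stated by ``scale``."""

    gene: str
    cn: float
    chrom: Optional[str] = None


def gene_copy_number(
    segments: Sequence[CNSegment],
    gene_exons: Mapping[str, Sequence[tuple[str, int, int]]],
) -> list[GeneCN]:
    """Map segment means to genes through exon overlap.

    A gene's CN is the unweighted mean of ``mean_log2`` over every segment
    overlapping at least one of its exons (0-based half-open intervals);
    genes with no overlapping segment are omitted.
    """
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    out: list[GeneCN] = []
    for gene, exons in gene_exons.items():
        hits: list[CNSegment] = []
        for chrom, start, end in exons:
            for seg in by_chrom.get(chrom, []):
                if seg.start < end and start < seg.end and seg not in hits:
                    hits.append(seg)
        if hits:
            out.append(GeneCN(gene, float(np.mean([s.mean_log2 for s in hits])), hits[0].chrom))
    return out


@dataclass(frozen=True)
class DeltaCNCall:
    gene: str
    delta: float
    call: str  # gain | loss | none | not_evaluable
    chrom: Optional[str] = None


def delta_cn_calls(
    pt: Sequence[GeneCN],
    ibtr: Sequence[GeneCN],
    gain: float = 0.75,
    loss: float = -0.75,
    min_cn: float = 0.5,
) -> list[DeltaCNCall]:
    """Paired per-gene gain/loss calls from delta = CN(recurrence) - CN(primary).

    A gene is evaluable only when both CN values are >= ``min_cn``; then
    delta > ``gain`` is a gain, delta < ``loss`` a loss, anything else none.
    Pure threshold arithmetic on whatever CN scale the inputs carry.
    """
    pt_map = {g.gene: g for g in pt}
    ibtr_map = {g.gene: g for g in ibtr}
    calls: list[DeltaCNCall] = []
    for gene in sorted(pt_map.keys() & ibtr_map.keys()):
        a, b = pt_map[gene], ibtr_map[gene]
        delta = b.cn - a.cn
        if a.cn < min_cn or b.cn < min_cn:
            call = "not_evaluable"
        elif delta > gain:
            call = "gain"
        elif delta < loss:
            call = "loss"
        else:
            call = "none"
        calls.append(DeltaCNCall(gene, float(delta), call, a.chrom or b.chrom))
    return calls


def gain_loss_counts(calls: Sequence[DeltaCNCall]) -> pd.DataFrame:
    """Gain/loss tallies overall and per chromosome (bar-chart companion)."""
    rows = [{"chrom": c.chrom or "all", "call": c.call} for c in calls]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["chrom", "gain", "loss"])
    table = df.pivot_table(index="chrom", columns="call", aggfunc="size", fill_value=0)
    for col in ("gain", "loss"):
        if col not in table:
            table[col] = 0
    return table[["gain", "loss"]].reset_index()


def paired_gene_cn_calls(
    segments_pt: Sequence[CNSegment],
    segments_ibtr: Sequence[CNSegment],
    gene_exons: Mapping[str, Sequence[tuple[str, int, int]]],
    gain: float = 0.75,
    loss: float = -0.75,
    min_cn: float = 0.5,
    scale: str = "ratio",
) -> list[DeltaCNCall]:
    """Gene CN for both pair members plus paired gain/loss calls.

    ``scale="ratio"`` (default) converts per-gene mean log2 to the relative
    copy-ratio ``2**log2`` before thresholding, so a diploid-baseline gene
    sits at 1 and the 0.5 minimum excludes deep deletions only;
    ``scale="log2"`` thresholds the centered log2 means directly.
    """
    if scale not in ("ratio", "log2"):
        raise CopyNumberError(f"unknown CN scale {scale!r}")
    pt = gene_copy_number(segments_pt, gene_exons)
    ibtr = gene_copy_number(segments_ibtr, gene_exons)
    if scale == "ratio":
        pt = [GeneCN(g.gene, float(2.0**g.cn), g.chrom) for g in pt]
        ibtr = [GeneCN(g.gene, float(2.0**g.cn), g.chrom) for g in ibtr]
    return delta_cn_calls(pt, ibtr, gain=gain, loss=loss, min_cn=min_cn)
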