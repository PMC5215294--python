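"""Island calling and differential testing of ChIP enrichment.

Caller
------
A self-contained fixed-width scanning-window Poisson caller: the genome is
tiled with non-overlapping windows (default 200 bp) and tags are assigned
to windows by extended-fragment midpoint.  A window with k tags is eligible
when the Poisson upper tail P(X >= k) under the genome-wide expected tags
per window is below ``p_threshold`` (default 1e-5).  Eligible windows
separated by at most ``gap`` bp (default 400) are merged, and each merged
island is trimmed to its outermost eligible windows.

Differential analysis (M-A normalization)
-----------------------------------------
Islands called in two samples are merged into union regions; regions
overlapping a called island in *both* samples are "common".  For every
region with raw counts (a, b) (pseudocount 0.5 for zeros),

    M = log2(a/b),   A = (1/2) log2(a*b)

and an ordinary-least-squares line M = c0 + c1*A fitted on the common
regions — systematic depth and intensity-dependent bias — is subtracted
from every region's M to give M_adjusted.  A region is differential when

    p < 0.01  and  |M_adjusted| > 1 (i.e. adjusted fold change > 2)
    and max(raw a, raw b) >= 15 reads,

where p comes from a conditional binomial exact test of the normalized
count pair against an equal-means null (equivalent to the exact Poisson
comparison).  Direction: gained = stronger in sample A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .coverage import DEFAULT_FRAGMENT_LENGTH, count_in_intervals, midpoints_array
from .io_formats import Tag

DEFAULT_WINDOW = 200
DEFAULT_GAP = 400
DEFAULT_P_THRESHOLD = 1e-5

DIFF_P_THRESHOLD = 0.01
DIFF_MIN_ABS_M = 1.0  # log2; adjusted fold change > 2
DIFF_MIN_READS = 15
PSEUDOCOUNT = 0.5


@dataclass
class Island:
    chrom: str
    start: int
    end: int
    counts: dict[str, int] = field(default_factory=dict)
    pvalue_enrichment: float = 1.0


@dataclass
class DifferentialResult:
    chrom: str
    start: int
    end: int
    count_a: int
    count_b: int
    common: bool
    M: float
    A: float
    m_adjusted: float
    pvalue: float
    passes: bool
    direction: str  # gained | lost | unchanged


# ---------------------------------------------------------------------------
# Island calling
# ---------------------------------------------------------------------------

def call_islands(
    tags_by_chrom: Mapping[str, Sequence[Tag]],
    chrom_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    gap: int = DEFAULT_GAP,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    sample_id: str = "sample",
) -> list[Island]:
    """Call enrichment islands against a genome-wide Poisson background."""
    if window < 100:
        raise ValueError(f"window must be >= 100 bp, got {window}")
    mids = {
        chrom: midpoints_array(tags, fragment_length)
        for chrom, tags in tags_by_chrom.items()
    }
    n_tags = sum(m.size for m in mids.values())
    if n_tags == 0:
        return []
    n_windows = sum(-(-chrom_lengths[c] // window) for c in chrom_lengths)
    lam = n_tags / n_windows

    islands: list[Island] = []
    for chrom, clen in chrom_lengths.items():
        m = mids.get(chrom)
        if m is None or m.size == 0:
            continue
        m = np.clip(m, 0, clen - 1)
        nwin = -(-clen // window)
        counts = np.bincount(m // window, minlength=nwin)
        pvals = stats.poisson.sf(counts - 1, lam)
        eligible = np.flatnonzero(pvals < p_threshold)
        if eligible.size == 0:
            continue
        # merge eligible windows separated by <= gap bp
        runs: list[list[int]] = [[eligible[0], eligible[0]]]
        for w in eligible[1:]:
            prev_end = (runs[-1][1] + 1) * window
            if w * window - prev_end <= gap:
                runs[-1][1] = w
            else:
                runs.append([w, w])
        for w0, w1 in runs:
            start = w0 * window
            end = min((w1 + 1) * window, clen)
            total = int(
                np.searchsorted(m, end, side="left")
                - np.searchsorted(m, start, side="left")
            )
            lam_island = lam * (end - start) / window
            islands.append(
                Island(
                    chrom=chrom,
                    start=start,
                    end=end,
                    counts={sample_id: total},
                    pvalue_enrichment=float(stats.poisson.sf(total - 1, lam_island)),
                )
            )
    islands.sort(key=lambda i: (i.chrom, i.start))
    return islands


# ---------------------------------------------------------------------------
# Region merging across samples
# ---------------------------------------------------------------------------

def merge_island_sets(
    islands_a: Sequence[Island], islands_b: Sequence[Island]
) -> list[tuple[str, int, int, bool]]:
    """Union regions over two island sets.

    Overlapping/adjacent islands from either sample are merged into one
    region; a region is *common* when it overlaps at least one called
    island from each sample.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for src, isl_list in (("a", islands_a), ("b", islands_b)):
        for isl in isl_list:
            by_chrom.setdefault(isl.chrom, []).append((isl.start, isl.end, src))
    regions: list[tuple[str, int, int, bool]] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e, srcs = ivs[0][0], ivs[0][1], {ivs[0][2]}
        for s, e, src in ivs[1:]:
            if s < cur_e:  # strict overlap; abutting islands stay separate
                cur_e = max(cur_e, e)
                srcs.add(src)
            else:
                regions.append((chrom, cur_s, cur_e, srcs == {"a", "b"}))
                cur_s, cur_e, srcs = s, e, {src}
        regions.append((chrom, cur_s, cur_e, srcs == {"a", "b"}))
    return regions


# ---------------------------------------------------------------------------
# M-A normalization
# ---------------------------------------------------------------------------

@dataclass
class MAFit:
    intercept: float
    slope: float
    n_common: int

    def predict(self, A: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(A, dtype=float)


def ma_values(counts_a: np.ndarray, counts_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.where(counts_a == 0, PSEUDOCOUNT, counts_a).astype(float)
    b = np.where(counts_b == 0, PSEUDOCOUNT, counts_b).astype(float)
    M = np.log2(a / b)
    A = 0.5 * np.log2(a * b)
    return M, A


def ma_normalize(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    common: np.ndarray,
) -> tuple[np.ndarray, MAFit]:
    """Fit M ~ A by OLS on common regions; return M_adjusted for all.

    Requires at least 10 common regions (fewer means the normalization is
    unidentifiable — simulate deeper or call with a laxer threshold).
    """
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    common = np.asarray(common, dtype=bool)
    n_common = int(common.sum())
    if n_common < 10:
        raise ValueError(
            f"only {n_common} common islands (< 10): M-A normalization is "
            "unreliable; use deeper data or laxer island calling"
        )
    M, A = ma_values(counts_a, counts_b)
    if np.ptp(A[common]) == 0:  # degenerate: all common at one intensity
        slope, intercept = 0.0, float(np.mean(M[common]))
    else:
        slope, intercept = np.polyfit(A[common], M[common], 1)
    fit = MAFit(intercept=float(intercept), slope=float(slope), n_common=n_common)
    m_adjusted = M - fit.predict(A)
    return m_adjusted, fit


# ---------------------------------------------------------------------------
# Differential test
# ---------------------------------------------------------------------------

def differential_pvalue(count_a: float, count_b: float, m_adjusted: float) -> float:
    """Conditional binomial exact test of the normalized pair.

    The raw total is redistributed according to M_adjusted — the pair
    (x, y) with x + y = a + b and log2(x/y) = M_adjusted — and tested
    against Binomial(n = x + y, p = 1/2), the equal-means Poisson null
    conditioned on the total.
    """
    a = max(count_a, PSEUDOCOUNT)
    b = max(count_b, PSEUDOCOUNT)
    total = a + b
    r = 2.0 ** m_adjusted
    x = total * r / (1.0 + r)
    k_a = int(round(x))
    k_b = int(round(total - x))
    n = k_a + k_b
    if n == 0:
        return 1.0
    return float(stats.binomtest(k_a, n, 0.5).pvalue)


def differential_test(
    chrom: str,
    start: int,
    end: int,
    count_a: int,
    count_b: int,
    m_adjusted: float,
    A: float,
    M: float,
    common: bool,
    p_threshold: float = DIFF_P_THRESHOLD,
    min_abs_m: float = DIFF_MIN_ABS_M,
    min_reads: int = DIFF_MIN_READS,
) -> DifferentialResult:
    """Apply the three differential criteria to one region."""
    pvalue = differential_pvalue(count_a, count_b, m_adjusted)
    passes = (
        pvalue < p_threshold
        and abs(m_adjusted) > min_abs_m
        and max(count_a, count_b) >= min_reads
    )
    if not passes:
        direction = "unchanged"
    else:
        direction = "gained" if m_adjusted > 0 else "lost"
    return DifferentialResult(
        chrom=chrom,
        start=start,
        end=end,
        count_a=int(count_a),
        count_b=int(count_b),
        common=common,
        M=float(M),
        A=float(A),
        m_adjusted=float(m_adjusted),
        pvalue=pvalue,
        passes=passes,
        direction=direction,
    )


def differential_islands(
    tags_a: Mapping[str, Sequence[Tag]],
    tags_b: Mapping[str, Sequence[Tag]],
    chrom_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    gap: int = DEFAULT_GAP,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
) -> list[DifferentialResult]:
    """End-to-end two-sample comparison: call, merge, normalize, test.

    Sample A is the test sample: "gained" means stronger in A than in B.
    """
    islands_a = call_islands(
        tags_a, chrom_lengths, window, gap, p_threshold, fragment_length, "a"
    )
    islands_b = call_islands(
        tags_b, chrom_lengths, window, gap, p_threshold, fragment_length, "b"
    )
    regions = merge_island_sets(islands_a, islands_b)
    if not regions:
        return []
    mids_a = {c: midpoints_array(t, fragment_length) for c, t in tags_a.items()}
    mids_b = {c: midpoints_array(t, fragment_length) for c, t in tags_b.items()}
    counts_a = np.zeros(len(regions), dtype=np.int64)
    counts_b = np.zeros(len(regions), dtype=np.int64)
    empty = np.empty(0, dtype=np.int64)
    for i, (chrom, s, e, _) in enumerate(regions):
        counts_a[i] = count_in_intervals(mids_a.get(chrom, empty), [(s, e)])[0]
        counts_b[i] = count_in_intervals(mids_b.get(chrom, empty), [(s, e)])[0]
    common = np.array([r[3] for r in regions], dtype=bool)
    m_adjusted, fit = ma_normalize(counts_a, counts_b, common)
    M, A = ma_values(counts_a, counts_b)
    return [
        differential_test(
            chrom, s, e, counts_a[i], counts_b[i], m_adjusted[i], A[i], M[i],
            bool(common[i]),
        )
        for i, (chrom, s, e, _) in enumerate(regions)
    ]
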