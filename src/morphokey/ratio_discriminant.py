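"""Two-group LDA ratio extractor.

The linear discriminant between two species in log-measurement space is
generally a dense combination of all variables and hence useless at the
microscope.  The ratio extractor searches the restricted family of
*ratio directions* ``(e_i - e_j)/sqrt(2)`` — each corresponding to a
single body ratio ``x_i / x_j`` — and ranks every pair by the
standardized separation of the two groups along it.  The winning pair is
the single ratio that best reproduces the discriminant separation while
remaining measurable with two distances and a division.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from morphokey.measurement_io import MeasurementTable, RatioSeries, compute_ratio
from morphokey.mra import LogShapeData


@dataclass(frozen=True)
class ThresholdReport:
    """Separating threshold for one ratio between two groups.

    When the groups' observed ratio ranges are disjoint the threshold is
    the midpoint of the gap, rounded to 2 decimals; otherwise
    ``overlap`` is True and ``overlap_interval`` holds the intersection.
    """

    group_low: str
    group_high: str
    range_low: tuple[float, float]
    range_high: tuple[float, float]
    threshold: float | None
    overlap: bool
    overlap_interval: tuple[float, float] | None


@dataclass(frozen=True)
class RatioExtraction:
    """One candidate ratio with its two-group separation statistics."""

    numerator: str
    denominator: str
    separation: float
    group1: str
    group2: str
    range1: tuple[float, float]
    range2: tuple[float, float]
    high_group: str
    threshold: float | None
    overlap: bool
    overlap_interval: tuple[float, float] | None

    @property
    def name(self) -> str:
        return f"{self.numerator}/{self.denominator}"


def _two_group_arrays(data: LogShapeData, groups=None):
    labels = sorted(data.group.unique()) if groups is None else list(groups)
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    masks = [data.group == g for g in labels]
    for g, m in zip(labels, masks):
        if m.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 specimens")
    X = data.shape.to_numpy(dtype=float)
    return labels, [X[m.to_numpy()] for m in masks]


def discriminant_direction(
    data: LogShapeData, groups=None, ridge: float | None = None
) -> np.ndarray:
    """Fisher discriminant direction between two groups in shape space.

    Solves ``S_w d = (m1 - m2)`` with the pooled within-group covariance
    ``S_w`` and normalises ``d``.  ``ridge`` adds ``ridge * I`` before the
    solve; ``None`` uses a tiny default of ``1e-8 * trace(S_w)/p`` which
    leaves well-conditioned problems untouched.  Raises when the group
    means coincide (nothing to discriminate) or when the pooled
    covariance is singular and no ridge helps.
    """
    labels, (X1, X2) = _two_group_arrays(data, groups)
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    diff = m1 - m2
    if np.allclose(diff, 0):
        raise ValueError("no discrimination: group means are identical")
    n1, n2 = len(X1), len(X2)
    S1 = np.cov(X1, rowvar=False)
    S2 = np.cov(X2, rowvar=False)
    Sw = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    p = Sw.shape[0]
    lam = ridge if ridge is not None else 1e-8 * np.trace(Sw) / p
    try:
        d = np.linalg.solve(Sw + lam * np.eye(p), diff)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "pooled within-group covariance is singular; pass a ridge term "
            "to regularize"
        ) from err
    norm = np.linalg.norm(d)
    if not np.isfinite(norm) or norm == 0:
        raise np.linalg.LinAlgError(
            "pooled within-group covariance is singular; pass a ridge term "
            "to regularize"
        )
    return d / norm


def _standardized_separation(a: np.ndarray, b: np.ndarray) -> float:
    """|mean difference| / pooled within-group SD of two projected samples."""
    n1, n2 = len(a), len(b)
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (
        n1 + n2 - 2
    )
    delta = abs(a.mean() - b.mean())
    if pooled_var == 0:
        return np.inf if delta > 0 else 0.0
    return float(delta / np.sqrt(pooled_var))


def _threshold_from_ranges(
    g_low: str,
    g_high: str,
    r_low: tuple[float, float],
    r_high: tuple[float, float],
):
    if r_low[1] < r_high[0]:
        mid = (r_low[1] + r_high[0]) / 2
        thr = round(mid, 2)
        if not r_low[1] < thr < r_high[0]:
            thr = mid  # keep the exact midpoint when rounding leaves the gap
        return thr, False, None
    lo = max(r_low[0], r_high[0])
    hi = min(r_low[1], r_high[1])
    return None, True, (lo, hi)


def extract_best_ratios(
    data: LogShapeData, groups=None, top_k: int = 1
) -> list[RatioExtraction]:
    """Rank every variable pair by two-group separation of its log ratio.

    For each unordered pair ``(i, j)`` the specimens are projected onto
    ``(e_i - e_j)/sqrt(2)`` (equivalently, onto their log ratio
    ``ln x_i - ln x_j``; the specimen's size term cancels) and scored by
    ``|mean1 - mean2| / pooled SD``.  Pairs are reported best-first;
    ties break lexicographically by variable codes.  Each result carries
    the raw-scale per-group ratio ranges, which group lies high, and a
    gap-midpoint threshold when the ranges are disjoint.
    """
    labels, (X1, X2) = _two_group_arrays(data, groups)
    variables = data.variables
    if len(variables) < 2:
        raise ValueError("at least 2 variables are required")
    scored = []
    for i, j in combinations(range(len(variables)), 2):
        a = (X1[:, i] - X1[:, j]) / np.sqrt(2)
        b = (X2[:, i] - X2[:, j]) / np.sqrt(2)
        sep = _standardized_separation(a, b)
        scored.append((sep, variables[i], variables[j]))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    results = []
    for sep, num, den in scored[: max(top_k, 0)]:
        i, j = variables.index(num), variables.index(den)
        log_r1 = X1[:, i] - X1[:, j]
        log_r2 = X2[:, i] - X2[:, j]
        r1 = (float(np.exp(log_r1.min())), float(np.exp(log_r1.max())))
        r2 = (float(np.exp(log_r2.min())), float(np.exp(log_r2.max())))
        high = labels[0] if log_r1.mean() >= log_r2.mean() else labels[1]
        if high == labels[0]:
            thr, ov, interval = _threshold_from_ranges(labels[1], labels[0], r2, r1)
        else:
            thr, ov, interval = _threshold_from_ranges(labels[0], labels[1], r1, r2)
        results.append(
            RatioExtraction(
                numerator=num,
                denominator=den,
                separation=sep,
                group1=labels[0],
                group2=labels[1],
                range1=r1,
                range2=r2,
                high_group=high,
                threshold=thr,
                overlap=ov,
                overlap_interval=interval,
            )
        )
    return results


def separation_threshold(
    ratio: RatioSeries, species: pd.Series, group1: str, group2: str
) -> ThresholdReport:
    """Gap-midpoint threshold for a ratio between two named groups.

    The threshold exists iff the observed per-group ranges are disjoint;
    it is then the midpoint between the adjacent extremes, rounded to 2
    decimals, and satisfies ``max(low group) < threshold < min(high
    group)``.
    """
    values = ratio.values
    out = {}
    for g in (group1, group2):
        idx = species.index[species == g].intersection(values.index)
        if len(idx) == 0:
            raise ValueError(f"group {g!r} has no ratio values")
        v = values.loc[idx]
        out[g] = (float(v.min()), float(v.max()))
    if np.mean(out[group1]) >= np.mean(out[group2]):
        g_high, g_low = group1, group2
    else:
        g_high, g_low = group2, group1
    thr, ov, interval = _threshold_from_ranges(
        g_low, g_high, out[g_low], out[g_high]
    )
    return ThresholdReport(
        group_low=g_low,
        group_high=g_high,
        range_low=out[g_low],
        range_high=out[g_high],
        threshold=thr,
        overlap=ov,
        overlap_interval=interval,
    )


def ratio_report_frame(extractions: list[RatioExtraction]) -> pd.DataFrame:
    """Tabular report mirroring a best-ratio table: one row per ranked pair."""
    rows = []
    for rank, e in enumerate(extractions, start=1):
        rows.append(
            {
                "rank": rank,
                "numerator": e.numerator,
                "denominator": e.denominator,
                "separation": e.separation,
                "group1": e.group1,
                "group1_min": e.range1[0],
                "group1_max": e.range1[1],
                "group2": e.group2,
                "group2_min": e.range2[0],
                "group2_max": e.range2[1],
                "high_group": e.high_group,
                "threshold": e.threshold,
                "overlap": e.overlap,
            }
        )
    return pd.DataFrame(rows)


def ratio_series_for(
    table: MeasurementTable, extraction: RatioExtraction
) -> RatioSeries:
    """Raw-scale ratio series for an extraction's winning pair."""
    return compute_ratio(table, extraction.numerator, extraction.denominator)
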