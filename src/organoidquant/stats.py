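"""Group-comparison chain: isogenic-control pooling, Shapiro–Wilk, one-way
ANOVA, and Tukey's multiple-comparison post-hoc test.

The chain mirrors common practice in organoid immunofluorescence work:
normality is *reported* (Shapiro–Wilk) but does not switch the test; the
omnibus comparison is a fixed-effects one-way ANOVA; pairwise differences use
the studentized-range (Tukey HSD) adjustment, with the Tukey–Kramer standard
error for unbalanced groups.  Isogenic control lines belonging to the same
patient are pooled into a single comparator group before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TukeyPair",
    "pool_isogenic_controls",
    "shapiro_wilk",
    "one_way_anova",
    "tukey_hsd",
    "validate_groups",
]

# GroupedMeasurements: ordered mapping group label -> 1D array of measurements.
GroupedMeasurements = Mapping[str, Sequence[float]]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_difference: float
    q: float
    p_adjusted: float


def validate_groups(groups: GroupedMeasurements, min_groups: int = 2) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float).ravel()
        if arr.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
        out[str(label)] = arr
    if len(out) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    return out


def pool_isogenic_controls(
    records: Iterable[tuple[str, float]],
    lineage_map: Mapping[str, str],
    patient_map: Mapping[str, str],
    per_line_means: bool = False,
) -> dict[str, np.ndarray]:
    """Pool each patient's isogenic-control lines into one comparator group.

    ``records`` is an iterable of (cell line, measurement).  ``lineage_map``
    labels each line ``"edited"`` or ``"isogenic_control"``; ``patient_map``
    gives the line's patient.  Control lines of the same patient are merged —
    by default their raw measurements are concatenated; with
    ``per_line_means=True`` each control line contributes its mean instead.
    Edited lines pass through as their own groups.
    """
    by_line: dict[str, list[float]] = {}
    for line, value in records:
        if line not in lineage_map or line not in patient_map:
            raise KeyError(f"cell line {line!r} missing from lineage or patient map")
        by_line.setdefault(line, []).append(float(value))

    groups: dict[str, list[float]] = {}
    for line, values in by_line.items():
        if lineage_map[line] == "isogenic_control":
            key = f"{patient_map[line]}_isogenic_control"
            groups.setdefault(key, []).extend(
                [float(np.mean(values))] if per_line_means else values
            )
        elif lineage_map[line] == "edited":
            groups.setdefault(line, []).extend(values)
        else:
            raise ValueError(f"lineage for {line!r} must be 'edited' or 'isogenic_control'")
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and p; requires 3 <= n <= 5000 and non-zero variance."""
    arr = np.asarray(x, dtype=float).ravel()
    if not (3 <= arr.size <= 5000):
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro–Wilk undefined for a constant sample")
    res = sps.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


def _sums_of_squares(arrays: list[np.ndarray]) -> tuple[float, float, int, int]:
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    return float(ss_between), float(ss_within), len(arrays) - 1, n_total - len(arrays)


def one_way_anova(groups: GroupedMeasurements, welch: bool = False) -> AnovaResult:
    """Fixed-effects one-way ANOVA from explicit sums of squares.

    When every group mean coincides, F = 0 and p = 1 by definition (including
    the fully degenerate all-identical case).  ``welch=True`` switches to the
    Welch variance-weighted ANOVA for heteroscedastic groups.
    """
    g = validate_groups(groups)
    arrays = list(g.values())
    if welch:
        return _welch_anova(arrays)
    ss_b, ss_w, df_b, df_w = _sums_of_squares(arrays)
    if ss_b == 0:
        return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
    if ss_w == 0:
        return AnovaResult(F=np.inf, df_between=df_b, df_within=df_w, p=0.0)
    F = (ss_b / df_b) / (ss_w / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def _welch_anova(arrays: list[np.ndarray]) -> AnovaResult:
    k = len(arrays)
    w = np.array([a.size / a.var(ddof=1) for a in arrays])
    m = np.array([a.mean() for a in arrays])
    mw = (w * m).sum() / w.sum()
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    lam = (3.0 / (k**2 - 1)) * sum(
        (1 - wi / w.sum()) ** 2 / (a.size - 1) for wi, a in zip(w, arrays)
    )
    F = num / (1 + 2 * lam * (k - 2) / 3)
    df2 = 1.0 / lam
    p = float(sps.f.sf(F, k - 1, df2))
    return AnovaResult(F=float(F), df_between=k - 1, df_within=int(round(df2)), p=p)


def tukey_hsd(groups: GroupedMeasurements) -> list[TukeyPair]:
    """Tukey multiple-comparison table with Tukey–Kramer SEs.

    For groups i, j: ``q = |mean_i − mean_j| / sqrt(MS_within/2 · (1/n_i + 1/n_j))``
    and the adjusted p is the studentized-range upper tail with k groups and
    the ANOVA within-group degrees of freedom.
    """
    g = validate_groups(groups)
    arrays = list(g.values())
    labels = list(g.keys())
    _, ss_w, _, df_w = _sums_of_squares(arrays)
    if df_w <= 0:
        raise ValueError("no within-group degrees of freedom")
    ms_w = ss_w / df_w
    if ms_w == 0:
        raise ValueError("zero within-group variance: studentized range undefined")
    k = len(arrays)
    pairs = []
    for (ia, a), (ib, b) in combinations(enumerate(arrays), 2):
        diff = a.mean() - b.mean()
        se = np.sqrt(ms_w / 2.0 * (1.0 / a.size + 1.0 / b.size))
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_w))
        pairs.append(
            TukeyPair(
                group_a=labels[ia],
                group_b=labels[ib],
                mean_difference=float(diff),
                q=float(q),
                p_adjusted=min(1.0, p),
            )
        )
    return pairs


def stats_report(groups: GroupedMeasurements, welch: bool = False) -> dict:
    """Full chain on one measurement table: per-group Shapiro–Wilk, one-way
    ANOVA, and the Tukey post-hoc table, as a JSON-serializable dict."""
    g = validate_groups(groups)
    normality = {}
    for label, arr in g.items():
        try:
            W, p = shapiro_wilk(arr)
            normality[label] = {"W": W, "p": p}
        except ValueError as exc:
            normality[label] = {"error": str(exc)}
    anova = one_way_anova(g, welch=welch)
    try:
        tukey = tukey_hsd(g)
    except ValueError:
        tukey = []  # zero within-group variance: no post-hoc comparisons possible
    return {
        "groups": {k: int(v.size) for k, v in g.items()},
        "shapiro_wilk": normality,
        "anova": {
            "F": anova.F,
            "df_between": anova.df_between,
            "df_within": anova.df_within,
            "p": anova.p,
        },
        "tukey": [
            {
                "pair": [t.group_a, t.group_b],
                "mean_difference": t.mean_difference,
                "q": t.q,
                "p_adjusted": t.p_adjusted,
            }
            for t in tukey
        ],
    }


__all__.append("stats_report")
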