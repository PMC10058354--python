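"""Accuracy metrics, functional-use percentages and nonparametric group statistics.

Accuracy is chunk-size weighted: each block contributes proportionally to its
sample count, which makes variable-length-block results comparable with the
fixed 800-sample-block results (for equal sizes it reduces to plain
accuracy).  Functional use (FU%) is the percentage of labelled *time* spent
functional.  Group summaries are medians with (min–max) ranges; the
between-group comparison is a Mann-Whitney U test and the between-method
(paired) comparison a Wilcoxon signed-rank test.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .annotation import EXCLUDED, FUNCTIONAL, LABEL_VALUES


def _as_label_array(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OU":
        labels = np.asarray([LABEL_VALUES[str(v)] for v in labels], dtype=int)
    return labels.astype(int)


def weighted_accuracy(correct, sizes) -> float:
    """Σ sizes over correct blocks / Σ sizes over all blocks."""
    correct = np.asarray(correct, dtype=bool)
    sizes = np.asarray(sizes, dtype=float)
    if correct.size == 0:
        raise ValueError("no blocks to score")
    if correct.shape != sizes.shape or np.any(sizes <= 0):
        raise ValueError("correct flags and positive sizes must align")
    return float(sizes[correct].sum() / sizes.sum())


def functional_use_percent(labels, sizes) -> float:
    """Percentage of labelled time carrying the functional label.

    ``labels`` may be integer labels or their names; excluded blocks are
    ignored.  Size-weighting makes this a percent of *time*, not of blocks.
    """
    labels = _as_label_array(labels)
    sizes = np.asarray(sizes, dtype=float)
    keep = labels != EXCLUDED
    if not keep.any():
        raise ValueError("all blocks are excluded")
    total = sizes[keep].sum()
    return float(100.0 * sizes[keep & (labels == FUNCTIONAL)].sum() / total)


def fu_error(predicted_pct: float, truth_pct: float) -> float:
    """Magnitude of the functional-use estimation error, in percentage points."""
    for v in (predicted_pct, truth_pct):
        if not 0.0 <= v <= 100.0:
            raise ValueError("functional-use percentages must lie in [0, 100]")
    return abs(predicted_pct - truth_pct)


def median_range(values) -> tuple[float, float, float]:
    """(median, min, max); even-length medians average the central pair."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("median of an empty set")
    return float(np.median(values)), float(values.min()), float(values.max())


@dataclasses.dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str


def mann_whitney_u(group_a, group_b) -> TestResult:
    """Two-sided Mann-Whitney U between two independent groups.

    The exact null distribution is used when the pooled sample has at most
    20 observations and no ties; otherwise the normal approximation with tie
    correction (no continuity correction) is used.  The method actually
    applied is reported alongside the p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    if no_ties and pooled.size <= 20:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    return TestResult(float(res.statistic), float(min(1.0, res.pvalue)), method)


def wilcoxon_signed_rank(differences) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  The exact distribution is used for up to
    25 non-zero differences without tied magnitudes, otherwise the normal
    approximation.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    mags = np.abs(d)
    no_ties = len(np.unique(mags)) == mags.size
    if no_ties and d.size <= 25:
        method = "exact"
        res = stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        method = "approx"
        res = stats.wilcoxon(d, alternative="two-sided", method="approx")
    return TestResult(float(res.statistic), float(min(1.0, res.pvalue)), method)


def _summary(values) -> dict:
    med, lo, hi = median_range(values)
    return {"median": med, "min": lo, "max": hi}


def build_report(per_subject: list[dict],
                 paired_keys: tuple[tuple[str, str], ...] = ()) -> dict:
    """Aggregate per-subject metrics into a cohort report.

    Parameters
    ----------
    per_subject : list of dict
        One mapping per subject.  Must contain ``subject_id``; every other
        numeric key is summarised as median + range, grouped by ``group``
        when present.
    paired_keys : pairs of metric names
        For each (a, b) pair a Wilcoxon signed-rank test on a−b is added
        (per group), mirroring the fixed-vs-variable method comparison.

    Returns a JSON-serialisable dict with ``per_subject``, ``summary`` and
    ``tests`` sections.
    """
    if not per_subject:
        raise ValueError("empty cohort")
    groups: dict[str, list[dict]] = {}
    for row in per_subject:
        groups.setdefault(row.get("group", "all"), []).append(row)
    metric_keys = sorted({
        k for row in per_subject for k, v in row.items()
        if isinstance(v, (int, float)) and k not in ("subject_id",)
    })
    summary: dict = {}
    tests: dict = {}
    for gname, rows in groups.items():
        summary[gname] = {}
        for key in metric_keys:
            vals = [r[key] for r in rows if key in r]
            if vals:
                summary[gname][key] = _summary(vals)
        for ka, kb in paired_keys:
            pairs = [(r[ka], r[kb]) for r in rows if ka in r and kb in r]
            diffs = [x - y for x, y in pairs]
            if diffs and any(d != 0 for d in diffs):
                res = wilcoxon_signed_rank(diffs)
                tests[f"{gname}:{ka}_vs_{kb}"] = dataclasses.asdict(res)
    gnames = list(groups)
    if len(gnames) == 2:
        for key in metric_keys:
            va = [r[key] for r in groups[gnames[0]] if key in r]
            vb = [r[key] for r in groups[gnames[1]] if key in r]
            if va and vb:
                res = mann_whitney_u(va, vb)
                tests[f"{gnames[0]}_vs_{gnames[1]}:{key}"] = dataclasses.asdict(res)
    return {"per_subject": per_subject, "summary": summary, "tests": tests}


def render_markdown(report: dict) -> str:
    """Render a report's summary section as markdown tables."""
    lines = []
    for gname, metrics in report["summary"].items():
        lines.append(f"### {gname}")
        lines.append("| metric | median | range |")
        lines.append("| --- | --- | --- |")
        for key, s in metrics.items():
            lines.append(
                f"| {key} | {s['median']:.2f} | {s['min']:.2f}–{s['max']:.2f} |"
            )
        lines.append("")
    if report.get("tests"):
        lines.append("### tests")
        lines.append("| comparison | statistic | p | method |")
        lines.append("| --- | --- | --- | --- |")
        for name, t in report["tests"].items():
            lines.append(
                f"| {name} | {t['statistic']:.3g} | {t['p_value']:.3g} "
                f"| {t['method']} |"
            )
    return "\n".join(lines)
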