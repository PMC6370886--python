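"""Statistical layer: correlations, perturbation comparisons, lineage
memory, and ploidy comparisons.

Thin, explicit wrappers around scipy/statsmodels that return structured
results (test name, statistic, p, group summaries) ready for a JSON report.
All tests are two-sided; significance levels are reported, never hard-coded
into pass/fail decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    valid: bool = True
    note: str = ""


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p: float
    groups: dict = field(default_factory=dict)   # name -> {n, mean, median}
    extra: dict = field(default_factory=dict)


@dataclass
class MemoryResult:
    contingency: np.ndarray        # 2x2: mother on/off x daughter on/off
    test: str
    statistic: float
    p: float
    span_comparison: GroupComparison | None
    valid: bool = True
    note: str = ""


def _summary(name, values) -> dict:
    v = np.asarray(values, dtype=float)
    return {name: {"n": int(len(v)), "mean": float(np.mean(v)),
                   "median": float(np.median(v))}}


# ---------------------------------------------------------------------------

def correlate_lengths(records, cycles, against: str = "S") -> CorrelationResult:
    """Pearson correlation of expression span against a cycle quantity.

    ``records`` are ExpressionRecords, ``cycles`` CellCycleRecords; pairs
    are formed by track id.  ``against`` selects cycle / S / M length.
    Degenerate inputs (fewer than 3 pairs, zero variance) are flagged, not
    raised.
    """
    attr = {"cycle": "cycle_length_s", "S": "s_length_s",
            "M": "m_length_s"}.get(against)
    if attr is None:
        raise ValueError("against must be one of 'cycle', 'S', 'M'")
    spans = {r.track_id: r.span_s for r in records}
    x, y = [], []
    for c in cycles:
        if c.track_id in spans:
            x.append(spans[c.track_id])
            y.append(getattr(c, attr))
    return pearson(x, y)


def pearson(x, y) -> CorrelationResult:
    """Pearson r with the two-sided p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        return CorrelationResult(float("nan"), float("nan"), n, False,
                                 "fewer than 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, False,
                                 "zero variance")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n)


# ---------------------------------------------------------------------------

_QUANT_ATTR = {"cycle": "cycle_length_s", "S": "s_length_s", "M": "m_length_s"}


def _extract(group, quantity):
    if len(group) and hasattr(group[0], "cycle_length_s"):
        return [getattr(c, _QUANT_ATTR[quantity]) for c in group]
    return list(group)


def compare_perturbation(control, treated, quantity: str = "cycle",
                         test: str = "mann-whitney") -> GroupComparison:
    """Two-group comparison of a cycle quantity (or raw value lists).

    ``test``: 'mann-whitney' (rank sum), 't' (unpaired, Welch), or
    'anova-tukey' (one-way ANOVA; with two groups this reduces to the
    classical F test).  Groups must be non-empty.
    """
    if quantity not in _QUANT_ATTR:
        raise ValueError("quantity must be one of 'cycle', 'S', 'M'")
    a = np.asarray(_extract(control, quantity), dtype=float)
    b = np.asarray(_extract(treated, quantity), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    groups = {**_summary("control", a), **_summary("treated", b)}
    if test == "mann-whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison("mann-whitney", float(res.statistic),
                               float(res.pvalue), groups)
    if test == "t":
        res = sps.ttest_ind(a, b, equal_var=False)
        return GroupComparison("t", float(res.statistic), float(res.pvalue),
                               groups)
    if test == "anova-tukey":
        return anova_tukey({"control": a, "treated": b})
    raise ValueError(f"unknown test {test!r}")


def anova_tukey(groups: dict) -> GroupComparison:
    """One-way ANOVA across named groups with Tukey HSD pairwise p-values."""
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    f, p = sps.f_oneway(*arrays)
    extra = {}
    if len(arrays) >= 2:
        tk = sps.tukey_hsd(*arrays)
        extra["tukey"] = {
            f"{names[i]} vs {names[j]}": float(tk.pvalue[i, j])
            for i in range(len(names)) for j in range(i + 1, len(names))}
    summaries = {}
    for k, a in zip(names, arrays):
        summaries.update(_summary(k, a))
    return GroupComparison("anova-tukey", float(f), float(p), summaries, extra)


# ---------------------------------------------------------------------------

def memory_analysis(tracks, records, mother_generation: int | None = None,
                    ) -> MemoryResult:
    """Does a mother's expression state carry over to her daughters?

    Builds the 2x2 mother-state x daughter-state table over all recovered
    divisions (optionally restricted to mothers of one generation depth),
    tests the association with a chi-square test (Fisher's exact when any
    expected cell is below 5), and compares daughter expression spans by
    mother state with a rank-sum test.
    """
    by_id = {t.track_id: t for t in tracks}

    def depth(t):
        d = 0
        while t.mother_track_id is not None and t.mother_track_id in by_id:
            t = by_id[t.mother_track_id]
            d += 1
        return d

    expressed = {r.track_id: True for r in records if r.expressed}
    spans = {r.track_id: r.span_s for r in records}
    table = np.zeros((2, 2), dtype=int)     # [mother on/off, daughter on/off]
    spans_on, spans_off = [], []
    for t in tracks:
        if t.daughters is None:
            continue
        if mother_generation is not None and depth(t) != mother_generation:
            continue
        m_on = expressed.get(t.track_id, False)
        for d in t.daughters:
            if d not in by_id:
                continue
            d_on = expressed.get(d, False)
            table[0 if m_on else 1, 0 if d_on else 1] += 1
            if d_on:
                (spans_on if m_on else spans_off).append(spans[d])
    if table.sum() == 0:
        return MemoryResult(table, "none", float("nan"), float("nan"), None,
                            valid=False, note="no divisions across boundary")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return MemoryResult(table, "none", float("nan"), float("nan"), None,
                            valid=False, note="degenerate margin")
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if (expected < 5).any():
        odds, p = sps.fisher_exact(table)
        test, stat = "fisher", float(odds)
    else:
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        test, stat = "chi-square", float(chi2)
    span_cmp = None
    if len(spans_on) >= 2 and len(spans_off) >= 2:
        res = sps.mannwhitneyu(spans_on, spans_off, alternative="two-sided")
        span_cmp = GroupComparison(
            "mann-whitney", float(res.statistic), float(res.pvalue),
            {**_summary("mother_on", spans_on),
             **_summary("mother_off", spans_off)})
    return MemoryResult(table, test, stat, float(p), span_cmp)


# ---------------------------------------------------------------------------

def ploidy_comparison(counts_diploid, counts_tetraploid,
                      onsets_diploid=None, onsets_tetraploid=None) -> dict:
    """Compare foci-count distributions (and optionally onset times)
    between diploid and tetraploid embryos.

    Returns modal counts, their ratio, a rank-sum comparison of the count
    distributions, and — when onset times are given — a rank-sum
    comparison of expression onset times.
    """
    a = np.asarray(list(counts_diploid), dtype=float)
    b = np.asarray(list(counts_tetraploid), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both ploidy groups must be non-empty")
    mode_a = float(sps.mode(a, keepdims=False).mode)
    mode_b = float(sps.mode(b, keepdims=False).mode)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    out = {
        "modal_count_diploid": mode_a,
        "modal_count_tetraploid": mode_b,
        "modal_ratio": mode_b / mode_a if mode_a else float("nan"),
        "count_comparison": GroupComparison(
            "mann-whitney", float(res.statistic), float(res.pvalue),
            {**_summary("diploid", a), **_summary("tetraploid", b)}),
    }
    if onsets_diploid is not None and onsets_tetraploid is not None \
            and len(onsets_diploid) >= 2 and len(onsets_tetraploid) >= 2:
        r2 = sps.mannwhitneyu(np.asarray(onsets_diploid, dtype=float),
                              np.asarray(onsets_tetraploid, dtype=float),
                              alternative="two-sided")
        out["onset_comparison"] = GroupComparison(
            "mann-whitney", float(r2.statistic), float(r2.pvalue),
            {**_summary("diploid", onsets_diploid),
             **_summary("tetraploid", onsets_tetraploid)})
    return out
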