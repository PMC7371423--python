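"""Hypothesis-testing conventions used throughout: two-tailed rank tests,
exact for small samples, with Bonferroni correction across groups."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from fiberlearn.io import PhotometrySession, TrialTable, ValidationError
from fiberlearn.photometry import phase_mask, window_response

ALPHA = 0.05
EXACT_MAX_N = 8


@dataclass
class TestResult:
    statistic: float
    p: float
    two_tailed: bool
    n_a: int
    n_b: int
    direction: int  # sign of the median difference (a - b)
    test: str = ""

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def rank_sum(a, b) -> TestResult:
    """Two-tailed Wilcoxon-Mann-Whitney test between two independent
    samples; exact enumeration for min(n) <= 8 without ties, normal
    approximation (tie-corrected) otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        two_tailed=True,
        n_a=int(a.size),
        n_b=int(b.size),
        direction=int(np.sign(np.median(a) - np.median(b))),
        test="rank_sum",
    )


def signed_rank(x, y=None) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test of paired differences (or of a
    single sample against zero).  Zero differences are dropped; when all
    differences are zero, p = 1."""
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if y is not None and len(x) != len(np.asarray(y)):
        raise ValidationError("paired samples must have equal length")
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(0.0, 1.0, True, int(d.size), int(d.size), 0, "signed_rank")
    method = "exact" if nz.size <= 25 and len(np.unique(np.abs(nz))) == nz.size else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method, zero_method="wilcox")
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        two_tailed=True,
        n_a=int(d.size),
        n_b=int(d.size),
        direction=int(np.sign(np.median(nz))),
        test="signed_rank",
    )


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni multiple-group correction: p * m clipped to 1 (never
    decreases any p-value)."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0)


def per_mouse_choice_test(
    session: PhotometrySession,
    table: TrialTable,
    phase: str,
    window_s: tuple[float, float],
    min_trials: int = 40,
) -> TestResult | None:
    """Rank-sum test of hit vs miss windowed responses within a phase for
    one mouse; None ("not available") when either class has fewer than
    ``min_trials`` trials."""
    pm = phase_mask(table.n_trials, phase)
    resp = window_response(session, window_s)
    hit = resp[pm & (table.outcome == "hit")]
    miss = resp[pm & (table.outcome == "miss")]
    if hit.size < min_trials or miss.size < min_trials:
        return None
    return rank_sum(hit, miss)
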