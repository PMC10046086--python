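"""Checks for unintended selection during mutation accumulation.

Under neutral accumulation the fraction of non-synonymous SNVs among coding
SNVs and the fraction of genic SNVs among all SNVs should match their
mutational-opportunity expectations (0.76 and 0.74 for the yeast nuclear
genome), and SNV counts should scale linearly with chromosome length.
Departures from either pattern would indicate selection or calling bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Neutral-expectation constants for the yeast nuclear genome (literature
#: values, used as configuration, not recomputed from the annotation).
EXPECTED_NONSYN_FRACTION = 0.76
EXPECTED_GENIC_FRACTION = 0.74


@dataclass
class NeutralityResult:
    """Exact test of an observed fraction against a neutral expectation."""

    count: int
    total: int
    observed_fraction: float
    expected_fraction: float
    p_value: float
    method: str

    def summary(self) -> str:
        return (
            f"Neutral-fraction test ({self.method}): "
            f"{self.count}/{self.total} = {self.observed_fraction:.3f} "
            f"vs expected {self.expected_fraction:.2f}, "
            f"two-sided p = {self.p_value:.4g}"
        )


def neutral_fraction_test(
    count: int, total: int, expected: float, method: str = "binomial"
) -> NeutralityResult:
    """Two-sided exact test of count/total against an expected fraction.

    ``method='binomial'`` (default) is an exact binomial test. With
    ``method='fisher'`` the observed counts (count, total - count) are
    tested in a 2x2 table against the rounded expected counts
    (round(expected * total), total - round(expected * total)).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must be between 0 and total")
    if not 0 < expected < 1:
        raise ValueError("expected fraction must be in (0, 1)")
    if method == "binomial":
        p = float(stats.binomtest(count, total, expected).pvalue)
    elif method == "fisher":
        exp_count = round(expected * total)
        table = [[count, total - count], [exp_count, total - exp_count]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        p = float(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    return NeutralityResult(
        count=count,
        total=total,
        observed_fraction=count / total,
        expected_fraction=expected,
        p_value=p,
        method=method,
    )


@dataclass
class ChromRegression:
    """OLS of per-chromosome SNV counts on chromosome lengths."""

    slope: float
    intercept: float
    r_squared: float | None
    p_value: float | None
    chromosomes: tuple
    counts: tuple
    lengths: tuple
    flagged: str | None = None

    def summary(self) -> str:
        r2 = "undefined" if self.r_squared is None else f"{self.r_squared:.3f}"
        p = "undefined" if self.p_value is None else f"{self.p_value:.4g}"
        note = f"\n  note: {self.flagged}" if self.flagged else ""
        return (
            f"SNV count vs chromosome length regression "
            f"({len(self.chromosomes)} chromosomes)\n"
            f"  slope = {self.slope:.3e} per bp, intercept = {self.intercept:.3f}\n"
            f"  R^2 = {r2}, slope p = {p}" + note
        )


def chromosome_length_regression(
    counts, lengths, chromosomes=None
) -> ChromRegression:
    """Ordinary least squares (with intercept) of SNV counts on lengths.

    Degenerate inputs are reported explicitly: constant nonzero counts give
    slope 0 and R^2 = 0 with p undefined; all-zero counts leave R^2
    undefined and flagged.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape or counts.ndim != 1:
        raise ValueError("counts and lengths must be equal-length vectors")
    if len(counts) < 3:
        raise ValueError("regression needs at least 3 chromosomes")
    if chromosomes is None:
        chromosomes = tuple(f"chr{i + 1}" for i in range(len(counts)))
    if np.ptp(counts) == 0:
        if np.all(counts == 0):
            return ChromRegression(
                slope=0.0, intercept=0.0, r_squared=None, p_value=None,
                chromosomes=tuple(chromosomes), counts=tuple(counts),
                lengths=tuple(lengths),
                flagged="all counts zero: R^2 undefined",
            )
        return ChromRegression(
            slope=0.0, intercept=float(counts[0]), r_squared=0.0, p_value=None,
            chromosomes=tuple(chromosomes), counts=tuple(counts),
            lengths=tuple(lengths),
            flagged="counts constant across chromosomes: slope p undefined",
        )
    res = stats.linregress(lengths, counts)
    return ChromRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        chromosomes=tuple(chromosomes),
        counts=tuple(counts),
        lengths=tuple(lengths),
    )
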