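"""Per-base per-generation mutation rate estimation and strain comparison.

In a mutation accumulation experiment with m_i de novo mutations observed in
replicate i after T generations over L callable bases, the replicate rate is

    mu_i = m_i / (L * T)

and the strain rate is the arithmetic mean of the replicate rates, with its
standard error over replicates. The pooled estimate sum(m_i) / (r * L * T)
is reported alongside (identical to the mean when all replicates share L and
T). Strains are compared with a Welch two-sample t-test on the replicate
rates plus the fold change of the strain means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class RateEstimate:
    """Fitted mutation rate for one strain x variant class x compartment."""

    strain_id: str
    var_class: str
    compartment: str
    per_replicate_rates: tuple
    counts: tuple
    mean_rate: float
    standard_error: float | None
    pooled_rate: float
    callable_length: int
    generations: int
    replicates_used: tuple

    def summary(self) -> str:
        lines = [
            f"Mutation rate estimate: {self.strain_id} "
            f"[{self.var_class}, {self.compartment}]",
            f"  callable length L = {self.callable_length:,} bp, "
            f"generations T = {self.generations}",
            f"  replicates ({len(self.replicates_used)}): "
            + ", ".join(
                f"{r}={m}" for r, m in zip(self.replicates_used, self.counts)
            ),
            f"  mean rate  = {self.mean_rate:.3e} per base per generation",
            f"  std error  = "
            + (f"{self.standard_error:.3e}" if self.standard_error is not None else "n/a (single replicate)"),
            f"  pooled rate = {self.pooled_rate:.3e}",
        ]
        return "\n".join(lines)


class MutationRateModel:
    """Per-base per-generation rate model for one strain.

    Parameters
    ----------
    counts_per_replicate
        De novo mutation counts m_i, one per retained replicate.
    callable_length
        Callable bases L of the relevant compartment (reference length
        minus excluded regions).
    generations
        Total cell divisions T over the propagation.
    """

    def __init__(
        self,
        counts_per_replicate,
        callable_length: int,
        generations: int,
        *,
        strain_id: str = "strain",
        var_class: str = "SNV",
        compartment: str = "nuclear",
        replicate_ids=None,
    ):
        counts = [int(c) for c in counts_per_replicate]
        if not counts:
            raise ValueError("no replicate counts supplied")
        if any(c < 0 for c in counts):
            raise ValueError("mutation counts must be >= 0")
        if callable_length <= 0 or generations <= 0:
            raise ValueError("callable_length and generations must be positive")
        self.counts = counts
        self.callable_length = int(callable_length)
        self.generations = int(generations)
        self.strain_id = strain_id
        self.var_class = var_class
        self.compartment = compartment
        self.replicate_ids = (
            list(replicate_ids)
            if replicate_ids is not None
            else [f"r{i + 1}" for i in range(len(counts))]
        )
        if len(self.replicate_ids) != len(counts):
            raise ValueError("one replicate id per count required")

    def fit(self) -> RateEstimate:
        denom = self.callable_length * self.generations
        rates = np.array([c / denom for c in self.counts])
        r = len(rates)
        se = float(rates.std(ddof=1) / math.sqrt(r)) if r > 1 else None
        return RateEstimate(
            strain_id=self.strain_id,
            var_class=self.var_class,
            compartment=self.compartment,
            per_replicate_rates=tuple(float(x) for x in rates),
            counts=tuple(self.counts),
            mean_rate=float(rates.mean()),
            standard_error=se,
            pooled_rate=float(sum(self.counts) / (r * denom)),
            callable_length=self.callable_length,
            generations=self.generations,
            replicates_used=tuple(self.replicate_ids),
        )


def estimate_rate(
    counts_per_replicate, callable_length: int, generations: int, **kwargs
) -> RateEstimate:
    """Functional wrapper around :class:`MutationRateModel`."""
    return MutationRateModel(
        counts_per_replicate, callable_length, generations, **kwargs
    ).fit()


@dataclass
class RateComparison:
    """Fold change and Welch t-test between two strains' rates."""

    strain_a: str
    strain_b: str
    fold_change: float | None
    t_statistic: float
    p_value: float
    flagged: str | None = None

    def summary(self) -> str:
        fold = "undefined" if self.fold_change is None else f"{self.fold_change:.3f}"
        note = f"  note: {self.flagged}\n" if self.flagged else ""
        return (
            f"Rate comparison {self.strain_a} vs {self.strain_b}\n"
            f"  fold change = {fold}\n"
            f"  Welch t = {self.t_statistic:.4f}, two-sided p = {self.p_value:.4g}\n"
            + note
        ).rstrip()


def compare_rates(estimate_a: RateEstimate, estimate_b: RateEstimate) -> RateComparison:
    """Fold change (mean_a / mean_b) and Welch two-sample t-test on the
    per-replicate rates. Requires >= 2 replicates on each side.

    Degenerate inputs are handled explicitly: when both replicate vectors
    have zero variance the p-value is 1.0 if the means agree and 0.0
    otherwise; a zero denominator mean leaves the fold change undefined and
    flagged.
    """
    a = np.asarray(estimate_a.per_replicate_rates)
    b = np.asarray(estimate_b.per_replicate_rates)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("rate comparison needs >= 2 replicates per strain")
    flagged = None
    if estimate_b.mean_rate == 0:
        fold = None
        flagged = "fold change undefined: comparison strain mean rate is 0"
    else:
        fold = float(estimate_a.mean_rate / estimate_b.mean_rate)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        equal = math.isclose(a.mean(), b.mean(), rel_tol=1e-12, abs_tol=0.0) or (
            a.mean() == b.mean()
        )
        t, p = (0.0, 1.0) if equal else (math.inf, 0.0)
    else:
        import warnings

        with warnings.catch_warnings():
            # near-constant replicate vectors trip scipy's precision-loss
            # warning; zero-variance cases are handled explicitly above
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(t), float(p)
    return RateComparison(
        strain_a=estimate_a.strain_id,
        strain_b=estimate_b.strain_id,
        fold_change=fold,
        t_statistic=t,
        p_value=p,
        flagged=flagged,
    )
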