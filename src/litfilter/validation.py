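"""Diagnostic-accuracy evaluation of search filters.

A filter applied to a labeled corpus yields a 2×2 table: relevant articles
retrieved (tp) or missed (fn), non-relevant articles retrieved (fp) or not
(tn).  Sensitivity tp/(tp+fn), specificity tn/(fp+tn) and precision
tp/(tp+fp) are reported with exact (Clopper–Pearson) binomial confidence
intervals, obtained by inverting the binomial tails through beta quantiles;
these intervals are conservative (coverage at least nominal).  Display forms
round half-up to integer percent, matching how filter performance tables are
conventionally printed.

Also here: the normal-approximation sample-size formula for validating a
filter to a target sensitivity within a CI half-width,
``n = ceil(z² p (1−p) / d²)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from scipy import stats as sps

from ._util import round_half_up
from .corpus_io import Article, CorpusError, LabeledCorpus, Relevance
from .query_engine import QueryNode, retrieve


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class BinomialCI:
    """An exact binomial confidence interval for x successes in n trials."""

    x: int
    n: int
    level: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.x <= self.n):
            raise ValidationError("need 0 <= x <= n")
        if not (0.0 <= self.lo <= self.x / self.n <= self.hi <= 1.0):
            raise ValidationError("CI bounds must bracket the point estimate within [0, 1]")

    @property
    def point(self) -> float:
        return self.x / self.n

    def display(self, decimals: int = 0) -> str:
        fmt = lambda v: f"{round_half_up(100.0 * v, decimals):.{decimals}f}"
        return f"{fmt(self.point)} ({fmt(self.lo)}-{fmt(self.hi)})"


def clopper_pearson(x: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact binomial CI via inverted incomplete-beta tails.

    lower = Beta(alpha/2; x, n−x+1) quantile (0 when x=0);
    upper = Beta(1−alpha/2; x+1, n−x) quantile (1 when x=n).
    """
    if n < 1 or not (0 <= x <= n):
        raise ValidationError(f"invalid binomial counts x={x}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must lie in (0, 1)")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2.0, x, n - x + 1))
    hi = 1.0 if x == n else float(sps.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return BinomialCI(x=x, n=n, level=level, lo=lo, hi=hi)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n_relevant(self) -> int:
        return self.tp + self.fn

    @property
    def n_non_relevant(self) -> int:
        return self.fp + self.tn

    @property
    def n_retrieved(self) -> int:
        return self.tp + self.fp


def display_percent(fraction: float, decimals: int = 0) -> float:
    """Percent display value, rounded half-up (92 for 0.9200; 0.94 for 0.00944)."""
    return round_half_up(100.0 * fraction, decimals)


@dataclass(frozen=True)
class PerformanceReport:
    """Sensitivity/specificity/precision with exact CIs and display forms.

    ``precision`` is ``None`` (flagged ``precision_undefined``) when the
    filter retrieves nothing; missed relevant article ids are listed so they
    can be inspected for shared features (e.g. absent abstracts).
    """

    counts: ConfusionCounts
    sensitivity: BinomialCI
    specificity: BinomialCI
    precision: Optional[BinomialCI]
    missed_relevant_ids: tuple[str, ...] = ()

    @property
    def precision_undefined(self) -> bool:
        return self.precision is None

    def display(self, decimals: int = 0) -> dict[str, Optional[float]]:
        out = {
            "sensitivity": display_percent(self.sensitivity.point, decimals),
            "sensitivity_lo": display_percent(self.sensitivity.lo, decimals),
            "sensitivity_hi": display_percent(self.sensitivity.hi, decimals),
            "specificity": display_percent(self.specificity.point, decimals),
            "specificity_lo": display_percent(self.specificity.lo, decimals),
            "specificity_hi": display_percent(self.specificity.hi, decimals),
        }
        if self.precision is None:
            out.update(precision=None, precision_lo=None, precision_hi=None)
        else:
            out.update(
                precision=display_percent(self.precision.point, decimals),
                precision_lo=display_percent(self.precision.lo, decimals),
                precision_hi=display_percent(self.precision.hi, decimals),
            )
        return out


def performance_from_counts(
    counts: ConfusionCounts,
    level: float = 0.95,
    missed_relevant_ids: Sequence[str] = (),
) -> PerformanceReport:
    """Build a full report from a 2×2 table (metrics recompute exactly)."""
    if counts.n_relevant == 0 or counts.n_non_relevant == 0:
        raise ValidationError("both relevance classes must be non-empty")
    sens = clopper_pearson(counts.tp, counts.n_relevant, level)
    spec = clopper_pearson(counts.tn, counts.n_non_relevant, level)
    prec = (
        clopper_pearson(counts.tp, counts.n_retrieved, level)
        if counts.n_retrieved > 0
        else None
    )
    return PerformanceReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        missed_relevant_ids=tuple(missed_relevant_ids),
    )


def evaluate_filter(
    node: QueryNode, corpus: LabeledCorpus, level: float = 0.95
) -> PerformanceReport:
    """Run the filter on a fully labeled corpus and report its accuracy."""
    if any(a.relevance is Relevance.UNLABELED for a in corpus):
        raise ValidationError("evaluate_filter requires a fully labeled corpus")
    n_rel, n_non = corpus.n_relevant, corpus.n_non_relevant
    if n_rel == 0 or n_non == 0:
        raise ValidationError("both relevance classes must be present in the corpus")
    result = retrieve(node, corpus)
    tp = result.n_relevant
    fp = result.n_non_relevant
    counts = ConfusionCounts(tp=tp, fn=n_rel - tp, fp=fp, tn=n_non - fp)
    missed = tuple(
        a.id
        for a in corpus
        if a.relevance is Relevance.RELEVANT and a.id not in result.ids
    )
    return performance_from_counts(counts, level=level, missed_relevant_ids=missed)


def subgroup_sensitivity(
    node: QueryNode,
    corpus: LabeledCorpus,
    predicate: Callable[[Article], bool],
    level: float = 0.95,
) -> BinomialCI:
    """Sensitivity restricted to relevant articles satisfying ``predicate``
    (e.g. original articles only: ``lambda a: a.pub_type is PubType.ARTICLE``)."""
    subgroup = [
        a for a in corpus if a.relevance is Relevance.RELEVANT and predicate(a)
    ]
    if not subgroup:
        raise ValidationError("subgroup contains no relevant articles")
    sub_corpus = LabeledCorpus(tuple(subgroup))
    hits = retrieve(node, sub_corpus)
    return clopper_pearson(len(hits.ids), len(subgroup), level)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Required validation-set size for estimating a sensitivity ``p`` to a
    CI half-width ``d`` at the given confidence level."""

    p: float
    d: float
    level: float
    z: float
    n: int


def sample_size(p: float, d: float, level: float = 0.95) -> SampleSizeSpec:
    """``n = ceil(z² p (1−p) / d²)`` with z the two-sided normal quantile."""
    if not 0.0 < p < 1.0:
        raise ValidationError("anticipated sensitivity p must lie strictly in (0, 1)")
    if d <= 0.0:
        raise ValidationError("half-width d must be positive")
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must lie in (0, 1)")
    z = float(sps.norm.ppf(1.0 - (1.0 - level) / 2.0))
    n = math.ceil(z * z * p * (1.0 - p) / (d * d))
    return SampleSizeSpec(p=p, d=d, level=level, z=z, n=max(n, 1))
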