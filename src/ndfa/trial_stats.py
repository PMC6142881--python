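"""Field-trial statistics: balanced factorial ANOVA, Duncan's MRT, correlation.

The ANOVA is the classical fixed-effects decomposition for balanced full or
additive factorial designs (Type I = Type III under balance): each term's sum
of squares is the replication-weighted squared deviation of its marginal
means from the grand mean, minus the sums of squares of all its sub-terms.
Duncan's multiple range test uses studentized-range quantiles at the
span-dependent protection level α_p = 1 − (1 − α)^(p−1).

Unbalanced data are rejected outright: the sums-of-squares decomposition
implemented here is exact only under balance, and approximations for
unbalanced designs are method-dependent.
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "UnbalancedDesignError",
    "DegenerateDataError",
    "FactorialDataset",
    "AnovaTable",
    "LetterGrouping",
    "factorial_anova",
    "duncan_critical_ranges",
    "duncan_mrt",
    "pearson_correlation",
    "linear_regression",
]


class UnbalancedDesignError(ValueError):
    """The design is not balanced; this ANOVA decomposition does not apply."""


class DegenerateDataError(ValueError):
    """Data admit no answer (zero variance, empty design, no residual df...)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FactorialDataset:
    """A response vector with one categorical factor label per observation."""

    response: np.ndarray
    factors: dict[str, np.ndarray]

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, response: str, factors: Sequence[str]
    ) -> "FactorialDataset":
        y = frame[response].to_numpy(dtype=float)
        return cls(response=y, factors={f: frame[f].to_numpy() for f in factors})

    def __post_init__(self) -> None:
        n = len(self.response)
        if n == 0:
            raise DegenerateDataError("empty dataset")
        if np.isnan(self.response).any():
            raise DegenerateDataError("missing responses are not supported")
        for name, labels in self.factors.items():
            if len(labels) != n:
                raise ValueError(f"factor {name!r} length mismatch")

    @property
    def is_balanced(self) -> bool:
        """True when every full factor-level combination has equal replication."""
        key = list(zip(*self.factors.values()))
        counts = pd.Series(key).value_counts()
        n_levels = math.prod(len(np.unique(v)) for v in self.factors.values())
        return len(counts) == n_levels and counts.nunique() == 1


@dataclass(frozen=True)
class AnovaTable:
    """Per-term df, SS, MS, F and p, plus the residual row.

    ``table`` is indexed by term label ("landrace", "landrace:inoculation",
    ..., "Residual") with columns df, sum_sq, mean_sq, F, p. Infinite F with
    p = 0 marks a zero-residual-variance fit.
    """

    table: pd.DataFrame

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    @property
    def terms(self) -> list[str]:
        return [t for t in self.table.index if t != "Residual"]

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


@dataclass(frozen=True)
class LetterGrouping:
    """Duncan letter display: per level its mean, SE and letter string.

    Levels are ordered by descending mean; two levels share a letter iff the
    test finds them not significantly different.
    """

    levels: tuple[str, ...]
    means: tuple[float, ...]
    se: float
    letters: tuple[str, ...]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.levels, self.letters))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.means, "se": self.se, "letters": self.letters},
            index=pd.Index(self.levels, name="level"),
        )


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def _term_label(term: tuple[str, ...]) -> str:
    return ":".join(term)


def factorial_anova(
    data: FactorialDataset,
    model: Sequence[Sequence[str]] | None = None,
) -> AnovaTable:
    """Balanced fixed-effects factorial ANOVA.

    Parameters
    ----------
    data
        Balanced factorial observations.
    model
        Terms to fit, each a sequence of factor names (main effects are
        1-tuples, interactions longer). Default: the full factorial model —
        every non-empty subset of the factors.

    Raises
    ------
    UnbalancedDesignError
        If any factor-level combination is missing or unequally replicated.
    DegenerateDataError
        If the residual has zero degrees of freedom.
    """
    if not data.is_balanced:
        raise UnbalancedDesignError(
            "unequal replication across factor-level combinations; "
            "only balanced designs are supported"
        )
    names = list(data.factors)
    if model is None:
        model = [
            c for r in range(1, len(names) + 1) for c in itertools.combinations(names, r)
        ]
    model = [tuple(t) for t in model]
    for term in model:
        unknown = set(term) - set(names)
        if unknown:
            raise ValueError(f"unknown factors in model term {term}: {unknown}")

    y = data.response
    n = len(y)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    levels = {f: len(np.unique(v)) for f, v in data.factors.items()}

    frame = pd.DataFrame(data.factors)
    frame["__y__"] = y

    # SS of every subset term is needed to peel sub-effects off interactions.
    needed: set[tuple[str, ...]] = set()
    for term in model:
        for r in range(1, len(term) + 1):
            needed.update(itertools.combinations(term, r))

    ss_raw: dict[tuple[str, ...], float] = {}
    for term in needed:
        g = frame.groupby(list(term), observed=True)["__y__"]
        ss_raw[term] = float((g.count() * (g.mean() - grand) ** 2).sum())

    ss: dict[tuple[str, ...], float] = {}
    for term in sorted(needed, key=len):
        sub = sum(
            ss[s]
            for r in range(1, len(term))
            for s in itertools.combinations(term, r)
        )
        ss[term] = ss_raw[term] - sub

    rows = []
    df_model = 0
    ss_model = 0.0
    for term in model:
        df_t = math.prod(levels[f] - 1 for f in term)
        rows.append((_term_label(term), df_t, ss[term]))
        df_model += df_t
        ss_model += ss[term]

    df_res = n - 1 - df_model
    if df_res <= 0:
        raise DegenerateDataError(
            f"no residual degrees of freedom (n={n}, model df={df_model}); "
            "replicate the design or drop terms"
        )
    ss_res = max(ss_total - ss_model, 0.0)
    ms_res = ss_res / df_res

    out = []
    for label, df_t, ss_t in rows:
        ms_t = ss_t / df_t
        if ms_res > 0:
            f_stat = ms_t / ms_res
            p = float(sps.f.sf(f_stat, df_t, df_res))
        else:
            # Zero residual variance: any effect is infinitely significant.
            f_stat, p = math.inf, 0.0
        out.append((label, df_t, ss_t, ms_t, f_stat, p))
    out.append(("Residual", df_res, ss_res, ms_res, math.nan, math.nan))

    table = pd.DataFrame(
        out, columns=["term", "df", "sum_sq", "mean_sq", "F", "p"]
    ).set_index("term")
    return AnovaTable(table=table)


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4096)
def _studentized_range_quantile(upper_tail: float, p: int, df: int) -> float:
    # the same (span, df) pairs recur for every response/site; ppf is costly
    return float(sps.studentized_range.ppf(1.0 - upper_tail, p, df))


def duncan_critical_ranges(
    k: int, ms_error: float, df_error: int, n_per_level: int, alpha: float = 0.05
) -> dict[int, float]:
    """Critical range R_p for each span p = 2..k.

    R_p = q(1 − α_p; p, df) × sqrt(MS_error / n), with the Duncan protection
    level α_p = 1 − (1 − α)^(p−1). Quantiles come from the studentized-range
    distribution computed numerically.
    """
    if df_error < 1:
        raise DegenerateDataError("df_error must be >= 1")
    if ms_error < 0:
        raise ValueError("ms_error cannot be negative")
    se = math.sqrt(ms_error / n_per_level)
    ranges: dict[int, float] = {}
    for p in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        ranges[p] = _studentized_range_quantile(alpha_p, p, df_error) * se
    return ranges


def duncan_mrt(
    means: Mapping[str, float],
    n_per_level: int,
    ms_error: float,
    df_error: int,
    alpha: float = 0.05,
) -> LetterGrouping:
    """Duncan's multiple range test with compact-letter display.

    Levels are sorted by descending mean. A contiguous span of p ordered
    means is homogeneous when its range does not exceed R_p; maximal
    homogeneous spans each receive one letter, and every level's string is
    the set of letters of the spans covering it. With ms_error = 0, tied
    means share a letter and distinct means are all separated.
    """
    if not means:
        raise DegenerateDataError("no level means supplied")
    order = sorted(means, key=lambda lvl: (-means[lvl], str(lvl)))
    m = [float(means[lvl]) for lvl in order]
    k = len(m)
    se = math.sqrt(ms_error / n_per_level)
    if k == 1:
        return LetterGrouping(tuple(order), tuple(m), se, ("a",))

    ranges = duncan_critical_ranges(k, ms_error, df_error, n_per_level, alpha)

    # Every contiguous span is tested against its own critical range; spans
    # contained in a homogeneous span are homogeneous by protection, so the
    # letter display only needs the maximal passing spans.
    spans: list[tuple[int, int]] = []
    for i in range(k):
        best = i
        for j in range(i + 1, k):
            if m[i] - m[j] <= ranges[j - i + 1]:
                best = j
        spans.append((i, best))
    maximal = [
        (i, j)
        for (i, j) in spans
        if not any((a <= i and j <= b) and (a, b) != (i, j) for a, b in spans)
    ]
    maximal.sort()

    alphabet = string.ascii_lowercase
    letters = ["" for _ in range(k)]
    for idx, (a, b) in enumerate(maximal):
        letter = (
            alphabet[idx]
            if idx < len(alphabet)
            else alphabet[idx // 26 - 1] + alphabet[idx % 26]
        )
        for pos in range(a, b + 1):
            letters[pos] += letter
    return LetterGrouping(tuple(order), tuple(m), se, tuple(letters))


# ---------------------------------------------------------------------------
# Correlation and regression
# ---------------------------------------------------------------------------


def _validate_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise DegenerateDataError("need at least 3 paired observations")
    return x, y


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value (t on n−2 df)."""
    x, y = _validate_pair(x, y)
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateDataError("zero variance; correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def linear_regression(x, y) -> tuple[float, float, float]:
    """Ordinary least-squares line: (slope, intercept, r²)."""
    x, y = _validate_pair(x, y)
    if np.var(x) == 0:
        raise DegenerateDataError("x has zero variance; slope undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
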