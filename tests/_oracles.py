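"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle recomputes a quantity by the most literal route available —
observation-level mean decomposition for ANOVA sums of squares, an
all-spans sweep for Duncan letters, an every-(start, unit) scan for SSRs —
and stays independent of the library code paths it checks.
"""

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from ndfa.ssr import DEFAULT_MIN_REPEATS, SsrHit


def anova_ss_oracle(frame: pd.DataFrame, response: str, factors: list[str]) -> dict:
    """Brute-force observation-level mean decomposition.

    For each term, fit the inclusion–exclusion combination of marginal means
    at every observation and sum its squares — an independent route to the
    sums of squares of a balanced full-factorial design.
    """
    y = frame[response].to_numpy(float)
    grand = y.mean()
    ss = {}
    for r in range(1, len(factors) + 1):
        for term in itertools.combinations(factors, r):
            effects = np.zeros(len(y))
            for i in range(len(y)):
                total = 0.0
                # inclusion-exclusion over subsets of the term (incl. empty)
                for k in range(len(term) + 1):
                    for sub in itertools.combinations(term, k):
                        if not sub:
                            contrib = grand
                        else:
                            mask = np.ones(len(y), bool)
                            for f in sub:
                                mask &= (frame[f] == frame[f].iloc[i]).to_numpy()
                            contrib = y[mask].mean()
                        total += (-1) ** (len(term) - len(sub)) * contrib
                effects[i] = total
            ss[":".join(term)] = float((effects**2).sum())
    return ss


def duncan_oracle(means: dict, n: int, ms_error: float, df_error: int, alpha: float):
    """All-spans Duncan oracle: test every contiguous span of ordered means
    against its own critical range; letters come from maximal passing spans."""
    order = sorted(means, key=lambda k: (-means[k], str(k)))
    m = [means[k] for k in order]
    k = len(m)
    passing = []
    for i in range(k):
        for j in range(i, k):
            p = j - i + 1
            if p == 1:
                passing.append((i, j))
                continue
            alpha_p = 1 - (1 - alpha) ** (p - 1)
            r_p = sps.studentized_range.ppf(1 - alpha_p, p, df_error) * math.sqrt(
                ms_error / n
            )
            if m[i] - m[j] <= r_p:
                passing.append((i, j))
    maximal = [
        s for s in passing
        if not any(o != s and o[0] <= s[0] and s[1] <= o[1] for o in passing)
    ]
    return {frozenset(order[a : b + 1]) for a, b in sorted(maximal)}


def grouping_as_sets(grouping):
    """Convert a letter display back into the set of letter groups."""
    by_letter: dict[str, set] = {}
    for level, letters in zip(grouping.levels, grouping.letters):
        for ch in letters:
            by_letter.setdefault(ch, set()).add(level)
    return {frozenset(v) for v in by_letter.values()}


def scan_oracle(bases: str, min_repeats=DEFAULT_MIN_REPEATS) -> list[SsrHit]:
    """Test every (start, unit) pair independently: count exact unit copies
    rightward, keep maximal primitive runs above threshold, then drop
    overlapping runs in favor of the longer one."""
    runs = []
    n = len(bases)
    for unit in range(1, 7):
        for start in range(n - unit + 1):
            motif = bases[start : start + unit]
            if set(motif) - set("ACGT"):
                continue
            if any(motif == motif[:d] * (unit // d) for d in range(1, unit) if unit % d == 0):
                continue
            if start >= unit and bases[start - unit : start] == motif:
                continue
            count = 0
            while bases[start + count * unit : start + (count + 1) * unit] == motif:
                count += 1
            if count >= min_repeats[unit]:
                runs.append(SsrHit(motif, count, start + 1, start + count * unit))
    runs.sort(key=lambda h: (-(h.end - h.start + 1), h.start, len(h.motif)))
    kept = []
    for run in runs:
        if all(run.end < k.start or run.start > k.end for k in kept):
            kept.append(run)
    return sorted(kept, key=lambda h: (h.start, h.end))
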