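"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately use plain Python loops and none of the package's numerical
routines, so agreement with the implementation is a genuine cross-check.
"""

import math
from collections import defaultdict


def ks_oracle(epi, mes):
    """Signed two-sample KS statistic by exhaustive ECDF enumeration."""
    epi, mes = list(epi), list(mes)
    pooled = sorted(set(epi) | set(mes))
    d_plus = d_minus = 0.0
    for x in pooled:
        fe = sum(1 for v in epi if v <= x) / len(epi)
        fm = sum(1 for v in mes if v <= x) / len(mes)
        d_plus = max(d_plus, fe - fm)
        d_minus = max(d_minus, fm - fe)
    if d_plus > d_minus:
        score = d_plus
    elif d_minus > d_plus:
        score = -d_minus
    else:
        positions = defaultdict(list)
        for i, v in enumerate(sorted(epi + mes), start=1):
            positions[v].append(i)
        rank = {v: sum(p) / len(p) for v, p in positions.items()}
        mean_epi = sum(rank[v] for v in epi) / len(epi)
        mean_mes = sum(rank[v] for v in mes) / len(mes)
        if mean_mes > mean_epi:
            score = d_plus
        elif mean_epi > mean_mes:
            score = -d_minus
        else:
            score = 0.0
    return score, d_plus, d_minus


def cutpoint_oracle(marker, outcome):
    """Exhaustive search over midpoint/sentinel thresholds.

    Returns (threshold, sensitivity, specificity, distance) under the same
    tie rules as the implementation: min distance, then max Youden index,
    then min threshold.
    """
    marker, outcome = list(marker), list(outcome)
    u = sorted(set(marker))
    candidates = [u[0] - 1.0]
    candidates += [(a + b) / 2.0 for a, b in zip(u, u[1:])]
    candidates += [u[-1] + 1.0]
    n_pos = sum(1 for o in outcome if o == 1)
    n_neg = len(outcome) - n_pos
    best_key, best = None, None
    for t in candidates:
        tp = sum(1 for m, o in zip(marker, outcome) if o == 1 and m >= t)
        tn = sum(1 for m, o in zip(marker, outcome) if o == 0 and m < t)
        sens, spec = tp / n_pos, tn / n_neg
        dist = math.hypot(1.0 - sens, 1.0 - spec)
        key = (dist, -(sens + spec - 1.0), t)
        if best_key is None or key < best_key:
            best_key, best = key, (t, sens, spec, dist)
    return best
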