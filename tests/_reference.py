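"""Plain, loop-based reference implementations used as test oracles.

These deliberately avoid the package's code paths: lag windows are found by
scanning every candidate day, matching is plain greedy search over lists,
and the standardized mean difference is spelled out term by term.
"""

import itertools
import math

import numpy as np
from sklearn.linear_model import LogisticRegression


def enumerate_lag_rows(days_present, direction, T, need_confounders=True):
    """All valid (treatment_day, outcome_day) pairs by exhaustive scan.

    ``days_present`` maps day_index -> dict of available variables (a day
    in the map is assumed complete unless a variable is explicitly absent).
    """
    days = set(days_present)
    rows = []
    for t in sorted(days):
        if direction == "sleep_to_mood":
            outcome_day = t
        else:
            outcome_day = t + 1
            if outcome_day not in days:
                continue
        ok = True
        if need_confounders and (outcome_day - 1) not in days:
            ok = False
        for k in range(1, T + 1):
            if need_confounders and (t - k) not in days:
                ok = False
        if ok:
            rows.append((t, outcome_day))
    return rows


def reference_personal_effect(rows, confounder_names, binary_names=(),
                              caliper=0.2, seed=0, tie="strict"):
    """Straight-line per-subject pipeline: binarize -> logistic propensity
    -> greedy 1:1 caliper matching -> standardized mean difference.

    ``rows`` is a list of dicts with keys ``treatment``, ``outcome`` and
    the confounder names (numeric values only).  Columns named in
    ``confounder_names`` are z-scored; ``binary_names`` (0/1 indicators)
    enter as-is.  Returns (effect, pairs) or (None, reason).
    """
    treat = [r["treatment"] for r in rows]
    mean_t = sum(treat) / len(treat)
    z = [1 if (v > mean_t if tie == "strict" else v >= mean_t) else 0 for v in treat]
    if sum(z) == 0 or sum(z) == len(z):
        return None, "single_class"

    cols = []
    for name in confounder_names:
        vals = [float(r[name]) for r in rows]
        mu = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / len(vals))
        if sd > 1e-9:
            cols.append([(v - mu) / sd for v in vals])
    for name in binary_names:
        vals = [float(r[name]) for r in rows]
        if len(set(vals)) > 1:
            cols.append(vals)
    if cols:
        X = np.array(cols).T
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        clf.fit(X, np.array(z))
        p = clf.predict_proba(X)[:, 1]
    else:
        p = np.full(len(z), sum(z) / len(z))
    p = np.clip(p, 1e-9, 1 - 1e-9)
    logit = [math.log(v / (1 - v)) for v in p]

    sd_logit = float(np.std(logit))
    max_d = caliper * sd_logit if (caliper is not None and sd_logit > 1e-9) else float("inf")
    treated = [i for i, v in enumerate(z) if v == 1]
    controls = [i for i, v in enumerate(z) if v == 0]
    order = np.random.default_rng(seed).permutation(len(treated))
    pairs = []
    for k in order:
        ti = treated[k]
        if not controls:
            break
        best, best_d = None, None
        for ci in controls:
            d = abs(logit[ci] - logit[ti])
            if best_d is None or d < best_d:
                best, best_d = ci, d
        if best_d <= max_d + 1e-9:
            pairs.append((ti, best))
            controls.remove(best)
    if not pairs:
        return None, "no_match"

    yt = [rows[i]["outcome"] for i, _ in pairs]
    yc = [rows[j]["outcome"] for _, j in pairs]
    n1, n0 = len(yt), len(yc)
    m1, m0 = sum(yt) / n1, sum(yc) / n0
    if n1 + n0 <= 2:
        return None, "degenerate_outcome"
    s1 = sum((v - m1) ** 2 for v in yt) / (n1 - 1) if n1 > 1 else 0.0
    s0 = sum((v - m0) ** 2 for v in yc) / (n0 - 1) if n0 > 1 else 0.0
    pooled = math.sqrt(((n1 - 1) * s1 + (n0 - 1) * s0) / (n1 + n0 - 2))
    if pooled <= 0:
        return None, "degenerate_outcome"
    return (m1 - m0) / pooled, sorted(pairs)


def optimal_pair_count(logit_t, logit_c, max_dist):
    """Maximum number of 1:1 pairs within the caliper, by brute force."""
    best = 0
    nt, nc = len(logit_t), len(logit_c)
    k = min(nt, nc)
    for size in range(k, 0, -1):
        for tset in itertools.combinations(range(nt), size):
            for cperm in itertools.permutations(range(nc), size):
                if all(abs(logit_t[i] - logit_c[j]) <= max_dist + 1e-9
                       for i, j in zip(tset, cperm)):
                    return size
    return best
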