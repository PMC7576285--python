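"""Independent brute-force reference implementations used only by tests.

Each oracle applies the defining formula or the literal procedure directly,
with exact rational arithmetic where boundaries matter, and shares no code
with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction

from scipy import stats


def welch_t(a, b):
    """Welch two-sample t from the textbook formula."""
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p


def pearson_r(u, v):
    """Pearson r by direct evaluation of the covariance / sigma-sigma formula."""
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    cov = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    su = math.sqrt(sum((a - mu) ** 2 for a in u))
    sv = math.sqrt(sum((b - mv) ** 2 for b in v))
    return cov / (su * sv)


def product_limit(records):
    """Kaplan-Meier by hand: [(time, S(t), at_risk)] at each event time.

    Deaths precede censorings at tied times, so a record censored exactly at
    an event time still counts in that time's risk set.
    """
    event_times = sorted({t for t, e in records if e == 1})
    s = Fraction(1)
    out = []
    for t in event_times:
        at_risk = sum(1 for ti, _ in records if ti >= t)
        d = sum(1 for ti, ei in records if ti == t and ei == 1)
        s *= 1 - Fraction(d, at_risk)
        out.append((t, s, at_risk))
    return out


def risk_pipeline(expr_tumor, networks, directions,
                  down_frac=Fraction(3, 10), pop_frac=Fraction(1, 2), bounds=(4, 9)):
    """Literal four-step risk procedure with exact rational boundaries.

    ``expr_tumor``: {feature: {patient: value}} over tumor patients only.
    Step 1: per feature, rank patients high-to-low (ties by patient id);
    patients outside the top ``ceil(down_frac * N)`` block carry an
    up-regulated feature as risk, patients inside it carry a down-regulated
    one.  Step 2: count risk features per (patient, population).  Step 3: a
    population is risk when the count exceeds ``pop_frac`` of its features.
    Step 4: group by the risk-population count.
    """
    any_feat = next(iter(expr_tumor))
    patients = sorted(expr_tumor[any_feat])
    n = len(patients)
    k = math.ceil(down_frac * n)  # Fraction * int stays exact

    feature_risk = {}
    for feats in networks.values():
        for f in set(feats):
            ranked = sorted(patients, key=lambda p: (-expr_tumor[f][p], p))
            top = set(ranked[:k])
            if directions[f] == "up":
                feature_risk[f] = set(patients) - top
            else:
                feature_risk[f] = top

    risk_sets = {}
    is_risk = {}
    counts = {p: 0 for p in patients}
    for pop, feats in networks.items():
        feats = set(feats)
        for p in patients:
            held = {f for f in feats if p in feature_risk[f]}
            risk_sets[(p, pop)] = held
            flag = Fraction(len(held), len(feats)) > pop_frac
            is_risk[(p, pop)] = flag
            counts[p] += int(flag)

    groups = {}
    for p, c in counts.items():
        if c <= bounds[0]:
            groups[p] = "min_immune"
        elif c <= bounds[1]:
            groups[p] = "media_immune"
        else:
            groups[p] = "multi_immune"
    return risk_sets, is_risk, counts, groups
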