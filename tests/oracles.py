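"""Independent oracles used only by the test suite.

Each oracle re-derives an expected value through a different route than the
library (hand-written if-chains for the published score charts, bisection on
binomial tail probabilities for the exact interval, a pairwise O(n^2) count
for the Mann-Whitney AUC) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def news_chart(rr: int, spo2: float, on_o2: bool, temp: float, sbp: float,
               hr: float, alert: bool) -> int:
    """2012 NEWS chart, hand-encoded as explicit if-chains."""
    total = 0
    if rr <= 8:
        total += 3
    elif rr <= 11:
        total += 1
    elif rr <= 20:
        total += 0
    elif rr <= 24:
        total += 2
    else:
        total += 3
    if spo2 <= 91:
        total += 3
    elif spo2 <= 93:
        total += 2
    elif spo2 <= 95:
        total += 1
    if on_o2:
        total += 2
    t = round(temp, 1)
    if t <= 35.0:
        total += 3
    elif t <= 36.0:
        total += 1
    elif t <= 38.0:
        total += 0
    elif t <= 39.0:
        total += 1
    else:
        total += 2
    if sbp <= 90:
        total += 3
    elif sbp <= 100:
        total += 2
    elif sbp <= 110:
        total += 1
    elif sbp <= 219:
        total += 0
    else:
        total += 3
    if hr <= 40:
        total += 3
    elif hr <= 50:
        total += 1
    elif hr <= 90:
        total += 0
    elif hr <= 110:
        total += 1
    elif hr <= 130:
        total += 2
    else:
        total += 3
    if not alert:
        total += 3
    return total


def sofa_component_chart(organ: str, value=None, vasopressor: bool = False) -> int:
    """Published SOFA thresholds per organ, hand-encoded."""
    if organ == "respiration":  # value = PaO2/FiO2 mmHg
        if value < 100:
            return 4
        if value < 200:
            return 3
        if value < 300:
            return 2
        if value < 400:
            return 1
        return 0
    if organ == "coagulation":  # platelets 10^9/L
        if value < 20:
            return 4
        if value < 50:
            return 3
        if value < 100:
            return 2
        if value < 150:
            return 1
        return 0
    if organ == "liver":        # bilirubin umol/L
        if value > 204:
            return 4
        if value >= 102:
            return 3
        if value >= 33:
            return 2
        if value >= 20:
            return 1
        return 0
    if organ == "cardiovascular":
        if vasopressor:
            return 2
        return 1 if value < 70 else 0   # value = MAP
    if organ == "cns":          # GCS
        if value < 6:
            return 4
        if value < 10:
            return 3
        if value < 13:
            return 2
        if value < 15:
            return 1
        return 0
    if organ == "renal":        # creatinine umol/L
        if value > 440:
            return 4
        if value >= 300:
            return 3
        if value >= 171:
            return 2
        if value >= 110:
            return 1
        return 0
    raise ValueError(organ)


def clopper_pearson_bisect(k: int, n: int, alpha: float = 0.05,
                           tol: float = 1e-12) -> tuple[float, float]:
    """Exact binomial interval by bisection on the binomial tail equalities."""

    def solve(fn, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if fn(mid):
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    low = 0.0 if k == 0 else solve(lambda p: stats.binom.sf(k - 1, n, p) < alpha / 2, 0.0, 1.0)
    high = 1.0 if k == n else solve(lambda p: stats.binom.cdf(k, n, p) >= alpha / 2, 0.0, 1.0)
    return low, high


def pairwise_auc(scores, labels) -> float:
    """Mann-Whitney AUC by explicit pairwise comparison (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = s[y]
    neg = s[~y]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (pos.size * neg.size)


def classical_permutation_importance(model, n_reps: int, seed: int) -> dict[str, float]:
    """Classical (unconditional) permutation importance, independently coded.

    Mirrors the library's loop order and rng protocol so that, with the same
    seed, equality with the conditioning-disabled path is exact; the AUC and
    permutation mechanics are computed through different code (sklearn's
    roc_auc_score and direct index shuffles).
    """
    from sklearn.metrics import roc_auc_score

    X, y = model.X, model.y
    rng = np.random.default_rng(seed)
    usable = []
    for t, tree in enumerate(model.forest.estimators_):
        oob = model.oob_masks[t]
        y_oob = y[oob]
        if oob.sum() < 2 or y_oob.all() or (~y_oob).all():
            continue
        X_oob = X[oob]
        base = roc_auc_score(y_oob, tree.predict_proba(X_oob)[:, 1])
        usable.append((tree, X_oob, y_oob, base))
    p = X.shape[1]
    out = np.zeros((p, n_reps))
    for j in range(p):
        for tree, X_oob, y_oob, base in usable:
            X_perm = X_oob.copy()
            for r in range(n_reps):
                idx = rng.permutation(X_oob.shape[0])
                X_perm[:, j] = X_oob[idx, j]
                perm = roc_auc_score(y_oob, tree.predict_proba(X_perm)[:, 1])
                out[j, r] += base - perm
    out /= len(usable)
    return {name: float(out[j].mean()) for j, name in enumerate(model.feature_names)}
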