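"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own algorithmic paths: the Viterbi
oracle enumerates every local state path recursively; the metric oracles
work straight off explicit confusion counts.
"""

import math

import numpy as np

from caskit.profiles import AA_INDEX, MM, MI, MD, IM, II, DM, DD


def brute_force_bit_score(model, seq: str) -> float:
    """log2 best local-path odds by exhaustive state-path enumeration."""
    L = model.length
    x = [AA_INDEX.get(c, -1) for c in seq.upper()]
    n = len(x)
    me, ie, bg, t = model.match_emissions, model.insert_emissions, model.background, model.transitions
    best = -math.inf

    def odds_m(j, a):
        return 1.0 if a < 0 else me[j - 1, a] / bg[a]

    def odds_i(j, a):
        return 1.0 if a < 0 else ie[j, a] / bg[a]

    def rec(state, j, i, odds):
        nonlocal best
        if state == "M":
            if odds > 0:
                best = max(best, math.log2(odds))
            if j < L and i < n:
                rec("M", j + 1, i + 1, odds * t[j, MM] * odds_m(j + 1, x[i]))
            if i < n:
                rec("I", j, i + 1, odds * t[j, MI] * odds_i(j, x[i]))
            if j < L:
                rec("D", j + 1, i, odds * t[j, MD])
        elif state == "I":
            if i < n:
                rec("I", j, i + 1, odds * t[j, II] * odds_i(j, x[i]))
            if j < L and i < n:
                rec("M", j + 1, i + 1, odds * t[j, IM] * odds_m(j + 1, x[i]))
        else:
            if j < L and i < n:
                rec("M", j + 1, i + 1, odds * t[j, DM] * odds_m(j + 1, x[i]))
            if j < L:
                rec("D", j + 1, i, odds * t[j, DD])

    for i0 in range(n):
        for j0 in range(1, L + 1):
            rec("M", j0, i0 + 1, odds_m(j0, x[i0]))
    return best


def confusion_counts(y_true, y_pred, classes):
    table = {}
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        table[c] = (tp, fp, fn)
    return table


def brute_force_adjusted_balanced_accuracy(y_true, y_pred) -> float:
    classes = sorted(set(y_true))
    k = len(classes)
    recalls = []
    for c in classes:
        idx = [i for i, t in enumerate(y_true) if t == c]
        recalls.append(sum(1 for i in idx if y_pred[i] == c) / len(idx))
    ba = sum(recalls) / k
    return (ba - 1 / k) / (1 - 1 / k)


def brute_force_macro_f(y_true, y_pred) -> float:
    classes = sorted(set(y_true))
    table = confusion_counts(y_true, y_pred, classes)
    fs = []
    for c in classes:
        tp, fp, fn = table[c]
        denom = 2 * tp + fp + fn
        fs.append(2 * tp / denom if denom else 0.0)
    return sum(fs) / len(fs)


def random_profile_model(length: int, peaked: bool = True, seed: int = 0):
    """Random valid ProfileModel for oracle comparisons."""
    from caskit.profiles import AMINO_ACIDS, ProfileModel, ROBINSON_BACKGROUND

    r = np.random.default_rng(seed)
    me = r.dirichlet(np.full(20, 0.3 if peaked else 5.0), size=length)
    ie = np.tile(ROBINSON_BACKGROUND, (length + 1, 1))
    t = np.zeros((length + 1, 7))
    for j in range(length + 1):
        t[j, [MM, MI, MD]] = r.dirichlet([8, 1, 1])
        t[j, [IM, II]] = r.dirichlet([3, 1])
        t[j, [DM, DD]] = r.dirichlet([3, 1])
    cons = "".join(AMINO_ACIDS[int(np.argmax(me[k]))] for k in range(length))
    return ProfileModel(name=f"rand__cluster{seed}", family="rand",
                        match_emissions=me, insert_emissions=ie, transitions=t,
                        background=ROBINSON_BACKGROUND, consensus=cons)
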