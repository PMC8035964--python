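"""Independent brute-force reference implementations used only in tests.

Everything here is written as literal loops straight from the metric and
transform definitions, deliberately sharing no code with the package.
"""

import numpy as np


def naive_column_mean(scores, i):
    total = 0.0
    for j in range(scores.shape[0]):
        total += scores[j][i]
    return total / scores.shape[0]


def naive_ac(scores, i, lag):
    L = scores.shape[0]
    mean = naive_column_mean(scores, i)
    total = 0.0
    for j in range(L - lag):
        total += (scores[j][i] - mean) * (scores[j + lag][i] - mean)
    return total / (L - lag)


def naive_cc(scores, i, j, lag):
    L = scores.shape[0]
    mi, mj = naive_column_mean(scores, i), naive_column_mean(scores, j)
    total = 0.0
    for k in range(L - lag):
        total += (scores[k][i] - mi) * (scores[k + lag][j] - mj)
    return total / (L - lag)


def naive_acc_vector(scores, lg):
    out = []
    for i in range(20):
        for lag in range(1, lg + 1):
            out.append(naive_ac(scores, i, lag))
    for i in range(20):
        for j in range(20):
            if i == j:
                continue
            for lag in range(1, lg + 1):
                out.append(naive_cc(scores, i, j, lag))
    return np.array(out)


def naive_pseaac(sequence, lam, w, prop_tables, alphabet):
    """Type-I pseudo amino acid composition, written as direct loops."""
    normed = []
    for table in prop_tables:
        vals = [table[a] for a in alphabet]
        mean = sum(vals) / 20.0
        sd = (sum((v - mean) ** 2 for v in vals) / 20.0) ** 0.5
        normed.append({a: (table[a] - mean) / sd for a in alphabet})
    L = len(sequence)
    freqs = [sequence.count(a) / L for a in alphabet]
    thetas = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(L - k):
            corr = 0.0
            for table in normed:
                corr += (table[sequence[i]] - table[sequence[i + k]]) ** 2
            total += corr / len(normed)
        thetas.append(total / (L - k))
    denom = 1.0 + w * sum(thetas)
    return np.array(freqs + [w * t for t in thetas]) / denom


def naive_example_metrics(Y, P):
    n = len(Y)
    acc = prec = rec = f1 = subset = hamming = 0.0
    for y, p in zip(Y, P):
        inter = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
        union = sum(1 for a, b in zip(y, p) if a == 1 or b == 1)
        sy, sp = sum(y), sum(p)
        acc += inter / union
        prec += inter / sp if sp else 0.0
        rec += inter / sy
        f1 += 2 * inter / (sy + sp)
        subset += 1.0 if list(y) == list(p) else 0.0
        hamming += sum(1 for a, b in zip(y, p) if a != b) / len(y)
    return {
        "accuracy_score": acc / n,
        "precision": prec / n,
        "recall": rec / n,
        "f1": f1 / n,
        "subset_accuracy": subset / n,
        "hamming_loss": hamming / n,
    }


def naive_label_metrics(Y, P):
    q = len(Y[0])
    tps = [0] * q
    fps = [0] * q
    fns = [0] * q
    for y, p in zip(Y, P):
        for j in range(q):
            if y[j] == 1 and p[j] == 1:
                tps[j] += 1
            elif y[j] == 0 and p[j] == 1:
                fps[j] += 1
            elif y[j] == 1 and p[j] == 0:
                fns[j] += 1
    prec_j = [tps[j] / (tps[j] + fps[j]) if tps[j] + fps[j] else 0.0 for j in range(q)]
    rec_j = [tps[j] / (tps[j] + fns[j]) if tps[j] + fns[j] else 0.0 for j in range(q)]
    f1_j = [
        2 * tps[j] / (2 * tps[j] + fps[j] + fns[j]) if 2 * tps[j] + fps[j] + fns[j] else 0.0
        for j in range(q)
    ]
    macro_p = sum(prec_j) / q
    macro_r = sum(rec_j) / q
    micro_p = sum(tps) / (sum(tps) + sum(fps)) if sum(tps) + sum(fps) else 0.0
    micro_r = sum(tps) / (sum(tps) + sum(fns)) if sum(tps) + sum(fns) else 0.0

    def hm(p, r):
        return 2 * p * r / (p + r) if p + r else 0.0

    return {
        "macro_precision": macro_p,
        "macro_recall": macro_r,
        "macro_f1": hm(macro_p, macro_r),
        "macro_f1_per_label": sum(f1_j) / q,
        "micro_precision": micro_p,
        "micro_recall": micro_r,
        "micro_f1": hm(micro_p, micro_r),
    }


def naive_rank_loss(Y, S):
    losses = []
    for y, s in zip(Y, S):
        rel = [j for j in range(len(y)) if y[j] == 1]
        irr = [j for j in range(len(y)) if y[j] == 0]
        if not rel or not irr:
            continue
        bad = 0.0
        for j in rel:
            for l in irr:
                if s[l] > s[j]:
                    bad += 1.0
                elif s[l] == s[j]:
                    bad += 0.5
        losses.append(bad / (len(rel) * len(irr)))
    return sum(losses) / len(losses) if losses else 0.0


def mann_whitney_auc(truth, scores):
    """AUC as the normalized Mann-Whitney U statistic with tie correction."""
    pos = [s for t, s in zip(truth, scores) if t == 1]
    neg = [s for t, s in zip(truth, scores) if t == 0]
    u = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                u += 1.0
            elif p == n:
                u += 0.5
    return u / (len(pos) * len(neg))
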