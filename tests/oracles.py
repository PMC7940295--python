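"""Brute-force reference implementations used only to cross-check metrics."""

import math

import numpy as np


def brute_counts(test, reference):
    tp = fp = fn = 0
    t = np.asarray(test).astype(bool)
    r = np.asarray(reference).astype(bool)
    for idx in np.ndindex(t.shape):
        if t[idx] and r[idx]:
            tp += 1
        elif t[idx]:
            fp += 1
        elif r[idx]:
            fn += 1
    return tp, fp, fn


def brute_overlap(test, reference):
    tp, fp, fn = brute_counts(test, reference)
    div = lambda a, b: a / b if b else math.nan
    return {
        "dice": div(2 * tp, 2 * tp + fp + fn),
        "jaccard": div(tp, tp + fp + fn),
        "sensitivity": div(tp, tp + fn),
        "precision": div(tp, tp + fp),
    }


def brute_hausdorff(test, reference):
    a = np.argwhere(np.asarray(test).astype(bool))
    b = np.argwhere(np.asarray(reference).astype(bool))

    def directed(src, dst):
        worst = 0.0
        for p in src:
            best = min(math.dist(p, q) for q in dst)
            worst = max(worst, best)
        return worst

    return max(directed(a, b), directed(b, a))


def brute_volume_ml(mask, spacing):
    count = 0
    m = np.asarray(mask).astype(bool)
    for idx in np.ndindex(m.shape):
        count += bool(m[idx])
    return count * spacing[0] * spacing[1] * spacing[2] / 1000.0
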