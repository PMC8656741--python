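"""Independent brute-force oracles used only by the test suite.

Everything here recomputes quantities from first principles -- explicit
joint-distribution enumeration for the naive-Bayes metrics, pairwise
concordance counting for the AUC -- sharing no code path with the
engine it checks.
"""

import itertools
import math

import numpy as np


def enumerate_joint(prior, cpts):
    """Full joint P(y, x1..xk) over binary/categorical level tuples.

    ``cpts[name]`` is a (2, n_levels) array. Returns (names, table)
    where table maps (y, levels-tuple) -> probability.
    """
    names = list(cpts)
    level_ranges = [range(cpts[n].shape[1]) for n in names]
    table = {}
    for y in (0, 1):
        py = prior if y == 1 else 1 - prior
        for combo in itertools.product(*level_ranges):
            p = py
            for name, lvl in zip(names, combo):
                p *= cpts[name][y, lvl]
            table[(y, combo)] = p
    return names, table


def oracle_posterior(prior, cpts, evidence):
    """P(Y=1 | evidence) by summation over the enumerated joint."""
    names, table = enumerate_joint(prior, cpts)
    num = den = 0.0
    for (y, combo), p in table.items():
        if all(combo[names.index(v)] == lvl for v, lvl in evidence.items()):
            den += p
            if y == 1:
                num += p
    return num / den


def _h(p):
    if p in (0.0, 1.0):
        return 0.0
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def oracle_voi(prior, cpts, evidence, var):
    """I(Y; var | evidence) from the enumerated joint."""
    names, table = enumerate_joint(prior, cpts)
    vi = names.index(var)
    h_before = _h(oracle_posterior(prior, cpts, evidence))
    # P(var = x | evidence)
    total = 0.0
    h_after = 0.0
    marg = {}
    for (y, combo), p in table.items():
        if all(combo[names.index(v)] == lvl for v, lvl in evidence.items()):
            total += p
            marg[combo[vi]] = marg.get(combo[vi], 0.0) + p
    for x, p_x in marg.items():
        ev = dict(evidence)
        ev[var] = x
        h_after += (p_x / total) * _h(oracle_posterior(prior, cpts, ev))
    return h_before - h_after


def oracle_nl(prior, cpts, var, level):
    """P(e|Y=1)/P(e) for a single observed variable, by direct sums."""
    p_e1 = cpts[var][1, level]
    p_e0 = cpts[var][0, level]
    p_e = prior * p_e1 + (1 - prior) * p_e0
    return p_e1 / p_e


def oracle_auc(scores, labels):
    """Concordant-pair counting AUC (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                total += 1.0
            elif x == y:
                total += 0.5
    return total / (len(pos) * len(neg))
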