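"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written against explicit contingency tables and subset
enumeration with plain Python loops, deliberately sharing no code with the
package implementations it checks.
"""

import math
from collections import Counter
from itertools import combinations


def entropy_bf(codes):
    n = len(codes)
    return -sum((c / n) * math.log2(c / n) for c in Counter(codes).values())


def mi_bf(x, y):
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        p = c / n
        total += p * math.log2(p / ((px[a] / n) * (py[b] / n)))
    return total


def qmi_bf(x, y, utility):
    """Cell-by-cell QMI with a constant-per-feature utility."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        p = c / n
        total += utility * p * math.log2(p / ((px[a] / n) * (py[b] / n)))
    return total


def cmi_bf(x, y, z):
    n = len(x)
    joint = Counter(zip(x, y, z))
    pz = Counter(z)
    pxz = Counter(zip(x, z))
    pyz = Counter(zip(y, z))
    total = 0.0
    for (a, b, c), cnt in joint.items():
        p = cnt / n
        total += p * math.log2((p * (pz[c] / n)) / ((pxz[(a, c)] / n) * (pyz[(b, c)] / n)))
    return total


def su_bf(f, cls):
    hf = entropy_bf(f)
    if hf == 0.0:
        return 0.0
    return 2.0 * mi_bf(f, cls) / (entropy_bf(cls) + hf)


def payoff_bf(K, i, qmi, cmi):
    """Binary coalition payoff from raw qmi vector / cmi matrix lookups."""
    change = sum(cmi[i][j] - qmi[j] for j in K) / len(K)
    if change < 0:
        return 0
    psi = sum(1 for j in K if cmi[i][j] > qmi[j])
    return 1 if psi >= len(K) / 2 else 0


def shapley_bf(i, qmi, cmi, coalition_size):
    """Exhaustive enumeration of every size-k coalition not containing i."""
    n = len(qmi)
    others = [j for j in range(n) if j != i]
    count = sum(payoff_bf(K, i, qmi, cmi) for K in combinations(others, coalition_size))
    k = coalition_size
    return count * math.factorial(k) * math.factorial(n - k - 1) / math.factorial(n)
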