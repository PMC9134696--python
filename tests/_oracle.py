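"""Independent straight-line reimplementation of the CHE equation chain.

Deliberately written with plain Python loops and a hand-rolled percentile so
it shares no code path with chesurvey.che; used as the reference the package
implementation is compared against.
"""

import math


def percentile_linear(values, q):
    """Linear-interpolation percentile between order statistics."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    rank = q / 100.0 * (n - 1)
    lo = int(math.floor(rank))
    hi = min(lo + 1, n - 1)
    frac = rank - lo
    return xs[lo] * (1.0 - frac) + xs[hi] * frac


def oracle_chain(food, exp, oop, size, beta=0.56, band=(45.0, 55.0), threshold=0.40, weights=None):
    """Run the eight-step chain household by household; returns a dict of lists."""
    n = len(food)
    w = [1.0] * n if weights is None else list(weights)
    foodexp = [food[i] / exp[i] for i in range(n)]
    eqsize = [size[i] ** beta for i in range(n)]
    eqfood = [food[i] / eqsize[i] for i in range(n)]

    f_lo = percentile_linear(foodexp, band[0])
    f_hi = percentile_linear(foodexp, band[1])
    sel = [i for i in range(n) if f_lo < foodexp[i] < f_hi]
    if not sel:
        sel = [i for i in range(n) if f_lo <= foodexp[i] <= f_hi]
    pl = sum(w[i] * eqfood[i] for i in sel) / sum(w[i] for i in sel)

    se = [pl * eqsize[i] for i in range(n)]
    ctp = [exp[i] - se[i] if se[i] <= food[i] else exp[i] - food[i] for i in range(n)]
    oopctp = [oop[i] / ctp[i] if ctp[i] > 0 else float("nan") for i in range(n)]
    cata = [
        (1 if oopctp[i] >= threshold else 0) if ctp[i] > 0 else (1 if oop[i] > 0 else 0)
        for i in range(n)
    ]
    return {
        "foodexp": foodexp,
        "eqsize": eqsize,
        "eqfood": eqfood,
        "pl": pl,
        "se": se,
        "ctp": ctp,
        "oopctp": oopctp,
        "cata": cata,
    }
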