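"""Independent straight-line re-implementations used only as test oracles.

No code is shared with the package: plain Python loops and textbook
formulas, kept deliberately naive.
"""

import math


def oracle_toxpi(iv_rows, slices):
    """iv_rows: {chem: {assay: value}}; slices: [(name, [assay_ids], weight)].

    Returns {chem: (components dict, overall)} using raw-sum, min/max range
    normalization per slice, weighting, and summation.
    """
    chems = list(iv_rows)
    raw = {}
    for chem in chems:
        raw[chem] = {}
        for name, assays, _ in slices:
            total = 0.0
            for a in assays:
                total += iv_rows[chem].get(a, 0.0)
            raw[chem][name] = total
    out = {}
    for chem in chems:
        components = {}
        for name, _, weight in slices:
            values = [raw[c][name] for c in chems]
            lo, hi = min(values), max(values)
            if hi == lo:
                components[name] = 0.0
            else:
                components[name] = (raw[chem][name] - lo) / (hi - lo) * weight
        out[chem] = (components, sum(components.values()))
    return out


def oracle_pearson(row_a, row_b):
    """Pairwise-complete Pearson r of two equal-length lists with None = NA.

    Returns (r or None, n_overlap); r is None when the overlap has fewer
    than 2 points or either restricted vector is constant.
    """
    xs, ys = [], []
    for x, y in zip(row_a, row_b):
        if x is None or y is None:
            continue
        xs.append(x)
        ys.append(y)
    n = len(xs)
    if n < 2:
        return None, n
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    if sxx == 0.0 or syy == 0.0:
        return None, n
    return sxy / math.sqrt(sxx * syy), n
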