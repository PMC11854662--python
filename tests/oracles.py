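"""Independent brute-force oracles coded directly from the feature
definitions, deliberately avoiding the implementation's code paths."""

import math


def _percentile(sorted_x, q):
    """Linear-interpolation percentile on a pre-sorted list."""
    n = len(sorted_x)
    if n == 1:
        return sorted_x[0]
    rank = q / 100.0 * (n - 1)
    lo = int(math.floor(rank))
    hi = min(lo + 1, n - 1)
    frac = rank - lo
    return sorted_x[lo] * (1 - frac) + sorted_x[hi] * frac


def first_order_oracle(values, bin_width=0.25):
    """All 17 first-order statistics from their formulas, loops only."""
    x = [float(v) for v in values]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    if var > 0:
        skew = (sum((v - mean) ** 3 for v in x) / n) / var**1.5
        kurt = (sum((v - mean) ** 4 for v in x) / n) / var**2 - 3.0
    else:
        skew = kurt = 0.0
    s = sorted(x)
    median = _percentile(s, 50)
    p10 = _percentile(s, 10)
    p25 = _percentile(s, 25)
    p75 = _percentile(s, 75)
    p90 = _percentile(s, 90)
    mad = sum(abs(v - mean) for v in x) / n
    inner = [v for v in x if p10 <= v <= p90]
    imean = sum(inner) / len(inner)
    rmad = sum(abs(v - imean) for v in inner) / len(inner)
    energy = sum(v * v for v in x)
    rms = math.sqrt(energy / n)
    counts = {}
    for v in x:
        b = math.floor(v / bin_width)
        counts[b] = counts.get(b, 0) + 1
    probs = [c / n for c in counts.values()]
    uniformity = sum(p * p for p in probs)
    entropy = -sum(p * math.log2(p) for p in probs)
    return {
        "F_stat.mean": mean,
        "F_stat.var": var,
        "F_stat.skew": skew,
        "F_stat.kurt": kurt,
        "F_stat.median": median,
        "F_stat.min": min(x),
        "F_stat.10thpercentile": p10,
        "F_stat.90thpercentile": p90,
        "F_stat.max": max(x),
        "F_stat.iqr": p75 - p25,
        "F_stat.range": max(x) - min(x),
        "F_stat.mad": mad,
        "F_stat.rmad": rmad,
        "F_stat.energy": energy,
        "F_stat.rms": rms,
        "F_stat.uniformity": uniformity,
        "F_stat.entropy": entropy,
    }
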