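"""Independent brute-force oracles used by the test suite.

Everything here is written from the rule statements with plain loops, kept
deliberately separate from the package implementations it checks.
"""

from __future__ import annotations

import math


def percentile_linear(values, q: float) -> float:
    """Linear-interpolation percentile (the 'linear' definition), by hand."""
    xs = sorted(float(v) for v in values)
    if len(xs) == 1:
        return xs[0]
    pos = (q / 100.0) * (len(xs) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(xs) - 1)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def peak_oracle(
    x,
    t_frame: float,
    min_gap_s: float = 0.1,
    floor_quantile: float = 0.25,
    trough_fraction: float = 0.2,
) -> list[int]:
    """Exhaustive scan implementing the three peak rules.

    1. strict interior local maxima above the floor percentile;
    2. left-to-right minimum-gap suppression, larger peak survives
       (ties keep the earlier);
    3. adjacent accepted peaks must have a sample between them below
       min(peak pair) - trough_fraction * IQR; while violated, remove the
       smaller of the pair (ties remove the later) and restart.
    """
    x = [float(v) for v in x]
    n = len(x)
    floor = percentile_linear(x, 100.0 * floor_quantile)
    candidates = [
        i for i in range(1, n - 1) if x[i - 1] < x[i] and x[i] > x[i + 1] and x[i] > floor
    ]
    accepted: list[int] = []
    gap = min_gap_s / t_frame
    for c in candidates:
        if accepted and (c - accepted[-1]) < gap:
            if x[c] > x[accepted[-1]]:
                accepted[-1] = c
        else:
            accepted.append(c)
    iqr = percentile_linear(x, 75) - percentile_linear(x, 25)
    depth = trough_fraction * iqr
    restart = True
    while restart and len(accepted) > 1:
        restart = False
        for j in range(len(accepted) - 1):
            p, q = accepted[j], accepted[j + 1]
            lowest = min(x[p + 1 : q]) if q > p + 1 else float("inf")
            if lowest >= min(x[p], x[q]) - depth:
                del accepted[j if x[p] < x[q] else j + 1]
                restart = True
                break
    return accepted


def shannon_entropy(probabilities) -> float:
    return -sum(p * math.log(p) for p in probabilities if p > 0)


def histogram_entropy(values, bins: int = 10) -> float:
    """Entropy of the fixed-range histogram, counted by hand."""
    xs = [float(v) for v in values]
    lo, hi = min(xs), max(xs)
    if lo == hi:
        return 0.0
    counts = [0] * bins
    width = (hi - lo) / bins
    for v in xs:
        idx = min(bins - 1, int((v - lo) / width))
        counts[idx] += 1
    total = sum(counts)
    return shannon_entropy([c / total for c in counts])


def run_length_counts(speeds, t_frame, threshold=50.0, interruption_s=0.010, freeze_s=0.020):
    """(interruptions, freezes, longest freeze) by explicit run scanning."""
    runs = []
    current = 0
    for s in speeds:
        if s < threshold:
            current += 1
        else:
            if current:
                runs.append(current)
            current = 0
    if current:
        runs.append(current)
    durs = [r * t_frame for r in runs]
    interruptions = sum(1 for d in durs if d >= interruption_s)
    freezes = [d for d in durs if d > freeze_s]
    return interruptions, len(freezes), (max(freezes) if freezes else 0.0)


def ols_line(y) -> tuple[float, float, float]:
    """(slope, intercept, r_squared) via the normal equations, by hand."""
    n = len(y)
    xs = list(range(n))
    mx = sum(xs) / n
    my = sum(y) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (v - my) for x, v in zip(xs, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_tot = sum((v - my) ** 2 for v in y)
    if ss_tot == 0:
        return slope, intercept, 1.0
    ss_res = sum((v - (slope * x + intercept)) ** 2 for x, v in zip(xs, y))
    return slope, intercept, 1.0 - ss_res / ss_tot


def icc2_formula(table) -> tuple[float, tuple[float, float]]:
    """Two-way random, absolute agreement, single rater ICC with 95% CI.

    Classic ANOVA construction: MSR (between rows), MSC (between columns),
    MSE (residual), then (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n).
    """
    import scipy.stats as st

    rows = [list(map(float, r)) for r in table]
    n = len(rows)
    k = len(rows[0])
    grand = sum(sum(r) for r in rows) / (n * k)
    row_means = [sum(r) / k for r in rows]
    col_means = [sum(rows[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((rows[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # Shrout-Fleiss F-based interval
    fj = msc / mse
    f_obs = msr / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * (k - 1) ** 2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_lo = f_obs / st.f.ppf(0.975, n - 1, v)
    f_up = f_obs * st.f.ppf(0.975, v, n - 1)
    lo = n * (f_lo - 1) / (n * f_lo + k * (n - 1) - n + k)
    hi = n * (f_up - 1) / (n * f_up + k * (n - 1) - n + k)
    return icc, (lo, hi)


def krippendorff_ordinal_oracle(rows, level: str = "ordinal") -> float:
    """Alpha from first principles: explicit coincidence bookkeeping."""
    units = [[v for v in r if v == v] for r in rows]  # v == v filters NaN
    units = [u for u in units if len(u) >= 2]
    values = sorted({v for u in units for v in u})
    vi = {v: i for i, v in enumerate(values)}
    q = len(values)
    o = [[0.0] * q for _ in range(q)]
    for u in units:
        m = len(u)
        for a in range(m):
            for b in range(m):
                if a != b:
                    o[vi[u[a]]][vi[u[b]]] += 1.0 / (m - 1)
    n_c = [sum(row) for row in o]
    n_tot = sum(n_c)

    def delta2(c, k):
        if c == k:
            return 0.0
        lo, hi = min(c, k), max(c, k)
        if level == "ordinal":
            return (sum(n_c[lo : hi + 1]) - (n_c[lo] + n_c[hi]) / 2.0) ** 2
        if level == "interval":
            return (values[c] - values[k]) ** 2
        return 1.0
    d_o = sum(o[c][k] * delta2(c, k) for c in range(q) for k in range(q))
    d_e = sum(n_c[c] * n_c[k] * delta2(c, k) for c in range(q) for k in range(q)) / (n_tot - 1)
    if d_e == 0.0:
        return 1.0
    return 1.0 - d_o / d_e


def kendall_tau_oracle(a, b) -> float:
    """Tau-b by explicit pair counting."""
    n = len(a)
    conc = disc = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                ties_a += 1
                ties_b += 1
            elif da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - ties_a) * (n0 - ties_b))


def pearson_oracle(a, b) -> float:
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)


def ranks(values) -> list[float]:
    """Average ranks (1-based) with tie handling."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    out = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            out[order[t]] = avg
        i = j + 1
    return out
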