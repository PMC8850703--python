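"""Independent brute-force transcriptions used as oracles.

Every function here is a naive, loop-based evaluation of the defining
formulas — deliberately written without numpy vectorization or any code
shared with the package — so implementation and oracle can only agree by
both being right.
"""

from __future__ import annotations

import math


# -- Hjorth ------------------------------------------------------------------

def _mean(xs):
    return sum(xs) / len(xs)


def _pop_sd(xs):
    mu = _mean(xs)
    return math.sqrt(sum((v - mu) ** 2 for v in xs) / len(xs))


def hjorth_oracle(xs):
    """(activity, mobility, complexity) by line-by-line evaluation."""
    xs = list(map(float, xs))
    dx = [xs[n] - xs[n - 1] for n in range(1, len(xs))]
    ddx = [dx[n] - dx[n - 1] for n in range(1, len(dx))]
    sx, sx1, sx2 = _pop_sd(xs), _pop_sd(dx), _pop_sd(ddx)
    mob = sx1 / sx
    return sx * sx, mob, (sx2 / sx1) / mob


# -- Entropies ---------------------------------------------------------------

def shannon_oracle(xs, normalize=True):
    xs = list(map(float, xs))
    total = sum(v * v for v in xs)
    h = 0.0
    for v in xs:
        p = v * v / total
        if p > 0:
            h -= p * math.log(p)
    return h / math.log(len(xs)) if normalize else h


def sampen_oracle(xs, m=2, r_factor=0.2, tau=1):
    """-ln(A/B) with explicit loops; None when undefined (A or B zero)."""
    xs = list(map(float, xs))
    n = len(xs)
    sd = _pop_sd(xs)
    if sd == 0:
        return None
    r = r_factor * sd
    n_templ = n - m * tau  # both sizes over the same template range
    a = b = 0
    for i in range(n_templ):
        for j in range(i + 1, n_templ):
            db = max(abs(xs[i + k * tau] - xs[j + k * tau]) for k in range(m))
            if db <= r:
                b += 1
                da = max(abs(xs[i + k * tau] - xs[j + k * tau]) for k in range(m + 1))
                if da <= r:
                    a += 1
    if a == 0 or b == 0:
        return None
    return -math.log(a / b)


def perm_oracle(xs, m=3, tau=1, normalize=True):
    xs = list(map(float, xs))
    counts: dict = {}
    n_win = len(xs) - (m - 1) * tau
    for i in range(n_win):
        window = [xs[i + k * tau] for k in range(m)]
        pattern = tuple(sorted(range(m), key=lambda k: (window[k], k)))  # stable ties
        counts[pattern] = counts.get(pattern, 0) + 1
    h = 0.0
    for c in counts.values():
        p = c / n_win
        h -= p * math.log(p)
    return h / math.log(math.factorial(m)) if normalize else h


def _ncdf(v, mu, sd):
    return 0.5 * (1.0 + math.erf((v - mu) / (sd * math.sqrt(2.0))))


def disp_oracle(xs, m=2, a=6, tau=1, normalize=True):
    xs = list(map(float, xs))
    mu, sd = _mean(xs), _pop_sd(xs)
    if sd == 0:
        return 0.0
    classes = []
    for v in xs:
        z = round(a * _ncdf(v, mu, sd) + 0.5)  # banker's rounding, like np.round
        classes.append(min(max(z, 1), a))
    counts: dict = {}
    n_win = len(classes) - (m - 1) * tau
    for i in range(n_win):
        pat = tuple(classes[i + k * tau] for k in range(m))
        counts[pat] = counts.get(pat, 0) + 1
    h = 0.0
    for c in counts.values():
        p = c / n_win
        h -= p * math.log(p)
    return h / math.log(a**m) if normalize else h


def _bubble_swaps(vec):
    """Explicit bubble sort, counting swaps (strict inequality: ties don't swap)."""
    v = list(vec)
    swaps = 0
    for end in range(len(v) - 1, 0, -1):
        for i in range(end):
            if v[i] > v[i + 1]:
                v[i], v[i + 1] = v[i + 1], v[i]
                swaps += 1
    return swaps


def _renyi2_swaps_oracle(xs, m, tau):
    n_win = len(xs) - (m - 1) * tau
    counts: dict = {}
    for i in range(n_win):
        s = _bubble_swaps([xs[i + k * tau] for k in range(m)])
        counts[s] = counts.get(s, 0) + 1
    total = sum(counts.values())
    return -math.log(sum((c / total) ** 2 for c in counts.values()))


def bubble_oracle(xs, m=8, tau=1):
    xs = list(map(float, xs))
    h_m = _renyi2_swaps_oracle(xs, m, tau)
    h_m1 = _renyi2_swaps_oracle(xs, m + 1, tau)
    return (h_m1 - h_m) / math.log((m + 1) / (m - 1))


def slope_oracle(xs, m=3, gamma=1.0, delta=1e-3, normalize=True):
    xs = list(map(float, xs))
    syms = []
    for i in range(1, len(xs)):
        d = xs[i] - xs[i - 1]
        if d > gamma:
            syms.append(2)
        elif d > delta:
            syms.append(1)
        elif d >= -delta:
            syms.append(0)
        elif d >= -gamma:
            syms.append(-1)
        else:
            syms.append(-2)
    width = m - 1
    n_win = len(syms) - width + 1
    counts: dict = {}
    for i in range(n_win):
        pat = tuple(syms[i : i + width])
        counts[pat] = counts.get(pat, 0) + 1
    h = 0.0
    for c in counts.values():
        p = c / n_win
        h -= p * math.log(p)
    if normalize:
        denom = math.log(min(n_win, 5**width))
        return h / denom if denom > 0 else 0.0
    return h


# -- One-way ANOVA -----------------------------------------------------------

def anova_oracle(groups):
    """Textbook sums-of-squares one-way fixed-effects ANOVA: (F, p)."""
    from scipy.stats import f as f_dist  # distribution only, not the ANOVA

    groups = [list(map(float, g)) for g in groups]
    all_vals = [v for g in groups for v in g]
    grand = _mean(all_vals)
    k, n = len(groups), len(all_vals)
    ssb = sum(len(g) * (_mean(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - _mean(g)) ** 2 for v in g) for g in groups)
    f_stat = (ssb / (k - 1)) / (ssw / (n - k))
    return f_stat, float(f_dist.sf(f_stat, k - 1, n - k))
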