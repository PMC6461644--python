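"""Independent brute-force oracles used to verify the fast implementations.

Everything here is written as directly from definitions as possible (pure
Python loops, no shared code with the package internals) so agreement is
meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as _scipy_stats


def cindex_brute(scores, times, events, higher_is_worse=True):
    """O(n^2) pair enumeration of the non-censored concordance index."""
    s = [x if higher_is_worse else -x for x, e in zip(scores, events) if e]
    t = [x for x, e in zip(times, events) if e]
    num = den = 0.0
    for i in range(len(t)):
        for j in range(i + 1, len(t)):
            if t[i] == t[j]:
                continue
            den += 1
            short, long_ = (i, j) if t[i] < t[j] else (j, i)
            if s[short] > s[long_]:
                num += 1
            elif s[short] == s[long_]:
                num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


def weighted_oe_test(times_a, events_a, times_b, events_b, breslow=False):
    """Two-sample weighted observed-minus-expected test from the definition.

    Returns (chi_square, p). Unit weights give the log-rank test; at-risk
    weights give the Gehan-Breslow generalized Wilcoxon.
    """
    times = list(times_a) + list(times_b)
    events = list(events_a) + list(events_b)
    group = [0] * len(times_a) + [1] * len(times_b)
    event_times = sorted({t for t, e in zip(times, events) if e})
    u = v = 0.0
    for tau in event_times:
        at_risk = [i for i in range(len(times)) if times[i] >= tau]
        n = len(at_risk)
        n1 = sum(1 for i in at_risk if group[i] == 0)
        d = sum(1 for i in at_risk if times[i] == tau and events[i])
        d1 = sum(1 for i in at_risk if times[i] == tau and events[i]
                 and group[i] == 0)
        w = n if breslow else 1.0
        u += w * (d1 - d * n1 / n)
        if n > 1:
            v += w**2 * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        return 0.0, 1.0
    chi2 = u * u / v
    return chi2, float(_scipy_stats.chi2.sf(chi2, df=1))


def km_by_hand(times, events):
    """Product-limit estimate as {event_time: survival}."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    surv = 1.0
    out = {}
    event_times = sorted({times[i] for i in order if events[i]})
    for tau in event_times:
        n = sum(1 for t in times if t >= tau)
        d = sum(1 for t, e in zip(times, events) if t == tau and e)
        surv *= 1.0 - d / n
        out[tau] = surv
    return out


def cox_loglik_1d(beta, x, times, events):
    """Cox partial log-likelihood for one covariate (no tied event times)."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


def best_split_scan(feature, times, events, min_group_fraction=0.10,
                    significance=0.05, window=1):
    """Full-enumeration cutpoint search mirroring the published rule.

    Returns (threshold, p) for the best non-isolated significant candidate,
    or the overall best (with flag False) when none qualifies.
    """
    n = len(feature)
    xs = sorted(set(feature))
    cands = []
    min_n = max(1, math.ceil(min_group_fraction * n))
    for lo, hi in zip(xs[:-1], xs[1:]):
        thr = 0.5 * (lo + hi)
        n_low = sum(1 for f in feature if f <= thr)
        if n_low < min_n or n - n_low < min_n:
            continue
        low = [i for i in range(n) if feature[i] <= thr]
        high = [i for i in range(n) if feature[i] > thr]
        _, p = weighted_oe_test(
            [times[i] for i in low], [events[i] for i in low],
            [times[i] for i in high], [events[i] for i in high],
        )
        cands.append((thr, p))
    if not cands:
        raise ValueError("no admissible threshold")
    sig = [p < significance for _, p in cands]
    qualified = []
    for k, (thr, p) in enumerate(cands):
        if not sig[k]:
            continue
        neighbours = [sig[j] for j in range(max(0, k - window),
                                            min(len(cands), k + window + 1))
                      if j != k]
        if all(neighbours):
            qualified.append((p, thr))
    if qualified:
        p, thr = min(qualified)
        return thr, p, True
    k = min(range(len(cands)), key=lambda j: cands[j][1])
    return cands[k][0], cands[k][1], False


def best_dichotomized_cindex(scores, times, events, min_group_fraction=0.0):
    """Naive sweep: c-index of the binary indicator at every midpoint."""
    xs = sorted(set(scores))
    n = len(scores)
    min_n = max(1, math.ceil(min_group_fraction * n)) if min_group_fraction else 1
    best = None
    for lo, hi in zip(xs[:-1], xs[1:]):
        thr = 0.5 * (lo + hi)
        ind = [1.0 if s > thr else 0.0 for s in scores]
        n_high = sum(ind)
        if min_group_fraction and (n - n_high < min_n or n_high < min_n):
            continue
        try:
            c = cindex_brute(ind, times, events)
        except ValueError:
            continue
        if best is None or c > best[1]:
            best = (thr, c)
    if best is None:
        raise ValueError("no admissible threshold")
    return best


def olpm_nested_loop(seed_coefs, X, times, events, fraction, subintervals,
                     min_group_fraction=0.10):
    """Exhaustive coefficient-grid enumeration straight from the recipe."""
    grids = []
    for b in seed_coefs:
        if subintervals == 1 or fraction == 0 or b == 0:
            grids.append([b])
        else:
            half = fraction * abs(b)
            grids.append(list(np.linspace(b - half, b + half, subintervals)))
    best = None
    for combo in itertools.product(*grids):
        ps = [sum(c * x for c, x in zip(combo, row)) for row in X]
        if max(ps) == min(ps):
            continue
        try:
            thr, c = best_dichotomized_cindex(ps, times, events,
                                              min_group_fraction)
        except ValueError:
            continue
        if best is None or c > best[2]:
            best = (combo, thr, c)
    return best


def glcm_pairs_brute(quantized, offset, levels):
    """Raw symmetric co-occurrence counts by triple-loop enumeration."""
    counts = np.zeros((levels, levels))
    nz, ny, nx = quantized.shape
    dz, dy, dx = offset
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = quantized[z, y, x]
                if a == 0:
                    continue
                z2, y2, x2 = z + dz, y + dy, x + dx
                if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                b = quantized[z2, y2, x2]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
    return counts


def rlm_runs_brute(quantized, offset, levels):
    """Run enumeration by walking every maximal line through the volume."""
    nz, ny, nx = quantized.shape
    d = np.asarray(offset)
    runs = {}
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                pos = np.array([z, y, x])
                prev = pos - d
                prev_ok = (
                    0 <= prev[0] < nz and 0 <= prev[1] < ny and 0 <= prev[2] < nx
                )
                level = quantized[z, y, x]
                if level == 0:
                    continue
                if prev_ok and quantized[tuple(prev)] == level:
                    continue  # not a run start
                length = 1
                nxt = pos + d
                while (0 <= nxt[0] < nz and 0 <= nxt[1] < ny
                       and 0 <= nxt[2] < nx and quantized[tuple(nxt)] == level):
                    length += 1
                    nxt += d
                runs[(level, length)] = runs.get((level, length), 0) + 1
    max_len = max((l for (_, l) in runs), default=1)
    rlm = np.zeros((levels, max_len))
    for (lev, length), cnt in runs.items():
        rlm[lev - 1, length - 1] = cnt
    return rlm
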