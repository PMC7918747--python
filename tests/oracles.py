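"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's internal code paths: dispersion is
recomputed from slices, fixation windows are enumerated exhaustively, the
sign-flip null is enumerated over all 2^n assignments with scipy's t test.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import stats


def brute_dispersion(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return (max(x) - min(x)) + (max(y) - min(y))


def idt_oracle(t, x, y, valid, min_duration_ms, max_dispersion_px):
    """Exhaustive maximal-window fixation enumeration (greedy left to right).

    For each candidate start the maximal end is found by checking every
    window's dispersion from scratch (dispersion only grows with expansion,
    so the maximal end is well defined). Returns a list of dicts with
    start/end/centroid. Invalid samples break candidate windows.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    valid = np.asarray(valid, bool)
    period = float(np.median(np.diff(t))) if len(t) > 1 else 1000.0 / 120.0

    idx = np.flatnonzero(valid)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1) if len(idx) else []
    out = []
    for run in runs:
        i = 0
        n = len(run)
        while i < n:
            j = i
            while j + 1 < n and brute_dispersion(
                x[run[i : j + 2]], y[run[i : j + 2]]
            ) <= max_dispersion_px:
                j += 1
            span = (t[run[j]] + period) - t[run[i]]
            if span >= min_duration_ms - 1e-9:
                out.append(
                    dict(
                        start_ms=float(t[run[i]]),
                        end_ms=float(t[run[j]] + period),
                        centroid_x=float(np.mean(x[run[i : j + 1]])),
                        centroid_y=float(np.mean(y[run[i : j + 1]])),
                        n_samples=j - i + 1,
                    )
                )
                i = j + 1
            else:
                i += 1
    return out


def _oracle_bin_tests(matrix, chance, alpha_bin, min_n):
    """Per-bin one-sample t tests via scipy, returning (t, significant)."""
    m = np.asarray(matrix, float)
    nb = m.shape[1]
    tvals = np.full(nb, np.nan)
    sig = np.zeros(nb, bool)
    for b in range(nb):
        col = m[:, b]
        col = col[np.isfinite(col)]
        if len(col) < min_n or np.std(col, ddof=1) == 0:
            continue
        res = stats.ttest_1samp(col, chance)
        tvals[b] = res.statistic
        sig[b] = res.pvalue < alpha_bin
    return tvals, sig


def oracle_cluster_masses(tvals, sig):
    """Signed masses of maximal same-sign runs of significant bins."""
    masses = []
    cur = 0.0
    cur_sign = 0
    for b in range(len(sig) + 1):
        s = int(np.sign(tvals[b])) if b < len(sig) and sig[b] else 0
        if cur_sign and s != cur_sign:
            masses.append(cur)
            cur, cur_sign = 0.0, 0
        if s:
            cur += tvals[b]
            cur_sign = s
    return masses


def exact_signflip_null(matrix, chance=0.5, alpha_bin=0.05, min_n=2):
    """Exhaustive sign-flip enumeration: max |cluster mass| for every one of
    the 2^n_subjects equally likely sign assignments."""
    m = np.asarray(matrix, float)
    dev = m - chance
    out = []
    for signs in product((1.0, -1.0), repeat=m.shape[0]):
        flipped = chance + np.asarray(signs)[:, None] * dev
        tvals, sig = _oracle_bin_tests(flipped, chance, alpha_bin, min_n)
        masses = oracle_cluster_masses(tvals, sig)
        out.append(max((abs(mm) for mm in masses), default=0.0))
    return np.asarray(out)


def exact_cluster_p(mass, exact_null):
    return float(np.mean(exact_null >= abs(mass)))
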