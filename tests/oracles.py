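"""Independent reference implementations used only as test oracles.

Deliberately naive (explicit loops, no shared code with the package) so
that agreement with the vectorized implementations is evidence, not
tautology.
"""

from __future__ import annotations

import numpy as np


def spike_contrast_reference(trains, t_start, t_stop, min_bin_s=0.01,
                             shrink=0.9):
    """Loop-based multi-timescale synchrony (half-overlapping bins).

    For each bin size b on the geometric grid from (t_stop-t_start)/2
    down to max(min ISI / 2, min_bin_s): windows [k*b/2, k*b/2 + b)
    anchored at t_start; theta_k = pooled spike count in window k,
    n_k = trains with at least one spike there.  Synchrony =
    max_b [ sum_k |theta_{k+1}-theta_k| / (2 * n_spikes_total) ]
          * [ (sum_k n_k theta_k / sum_k theta_k - 1) / (N - 1) ].
    """
    trains = [np.asarray(t, float) for t in trains if len(t)]
    n = len(trains)
    total = sum(len(t) for t in trains)
    isi_min = np.inf
    for t in trains:
        for a, b in zip(t, t[1:]):
            isi_min = min(isi_min, b - a)
    bin_max = (t_stop - t_start) / 2.0
    bin_min = min(max(isi_min / 2.0, min_bin_s), bin_max)

    best = -np.inf
    b = bin_max
    while b >= bin_min * (1 - 1e-12):
        step = b / 2.0
        edges = np.arange(t_start, t_stop + step, step)
        n_halves = len(edges) - 1

        def in_half(s, m):
            # histogram half-bins: half-open except the last one
            if m == n_halves - 1:
                return edges[m] <= s <= edges[m + 1]
            return edges[m] <= s < edges[m + 1]

        theta = []
        nk = []
        for k in range(n_halves - 1):   # overlapping bin = halves k, k+1
            cnt = 0
            active = 0
            for t in trains:
                c = sum(1 for s in t if in_half(s, k) or in_half(s, k + 1))
                cnt += c
                active += c > 0
            theta.append(cnt)
            nk.append(active)
        theta = np.array(theta, float)
        nk = np.array(nk, float)
        if theta.sum() > 0:
            contrast = sum(abs(theta[k + 1] - theta[k])
                           for k in range(len(theta) - 1)) / (2.0 * total)
            activef = ((nk * theta).sum() / theta.sum() - 1.0) / (n - 1.0)
            best = max(best, contrast * activef)
        else:
            best = max(best, 0.0)
        b *= shrink
    return best


def bursts_reference(times, max_isi_ms=10.0, min_spikes=3,
                     min_duration_ms=1.0, min_ibi_ms=200.0):
    """Brute-force MaxInterval burst rules; returns (start, end, n) tuples.

    Step 1: exhaustively grow runs spike-by-spike while the next ISI is
    within max_isi.  Step 2: keep runs with >= min_spikes.  Step 3: merge
    kept runs whose gap is below min_ibi (counting every spike inside
    the merged span).  Step 4: drop merged bursts shorter than
    min_duration.
    """
    t = sorted(float(x) for x in times)
    runs = []
    i = 0
    while i < len(t):
        j = i
        while j + 1 < len(t) and (t[j + 1] - t[j]) * 1e3 <= max_isi_ms:
            j += 1
        runs.append((i, j))
        i = j + 1
    cand = [(a, b) for a, b in runs if b - a + 1 >= min_spikes]
    merged = []
    for a, b in cand:
        if merged and (t[a] - t[merged[-1][1]]) * 1e3 < min_ibi_ms:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    out = []
    for a, b in merged:
        start, end = t[a], t[b]
        if (end - start) * 1e3 < min_duration_ms:
            continue
        n = sum(1 for x in t if start <= x <= end)
        out.append((start, end, n))
    return out
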