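"""Independent straight-line re-implementations used as oracles.

These deliberately share no code with the package: plain Python loops and
the ``statistics`` module only, so that agreement with the package is a
genuine dual-route check.
"""

import math
import statistics


def oracle_smooth(values, window, segment_ids):
    """Centred moving average, symmetric shrink at segment ends."""
    n = len(values)
    half = window // 2
    out = [0.0] * n
    for i in range(n):
        # segment extent around i
        lo = i
        while lo > 0 and segment_ids[lo - 1] == segment_ids[i]:
            lo -= 1
        hi = i
        while hi < n - 1 and segment_ids[hi + 1] == segment_ids[i]:
            hi += 1
        h = min(half, i - lo, hi - i)
        window_vals = values[i - h: i + h + 1]
        out[i] = sum(window_vals) / len(window_vals)
    return out


def oracle_top_half_cutoff(values, k):
    ordered = sorted(values, reverse=True)
    top = ordered[: math.ceil(len(ordered) / 2)]
    mean = sum(top) / len(top)
    sd = statistics.stdev(top) if len(top) >= 2 else 0.0
    return mean - k * sd


def oracle_trim(cc, segment_ids, params, plddt=None):
    """Straight-line version of the full three-step trim.

    ``params`` is any object with the trimming parameter attributes.
    Returns the list of kept residue indices.
    """
    n = len(cc)
    window = params.minimum_domain_length
    smoothed = oracle_smooth(cc, window, segment_ids)
    use_plddt = plddt is not None
    if use_plddt:
        smoothed_plddt = oracle_smooth(plddt, window, segment_ids)

    # step 1: remove where smoothed cc (and, if given, smoothed plddt) are low
    cc_cut = oracle_top_half_cutoff(smoothed, params.cc_sd_ratio)
    if use_plddt:
        plddt_cut = oracle_top_half_cutoff(smoothed_plddt, params.cc_sd_ratio)
    keep = []
    for i in range(n):
        low_cc = smoothed[i] < cc_cut
        if use_plddt:
            removed = low_cc and (smoothed_plddt[i] < plddt_cut)
        else:
            removed = low_cc
        keep.append(not removed)

    def segments_of(mask):
        segs = []
        current = []
        for i in range(n):
            if not mask[i]:
                if current:
                    segs.append(current)
                    current = []
                continue
            if current and segment_ids[i] != segment_ids[current[-1]]:
                segs.append(current)
                current = []
            current.append(i)
        if current:
            segs.append(current)
        return segs

    # step 2: strip weak segment ends at a higher cutoff, then drop short segs
    survivors = [i for i in range(n) if keep[i]]
    if survivors:
        end_cut = oracle_top_half_cutoff([cc[i] for i in survivors],
                                         params.cc_sd_ratio_end)
        for seg in segments_of(keep):
            a, b = 0, len(seg) - 1
            while a <= b and cc[seg[a]] < end_cut and smoothed[seg[a]] < end_cut:
                keep[seg[a]] = False
                a += 1
            while b >= a and cc[seg[b]] < end_cut and smoothed[seg[b]] < end_cut:
                keep[seg[b]] = False
                b -= 1
        for seg in segments_of(keep):
            if len(seg) < window:
                for i in seg:
                    keep[i] = False

    # step 3: drop whole segments with much lower mean cc
    segs = segments_of(keep)
    if not segs:
        return []
    means = [sum(cc[i] for i in seg) / len(seg) for seg in segs]
    ordered = sorted(means, reverse=True)
    top = ordered[: math.ceil(len(ordered) / 2)]
    m = sum(top) / len(top)
    cutoff = max(params.reasonable_cc_ratio ** 2 * m,
                 m - 2 * params.reasonable_cc_diff)
    kept = []
    for seg, mean in zip(segs, means):
        if not (mean < cutoff):
            kept.extend(seg)
    return kept


def oracle_rmsd_minimum(coords_a, coords_b, n_grid=40):
    """Brute-force minimum rmsd over rotations (coarse Euler grid + refine).

    Only suitable for tiny point sets; used to sanity-check least-squares
    superposition.
    """
    import numpy as np
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def cost(euler):
        rot = Rotation.from_euler("xyz", euler).as_matrix()
        return float(np.sqrt(np.mean(np.sum((a0 - b0 @ rot.T) ** 2, axis=1))))

    best = None
    grid = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    for ex in grid[::4]:
        for ey in grid[::4]:
            for ez in grid[::4]:
                c = cost((ex, ey, ez))
                if best is None or c < best[0]:
                    best = (c, (ex, ey, ez))
    result = minimize(cost, best[1], method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12})
    return float(result.fun)
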