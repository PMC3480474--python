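"""Independent brute-force oracle for the space-time scan.

Enumerates every cylinder with plain Python loops and computes the
Poisson log likelihood ratio directly with ``numpy.log`` — no tables, no
compiled kernels, no code shared with the implementation under test.
"""

import math

import numpy as np


def brute_cylinders(coords, n_st, max_spatial_frac=0.5, max_temporal_frac=0.5):
    """Yield (g, k, s, e, radius, c, mu, glr) for every candidate cylinder."""
    coords = np.asarray(coords, float)
    n_st = np.asarray(n_st, int)
    L, T = n_st.shape
    ns = n_st.sum(axis=1)
    nt = n_st.sum(axis=0)
    N = int(n_st.sum())
    cap = math.floor(max_spatial_frac * N)
    t_max = max(1, math.floor(max_temporal_frac * T))
    for g in range(L):
        d = np.hypot(coords[:, 0] - coords[g, 0], coords[:, 1] - coords[g, 1])
        order = np.argsort(d, kind="stable")
        mass = 0
        included = []
        for k, loc in enumerate(order):
            mass += ns[loc]
            if k > 0 and mass > cap:
                break
            included.append(loc)
            radius = float(d[loc])
            circle_ns = int(sum(ns[j] for j in included))
            for s in range(T):
                for e in range(s, min(T, s + t_max)):
                    c = int(n_st[np.array(included)][:, s : e + 1].sum())
                    nti = int(nt[s : e + 1].sum())
                    mu = circle_ns * nti / N
                    if c > mu:
                        glr = c * math.log(c / mu)
                        if c < N:
                            glr += (N - c) * math.log((N - c) / (N - mu))
                    else:
                        glr = 0.0
                    yield g, k, s, e, radius, c, mu, glr


def brute_max(coords, n_st, max_spatial_frac=0.5, max_temporal_frac=0.5):
    """argmax cylinder under the same deterministic tie-break order:
    higher glr, then smaller radius, shorter interval, lower center id,
    earlier start."""
    best = None
    for g, k, s, e, radius, c, mu, glr in brute_cylinders(
        coords, n_st, max_spatial_frac, max_temporal_frac
    ):
        key = (-glr, radius, e - s, g, s)
        if best is None or key < best[0]:
            best = (key, dict(g=g, k=k, s=s, e=e, radius=radius, c=c, mu=mu, glr=glr))
    return best[1]


def random_instance(rng, max_L=8, max_T=6):
    """Small random scan instance: clustered integer coordinates (to
    exercise distance ties) and sparse random counts."""
    L = int(rng.integers(2, max_L + 1))
    T = int(rng.integers(2, max_T + 1))
    coords = rng.integers(0, 4, size=(L, 2)).astype(float)
    n_st = rng.integers(0, 4, size=(L, T))
    # ensure every location holds at least one case and >= 2 months used
    for i in range(L):
        if n_st[i].sum() == 0:
            n_st[i, int(rng.integers(0, T))] = 1
    if (n_st.sum(axis=0) > 0).sum() < 2:
        n_st[int(rng.integers(0, L)), 0] += 1
        n_st[int(rng.integers(0, L)), T - 1] += 1
    return coords, n_st.astype(np.int64)
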