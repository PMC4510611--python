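"""Independent naive oracles shared by the system-level checks.

These deliberately re-derive each quantity with direct loops/enumeration,
never calling the library code paths they are used to verify.
"""

import numpy as np

from cascadet.haar import signed_rects


def naive_haar(img, f):
    total = 0.0
    for s, r in signed_rects(f):
        total += s * img[r.y : r.y + r.h, r.x : r.x + r.w].sum()
    return total


def naive_first_order(h):
    N = len(h)
    idx = np.arange(N)
    mu = sum(i * h[i] for i in idx)
    var = sum((i - mu) ** 2 * h[i] for i in idx)
    cum = np.cumsum(h)
    quart = [next(i for i in idx if cum[i] >= q) for q in (0.25, 0.5, 0.75)]
    nz = idx[h > 0]
    sd = np.sqrt(var)
    return dict(
        mean=mu, mode=float(np.argmax(h)), variance=var,
        q1=quart[0], q2=quart[1], q3=quart[2], iqr=quart[2] - quart[0],
        minimum=nz[0], maximum=nz[-1], value_range=nz[-1] - nz[0],
        entropy=-sum(h[i] * np.log(h[i]) for i in idx if h[i] > 0),
        asymmetry=sum((i - mu) ** 3 * h[i] for i in idx) / sd**3 if sd > 0 else 0.0,
        kurtosis=sum((i - mu) ** 4 * h[i] for i in idx) / sd**4 if sd > 0 else 0.0,
    )


def naive_haralick(p):
    N = p.shape[0]
    px, py = p.sum(1), p.sum(0)
    mux = sum(i * px[i] for i in range(N))
    muy = sum(j * py[j] for j in range(N))
    sdx = np.sqrt(sum((i - mux) ** 2 * px[i] for i in range(N)))
    sdy = np.sqrt(sum((j - muy) ** 2 * py[j] for j in range(N)))
    ps = np.zeros(2 * N - 1)
    pd = np.zeros(N)
    for i in range(N):
        for j in range(N):
            ps[i + j] += p[i, j]
            pd[abs(i - j)] += p[i, j]
    ent = lambda v: -sum(x * np.log(x) for x in np.ravel(v) if x > 0)
    sa = sum(k * ps[k] for k in range(2 * N - 1))
    mud = sum(k * pd[k] for k in range(N))
    hx, hy, hxy = ent(px), ent(py), ent(p)
    hxy1 = -sum(p[i, j] * np.log(px[i] * py[j])
                for i in range(N) for j in range(N) if p[i, j] > 0)
    hxy2 = ent(np.outer(px, py))
    return dict(
        energy=(p**2).sum(),
        correlation=(sum(i * j * p[i, j] for i in range(N) for j in range(N))
                     - mux * muy) / (sdx * sdy) if sdx * sdy > 0 else 0.0,
        contrast=sum((i - j) ** 2 * p[i, j] for i in range(N) for j in range(N)),
        variance=sum((i - mux) ** 2 * p[i, j] for i in range(N) for j in range(N)),
        sum_average=sa,
        sum_entropy=ent(ps),
        sum_variance=sum((k - sa) ** 2 * ps[k] for k in range(2 * N - 1)),
        entropy=hxy,
        difference_variance=sum((k - mud) ** 2 * pd[k] for k in range(N)),
        difference_entropy=ent(pd),
        corr_info_1=(hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        corr_info_2=np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy)))),
        homogeneity_1=sum(p[i, j] / (1 + (i - j) ** 2)
                          for i in range(N) for j in range(N)),
        homogeneity_2=sum(p[i, j] / (1 + abs(i - j))
                          for i in range(N) for j in range(N)),
        cluster_shade=sum((i + j - mux - muy) ** 3 * p[i, j]
                          for i in range(N) for j in range(N)),
        cluster_prominence=sum((i + j - mux - muy) ** 4 * p[i, j]
                               for i in range(N) for j in range(N)),
        autocorrelation=sum(i * j * p[i, j] for i in range(N) for j in range(N)),
        dissimilarity=sum(abs(i - j) * p[i, j] for i in range(N) for j in range(N)),
        max_probability=p.max(),
    )


def exhaustive_best_error(X, y, w):
    best = np.inf
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        cands = [-np.inf, np.inf] + list((vals[:-1] + vals[1:]) / 2)
        for thr in cands:
            for pol in (1, -1):
                pred = np.where(pol * (X[:, j] - thr) > 0, 1, -1)
                best = min(best, w[pred != y].sum())
    return best
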