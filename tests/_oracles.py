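"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's computational paths: the posterior
oracle integrates the full 4-D parameter box on a single dense grid with no
analytic marginalisation and no refinement, and the signed-rank oracle
enumerates all sign assignments explicitly.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_posterior_medians(curve, priors, sigma, n=100):
    """Marginal posterior medians by dense 4-D grid integration.

    Axes: S0, f and D are uniform linear grids over their prior bounds; any
    parameter named in ``priors.log_scale`` uses a uniform grid in log space
    (equivalent to a log-uniform prior with uniform node weights).
    """
    b, y = np.asarray(curve.abscissa, float), np.asarray(curve.signal, float)
    s0_max = priors.resolve_s0_max(curve)

    def axis(bounds, name):
        if name in priors.log_scale:
            return np.geomspace(*bounds, n)
        return np.linspace(*bounds, n)

    s0_ax = np.linspace(s0_max / (2 * n), s0_max, n)
    f_ax = np.linspace(*priors.f_bounds, n)
    d_ax = axis(priors.d_bounds, "d")
    ds_ax = axis(priors.d_star_bounds, "d_star")

    def weights(x):
        w = np.empty_like(x)
        w[1:-1] = 0.5 * (x[2:] - x[:-2])
        w[0] = 0.5 * (x[1] - x[0])
        w[-1] = 0.5 * (x[-1] - x[-2])
        # log axes: uniform weight in log space
        return w

    w_s0, w_f = weights(s0_ax), weights(f_ax)
    w_d = weights(np.log(d_ax)) if "d" in priors.log_scale else weights(d_ax)
    w_ds = weights(np.log(ds_ax)) if "d_star" in priors.log_scale else weights(ds_ax)

    C = float(y @ y)
    ed = np.exp(-np.outer(d_ax, b))    # (n, nb)
    eds = np.exp(-np.outer(ds_ax, b))  # (n, nb)

    def slice_AB(fi):
        g = fi * eds[None, :, :] + (1 - fi) * ed[:, None, :]  # (nd, nds, nb)
        return np.einsum("ijb,ijb->ij", g, g), g @ y

    # pass 1: global log-likelihood maximum (profiled over s0 analytically)
    gmax = -np.inf
    for fi in f_ax:
        A, B = slice_AB(fi)
        s0_star = np.clip(B / A, s0_ax[0], s0_ax[-1])
        ll = -(C - 2 * s0_star * B + s0_star**2 * A) / (2 * sigma**2)
        gmax = max(gmax, float(ll.max()))

    # pass 2: accumulate marginal masses
    marg = {k: np.zeros(n) for k in ("s0", "f", "d", "d_star")}
    for i, fi in enumerate(f_ax):
        A, B = slice_AB(fi)
        ssr = (
            C
            - 2 * s0_ax[None, None, :] * B[:, :, None]
            + s0_ax[None, None, :] ** 2 * A[:, :, None]
        )
        w = np.exp(-ssr / (2 * sigma**2) - gmax)  # (nd, nds, ns0)
        w *= w_d[:, None, None] * w_ds[None, :, None] * w_s0[None, None, :]
        marg["f"][i] += w_f[i] * w.sum()
        marg["d"] += w_f[i] * w.sum(axis=(1, 2))
        marg["d_star"] += w_f[i] * w.sum(axis=(0, 2))
        marg["s0"] += w_f[i] * w.sum(axis=(0, 1))

    axes = {"s0": s0_ax, "f": f_ax, "d": d_ax, "d_star": ds_ax}
    out = {}
    for k, m in marg.items():
        cdf = (np.cumsum(m) - 0.5 * m) / m.sum()
        out[k] = float(np.interp(0.5, cdf, axes[k]))
    return out


def wilcoxon_exact_two_sided_p(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign assignments.

    Zero differences are removed first; p = 2*min(P(W+ <= w), P(W+ >= w)),
    capped at 1 (the convention scipy uses for the exact null).
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = _rank(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product((False, True), repeat=n)
    ])
    p_le = np.mean(stats <= w_obs)
    p_ge = np.mean(stats >= w_obs)
    return float(min(1.0, 2 * min(p_le, p_ge)))


def _rank(values):
    """Average ranks (1-based) with midrank ties."""
    order = np.argsort(values)
    ranks = np.empty(len(values))
    i = 0
    sorted_v = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks
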