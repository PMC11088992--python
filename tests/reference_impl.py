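"""Independent brute-force reference of the attribution update equations.

Deliberately written with plain Python loops and ``math`` only, so it
shares no code path with the package implementation. Used as the
oracle for trajectory equivalence checks.
"""

import math


def reference_trajectory(par, outcomes, hi_bins, si_bins, block_starts, nb=9):
    """Return (list of nb x nb grids, total report log-likelihood).

    ``par`` is a dict with keys pHI0, pSI0, uPri_HI, uPri_SI, w0, wHI,
    wSI, u_pi, eta (model space). Bins are 1-based; block_starts are
    0-based first-trial indices per partner.
    """
    xi = 0.02 / nb**2

    def marginal(p0, u):
        n = nb - 1
        pmf = [math.comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in range(nb)]
        powed = [p ** (1.0 / u) for p in pmf]
        s = sum(powed)
        return [p / s for p in powed]

    hi_m = marginal(par["pHI0"], par["uPri_HI"])
    si_m = marginal(par["pSI0"], par["uPri_SI"])
    prior = [[hi_m[i] * si_m[j] for j in range(nb)] for i in range(nb)]

    delta = (nb + 1) / 2
    p_unfair = [
        [
            1.0 / (1.0 + math.exp(-(par["w0"] + par["wHI"] * (i + 1 - delta)
                                    + par["wSI"] * (j + 1 - delta))))
            for j in range(nb)
        ]
        for i in range(nb)
    ]

    g = [row[:] for row in prior]
    grids, total_ll = [], 0.0
    for t, rew in enumerate(outcomes):
        if t in block_starts and t != 0:
            g = [
                [(1 - par["eta"]) * prior[i][j] + par["eta"] * g[i][j]
                 for j in range(nb)]
                for i in range(nb)
            ]
        lik = p_unfair if rew == 0.0 else [
            [1.0 - p_unfair[i][j] for j in range(nb)] for i in range(nb)
        ]
        g = [[g[i][j] * lik[i][j] for j in range(nb)] for i in range(nb)]
        s = sum(sum(row) for row in g)
        g = [[c / s for c in row] for row in g]
        g = [[c ** (1.0 / par["u_pi"]) + xi for c in row] for row in g]
        s = sum(sum(row) for row in g)
        g = [[c / s for c in row] for row in g]
        grids.append([row[:] for row in g])
        total_ll += math.log(max(g[hi_bins[t] - 1][si_bins[t] - 1], 1e-12))
    return grids, total_ll
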