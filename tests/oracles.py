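"""Independent reference implementations used as test oracles.

Everything here is written as a literal, slow re-derivation of the
statistic it checks (loops, sorting, enumeration) and is deliberately
kept independent of the code paths in :mod:`clinexp`.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize


def tmm_factors_reference(counts: np.ndarray, trim_m: float = 0.3, trim_a: float = 0.05) -> np.ndarray:
    """Step-by-step TMM recipe: UQ reference, M/A trims, precision weights."""
    counts = np.asarray(counts, float)
    lib = counts.sum(axis=0)
    n_samples = counts.shape[1]

    uq = []
    for j in range(n_samples):
        uq.append(np.quantile(counts[:, j] / lib[j], 0.75))
    uq = np.array(uq)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = []
    for j in range(n_samples):
        if j == ref:
            log_factors.append(0.0)
            continue
        m_vals, a_vals, w_vals = [], [], []
        for g in range(counts.shape[0]):
            yo, yr = counts[g, j], counts[g, ref]
            if yo > 0 and yr > 0:
                po, pr = yo / lib[j], yr / lib[ref]
                m_vals.append(math.log2(po / pr))
                a_vals.append(0.5 * math.log2(po * pr))
                w_vals.append((lib[j] - yo) / (lib[j] * yo) + (lib[ref] - yr) / (lib[ref] * yr))
        m = np.array(m_vals)
        a = np.array(a_vals)
        w = np.array(w_vals)
        if m.size == 0 or np.max(np.abs(m)) < 1e-6:
            log_factors.append(0.0)
            continue
        n = m.size

        def avg_rank(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(n)
            sv = v[order]
            i = 0
            while i < n:
                jj = i
                while jj + 1 < n and sv[jj + 1] == sv[i]:
                    jj += 1
                ranks[order[i : jj + 1]] = (i + jj) / 2.0 + 1.0
                i = jj + 1
            return ranks

        rm, ra = avg_rank(m), avg_rank(a)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            log_factors.append(0.0)
            continue
        f = float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
        log_factors.append(f)

    factors = np.array([2.0**f for f in log_factors])
    return factors / np.exp(np.mean(np.log(factors)))


def bh_reference(pvals: list[float]) -> list[float]:
    """Textbook BH step-up with monotonicity enforcement."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [pvals[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = [0.0] * m
    for i, idx in enumerate(order):
        q[idx] = min(q_sorted[i], 1.0)
    return q


def pearson_reference(x, y) -> float:
    """Covariance / variance formula evaluated directly."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / math.sqrt(vx * vy)


def tau_reference(profile) -> float:
    """Direct evaluation of the tau formula."""
    mx = max(profile)
    n = len(profile)
    return sum(1.0 - v / mx for v in profile) / (n - 1)


def chi2_2x2_reference(table, yates: bool) -> float:
    """Sum over cells of (|O - E| - correction)^2 / E."""
    table = [[float(v) for v in row] for row in table]
    n = sum(sum(row) for row in table)
    rows = [sum(row) for row in table]
    cols = [table[0][j] + table[1][j] for j in range(2)]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            dev = abs(table[i][j] - e)
            if yates:
                dev = max(dev - 0.5, 0.0)
            stat += dev**2 / e
    return stat


def adjusted_residuals_reference(table) -> np.ndarray:
    table = np.asarray(table, float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    out = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            out[i, j] = (table[i][j] - e) / math.sqrt(
                e * (1 - rows[i] / n) * (1 - cols[j] / n)
            )
    return out


def fisher_reference(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d

    def hyper(k):
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = hyper(a)
    return sum(p for k in range(lo, hi + 1) if (p := hyper(k)) <= p_obs * (1 + 1e-7))


def wilcoxon_w_reference(x, y) -> float:
    """Pairwise-count definition: #{x_i > y_j} + ties / 2."""
    w = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                w += 1.0
            elif xi == yj:
                w += 0.5
    return w


def exact_wilcoxon_p_reference(x, y) -> float:
    """Two-sided exact p by enumeration of all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    w_obs = wilcoxon_w_reference(x, y)
    mu = n1 * len(y) / 2.0
    dev = abs(w_obs - mu)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in comb]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in comb]
        w = wilcoxon_w_reference(g1, g2)
        total += 1
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return count / total


def dense_grid_shape_search(
    x: np.ndarray,
    l: np.ndarray,
    kappa_bounds=(1e-2, 50.0),
    n_c: int = 80,
    n_k: int = 60,
    sigma_floor: float = 1e-6,
):
    """Brute-force ML search over the four cline models.

    Dense (kappa, c) grid with closed-form (x_s, d) per grid point,
    polished by Nelder-Mead clipped to the same box; null/linear/step in
    closed form.  Returns {model: (aic, rss)} and the minimum-AIC model
    with ties toward fewer parameters.
    """
    n = len(x)
    l_max = float(l.max())

    def aic_of(rss, k):
        s2 = max(rss / n, sigma_floor**2)
        logl = -(n / 2.0) * math.log(2 * math.pi * s2) - rss / (2 * s2)
        return 2 * k - 2 * logl

    out = {}
    # null
    rss = float(np.sum((x - x.mean()) ** 2))
    out["null"] = (aic_of(rss, 2), rss)
    # linear (normal equations written out)
    sl, sx = l.sum(), x.sum()
    sll, slx = float(l @ l), float(l @ x)
    det = n * sll - sl * sl
    b = (n * slx - sl * sx) / det
    a0 = (sx - b * sl) / n
    rss = float(np.sum((x - a0 - b * l) ** 2))
    out["linear"] = (aic_of(rss, 3), rss)
    # step over midpoints
    sites = np.unique(l)
    best = math.inf
    for lc in (sites[:-1] + sites[1:]) / 2:
        south = l < lc
        rss = float(
            np.sum((x[south] - x[south].mean()) ** 2)
            + np.sum((x[~south] - x[~south].mean()) ** 2)
        )
        best = min(best, rss)
    out["step"] = (aic_of(best, 4), best)
    # sigmoid: dense grid over (kappa, c) with closed-form (x_s, d),
    # then iterative grid refinement around the incumbent
    def scan(kappas, cs, best):
        for kappa in kappas:
            for c in cs:
                h = (1.0 + np.tanh(kappa * (l - c))) / 2.0
                vh = h.var()
                if vh < 1e-12:
                    continue
                d = float(np.cov(h, x, bias=True)[0, 1] / vh)
                xs = float(x.mean() - d * h.mean())
                xs = min(max(xs, -3.0), 3.0)
                d = min(max(d, -3.0), 3.0)
                rss = float(np.sum((x - xs - d * h) ** 2))
                if rss < best[0]:
                    best = (rss, kappa, c)
        return best

    kappas = np.geomspace(kappa_bounds[0], kappa_bounds[1], n_k)
    cs = np.linspace(0.0, l_max, n_c)
    grid_rss = np.full((n_k, n_c), math.inf)
    for i, kappa in enumerate(kappas):
        for j, c in enumerate(cs):
            b = scan([kappa], [c], (math.inf, None, None))
            grid_rss[i, j] = b[0]

    def profiled(p):
        kappa = math.exp(min(max(p[0], math.log(kappa_bounds[0])),
                             math.log(kappa_bounds[1])))
        c = min(max(p[1], 0.0), l_max)
        return scan([kappa], [c], (math.inf, None, None))[0]

    best_rss = grid_rss.min()
    flat_order = np.argsort(grid_rss, axis=None)[:8]
    for flat in flat_order:
        i, j = np.unravel_index(flat, grid_rss.shape)
        res = minimize(profiled, [math.log(kappas[i]), cs[j]], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 4000})
        best_rss = min(best_rss, float(res.fun))
    out["sigmoid"] = (aic_of(best_rss, 5), best_rss)

    order = ["null", "linear", "step", "sigmoid"]
    best_aic = min(a for a, _ in out.values())
    winner = next(m for m in order if out[m][0] - best_aic < 1e-6)
    return out, winner
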