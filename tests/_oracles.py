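"""Independent reference implementations used to check the package.

Deliberately naive: explicit loops, enumeration, quadrature and scalar
optimization, sharing no code with the implementation paths they verify.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar


def flood_fill_threshold(data: np.ndarray, seed_idx: tuple, threshold: float) -> np.ndarray:
    """Breadth-first flood fill of {data >= threshold} from a seed voxel,
    26-neighbourhood, as an oracle for connected-component MTV segmentation."""
    shape = data.shape
    assert data[seed_idx] >= threshold
    visited = np.zeros(shape, dtype=bool)
    stack = [seed_idx]
    visited[seed_idx] = True
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    while stack:
        i, j, k = stack.pop()
        for dx, dy, dz in offsets:
            a, b, c = i + dx, j + dy, k + dz
            if 0 <= a < shape[0] and 0 <= b < shape[1] and 0 <= c < shape[2]:
                if not visited[a, b, c] and data[a, b, c] >= threshold:
                    visited[a, b, c] = True
                    stack.append((a, b, c))
    return visited


def _u_greater(a: np.ndarray, b: np.ndarray) -> float:
    """Count of pairs with a > b, plus half of the ties (pure loops)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mannwhitney_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of all
    C(nA+nB, nA) group labelings of the pooled sample (tie-free data)."""
    pooled = np.concatenate([a, b])
    n = pooled.size
    n_a = a.size
    u_obs = _u_greater(a, b)
    u_hi = max(u_obs, n_a * (n - n_a) - u_obs)
    count = 0
    total = 0
    for idx_a in combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx_a)] = True
        u = _u_greater(pooled[mask], pooled[~mask])
        total += 1
        if u >= u_hi:
            count += 1
    return min(2.0 * count / total, 1.0)


def pearson_p_quadrature(r: float, n: int) -> float:
    """Two-sided t-test p for a Pearson correlation by numeric integration
    of the Student-t density (gamma-function form, no scipy.stats)."""
    nu = n - 2
    t = abs(r) * math.sqrt(nu / (1.0 - r * r))

    def t_pdf(s: float) -> float:
        return (
            math.gamma((nu + 1) / 2.0)
            / (math.sqrt(nu * math.pi) * math.gamma(nu / 2.0))
            * (1.0 + s * s / nu) ** (-(nu + 1) / 2.0)
        )

    tail, _ = quad(t_pdf, t, np.inf)
    return 2.0 * tail


def cox_beta_brute_force(times, events, x, ties: str = "breslow") -> float:
    """Maximize the Cox partial likelihood (written out directly from its
    definition) over a bounded beta grid via scalar optimization."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)

    def neg_log_pl(beta: float) -> float:
        ll = 0.0
        for t in np.unique(times[events]):
            at_risk = times >= t
            dead = events & (times == t)
            d = int(dead.sum())
            risk_sum = np.exp(beta * x[at_risk]).sum()
            ll += beta * x[dead].sum()
            if ties == "breslow":
                ll -= d * math.log(risk_sum)
            else:
                raise ValueError(ties)
        return -ll

    res = minimize_scalar(
        neg_log_pl, bounds=(-10.0, 10.0), method="bounded", options={"xatol": 1e-10}
    )
    return float(res.x)


def km_by_counting(times, events) -> dict[float, float]:
    """Survival after each event time by direct counting (no-censoring-aware
    product over event times)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    s = 1.0
    out = {}
    for t in np.unique(times[events]):
        n_risk = int((times >= t).sum())
        d = int((events & (times == t)).sum())
        s *= (n_risk - d) / n_risk
        out[float(t)] = s
    return out
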