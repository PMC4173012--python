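"""Independent reference computations used by the test suite.

These deliberately avoid the package's own algorithmic paths: isotope
patterns are checked against full isotopologue enumeration, conjugate
updates against numerical integration, and the Gibbs sampler against an
exhaustive sum over all set partitions x formula links x adduct-isotope
assignments with joint multivariate-normal marginals from scipy.
"""

from __future__ import annotations

import itertools
import math
from math import lgamma

import numpy as np
from scipy import optimize, stats

from ionclust.elements import ISOTOPES
from ionclust.chem import Formula, PeakLibrary, monoisotopic_mass


# ---------------------------------------------------------------------------
# isotope patterns: full isotopologue enumeration
# ---------------------------------------------------------------------------

def _multinomial_compositions(n: int, k: int):
    """All (n_1..n_k) with sum n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _multinomial_compositions(n - first, k - 1):
            yield (first,) + rest


def _log_multinomial(n: int, parts: tuple[int, ...]) -> float:
    return lgamma(n + 1) - sum(lgamma(p + 1) for p in parts)


def brute_force_pattern(formula: Formula) -> dict[int, tuple[float, float]]:
    """Exact aggregated isotope pattern by enumerating every isotopologue.

    Returns {nominal shift: (probability, mean mass)} where the shift is the
    rounded difference between the isotopologue mass and the monoisotopic
    mass.  Exponential in atom count; intended for <= 10 atoms.
    """
    mono = monoisotopic_mass(formula)
    per_element = []
    for sym, count in formula.element_counts:
        isos = ISOTOPES[sym]
        entries = []  # (prob, mass) per composition of this element block
        for comp in _multinomial_compositions(count, len(isos)):
            logp = _log_multinomial(count, comp)
            mass = 0.0
            ok = True
            for n_j, (m_j, ab_j) in zip(comp, isos):
                if n_j and ab_j == 0.0:
                    ok = False
                    break
                if n_j:
                    logp += n_j * math.log(ab_j)
                    mass += n_j * m_j
            if ok:
                entries.append((math.exp(logp), mass))
        per_element.append(entries)
    agg: dict[int, list[float]] = {}
    for combo in itertools.product(*per_element):
        prob = math.prod(p for p, _ in combo)
        mass = sum(m for _, m in combo)
        shift = round(mass - mono)
        acc = agg.setdefault(shift, [0.0, 0.0])
        acc[0] += prob
        acc[1] += prob * mass
    return {s: (p, pm / p) for s, (p, pm) in agg.items()}


# ---------------------------------------------------------------------------
# conjugate updates: numerical integration of prior x likelihood
# ---------------------------------------------------------------------------

def numeric_gaussian_posterior(
    log_prior_lik, center_guess: float, span: float, n_grid: int = 8001
) -> tuple[float, float]:
    """Posterior mean and precision of a scalar parameter by quadrature.

    ``log_prior_lik(theta)`` is the unnormalised log posterior; ``span`` is a
    half-width guaranteed to contain the posterior mode around
    ``center_guess``.  The mode is located numerically, the curvature
    estimated by finite differences, and the moments integrated on a fine
    grid spanning +-12 posterior s.d.
    """
    neg = lambda t: -log_prior_lik(t)
    res = optimize.minimize_scalar(
        neg,
        bounds=(center_guess - span, center_guess + span),
        method="bounded",
        options={"xatol": span * 1e-12},
    )
    mode = float(res.x)
    # numerical curvature -> posterior scale
    scale0 = max(abs(mode), 1.0)
    for _ in range(60):
        eps = scale0 * 1e-3
        d2 = (neg(mode + eps) - 2 * neg(mode) + neg(mode - eps)) / eps**2
        if d2 > 0:
            sd = 1.0 / math.sqrt(d2)
            if 1e-4 * scale0 < sd:
                break
        scale0 /= 4.0
    else:
        raise RuntimeError("could not bracket posterior curvature")
    grid = np.linspace(mode - 12 * sd, mode + 12 * sd, n_grid)
    logp = np.array([log_prior_lik(t) for t in grid])
    w = np.exp(logp - logp.max())
    z = np.trapezoid(w, grid)
    mean = float(np.trapezoid(w * grid, grid) / z)
    var = float(np.trapezoid(w * (grid - mean) ** 2, grid) / z)
    return mean, 1.0 / var


def numeric_intensity_posterior(
    betas: list[float], ws: list[float], lambda0: float, kappa0: float, kappa: float
) -> tuple[float, float]:
    def logpost(lam: float) -> float:
        out = -0.5 * kappa0 * (lam - lambda0) ** 2
        for b, w in zip(betas, ws):
            out += -0.5 * kappa * (w - b * lam) ** 2
        return out

    guess = (
        sum(b * w for b, w in zip(betas, ws)) / sum(b * b for b in betas)
        if betas
        else lambda0
    )
    span = abs(guess - lambda0) + 30.0 / math.sqrt(kappa0)
    return numeric_gaussian_posterior(logpost, guess, span)


def numeric_rt_posterior(
    rs: list[float], mu0: float, delta0: float, gamma: float
) -> tuple[float, float]:
    def logpost(l: float) -> float:
        out = -0.5 * delta0 * (l - mu0) ** 2
        for r in rs:
            out += -0.5 * gamma * (r - l) ** 2
        return out

    guess = (sum(rs) / len(rs)) if rs else mu0
    span = abs(guess - mu0) + 30.0 / math.sqrt(delta0)
    return numeric_gaussian_posterior(logpost, guess, span)


# ---------------------------------------------------------------------------
# exhaustive posterior over partitions x formulas x assignments
# ---------------------------------------------------------------------------

def set_partitions(items: list):
    """All partitions of ``items`` into non-empty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield part + [[first]]


def _candidates(peak, library: PeakLibrary, h):
    """In-window (m, a, i, beta, log mass term + log assignment weight)."""
    sd = h.ppm * 1e-6 / 3.0
    out = []
    for (m, a), entries in library.series.items():
        a_m = library.n_adducts(m)
        for tp in entries:
            if abs(math.log(peak.mz) - math.log(tp.mz)) > h.ppm * 1e-6:
                continue
            log_mass = stats.norm.logpdf(
                math.log(peak.mz), math.log(tp.mz), sd
            )
            out.append(
                (
                    m,
                    a,
                    tp.isotope_index,
                    tp.proportion,
                    log_mass - math.log(a_m * len(entries)),
                )
            )
    return out


def _joint_rt_logpdf(rs: np.ndarray, h) -> float:
    n = len(rs)
    cov = np.eye(n) / h.gamma + np.ones((n, n)) / h.delta0
    return float(
        stats.multivariate_normal.logpdf(rs, mean=np.full(n, h.mu0), cov=cov)
    )


def _joint_intensity_logpdf(betas: np.ndarray, ws: np.ndarray, h) -> float:
    n = len(ws)
    cov = np.eye(n) / h.kappa + np.outer(betas, betas) / h.kappa0
    return float(
        stats.multivariate_normal.logpdf(ws, mean=betas * h.lambda0, cov=cov)
    )


def exhaustive_annotation_posterior(peaks, library: PeakLibrary, h):
    """Exact per-peak marginal posterior over (formula, adduct, isotope).

    Sums over every set partition of the peaks, every formula link per
    cluster (weighted by the Chinese-restaurant prior, pi_m and the joint
    Gaussian marginals) and every adduct-isotope assignment combination.
    Returns ``(marginals, log_evidence)`` with ``marginals[peak_id]`` a dict
    ``(m, a, i) -> probability``.
    """
    cands = {p.id: _candidates(p, library, h) for p in peaks}
    log_alpha = math.log(h.alpha)
    n_m = library.n_formulas

    def log_pi(m: int) -> float:
        return -math.log(n_m) if h.pi is None else math.log(h.pi[m])

    # cache per (cluster peak-id tuple): total log weight and per-peak sums
    cluster_cache: dict[tuple, tuple[float, dict]] = {}

    def cluster_sum(block: tuple):
        if block in cluster_cache:
            return cluster_cache[block]
        members = [p for p in peaks if p.id in block]
        rs = np.array([p.rt for p in members])
        log_rt = _joint_rt_logpdf(rs, h)
        weights = []  # (log weight, [(pid, key)...])
        formulas = {c[0] for c in cands[members[0].id]}
        for m in formulas:
            lists = []
            ok = True
            for p in members:
                mine = [c for c in cands[p.id] if c[0] == m]
                if not mine:
                    ok = False
                    break
                lists.append(mine)
            if not ok:
                continue
            for combo in itertools.product(*lists):
                logw = log_pi(m) + log_rt + sum(c[4] for c in combo)
                groups: dict[int, list[int]] = {}
                for j, c in enumerate(combo):
                    groups.setdefault(c[1], []).append(j)
                for idxs in groups.values():
                    betas = np.array([combo[j][3] for j in idxs])
                    ws = np.array([members[j].intensity for j in idxs])
                    logw += _joint_intensity_logpdf(betas, ws, h)
                weights.append(
                    (
                        logw,
                        [
                            (p.id, (c[0], c[1], c[2]))
                            for p, c in zip(members, combo)
                        ],
                    )
                )
        if not weights:
            cluster_cache[block] = (float("-inf"), {})
            return cluster_cache[block]
        mx = max(w for w, _ in weights)
        total = sum(math.exp(w - mx) for w, _ in weights)
        log_total = mx + math.log(total)
        per_peak: dict[str, dict[tuple, float]] = {}
        for w, assign in weights:
            frac = math.exp(w - mx) / total
            for pid, key in assign:
                d = per_peak.setdefault(pid, {})
                d[key] = d.get(key, 0.0) + frac
        cluster_cache[block] = (log_total, per_peak)
        return cluster_cache[block]

    ids = [p.id for p in peaks]
    part_weights = []  # (log weight, [cluster blocks])
    for part in set_partitions(ids):
        logw = 0.0
        blocks = []
        for block in part:
            key = tuple(sorted(block))
            log_total, _ = cluster_sum(key)
            logw += log_alpha + lgamma(len(block)) + log_total
            blocks.append(key)
        part_weights.append((logw, blocks))
    mx = max(w for w, _ in part_weights)
    z = sum(math.exp(w - mx) for w, _ in part_weights)
    marginals: dict[str, dict[tuple, float]] = {pid: {} for pid in ids}
    for w, blocks in part_weights:
        frac = math.exp(w - mx) / z
        for block in blocks:
            _t, per_peak = cluster_sum(block)
            for pid, d in per_peak.items():
                for key, q in d.items():
                    marginals[pid][key] = marginals[pid].get(key, 0.0) + frac * q
    return marginals, mx + math.log(z)
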