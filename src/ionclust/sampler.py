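"""Collapsed Gibbs sampler over peak-to-cluster and adduct-isotope assignments.

Each cluster is linked to one molecular formula and carries cached sufficient
statistics (per-adduct intensity sums, RT sums) so that a single peak can be
resampled in O(candidates) time.  The prior over partitions is a Dirichlet
process (Chinese restaurant process): a peak joins an existing cluster k with
probability proportional to c_k times the cluster's marginal likelihood, or
opens a new cluster with probability proportional to alpha times the
formula-marginalised prior predictive.

The per-peak assignment is drawn as a single categorical over all in-window
(cluster, adduct, isotope) triples plus all (new-cluster, formula, adduct,
isotope) options; this is distributionally identical to first drawing the
cluster and then the within-cluster assignment, but needs one pass.

Peaks that match no theoretical peak in any formula's ppm window cannot be
expressed by the model at all; they are held in permanent *noise singletons*
that never participate in the sampler and are reported with zero annotation
probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import lgamma

import numpy as np

from .chem import PeakLibrary
from .likelihoods import (
    LOG_ZERO,
    AdductStats,
    Hyperparameters,
    RtStats,
    intensity_log_density,
    intensity_posterior,
    mass_log_density,
    rt_log_density,
    rt_posterior,
)

__all__ = [
    "Peak",
    "ClusterState",
    "SamplerState",
    "SampleRecord",
    "init_state",
    "resample_peak",
    "gibbs_sweep",
    "run",
    "log_joint",
]


@dataclass(frozen=True)
class Peak:
    """One measured LC-MS feature: m/z (x_n), retention time in seconds
    (r_n) and intensity in detector counts (w_n)."""

    id: str
    mz: float
    rt: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak {self.id}: m/z must be positive")
        if self.intensity <= 0:
            raise ValueError(f"peak {self.id}: intensity must be positive")
        if not math.isfinite(self.rt):
            raise ValueError(f"peak {self.id}: retention time must be finite")


@dataclass(frozen=True)
class Candidate:
    """One in-window theoretical species for a peak, with its fixed
    log-likelihood contributions precomputed."""

    formula_index: int
    adduct_index: int
    isotope_index: int
    beta: float
    # log mass density + log uniform assignment weight 1/(A_m * I_ma)
    base: float
    # base + prior-predictive intensity term (constant per peak)
    new_base: float


class ClusterState:
    """One cluster: a formula link plus member peaks with their
    adduct-isotope assignments and cached sufficient statistics."""

    __slots__ = ("formula_index", "members", "_adduct", "sum_r")

    def __init__(self, formula_index: int):
        self.formula_index = formula_index
        # peak id -> (adduct, isotope, beta, intensity, rt)
        self.members: dict[str, tuple[int, int, float, float, float]] = {}
        # adduct -> [sum beta^2, sum beta*w, count]
        self._adduct: dict[int, list[float]] = {}
        self.sum_r = 0.0

    @property
    def size(self) -> int:
        return len(self.members)

    def add(self, peak: Peak, a: int, i: int, beta: float) -> None:
        self.members[peak.id] = (a, i, beta, peak.intensity, peak.rt)
        st = self._adduct.setdefault(a, [0.0, 0.0, 0])
        st[0] += beta * beta
        st[1] += beta * peak.intensity
        st[2] += 1
        self.sum_r += peak.rt

    def remove(self, peak_id: str) -> None:
        a, _i, beta, w, r = self.members.pop(peak_id)
        st = self._adduct[a]
        st[0] -= beta * beta
        st[1] -= beta * w
        st[2] -= 1
        if st[2] == 0:
            del self._adduct[a]
        self.sum_r -= r

    # --- views used by the likelihood layer -------------------------------
    @property
    def rt_stats(self) -> RtStats:
        return RtStats(sum_r=self.sum_r, count=len(self.members))

    def rt_stats_excluding(self, peak_id: str) -> RtStats:
        if peak_id in self.members:
            r = self.members[peak_id][4]
            return RtStats(sum_r=self.sum_r - r, count=len(self.members) - 1)
        return self.rt_stats

    def adduct_stats(self, a: int) -> AdductStats:
        st = self._adduct.get(a)
        if st is None:
            return AdductStats()
        return AdductStats(sum_beta_sq=st[0], sum_beta_w=st[1], count=st[2])

    def adduct_stats_excluding(self, peak_id: str, a: int) -> AdductStats:
        stats = self.adduct_stats(a)
        mem = self.members.get(peak_id)
        if mem is not None and mem[0] == a:
            _a, _i, beta, w, _r = mem
            stats.sum_beta_sq -= beta * beta
            stats.sum_beta_w -= beta * w
            stats.count -= 1
        return stats

    def recompute_stats(self) -> tuple[dict[int, list[float]], float]:
        """Recompute sufficient statistics from members (for invariants)."""
        adduct: dict[int, list[float]] = {}
        sum_r = 0.0
        for a, _i, beta, w, r in self.members.values():
            st = adduct.setdefault(a, [0.0, 0.0, 0])
            st[0] += beta * beta
            st[1] += beta * w
            st[2] += 1
            sum_r += r
        return adduct, sum_r


@dataclass
class SampleRecord:
    """One post-burn-in Gibbs sample.

    ``assignments`` maps each peak id to ``(formula, adduct, isotope,
    cluster_label, g)`` or ``None`` for noise singletons; ``support`` holds
    S_m, the number of 'good' (g=1) peaks backing each formula."""

    assignments: dict[str, tuple[int, int, int, int, int] | None]
    support: dict[int, int]


@dataclass
class SamplerState:
    peaks: list[Peak]
    clusters: dict[int, ClusterState]
    assignment: dict[str, int]              # peak id -> cluster label
    noise_ids: set[str]
    candidates: dict[str, list[Candidate]]  # per peak, grouped arbitrarily
    cand_by_formula: dict[str, dict[int, list[Candidate]]]
    new_formula_logp: dict[str, dict[int, float]]  # peak -> m -> log alpha*pi_m*sum
    prior_rt_logp: dict[str, float]
    rng: np.random.Generator
    iteration: int = 0
    next_label: int = 0
    formula_clusters: dict[int, set[int]] = field(default_factory=dict)

    def new_cluster(self, m: int) -> int:
        label = self.next_label
        self.next_label += 1
        self.clusters[label] = ClusterState(m)
        self.formula_clusters.setdefault(m, set()).add(label)
        return label

    def drop_cluster(self, label: int) -> None:
        cl = self.clusters.pop(label)
        self.formula_clusters[cl.formula_index].discard(label)


def _peak_candidates(
    peak: Peak, library: PeakLibrary, h: Hyperparameters
) -> list[Candidate]:
    out = []
    for tp in library.lookup(peak.mz, h.ppm):
        log_mass = mass_log_density(peak.mz, tp.mz, h.zeta, h.log_window)
        if log_mass == LOG_ZERO:
            continue
        m, a = tp.formula_index, tp.adduct_index
        log_norm = -math.log(library.n_adducts(m) * library.n_isotopes(m, a))
        base = log_mass + log_norm
        prior_int = intensity_log_density(
            peak.intensity, tp.proportion, h.lambda0, h.kappa0, h.kappa
        )
        out.append(Candidate(m, a, tp.isotope_index, tp.proportion, base, base + prior_int))
    return out


def _logsumexp(vals: list[float]) -> float:
    m = max(vals, default=LOG_ZERO)
    if m == LOG_ZERO:
        return LOG_ZERO
    return m + math.log(sum(math.exp(v - m) for v in vals))


def init_state(
    peaks: list[Peak],
    library: PeakLibrary,
    h: Hyperparameters,
    seed: int | np.random.Generator,
) -> SamplerState:
    """Random initial state: each matchable peak in a singleton cluster with a
    uniformly drawn in-window (formula, adduct, isotope); unmatchable peaks in
    permanent noise singletons.  Deterministic given the seed."""
    if not peaks:
        raise ValueError("peak list must be non-empty")
    ids = [p.id for p in peaks]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate peak ids")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_m = library.n_formulas
    log_alpha = math.log(h.alpha)

    candidates: dict[str, list[Candidate]] = {}
    cand_by_formula: dict[str, dict[int, list[Candidate]]] = {}
    new_formula_logp: dict[str, dict[int, float]] = {}
    prior_rt_logp: dict[str, float] = {}
    noise_ids: set[str] = set()
    for p in peaks:
        cands = _peak_candidates(p, library, h)
        candidates[p.id] = cands
        if not cands:
            noise_ids.add(p.id)
            continue
        byf: dict[int, list[Candidate]] = {}
        for c in cands:
            byf.setdefault(c.formula_index, []).append(c)
        cand_by_formula[p.id] = byf
        prior_rt = rt_log_density(p.rt, h.mu0, h.delta0, h.gamma)
        prior_rt_logp[p.id] = prior_rt
        new_formula_logp[p.id] = {
            m: log_alpha
            + h.log_pi(m, n_m)
            + prior_rt
            + _logsumexp([c.new_base for c in cs])
            for m, cs in byf.items()
        }

    state = SamplerState(
        peaks=list(peaks),
        clusters={},
        assignment={},
        noise_ids=noise_ids,
        candidates=candidates,
        cand_by_formula=cand_by_formula,
        new_formula_logp=new_formula_logp,
        prior_rt_logp=prior_rt_logp,
        rng=rng,
    )
    for p in peaks:
        if p.id in noise_ids:
            continue
        cands = candidates[p.id]
        c = cands[int(rng.integers(len(cands)))]
        label = state.new_cluster(c.formula_index)
        state.clusters[label].add(p, c.adduct_index, c.isotope_index, c.beta)
        state.assignment[p.id] = label
    return state


def _draw_categorical(rng: np.random.Generator, log_weights: list[float]) -> int:
    m = max(log_weights)
    probs = [math.exp(v - m) for v in log_weights]
    total = sum(probs)
    u = rng.random() * total
    acc = 0.0
    for idx, pr in enumerate(probs):
        acc += pr
        if u <= acc:
            return idx
    return len(probs) - 1


def resample_peak(
    state: SamplerState, peak: Peak, library: PeakLibrary, h: Hyperparameters
) -> None:
    """Remove the peak from its cluster and redraw its assignment from the
    full conditional: existing (cluster, adduct, isotope) triples weighted by
    c_k * likelihood, new-cluster (formula, adduct, isotope) options weighted
    by alpha * pi_m * prior predictive."""
    if peak.id in state.noise_ids:
        return
    old_label = state.assignment.pop(peak.id)
    old = state.clusters[old_label]
    old.remove(peak.id)
    if old.size == 0:
        state.drop_cluster(old_label)

    byf = state.cand_by_formula[peak.id]
    options: list[tuple[int, Candidate]] = []  # (cluster label or -1-new marker, cand)
    log_weights: list[float] = []
    new_markers: list[int] = []  # parallel: formula index for new-cluster options

    for m, cands in byf.items():
        labels = state.formula_clusters.get(m)
        if not labels:
            continue
        for label in labels:
            cl = state.clusters[label]
            log_ck = math.log(cl.size)
            mu_star, delta_star = rt_posterior(cl.rt_stats, h)
            log_rt = rt_log_density(peak.rt, mu_star, delta_star, h.gamma)
            # group candidates by adduct to reuse the intensity posterior
            post_cache: dict[int, tuple[float, float]] = {}
            for c in cands:
                post = post_cache.get(c.adduct_index)
                if post is None:
                    post = intensity_posterior(cl.adduct_stats(c.adduct_index), h)
                    post_cache[c.adduct_index] = post
                log_int = intensity_log_density(
                    peak.intensity, c.beta, post[0], post[1], h.kappa
                )
                options.append((label, c))
                log_weights.append(log_ck + c.base + log_int + log_rt)
                new_markers.append(-1)

    log_alpha = math.log(h.alpha)
    prior_rt = state.prior_rt_logp[peak.id]
    for m, cands in byf.items():
        # per-option weight: alpha * pi_m * prior predictive of each (a, i)
        head = log_alpha + h.log_pi(m, library.n_formulas) + prior_rt
        for c in cands:
            options.append((-1, c))
            log_weights.append(head + c.new_base)
            new_markers.append(m)

    idx = _draw_categorical(state.rng, log_weights)
    label, cand = options[idx]
    if label == -1:
        label = state.new_cluster(new_markers[idx])
    state.clusters[label].add(peak, cand.adduct_index, cand.isotope_index, cand.beta)
    state.assignment[peak.id] = label


def resample_cluster_formula(
    state: SamplerState, label: int, library: PeakLibrary, h: Hyperparameters
) -> None:
    """Gibbs update of one cluster's formula link phi_k.

    Conditioned on the members' (adduct, isotope) assignments, the formula
    posterior is pi_m times the product of each member's mass term and
    assignment weight under m, times the per-adduct intensity marginals with
    m's theoretical proportions (the RT marginal is formula-independent and
    cancels).  Formulas for which any member's assignment falls outside the
    mass window have probability zero.  This move lets an established
    cluster switch between near-isobaric formulas without dissolving, which
    single-peak updates alone mix over extremely slowly.
    """
    cl = state.clusters[label]
    member_ids = list(cl.members)
    # candidate lookup (m, a, i) -> Candidate per member
    lookups = []
    for pid in member_ids:
        lookups.append(
            {
                (c.formula_index, c.adduct_index, c.isotope_index): c
                for c in state.candidates[pid]
            }
        )
    first_formulas = {c.formula_index for c in state.candidates[member_ids[0]]}
    options: list[tuple[int, list]] = []
    log_weights: list[float] = []
    n_m = library.n_formulas
    for m in first_formulas:
        cands = []
        ok = True
        for pid, lut in zip(member_ids, lookups):
            a, i, _beta, _w, _r = cl.members[pid]
            c = lut.get((m, a, i))
            if c is None:
                ok = False
                break
            cands.append(c)
        if not ok:
            continue
        logw = h.log_pi(m, n_m) + sum(c.base for c in cands)
        # intensity marginals per adduct with this formula's proportions
        groups: dict[int, list[tuple[float, float]]] = {}
        for pid, c in zip(member_ids, cands):
            groups.setdefault(c.adduct_index, []).append(
                (c.beta, cl.members[pid][3])
            )
        for pairs in groups.values():
            st = AdductStats()
            for beta, w in pairs:
                lam, kap = intensity_posterior(st, h)
                logw += intensity_log_density(w, beta, lam, kap, h.kappa)
                st.add(beta, w)
        options.append((m, cands))
        log_weights.append(logw)
    if not options:  # cannot happen: the current formula is always valid
        return
    m_new, cands = options[_draw_categorical(state.rng, log_weights)]
    if m_new == cl.formula_index:
        return
    state.formula_clusters[cl.formula_index].discard(label)
    state.formula_clusters.setdefault(m_new, set()).add(label)
    cl.formula_index = m_new
    # rebuild member tuples and cached stats with the new proportions
    old_members = dict(cl.members)
    cl.members.clear()
    cl._adduct.clear()
    cl.sum_r = 0.0
    for pid, c in zip(member_ids, cands):
        _a, _i, _beta, w, r = old_members[pid]
        cl.members[pid] = (c.adduct_index, c.isotope_index, c.beta, w, r)
        st = cl._adduct.setdefault(c.adduct_index, [0.0, 0.0, 0])
        st[0] += c.beta * c.beta
        st[1] += c.beta * w
        st[2] += 1
        cl.sum_r += r


def gibbs_sweep(
    state: SamplerState, library: PeakLibrary, h: Hyperparameters
) -> float:
    """Resample every (matchable) peak once in a random order driven by the
    run seed, then re-draw each cluster's formula link.  Returns the log
    joint of the resulting state (convergence diagnostic)."""
    order = [p for p in state.peaks if p.id not in state.noise_ids]
    perm = state.rng.permutation(len(order))
    for j in perm:
        resample_peak(state, order[int(j)], library, h)
    for label in list(state.clusters):
        resample_cluster_formula(state, label, library, h)
    state.iteration += 1
    return log_joint(state, library, h)


def log_joint(state: SamplerState, library: PeakLibrary, h: Hyperparameters) -> float:
    """Log joint probability of the current configuration (up to the CRP
    normalising constant, which is fixed given N)."""
    total = 0.0
    n_m = library.n_formulas
    for cl in state.clusters.values():
        total += math.log(h.alpha) + lgamma(cl.size)  # CRP factor alpha*(c_k-1)!
        total += h.log_pi(cl.formula_index, n_m)
        # mass terms + assignment weights via the cached candidate bases
        for pid, (a, i, _beta, _w, _r) in cl.members.items():
            for c in state.candidates[pid]:
                if (
                    c.formula_index == cl.formula_index
                    and c.adduct_index == a
                    and c.isotope_index == i
                ):
                    total += c.base
                    break
        # RT marginal: sequential predictive (order-invariant)
        rt = RtStats()
        for _a, _i, _beta, _w, r in cl.members.values():
            mu_star, delta_star = rt_posterior(rt, h)
            total += rt_log_density(r, mu_star, delta_star, h.gamma)
            rt.add(r)
        # intensity marginal per adduct
        groups: dict[int, list[tuple[float, float]]] = {}
        for a, _i, beta, w, _r in cl.members.values():
            groups.setdefault(a, []).append((beta, w))
        for pairs in groups.values():
            st = AdductStats()
            for beta, w in pairs:
                lam, kap = intensity_posterior(st, h)
                total += intensity_log_density(w, beta, lam, kap, h.kappa)
                st.add(beta, w)
    return total


def run(
    peaks: list[Peak],
    library: PeakLibrary,
    h: Hyperparameters,
    n_iterations: int = 1000,
    burn_in: int = 200,
    seed: int | np.random.Generator = 0,
    trace_out: list[float] | None = None,
) -> list[SampleRecord]:
    """Run the Gibbs sampler and return one :class:`SampleRecord` per
    post-burn-in sweep.  ``trace_out``, if given, collects the per-sweep log
    joint for convergence diagnostics.  Deterministic given the seed."""
    from .posterior import good_flags  # runtime import: posterior sits above

    if burn_in < 0 or n_iterations <= burn_in:
        raise ValueError("need n_iterations > burn_in >= 0")
    state = init_state(peaks, library, h, seed)
    records: list[SampleRecord] = []
    for it in range(n_iterations):
        score = gibbs_sweep(state, library, h)
        if trace_out is not None:
            trace_out.append(score)
        if it < burn_in:
            continue
        assignments: dict[str, tuple[int, int, int, int, int] | None] = {
            pid: None for pid in state.noise_ids
        }
        support: dict[int, int] = {}
        for label, cl in state.clusters.items():
            flags = good_flags(cl, library)
            m = cl.formula_index
            for pid, (a, i, _beta, _w, _r) in cl.members.items():
                g = flags[pid]
                assignments[pid] = (m, a, i, label, g)
                if g:
                    support[m] = support.get(m, 0) + 1
        records.append(SampleRecord(assignments=assignments, support=support))
    return records
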