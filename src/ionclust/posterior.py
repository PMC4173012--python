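"""Posterior summaries: peak-level annotation probabilities and formula-level
presence probabilities at support levels.

Three probability variants are reported per peak annotation:

* ``prior`` — mass-only: the truncated mass densities over the peak's
  in-window candidates, normalised to one;
* ``posterior`` — the fraction of Gibbs samples in which the peak carries
  that (formula, adduct, isotope) assignment;
* ``filtered`` — as ``posterior`` but counting only samples in which the
  peak's good-peak flag g = 1, i.e. every higher-abundance isotope of its
  assigned adduct series is also observed in the cluster.

Formula presence at support level l is the fraction of samples in which at
least l good peaks back the formula (S_m >= l).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chem import PeakLibrary
from .likelihoods import LOG_ZERO, Hyperparameters, mass_log_density
from .sampler import ClusterState, Peak, SampleRecord

__all__ = [
    "PosteriorSummary",
    "prior_probabilities",
    "good_flags",
    "formula_support",
    "summarize",
]

Annotation = tuple[int, int, int]  # (formula, adduct, isotope)


@dataclass
class PosteriorSummary:
    """Per-peak annotation probabilities (three variants) and per-formula
    presence probabilities at support levels 1..L."""

    peak_prior: dict[str, dict[Annotation, float]]
    peak_posterior: dict[str, dict[Annotation, float]]
    peak_filtered: dict[str, dict[Annotation, float]]
    presence: dict[int, dict[int, float]]  # formula -> level -> probability
    levels: tuple[int, ...] = field(default=(1, 2, 3, 4, 5))

    def formula_probability(
        self, peak_id: str, variant: str = "posterior"
    ) -> dict[int, float]:
        """Per-formula probability for one peak, summed over (adduct, isotope)."""
        table = {
            "prior": self.peak_prior,
            "posterior": self.peak_posterior,
            "filtered": self.peak_filtered,
        }[variant]
        out: dict[int, float] = {}
        for (m, _a, _i), p in table.get(peak_id, {}).items():
            out[m] = out.get(m, 0.0) + p
        return out


def prior_probabilities(
    peaks: list[Peak], library: PeakLibrary, h: Hyperparameters
) -> dict[str, dict[Annotation, float]]:
    """Mass-only annotation probabilities: truncated mass densities over each
    peak's in-window candidates, normalised to sum to one.  Peaks with no
    candidate get an empty map."""
    out: dict[str, dict[Annotation, float]] = {}
    for p in peaks:
        logs: dict[Annotation, float] = {}
        for tp in library.lookup(p.mz, h.ppm):
            ld = mass_log_density(p.mz, tp.mz, h.zeta, h.log_window)
            if ld != LOG_ZERO:
                logs[(tp.formula_index, tp.adduct_index, tp.isotope_index)] = ld
        if not logs:
            out[p.id] = {}
            continue
        mx = max(logs.values())
        weights = {k: math.exp(v - mx) for k, v in logs.items()}
        total = sum(weights.values())
        out[p.id] = {k: w / total for k, w in weights.items()}
    return out


def good_flags(cluster: ClusterState, library: PeakLibrary) -> dict[str, int]:
    """Good-peak indicator g for every member of a cluster.

    Within each adduct series of the cluster, a member is good iff every
    theoretical isotope index of that adduct with *strictly higher*
    predicted abundance than the member's own index is occupied by a member
    that is itself good.  A member on the highest-abundance index is always
    good (nothing more abundant is expected); an orphan isotopologue whose
    more-abundant partners are missing is flagged bad.
    """
    m = cluster.formula_index
    # members grouped by adduct: isotope index -> peak ids assigned to it
    by_adduct: dict[int, dict[int, list[str]]] = {}
    for pid, (a, i, _beta, _w, _r) in cluster.members.items():
        by_adduct.setdefault(a, {}).setdefault(i, []).append(pid)
    flags: dict[str, int] = {}
    for a, occupied in by_adduct.items():
        betas = {tp.isotope_index: tp.proportion for tp in library.series[(m, a)]}
        # process occupied indices in descending theoretical abundance; all
        # members sharing an index share its flag
        order = sorted(occupied, key=lambda i: -betas[i])
        good_idx: set[int] = set()
        for i in order:
            higher = [j for j, b in betas.items() if b > betas[i]]
            ok = all(j in good_idx for j in higher)
            for pid in occupied[i]:
                flags[pid] = int(ok)
            if ok:
                good_idx.add(i)
    return flags


def formula_support(sample: SampleRecord) -> dict[int, int]:
    """S_m: number of good peaks assigned to formula m in one sample (summed
    across all clusters linked to m)."""
    support: dict[int, int] = {}
    for tup in sample.assignments.values():
        if tup is None:
            continue
        m, _a, _i, _label, g = tup
        if g:
            support[m] = support.get(m, 0) + 1
    return support


def summarize(
    chain: list[SampleRecord],
    peaks: list[Peak],
    library: PeakLibrary,
    h: Hyperparameters,
    levels: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> PosteriorSummary:
    """Convert a sample chain into annotation and presence probabilities.

    Summaries depend only on assignments, never on cluster labels, so they
    are invariant to label permutation and to sample order.
    """
    if not chain:
        raise ValueError("empty sample chain")
    n = len(chain)
    post: dict[str, dict[Annotation, float]] = {}
    filt: dict[str, dict[Annotation, float]] = {}
    pres_counts: dict[int, dict[int, int]] = {}
    for rec in chain:
        for pid, tup in rec.assignments.items():
            if tup is None:
                post.setdefault(pid, {})
                filt.setdefault(pid, {})
                continue
            m, a, i, _label, g = tup
            key = (m, a, i)
            d = post.setdefault(pid, {})
            d[key] = d.get(key, 0.0) + 1.0
            if g:
                d = filt.setdefault(pid, {})
                d[key] = d.get(key, 0.0) + 1.0
            else:
                filt.setdefault(pid, {})
        for m, s_m in rec.support.items():
            lv = pres_counts.setdefault(m, {l: 0 for l in levels})
            for l in levels:
                if s_m >= l:
                    lv[l] += 1
    for table in (post, filt):
        for d in table.values():
            for k in d:
                d[k] /= n
    presence = {
        m: {l: c / n for l, c in lv.items()} for m, lv in pres_counts.items()
    }
    # formulas never supported still deserve an explicit zero row
    for m in range(library.n_formulas):
        presence.setdefault(m, {l: 0.0 for l in levels})
    prior = prior_probabilities(peaks, library, h)
    return PosteriorSummary(
        peak_prior=prior,
        peak_posterior=post,
        peak_filtered=filt,
        presence=presence,
        levels=tuple(levels),
    )
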