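"""Per-peak likelihood terms and their conjugate posterior updates.

The model factorises each peak's likelihood into three Gaussian terms:

* **mass** — log m/z is Gaussian around the theoretical log m/z with
  precision zeta, truncated to a ppm window (outside the window the
  likelihood is exactly zero, which is what makes the problem sparse);
* **intensity** — each peak's intensity is Gaussian around beta * lambda_ka,
  where lambda_ka is a latent per-cluster, per-adduct intensity scale with a
  near-flat Gaussian prior; lambda is integrated out analytically;
* **retention time** — each peak's RT is Gaussian around a latent cluster
  elution time l_k with a near-flat Gaussian prior; l_k is integrated out.

All arithmetic is in log space; the near-flat priors (kappa0 = 1e-14,
delta0 = 1e-5) underflow otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chem import PeakLibrary

__all__ = [
    "Hyperparameters",
    "AdductStats",
    "RtStats",
    "LOG_ZERO",
    "mass_log_density",
    "intensity_posterior",
    "intensity_log_density",
    "rt_posterior",
    "rt_log_density",
    "peak_given_cluster",
    "peak_given_new_cluster",
]

LOG_ZERO = float("-inf")
_LOG_2PI = math.log(2.0 * math.pi)


def zeta_from_ppm(ppm: float) -> float:
    """Mass precision implied by an instrument ppm tolerance.

    The stated ppm tolerance is treated as a 3-sigma bound on the log-mass
    error: sigma_log = ppm*1e-6/3, zeta = sigma_log**-2.
    """
    if ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    sigma = ppm * 1e-6 / 3.0
    return sigma**-2


@dataclass
class Hyperparameters:
    """Model hyperparameters.

    Units: intensities in detector counts, retention times in seconds, masses
    in Da.  The defaults for the precisions follow orbitrap-scale data:
    ``kappa0`` and ``delta0`` give near-flat priors on the intensity scale and
    cluster elution time; ``kappa = 1e-8`` corresponds to an intensity noise
    s.d. of 1e4 counts and ``gamma = 0.25`` to an RT noise s.d. of 2 s.
    ``pi_m`` defaults to the uniform 1/M.
    """

    alpha: float = 1.0          # DP concentration
    ppm: float = 3.0            # mass window (3-sigma) in parts per million
    lambda0: float = 1e6        # intensity prior mean (set to data mean in runs)
    kappa0: float = 1e-14       # intensity prior precision
    kappa: float = 1e-8         # intensity observation precision
    mu0: float = 0.0            # RT prior mean (set to data mean in runs)
    delta0: float = 1e-5        # RT prior precision
    gamma: float = 0.25         # RT observation precision
    pi: list[float] | None = None  # per-formula prior; None = uniform 1/M

    zeta: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("alpha", "kappa0", "kappa", "delta0", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.zeta = zeta_from_ppm(self.ppm)

    @property
    def log_window(self) -> float:
        """Truncation half-width on |log x - log y|."""
        return self.ppm * 1e-6

    def log_pi(self, m: int, n_formulas: int) -> float:
        if self.pi is None:
            return -math.log(n_formulas)
        return math.log(self.pi[m]) if self.pi[m] > 0 else LOG_ZERO


@dataclass
class AdductStats:
    """Sufficient statistics of one (cluster, adduct) intensity group:
    sums of beta**2 and beta*w over member peaks."""

    sum_beta_sq: float = 0.0
    sum_beta_w: float = 0.0
    count: int = 0

    def add(self, beta: float, w: float) -> None:
        self.sum_beta_sq += beta * beta
        self.sum_beta_w += beta * w
        self.count += 1

    def remove(self, beta: float, w: float) -> None:
        self.sum_beta_sq -= beta * beta
        self.sum_beta_w -= beta * w
        self.count -= 1


@dataclass
class RtStats:
    """Sufficient statistics of one cluster's retention times: sum of r and
    the member count c_k."""

    sum_r: float = 0.0
    count: int = 0

    def add(self, r: float) -> None:
        self.sum_r += r
        self.count += 1

    def remove(self, r: float) -> None:
        self.sum_r -= r
        self.count -= 1


def mass_log_density(x: float, y: float, zeta: float, log_window: float | None = None) -> float:
    """log N(log x | log y, zeta^-1), truncated to ``|log x - log y| <= log_window``.

    Returns ``-inf`` outside the window (candidate excluded)."""
    if x <= 0 or y <= 0:
        raise ValueError("masses must be positive")
    resid = math.log(x) - math.log(y)
    if log_window is not None and abs(resid) > log_window:
        return LOG_ZERO
    return 0.5 * (math.log(zeta) - _LOG_2PI) - 0.5 * zeta * resid * resid


def intensity_posterior(stats: AdductStats, h: Hyperparameters) -> tuple[float, float]:
    """Posterior (lambda*, kappa*) of the per-adduct intensity scale.

    Conjugate Gaussian update for w_n ~ N(beta_n lambda, kappa^-1) with prior
    lambda ~ N(lambda0, kappa0^-1):

        kappa* = kappa0 + kappa * sum(beta^2)
        lambda* = (kappa0*lambda0 + kappa * sum(beta*w)) / kappa*
    """
    kappa_star = h.kappa0 + h.kappa * stats.sum_beta_sq
    lambda_star = (h.kappa0 * h.lambda0 + h.kappa * stats.sum_beta_w) / kappa_star
    return lambda_star, kappa_star


def intensity_log_density(
    w: float, beta: float, lambda_star: float, kappa_star: float, kappa: float
) -> float:
    """Predictive log-density of an intensity: N(w | beta*lambda*,
    kappa^-1 + beta^2 * kappa*^-1) with the latent scale integrated out."""
    var = 1.0 / kappa + beta * beta / kappa_star
    resid = w - beta * lambda_star
    return -0.5 * (_LOG_2PI + math.log(var) + resid * resid / var)


def rt_posterior(stats: RtStats, h: Hyperparameters) -> tuple[float, float]:
    """Posterior (mu*, delta*) of the cluster elution time.

    Conjugate update for r_n ~ N(l_k, gamma^-1), l_k ~ N(mu0, delta0^-1):

        delta* = delta0 + gamma * c_k
        mu* = (delta0*mu0 + gamma * sum(r)) / delta*
    """
    delta_star = h.delta0 + h.gamma * stats.count
    mu_star = (h.delta0 * h.mu0 + h.gamma * stats.sum_r) / delta_star
    return mu_star, delta_star


def rt_log_density(r: float, mu_star: float, delta_star: float, gamma: float) -> float:
    """Predictive log-density of a retention time: N(r | mu*,
    delta*^-1 + gamma^-1)."""
    var = 1.0 / delta_star + 1.0 / gamma
    resid = r - mu_star
    return -0.5 * (_LOG_2PI + math.log(var) + resid * resid / var)


def _logsumexp(values: list[float]) -> float:
    m = max(values, default=LOG_ZERO)
    if m == LOG_ZERO:
        return LOG_ZERO
    return m + math.log(sum(math.exp(v - m) for v in values))


def peak_given_cluster(peak, cluster, library: PeakLibrary, h: Hyperparameters):
    """Marginal likelihood of a peak under an existing cluster.

    Marginalises the adduct-isotope assignment uniformly over the A_m * I_ma
    species of the cluster's formula; each component is the product of the
    mass, intensity and RT predictive densities, with the cluster's posterior
    parameters computed *excluding* the peak itself if it is currently a
    member (collapsed-Gibbs exclusion).

    Returns ``(log_marginal, components)`` where ``components`` maps
    ``(adduct_index, isotope_index)`` to the component log-likelihood
    (including the uniform assignment weight).
    """
    m = cluster.formula_index
    excl = peak.id in cluster.members
    rt = cluster.rt_stats_excluding(peak.id) if excl else cluster.rt_stats
    mu_star, delta_star = rt_posterior(rt, h)
    log_rt = rt_log_density(peak.rt, mu_star, delta_star, h.gamma)
    a_m = library.n_adducts(m)
    components: dict[tuple[int, int], float] = {}
    for (fm, a), entries in library.series.items():
        if fm != m:
            continue
        stats = cluster.adduct_stats_excluding(peak.id, a) if excl else cluster.adduct_stats(a)
        lam_star, kap_star = intensity_posterior(stats, h)
        log_w_norm = -math.log(a_m * len(entries))
        for tp in entries:
            log_mass = mass_log_density(peak.mz, tp.mz, h.zeta, h.log_window)
            if log_mass == LOG_ZERO:
                continue
            log_int = intensity_log_density(
                peak.intensity, tp.proportion, lam_star, kap_star, h.kappa
            )
            components[(a, tp.isotope_index)] = log_w_norm + log_mass + log_int + log_rt
    return _logsumexp(list(components.values())), components


def peak_given_new_cluster(peak, library: PeakLibrary, h: Hyperparameters):
    """Marginal likelihood of a peak under a *new* cluster, marginalising over
    formulas with prior pi_m and using the prior parameters (lambda0, kappa0,
    mu0, delta0) in the predictive variances.

    Returns ``(log_marginal, per_formula)`` where ``per_formula`` maps formula
    index ``m`` to ``(log p(d, phi*=m), components)`` with components keyed by
    ``(adduct_index, isotope_index)`` as in :func:`peak_given_cluster`.
    """
    mu_star, delta_star = h.mu0, h.delta0
    log_rt = rt_log_density(peak.rt, mu_star, delta_star, h.gamma)
    per_formula: dict[int, tuple[float, dict[tuple[int, int], float]]] = {}
    n_m = library.n_formulas
    for (m, a), entries in library.series.items():
        log_w_norm = -math.log(library.n_adducts(m) * len(entries))
        for tp in entries:
            log_mass = mass_log_density(peak.mz, tp.mz, h.zeta, h.log_window)
            if log_mass == LOG_ZERO:
                continue
            log_int = intensity_log_density(
                peak.intensity, tp.proportion, h.lambda0, h.kappa0, h.kappa
            )
            comp = log_w_norm + log_mass + log_int + log_rt
            if m not in per_formula:
                per_formula[m] = (LOG_ZERO, {})
            per_formula[m][1][(a, tp.isotope_index)] = comp
    out: dict[int, tuple[float, dict[tuple[int, int], float]]] = {}
    totals = []
    for m, (_z, comps) in per_formula.items():
        log_m = h.log_pi(m, n_m) + _logsumexp(list(comps.values()))
        out[m] = (log_m, comps)
        totals.append(log_m)
    return _logsumexp(totals), out
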