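"""Ground-truthed synthetic LC-MS feature tables and decoy formula databases.

The generator draws data from the same structure the clustering model
assumes: each present formula elutes at one retention time; each of its
adduct forms carries an independent intensity scale; each detectable
isotopologue contributes one peak whose m/z has multiplicative (ppm-scale)
log-normal noise, whose RT jitters around the cluster elution time and whose
intensity is proportional to the theoretical isotope abundance.  Unassignable
noise peaks are appended uniformly over the observed m/z and RT ranges.

Decoy formulas — compositions known to be absent but within a small ppm
window of a present compound's mass — are constructed algebraically by
bounded enumeration of CHNOPS compositions, with no database access.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import (
    AdductRule,
    Formula,
    apply_adduct,
    isotope_pattern,
    monoisotopic_mass,
)
from .sampler import Peak

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_decoys",
    "intensity_prefilter",
]


@dataclass
class SyntheticConfig:
    """Generation parameters.

    Units: ppm_sigma in parts per million (s.d. of the multiplicative mass
    error), rt_sigma in seconds, intensities in detector counts.
    ``intensity_cv`` is the coefficient of variation of peak intensities
    around their theoretical value; ``adduct_probability`` is the chance each
    adduct form of a present compound ionises at all;
    ``isotope_detection_floor`` drops isotopologues whose expected intensity
    falls below the detector's limit.
    """

    ppm_sigma: float = 1.0
    rt_sigma: float = 2.0
    intensity_cv: float = 0.1
    mean_intensity: float = 5e5
    intensity_spread: float = 0.5  # s.d. of log adduct scale around the mean
    adduct_probability: float = 0.8
    isotope_detection_floor: float = 5000.0
    n_noise_peaks: int = 0
    rt_range: tuple[float, float] = (60.0, 1200.0)
    min_proportion: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if self.ppm_sigma < 0 or self.rt_sigma < 0 or self.intensity_cv < 0:
            raise ValueError("noise scales must be non-negative")
        if not (0.0 < self.adduct_probability <= 1.0):
            raise ValueError("adduct_probability must be in (0, 1]")
        if self.rt_range[1] <= self.rt_range[0]:
            raise ValueError("rt_range must be increasing")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be non-negative")


@dataclass
class GroundTruth:
    """What generated each peak: ``(formula_index, adduct_index,
    isotope_index)`` or ``None`` for noise; plus which formulas are present
    and the generation config."""

    peak_truth: dict[str, tuple[int, int, int] | None]
    present_formulas: set[int]
    config: SyntheticConfig = field(repr=False, default=None)  # type: ignore[assignment]


def generate_dataset(
    present_formulas: list[Formula],
    adducts: list[AdductRule],
    config: SyntheticConfig | None = None,
) -> tuple[list[Peak], GroundTruth]:
    """Simulate an aligned feature table for a known mixture.

    Formula indices in the truth record refer to positions in
    ``present_formulas``; callers building a larger library (with decoys
    appended) should place the present formulas first so indices agree.
    """
    if not present_formulas:
        raise ValueError("need at least one present formula")
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    peaks: list[Peak] = []
    truth: dict[str, tuple[int, int, int] | None] = {}
    counter = 0
    log_sigma = config.ppm_sigma * 1e-6
    for m, f in enumerate(present_formulas):
        l_k = rng.uniform(*config.rt_range)
        for a, rule in enumerate(adducts):
            if rng.random() > config.adduct_probability:
                continue
            lam = config.mean_intensity * math.exp(
                rng.normal(0.0, config.intensity_spread)
            )
            eff = f if rule.multiplicity == 1 else f * rule.multiplicity
            pat = isotope_pattern(eff, config.min_proportion)
            flat = AdductRule(rule.name, 1, rule.gained, rule.lost, rule.charge)
            for i, (mz_theo, beta) in enumerate(apply_adduct(pat, flat)):
                expected = beta * lam
                if expected < config.isotope_detection_floor:
                    continue
                mz = mz_theo * math.exp(rng.normal(0.0, log_sigma)) if log_sigma else mz_theo
                rt = l_k + (rng.normal(0.0, config.rt_sigma) if config.rt_sigma else 0.0)
                w = expected * (
                    1.0 + (rng.normal(0.0, config.intensity_cv) if config.intensity_cv else 0.0)
                )
                w = max(w, 1.0)
                pid = f"P{counter:05d}"
                counter += 1
                peaks.append(Peak(pid, mz, rt, w))
                truth[pid] = (m, a, i)
    if peaks:
        mz_lo = min(p.mz for p in peaks)
        mz_hi = max(p.mz for p in peaks)
    else:
        mz_lo, mz_hi = 100.0, 1000.0
    for _ in range(config.n_noise_peaks):
        pid = f"P{counter:05d}"
        counter += 1
        mz = rng.uniform(mz_lo, mz_hi)
        rt = rng.uniform(*config.rt_range)
        w = config.isotope_detection_floor + rng.exponential(config.mean_intensity / 5.0)
        peaks.append(Peak(pid, mz, rt, w))
        truth[pid] = None
    return peaks, GroundTruth(
        peak_truth=truth,
        present_formulas=set(range(len(present_formulas))),
        config=config,
    )


# bounded CHNOPS enumeration used for decoy construction
_DECOY_BOUNDS = {"S": 3, "P": 3, "N": 8, "O": 14}


def _element_masses() -> dict[str, float]:
    from .elements import lightest_mass

    return {sym: lightest_mass(sym) for sym in ("C", "H", "N", "O", "P", "S")}


def _formulas_near(target: float, ppm_window: float) -> list[Formula]:
    """All CHNOPS compositions (within the enumeration bounds) whose
    monoisotopic mass lies within ppm_window of ``target``."""
    em = _element_masses()
    tol = target * ppm_window * 1e-6
    out = []
    for s in range(_DECOY_BOUNDS["S"] + 1):
        ms = s * em["S"]
        if ms > target + tol:
            break
        for p in range(_DECOY_BOUNDS["P"] + 1):
            mp = ms + p * em["P"]
            if mp > target + tol:
                break
            for n in range(_DECOY_BOUNDS["N"] + 1):
                mn = mp + n * em["N"]
                if mn > target + tol:
                    break
                for o in range(_DECOY_BOUNDS["O"] + 1):
                    mo = mn + o * em["O"]
                    if mo > target + tol:
                        break
                    c_max = int((target + tol - mo) / em["C"])
                    for c in range(1, c_max + 1):
                        rem = target - (mo + c * em["C"])
                        h = round(rem / em["H"])
                        for hh in (h - 1, h, h + 1):
                            if hh < 0:
                                continue
                            # loose chemical sanity: bounded hydrogen count
                            if hh > 2 * c + n + 3:
                                continue
                            mass = mo + c * em["C"] + hh * em["H"]
                            if abs(mass - target) <= tol:
                                out.append(
                                    Formula.from_dict(
                                        {"C": c, "H": hh, "N": n, "O": o, "P": p, "S": s}
                                    )
                                )
    return out


def generate_decoys(
    present_formulas: list[Formula],
    n_decoys: int,
    ppm_window: float = 3.0,
    seed: int = 0,
) -> list[Formula]:
    """Construct absent (decoy) formulas mass-matched to the present ones.

    Candidate compositions are enumerated over bounded CHNOPS counts and
    accepted when their monoisotopic mass lies within ``ppm_window`` of a
    present formula's mass while the composition differs from every present
    formula.  Decoys are drawn round-robin across targets in a seeded random
    order.  Raises if fewer than ``n_decoys`` distinct decoys exist, stating
    how many were found.
    """
    if n_decoys == 0:
        return []
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed)
    present = {f.element_counts for f in present_formulas}
    pools: list[list[Formula]] = []
    for f in present_formulas:
        target = monoisotopic_mass(f)
        cands = [
            d
            for d in _formulas_near(target, ppm_window)
            if d.element_counts not in present
        ]
        # drop duplicates within the pool, shuffle deterministically
        uniq = list({d.element_counts: d for d in cands}.values())
        order = rng.permutation(len(uniq))
        pools.append([uniq[int(j)] for j in order])
    decoys: list[Formula] = []
    seen: set = set(present)
    round_idx = 0
    while len(decoys) < n_decoys:
        progressed = False
        for pool in pools:
            if round_idx < len(pool):
                d = pool[round_idx]
                if d.element_counts not in seen:
                    decoys.append(d)
                    seen.add(d.element_counts)
                    progressed = True
                    if len(decoys) == n_decoys:
                        return decoys
        if not progressed and round_idx >= max((len(p) for p in pools), default=0):
            raise ValueError(
                f"only {len(decoys)} decoys available within "
                f"{ppm_window} ppm (requested {n_decoys})"
            )
        round_idx += 1
    return decoys


def intensity_prefilter(peaks: list[Peak], floor: float) -> list[Peak]:
    """Drop peaks with intensity below ``floor`` (peaks exactly at the floor
    are kept); order preserved."""
    if floor < 0:
        raise ValueError("intensity floor must be non-negative")
    return [p for p in peaks if p.intensity >= floor]
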