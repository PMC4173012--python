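import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

import ionclust as ic
from ionclust import evaluation, posterior, sampler
from ionclust.likelihoods import Hyperparameters
from ionclust.synthetic import SyntheticConfig, generate_dataset, generate_decoys

# 20 small-molecule metabolites (amino acids, sugars, nucleosides, cofactors)
PRESENT_FORMULAS = [
    "C6H12O6",        # hexose
    "C9H11NO2",       # phenylalanine
    "C5H9NO4",        # glutamate
    "C6H13NO2",       # leucine
    "C4H7NO4",        # aspartate
    "C10H13N5O4",     # adenosine
    "C21H27N7O14P2",  # NAD
    "C6H8O7",         # citrate
    "C3H7NO3",        # serine
    "C9H11NO3",       # tyrosine
    "C5H11NO2",       # valine
    "C6H14N4O2",      # arginine
    "C10H14N5O7P",    # AMP
    "C12H22O11",      # sucrose
    "C7H6O2",         # benzoate
    "C8H10N4O2",      # caffeine
    "C10H12N5O6P",    # cAMP
    "C5H5N5",         # adenine
    "C4H9NO3",        # threonine
    "C19H19N7O6",     # folate
]


@pytest.fixture(scope="session")
def small_library():
    """Two near-isobaric formulas (~1.9 ppm apart) x two adducts, truncated
    to two isotope entries each."""
    formulas = [ic.parse_formula("C9H11NO2"), ic.parse_formula("C5H14N2O2P")]
    adducts = [ic.parse_adduct_rule("M+H", 1), ic.parse_adduct_rule("M+Na", 1)]
    return ic.build_library(formulas, adducts, min_proportion=0.01)


@pytest.fixture(scope="session")
def recovery_study():
    """Five synthetic mixtures of 20 known compounds against a database that
    also carries 80 mass-matched decoys: full pipeline runs used to assess
    annotation recovery and calibration.

    Conditions: adducts M+H and M+Na, 1 ppm mass noise, 30% unassignable
    noise peaks, 1000 Gibbs sweeps with 200 discarded as burn-in.
    """
    formulas = [ic.parse_formula(s) for s in PRESENT_FORMULAS]
    decoys = generate_decoys(formulas, 80, ppm_window=3.0, seed=5)
    all_formulas = formulas + decoys
    adducts = [ic.parse_adduct_rule("M+H", 1), ic.parse_adduct_rule("M+Na", 1)]
    library = ic.build_library(all_formulas, adducts)
    runs = []
    for seed in range(1, 6):
        base_cfg = SyntheticConfig(seed=seed, ppm_sigma=1.0)
        n_signal = len(generate_dataset(formulas, adducts, base_cfg)[0])
        cfg = SyntheticConfig(
            seed=seed, ppm_sigma=1.0, n_noise_peaks=int(round(0.3 * n_signal))
        )
        peaks, truth = generate_dataset(formulas, adducts, cfg)
        h = Hyperparameters(
            lambda0=float(np.mean([p.intensity for p in peaks])),
            mu0=float(np.mean([p.rt for p in peaks])),
        )
        chain = sampler.run(
            peaks, library, h, n_iterations=1000, burn_in=200, seed=100 + seed
        )
        summary = posterior.summarize(chain, peaks, library, h)
        runs.append(
            {"peaks": peaks, "truth": truth, "summary": summary, "seed": seed}
        )
    return {
        "runs": runs,
        "library": library,
        "n_present": len(formulas),
        "n_formulas": len(all_formulas),
    }
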