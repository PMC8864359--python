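"""Published posterior summaries for the Black Harrier population model.

The original Bayesian analysis of SABAP2 detection/non-detection data
(2008–2019) together with telemetry survival records reported marginal
posterior means and standard deviations for the model parameters. The raw
atlas and rainfall data are not redistributable, so viability scenarios in
this package can start from these summaries instead: parameters are drawn
from independent truncated-normal approximations of the marginals (see
:mod:`harrierpva.pva`). This ignores posterior correlations and is an
acknowledged approximation.

Values: posterior (mean, sd) per parameter.
"""

from __future__ import annotations

__all__ = ["POSTERIOR_SUMMARY", "N_PENTADS_DETECTED"]

#: Marginal posterior mean and sd per parameter from the published analysis.
POSTERIOR_SUMMARY: dict[str, tuple[float, float]] = {
    "phi1": (0.502, 0.070),         # fledgling annual survival
    "phi2": (0.704, 0.044),         # sub-adult/adult annual survival
    "r": (0.057, 0.002),            # per-individual detection probability
    "mu0": (1.277, 0.140),          # initial mean abundance per pentad
    "beta0": (0.092, 0.459),        # fecundity logit intercept
    "beta1": (0.862, 0.285),        # rainfall effect on logit fecundity
    "sigma_gamma": (0.338, 0.320),  # sd of annual fecundity random effect
    "psi": (1.365, 0.115),          # negative-binomial over-dispersion
}

#: Pentads with at least one Black Harrier detection, 2008–2019; scales mean
#: per-pentad abundance to a total population size.
N_PENTADS_DETECTED = 1070
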