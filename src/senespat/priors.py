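"""Prior scales shared across the spatial model.

``SIGMA_BETA`` is the fixed scale of group-level deviations of beta
around the AAR-level mean; it induces the N(0, sqrt(2) * SIGMA_BETA)
prior on a group difference used by the Savage-Dickey Bayes factor.
``MU_PRIOR_SD`` is the scale of the AAR-level mean log-rate prior.
"""

SIGMA_BETA = 1.0
MU_PRIOR_SD = 2.0

#: Half-normal prior scale of the spot-noise sd sigma. Under plug-in
#: MAP inference the latent-effect scales are weakly identified against
#: the dropout probability at ZIP rates -- a large noise scale mimics
#: structural zeros while shifting beta by -sigma^2/2 -- so the scale
#: must stay informative, in the spirit of spatial count models that
#: fix these scales outright. The ICAR field scale tau is fixed in
#: FitConfig for the same reason.
SIGMA_EPS_PRIOR_SCALE = 0.3
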