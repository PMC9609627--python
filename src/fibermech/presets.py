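"""Built-in SLS parameter sets for GelMA microfibers.

The lumped relaxation parameters (lambda1, lambda2 in uN/um; tau in s)
were obtained by fitting the stress-relaxation response of microfluidic
spun GelMA microfibers at two polymer concentrations.  The 7% w/v set
also carries the step elongation u0 = 9 um of the relaxation test it was
fitted from.
"""

from __future__ import annotations

from .sls import SLSParameters

#: 7% w/v GelMA microfiber
GELMA_7PCT = SLSParameters(lambda1=11.23, lambda2=0.7629, tau=44.94)

#: 5.5% w/v GelMA microfiber (softer network, slower relaxation)
GELMA_5P5PCT = SLSParameters(lambda1=30.72, lambda2=3.584, tau=56.20)

#: step elongation (um) of the relaxation test behind GELMA_7PCT
RELAXATION_U0_UM = 9.0

PRESETS: dict[str, SLSParameters] = {
    "gelma_7pct": GELMA_7PCT,
    "gelma_5p5pct": GELMA_5P5PCT,
}


def get_preset(name: str) -> SLSParameters:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
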