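"""Physical constants shared across the package."""

#: Boltzmann constant, J/K (exact SI value).
KB: float = 1.380649e-23
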