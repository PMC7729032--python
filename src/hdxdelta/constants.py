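"""Physical constants and column/sentinel conventions shared across the package."""

#: Mass difference between deuterium and protium, in Da.
DEUTERIUM_MASS_SHIFT = 1.00627675

#: Proton mass used for m/z -> neutral-mass conversion, in Da.
PROTON_MASS = 1.00728

#: Sentinel exposure value (seconds column) marking the undeuterated control.
UNDEUTERATED_EXPOSURE = 0.0

#: Sentinel exposure value marking the 24 h out-exchange (maximal-exchange) control.
OUT_EXCHANGE_EXPOSURE = -1.0

#: Default minimum separation between the two control masses before the
#: deuterated-fraction denominator is considered informative: the peptide must
#: resolve at least half a deuterium.
DEFAULT_CONTROL_MARGIN = 0.5 * DEUTERIUM_MASS_SHIFT
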