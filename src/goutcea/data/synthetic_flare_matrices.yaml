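# SYNTHETIC stand-in daily pain-state transition matrices, one per flare drug.
#
# The original model estimated these matrices from patient-level trial data
# that are not redistributable; only the naproxen matrix was published, in a
# supplementary file that is not bundled here.  These stand-ins are therefore
# synthetic: hand-constructed to be clinically plausible for effective
# anti-inflammatory treatment of an acute gout flare (substantial pain relief
# within 24-48 h, most patients at no/mild pain by day 3, near-complete
# resolution within 5-7 days), with the IL-1 inhibitor anakinra slightly
# faster and colchicine/prednisone slightly slower than naproxen, matching
# the qualitative effectiveness ordering reported for the original model.
#
# Rows = state on day t, columns = state on day t+1,
# order: no_pain, mild_pain, moderate_pain, severe_pain.  Rows sum to 1.

naproxen:
  - [0.92, 0.05, 0.02, 0.01]
  - [0.55, 0.35, 0.07, 0.03]
  - [0.25, 0.45, 0.22, 0.08]
  - [0.20, 0.40, 0.30, 0.10]
colchicine:
  - [0.90, 0.06, 0.025, 0.015]
  - [0.50, 0.38, 0.08, 0.04]
  - [0.22, 0.44, 0.24, 0.10]
  - [0.17, 0.39, 0.32, 0.12]
prednisone:
  - [0.90, 0.065, 0.02, 0.015]
  - [0.51, 0.38, 0.07, 0.04]
  - [0.23, 0.44, 0.23, 0.10]
  - [0.18, 0.39, 0.31, 0.12]
anakinra:
  - [0.93, 0.045, 0.015, 0.01]
  - [0.58, 0.33, 0.06, 0.03]
  - [0.28, 0.45, 0.20, 0.07]
  - [0.23, 0.41, 0.27, 0.09]
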