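# Triage protocol definitions, version 1.
#
# The three protocols differ only in which BHS totals end screening
# ("no further evaluation"): 0-1 (P1, the original algorithm), 0-2 (P2)
# and 0-3 (P3).  BHS >= 6 always means immediate psychiatric referral;
# the intermediate zone triggers BDI-9 completion.  BDI-9 19-24 indicates
# a DSM-5 major-depressive-episode assessment; BDI-9 >= 25 indicates
# immediate referral.
version: 1
protocols:
  P1: {bhs_stop_max: 1, bhs_refer_min: 6, bdi_assess_lo: 19, bdi_assess_hi: 24, bdi_refer_min: 25}
  P2: {bhs_stop_max: 2, bhs_refer_min: 6, bdi_assess_lo: 19, bdi_assess_hi: 24, bdi_refer_min: 25}
  P3: {bhs_stop_max: 3, bhs_refer_min: 6, bdi_assess_lo: 19, bdi_assess_hi: 24, bdi_refer_min: 25}
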