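# Cohort phenotype presets for the synthetic serum simulator.
#
# Means are mg/dL per (subclass, lipid); cv is the coefficient of
# variation of the log-normal concentration distribution. The
# "low_hdl_cm" preset emulates a low-HDL cohort with circulating
# chylomicrons and TG-rich large VLDL; its means are the placebo
# marginal means of that phenotype converted from mmol/L to mg/dL.
# "hyperchol" emulates a hypercholesterolemic cohort with essentially
# no chylomicrons, lower large-VLDL lipids and higher cholesterol in
# the large HDL subclasses. Unmodeled edge subclasses (LDL12/13,
# HDL14/19/20) carry small means and narrow spread in both phenotypes.
# These numbers are simulator inputs, not measured claims.

low_hdl_cm:
  correlation_within_category: 0.5
  classes:
    CM01:   {TG: {mean: 12.02, cv: 0.45}, CH: {mean:  2.93, cv: 0.45}}
    CM02:   {TG: {mean:  8.40, cv: 0.45}, CH: {mean:  1.81, cv: 0.45}}
    VLDL03: {TG: {mean: 21.13, cv: 0.35}, CH: {mean:  5.70, cv: 0.35}}
    VLDL04: {TG: {mean: 31.03, cv: 0.35}, CH: {mean:  8.20, cv: 0.35}}
    VLDL05: {TG: {mean: 31.56, cv: 0.35}, CH: {mean: 22.06, cv: 0.35}}
    VLDL06: {TG: {mean: 13.26, cv: 0.35}, CH: {mean: 10.86, cv: 0.35}}
    VLDL07: {TG: {mean:  5.83, cv: 0.35}, CH: {mean:  8.51, cv: 0.35}}
    LDL08:  {TG: {mean:  9.81, cv: 0.25}, CH: {mean: 31.69, cv: 0.25}}
    LDL09:  {TG: {mean:  9.55, cv: 0.25}, CH: {mean: 54.82, cv: 0.25}}
    LDL10:  {TG: {mean:  3.71, cv: 0.25}, CH: {mean: 21.98, cv: 0.25}}
    LDL11:  {TG: {mean:  1.24, cv: 0.25}, CH: {mean:  6.12, cv: 0.25}}
    LDL12:  {TG: {mean:  0.60, cv: 0.08}, CH: {mean:  2.50, cv: 0.08}}
    LDL13:  {TG: {mean:  0.30, cv: 0.08}, CH: {mean:  1.20, cv: 0.08}}
    HDL14:  {TG: {mean:  0.30, cv: 0.08}, CH: {mean:  0.60, cv: 0.08}}
    HDL15:  {TG: {mean:  0.44, cv: 0.20}, CH: {mean:  1.31, cv: 0.20}}
    HDL16:  {TG: {mean:  1.77, cv: 0.20}, CH: {mean:  4.08, cv: 0.20}}
    HDL17:  {TG: {mean:  4.95, cv: 0.20}, CH: {mean: 15.25, cv: 0.20}}
    HDL18:  {TG: {mean:  3.98, cv: 0.20}, CH: {mean: 16.21, cv: 0.20}}
    HDL19:  {TG: {mean:  2.00, cv: 0.08}, CH: {mean:  6.00, cv: 0.08}}
    HDL20:  {TG: {mean:  1.00, cv: 0.08}, CH: {mean:  4.00, cv: 0.08}}

hyperchol:
  correlation_within_category: 0.5
  classes:
    CM01:   {TG: {mean:  0.30, cv: 0.30}, CH: {mean:  0.05, cv: 0.30}}
    CM02:   {TG: {mean:  0.20, cv: 0.30}, CH: {mean:  0.05, cv: 0.30}}
    VLDL03: {TG: {mean:  6.00, cv: 0.35}, CH: {mean:  2.00, cv: 0.35}}
    VLDL04: {TG: {mean: 14.00, cv: 0.35}, CH: {mean:  4.00, cv: 0.35}}
    VLDL05: {TG: {mean: 20.00, cv: 0.35}, CH: {mean: 15.00, cv: 0.35}}
    VLDL06: {TG: {mean: 13.30, cv: 0.35}, CH: {mean: 10.90, cv: 0.35}}
    VLDL07: {TG: {mean:  5.80, cv: 0.35}, CH: {mean:  8.50, cv: 0.35}}
    LDL08:  {TG: {mean:  9.80, cv: 0.25}, CH: {mean: 40.00, cv: 0.25}}
    LDL09:  {TG: {mean:  9.50, cv: 0.25}, CH: {mean: 54.80, cv: 0.25}}
    LDL10:  {TG: {mean:  3.70, cv: 0.25}, CH: {mean: 22.00, cv: 0.25}}
    LDL11:  {TG: {mean:  1.24, cv: 0.25}, CH: {mean:  6.10, cv: 0.25}}
    LDL12:  {TG: {mean:  0.60, cv: 0.08}, CH: {mean:  2.50, cv: 0.08}}
    LDL13:  {TG: {mean:  0.30, cv: 0.08}, CH: {mean:  1.20, cv: 0.08}}
    HDL14:  {TG: {mean:  0.30, cv: 0.08}, CH: {mean:  0.80, cv: 0.08}}
    HDL15:  {TG: {mean:  0.50, cv: 0.20}, CH: {mean:  3.50, cv: 0.20}}
    HDL16:  {TG: {mean:  2.80, cv: 0.20}, CH: {mean:  9.00, cv: 0.20}}
    HDL17:  {TG: {mean:  3.50, cv: 0.20}, CH: {mean: 22.00, cv: 0.20}}
    HDL18:  {TG: {mean:  3.00, cv: 0.20}, CH: {mean: 16.20, cv: 0.20}}
    HDL19:  {TG: {mean:  2.00, cv: 0.08}, CH: {mean:  6.00, cv: 0.08}}
    HDL20:  {TG: {mean:  1.00, cv: 0.08}, CH: {mean:  4.00, cv: 0.08}}
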