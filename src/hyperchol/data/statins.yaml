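# Expected proportional LDL-C reduction by statin type and daily dose (mg).
# Commonly published mean reductions; swappable configuration, validated for
# monotonicity in dose within each statin.
statin_coefficients:
  atorvastatin: {10: 0.37, 20: 0.43, 40: 0.49, 80: 0.55}
  rosuvastatin: {5: 0.38, 10: 0.43, 20: 0.48, 40: 0.53}
  simvastatin:  {10: 0.27, 20: 0.32, 40: 0.37, 80: 0.42}
  pravastatin:  {10: 0.20, 20: 0.24, 40: 0.29, 80: 0.33}
  lovastatin:   {20: 0.25, 40: 0.31, 80: 0.37}
  fluvastatin:  {20: 0.17, 40: 0.23, 80: 0.29}
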