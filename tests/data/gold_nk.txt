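# Tabulated optical constants of evaporated gold films.
# Source: Johnson & Christy, Phys. Rev. B 6, 4370 (1972), experimental n,k
# interpolated onto round vacuum wavelengths.  Used as the independent
# reference for the Drude-Lorentz gold fit (agreement asserted at 633 nm).
# columns: wavelength_nm  n  k
500   0.970  1.860
550   0.350  2.450
600   0.250  2.990
633   0.183  3.433
650   0.166  3.590
700   0.131  4.100
750   0.140  4.620
800   0.154  5.120
900   0.206  5.920
1000  0.257  6.700
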