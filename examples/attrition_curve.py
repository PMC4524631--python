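"""Fit the dynamic control function u(t) from attrition-by-age statistics.

Normalizes the built-in population survey (average attrition index of the
lower first molar by age), fits the cubic control function, and samples a
nonlinear frame schedule. The three phases — fast wear of immature enamel,
a stable mineralized plateau, and accelerated dentin-exposed wear — show
up as the slope pattern of u(t).
"""

import numpy as np

from toothwear import (
    DEFAULT_ATTRITION_SERIES,
    NormalizedSeries,
    fit_dcf,
    nonlinear_schedule,
    normalize_minmax,
)

norm = normalize_minmax(DEFAULT_ATTRITION_SERIES)
table = NormalizedSeries(np.round(norm.x, 2), np.round(norm.y, 2))
dcf = fit_dcf(table, degree=3)
a3, a2, a1, a0 = dcf.coefficients
print(f"u(t) = {a3:.3f} t^3 {a2:+.3f} t^2 {a1:+.3f} t {a0:+.3f}")

t = np.linspace(0, 1, 100)
slope = np.polyval(np.polyder(dcf.coefficients), t)
for name, lo, hi in (("early", 0.0, 0.25), ("middle", 0.25, 0.7), ("late", 0.7, 1.0)):
    sel = (t >= lo) & (t <= hi)
    print(f"mean wear rate, {name} phase t in [{lo}, {hi}]: {slope[sel].mean():.3f}")

u = nonlinear_schedule(dcf, 6)
print("6-frame nonlinear schedule u_k:", np.round(u, 3).tolist())
# Compare with the uniform linear schedule [0, 0.2, ..., 1.0]: the middle
# frames bunch together because mineralized enamel wears slowly.
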