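"""Test whether a normal copula adequately represents the data.

The determinant of the empirical (Spearman) rank correlation matrix,
D_ER, is compared with the sampling distribution of D_NR, the determinant
of the normal-scores correlation matrix of same-size datasets simulated
from the fitted copula.  If D_ER falls inside the 90% band the copula
assumption cannot be rejected at the 10% level.
"""

import wetlandbn as w

table = w.generate(w.default_spec(n_wetlands=22, seed=11))
model = w.fit(table)

report = w.validate_model(model, table, n_sims=10_000, seed=1)
print(f"D_ER                = {report.d_er:.4f}")
print(f"90% band of D_NR    = ({report.band[0]:.4f}, {report.band[1]:.4f})")
print(f"quantile position   = {report.quantile_position:.2f}")
print(f"copula assumption   : {'not rejected' if report.passed else 'REJECTED'}")
# the quantile position says where the observed determinant sits inside
# the simulated distribution (0.5 = dead centre)
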