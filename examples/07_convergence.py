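"""Test whether two populations share elevation-responsive genes.

Given per-population lfsr and posterior effects, a gene is convergent
when it is significant in both populations with the same effect sign.
The overlap of the two significant lists is tested against a
hypergeometric null; concordance of effect sizes over the convergent
subset is compared with the all-gene correlation.
"""

import numpy as np

from asepop.convergence import (
    classify_convergent,
    effect_concordance,
    overlap_test,
)

# study-scale worked example: 341 and 260 significant genes of 13,632
# assayed, 20 in common
t = overlap_test(N=13632, K=341, n=260, x=20)
print(f"overlap test: x={t.x} of K={t.K}, n={t.n}, N={t.N}")
print(f"  P(X >= {t.x}) = {t.p:.3g}")
print(f"  overlap = {t.overlap_percent():.1f}% of the smaller list")

# classification on simulated per-population results
rng = np.random.default_rng(12)
n = 3000
shared = rng.random(n) < 0.01           # 1% truly convergent
effect = rng.normal(0, 1, n)
pm1 = np.where(shared, effect, rng.normal(0, 0.3, n))
pm2 = np.where(shared, effect, rng.normal(0, 0.3, n))
lfsr1 = np.where(shared | (rng.random(n) < 0.03), 0.01, 0.5)
lfsr2 = np.where(shared | (rng.random(n) < 0.03), 0.01, 0.5)

calls = classify_convergent(lfsr1, lfsr2, pm1, pm2, alpha=0.05)
print(f"\nsimulated: {int(calls['convergent'].sum())} convergent, "
      f"{int(calls['discordant'].sum())} significant-discordant")
conc = effect_concordance(pm1, pm2, calls["convergent"].to_numpy())
print(f"effect correlation, convergent subset: r = {conc['r_subset']:.2f}")
print(f"effect correlation, all genes:         r = {conc['r_all']:.2f}")
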