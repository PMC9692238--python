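"""Multivariate adaptive shrinkage on a table of effects and errors.

Given per-gene effect estimates and standard errors across conditions,
the mixture-of-multivariate-normals prior learns how effects are shared
(null, condition-specific, equal across conditions, ...) and returns
shrunken posterior effects plus the local false sign rate — the posterior
probability that a sign call would be wrong or the effect is zero.
"""

import numpy as np
import pandas as pd

from asepop.mashlite import EffectTable, mash_analysis

rng = np.random.default_rng(5)
n, r = 2000, 4
conditions = [f"tissue{i + 1}" for i in range(r)]

true = np.zeros((n, r))
shared = rng.random(n) < 0.15            # 15% of genes share a real effect
true[shared] = rng.normal(0, 1.5, size=(int(shared.sum()), 1))
shat = rng.uniform(0.5, 1.5, size=(n, r))
bhat = true + rng.normal(0, shat)

table = EffectTable(
    bhat=pd.DataFrame(bhat, columns=conditions),
    shat=pd.DataFrame(shat, columns=conditions),
)
res = mash_analysis(table)

pi = res.model.pi
family = pi.groupby(pi.index.str.split("@").str[0]).sum().sort_values(ascending=False)
print("mixture weight by covariance family:")
print(family[family > 0.01].round(3).to_string())

called = res.lfsr.min(axis=1) < 0.05
print(f"\ngenes called at lfsr < 0.05: {called.sum()} "
      f"(true nonzero: {shared.sum()})")
sign_ok = np.sign(res.posterior_mean.to_numpy()[shared]) == np.sign(true[shared])
print(f"sign agreement on true effects: {sign_ok.mean():.2%}")
shrink = np.abs(res.posterior_mean.to_numpy()) <= np.abs(bhat)
print(f"posterior effects shrunk toward zero: {shrink.mean():.0%} of cells")
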