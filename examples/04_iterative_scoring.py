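"""Iterative DIF correction and re-scoring on a 13-item assessment fixture.

The fixture mimics a computer-based problem-solving form: 13 binary items,
three grouping variables (two binary, one continuous), about half the items
carrying nuisance-mediated DIF.  The procedure alternates detection,
surrogate construction, calibration and trait re-estimation until
successive trait vectors correlate above 0.99.
"""

import numpy as np

from difreduce import between_group_ss_bias, iterate_procedure, make_piaac_like_fixture

fx = make_piaac_like_fixture(seed=5)
res = iterate_procedure(fx.dataset, link="logit", max_iter=3, tol_corr=0.99, seed=5)

print(f"converged: {res.converged} after {res.iteration} iteration(s)")
for t in res.trace:
    print(f"  iteration {t['iteration']}: {t['n_flagged']} items flagged, "
          f"corr with previous trait = {t['convergence']:.4f}")
print(f"corrected items: {sorted(res.surrogates)}")
ss = between_group_ss_bias(
    res.theta_hat * fx.theta_true.std() + fx.theta_true.mean(),
    fx.theta_true, fx.group_assignment)
print(f"between-group SS bias of the final scores: {ss:.2f}")
# The correlation between successive iterations exceeding 0.99 means one
# correction pass essentially suffices, mirroring how few passes such
# assessments need in practice.
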