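"""A reduced operating-characteristics study (T=3 cells only).

Runs the 36-cell quick grid — 4 truth families x n in {700, 1500, 3000} x
delta* in {0, 1, 2} at T=3 — and prints the confusion matrix of true
family versus inferred model, the mean q per sample size and the delta
gate's coverage under the null. Takes a few minutes.
"""

import fcrank as fc

grid = fc.default_grid(Ts=(3,))
study = fc.run_study(grid, master_seed=42, progress=True)

print()
print("confusion (rows: truth; columns: accumulation/sensitive/critical/unknown)")
print(study.confusion())
print()
print(study.summary())

# Off-diagonal entries outside the 'u' column would be misclassifications:
# a conclusive decision for a model other than the generating one. The 'u'
# column counts inconclusive cells, where no model reached 0.9 posterior
# probability (typically small n or small delta*).
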