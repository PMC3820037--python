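"""Compute the three diabetes risk scores and standardize them.

The Cambridge and Framingham Offspring scores are linear predictors of
published logistic models; FINDRISC is an integer point total. Per-sample
standardization (z = (x - mean)/SD) puts all three on the per-1-SD scale
used for the odds-ratio comparisons.
"""

from frailcast import SyntheticConfig, apply_score, builtin_definition, generate_cohort

df = generate_cohort(SyntheticConfig(n=5000, seed=3))

print(f"{'score':22s} {'family':20s} {'mean raw':>9s} {'SD':>7s} {'n used':>7s}")
for name in ("framingham_offspring", "cambridge", "findrisc"):
    d = builtin_definition(name)
    res = apply_score(df, d)
    print(f"{name:22s} {d.family:20s} {res.raw.mean():9.2f} {res.sd:7.2f} {res.n_used:7d}")

print("""
The weighted-logistic raw score is a log-odds of incident diabetes under
the source model; the FINDRISC raw score is a 0-26 point total. After
standardization each score has mean 0 and SD 1 over the analytic sample,
so a logistic coefficient on z exponentiates to the per-1-SD odds ratio.
""")

one = df.iloc[[0]]
print("first participant:", dict(age=round(float(one.age.iloc[0]), 1),
                                 sex=one.sex.iloc[0], bmi=round(float(one.bmi.iloc[0]), 1)))
for name in ("cambridge", "findrisc"):
    res = apply_score(df, builtin_definition(name))
    print(f"  {name}: raw={res.raw.iloc[0]:.2f}, z={res.z.iloc[0]:+.2f}")
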