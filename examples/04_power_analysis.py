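"""How large a rate increase could this experiment have detected?

Monte-Carlo power of the one-sided exact conditional binomial rate
comparison over a grid of multiplicative effect sizes, at the study's
exposures and control rate.
"""

from mastat import PowerConfig, minimum_detectable_effect, power_curve

cfg = PowerConfig(
    mu_control=3.58e-11, g1=5.02822e11, g2=5.37022e11,
    effect_grid=tuple(round(0.25 * i, 10) for i in range(13)),  # 0%..300%
    reps=1000, alpha=0.05, sided="one", seed=1,
)
curve = power_curve(cfg)
print("effect  power   (MC se)")
for row in curve.to_rows():
    print(f"{row['effect']:5.2f}  {row['power']:6.3f}  ({row['mc_se']:.3f})")

mde = minimum_detectable_effect(cfg, 0.80, curve=curve)
print(f"minimum detectable effect at 80% power: {mde:+.0%} increase")

# conditioning on the observed control count (18) asks what THIS
# experiment, as realised, could detect
cond = PowerConfig(**{**cfg.__dict__, "fixed_control": 18,
                      "effect_grid": (1.0,)})
print(f"power at a 100% increase, control count held at 18: "
      f"{power_curve(cond).power[0]:.3f}")
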