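"""Build a reduced-scale transition stripe and plot it.

Locates the demographic boundary y*(x) where creole dominance becomes
more likely than not, for epsilon = 0.05, 0.06 and 0.07, and writes the
stripe table and a figure with the Mulatto-fraction axis expanded by a
power 0.2.  Above the stripe the model predicts a creole; below it the
European language prevails; inside it the prediction is uncertain.
"""

from pathlib import Path

from creolang import ModelParams, build_stripe
from creolang.viz import plot_stripe

params = ModelParams(gamma=0.8, delta=0.1, epsilon=0.06)
stripe = build_stripe(
    params,
    xs=[0.02, 0.08, 0.25, 0.6],
    n_total=1000,
    n_replicates=9,
    y_tolerance=0.03,
    seed=3,
)

print(stripe.to_frame().to_string(index=False))
out = Path("scratch"); out.mkdir(exist_ok=True)
stripe.to_csv(out / "stripe.csv")
plot_stripe(stripe, path=out / "stripe.png")
print(f"wrote {out/'stripe.csv'} and {out/'stripe.png'}")
print("Each row gives, at Mulatto fraction x, the Black-population "
      "fraction y above which the creole wins for the three epsilon values.")
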