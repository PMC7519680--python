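"""Life table response experiment: decompose the growth-rate drop between
the good and bad season into vital-rate contributions.

The headline comparison: the summed effect of changes in transient
probabilities exceeds the effect of the (small) change in adult survival,
even though adult survival has by far the largest sensitivity — variable
rates with modest sensitivities can dominate realized changes in lambda.
"""

from pathlib import Path

import transientcmr as tc
from transientcmr.lifecycle import BAD_SEASON, GOOD_SEASON

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rep = tc.ltre_decompose(GOOD_SEASON, BAD_SEASON)
rep.table.to_csv(OUT / "ltre_table.csv")

print(f"lambda good = {rep.lambda_good:.4f}, bad = {rep.lambda_bad:.4f}, "
      f"delta = {rep.lambda_delta:.4f}")
print(f"sum of first-order contributions = {rep.sum_of_contributions:.4f} "
      f"(linearization residual {rep.residual:+.4f})\n")

print("contributions to the lambda decline (bad - good):")
for name, label in (("phiA", "adult survival"),
                    ("phi1", "first-year survival"),
                    ("F", "resident fertility"),
                    ("Fprime", "first-time-breeder fertility")):
    print(f"  {label:<28} {rep.contribution(name):+.3f}")
print(f"  {'transience (pooled total)':<28} "
      f"{rep.contribution('tau_total', 'pooled'):+.3f}  "
      f"(per-age sum {rep.contribution('tau_total', 'per_age'):+.3f})")
print(f"  {'recruitment (pooled total)':<28} "
      f"{rep.contribution('gamma_total', 'pooled'):+.3f}  "
      f"(per-age sum {rep.contribution('gamma_total', 'per_age'):+.3f})")

t, a = abs(rep.contribution("tau_total", "pooled")), abs(rep.contribution("phiA"))
print(f"\n|transience total| = {t:.3f} >= |adult survival| = {a:.3f}: "
      f"{'yes' if t >= a else 'NO'} — transient loss outweighs the adult-"
      f"survival change in driving the decline")
print(f"wrote {OUT / 'ltre_table.csv'}")
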