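"""Transient-structured matrix population model for the two contrasted
seasons: growth rate, stable structure, entry and vital-rate level
sensitivities and elasticities.

Uses the published good-season (1993-like, weak density-dependence) and
bad-season (2008-like, strong density-dependence) vital rates.  Writes
the labelled projection matrices, the growth rates, and the lower-level
sensitivity/elasticity tables.
"""

from pathlib import Path

import pandas as pd

import transientcmr as tc
from transientcmr.lifecycle import (BAD_SEASON, GOOD_SEASON, mean_rates,
                                    vital_rate_sensitivities)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for name, vr in (("good", GOOD_SEASON), ("bad", BAD_SEASON),
                 ("mean", mean_rates(GOOD_SEASON, BAD_SEASON))):
    M = tc.build_matrix(vr)
    ana = tc.asymptotic_analysis(M)
    M.to_dataframe().to_csv(OUT / f"matrix_{name}.csv")
    rows.append({"season": name, "lambda": ana.lam,
                 "elasticity_sum": ana.entry_elasticity.sum()})
    print(f"{name:>4} season: lambda = {ana.lam:.4f} "
          f"(entry elasticities sum to {ana.entry_elasticity.sum():.6f})")

pd.DataFrame(rows).to_csv(OUT / "lambda.csv", index=False)

elas = vital_rate_sensitivities(GOOD_SEASON)
sens = vital_rate_sensitivities(mean_rates(GOOD_SEASON, BAD_SEASON))
elas.to_csv(OUT / "vital_rate_elasticities_good.csv")
sens.to_csv(OUT / "vital_rate_sensitivities_mean.csv")

print("\nkey lower-level results (published values in brackets):")
print(f"  good-season elasticity of adult survival: "
      f"{elas.loc['phiA', 'elasticity']:.3f}  [0.849]")
print(f"  good-season elasticity of resident fertility: "
      f"{elas.loc['F', 'elasticity']:.3f}  [0.074]")
print(f"  mean-matrix sensitivity of adult survival: "
      f"{sens.loc['phiA', 'sensitivity']:.3f}  [printed 0.968; the published "
      f"contribution arithmetic implies 0.953]")
print(f"  per-age transience sensitivities (mean matrix): "
      + ", ".join(f"tau{i}: {sens.loc[f'tau{i}', 'sensitivity']:+.3f}"
                  for i in (3, 4, 5, 6, 7)))
print(f"wrote matrices and sensitivity tables under {OUT}")
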