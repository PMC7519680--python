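"""Fit transient-CJS models and locate the density-dependence signal.

Model set on the simulated case-study data: transient probability tau
constant per age group, tau driven by the food-per-capita covariate
(shared or group-specific slopes), and fully time-dependent tau.  Model
selection by AIC; the share of temporal deviance explained by the
covariate by ANODEV.  Writes the AIC table, the ANODEV summary and the
fitted tau-by-group-and-year estimates with 95% CIs.
"""

import json
from pathlib import Path

import pandas as pd

import transientcmr as tc
from transientcmr.cjs import ModelSpec, aic_table, anodev, fit, tau_from_fit

OUT = Path(__file__).resolve().parent.parent / "results"
data = tc.read_inp(OUT / "histories.inp")
cov = tuple(pd.read_csv(OUT / "covariate.csv")["covariate"])
ma = tc.build_marray(data)

specs = {
    "tau(group)": ModelSpec(tau="group"),
    "tau(group+cov)": ModelSpec(tau="group+cov", covariate=cov),
    "tau(group*cov)": ModelSpec(tau="group*cov", covariate=cov),
    "tau(group+time)": ModelSpec(tau="group+time"),
}
fits = {}
for name, spec in specs.items():
    fits[name] = fit(ma, spec, n_restarts=1,
                     compute_vcov=(name == "tau(group*cov)"))
    print(f"fitted {name}: np = {fits[name].n_params}, "
          f"deviance = {fits[name].deviance:.1f}, AIC = {fits[name].aic:.1f}")

table = aic_table(list(fits.values()))
table.to_csv(OUT / "aic_table.csv", index=False)
print("\nAIC ranking:\n", table[["model", "n_params", "delta_aic", "weight"]]
      .to_string(index=False))

F, pct, p = anodev(fits["tau(group)"], fits["tau(group+cov)"],
                   fits["tau(group+time)"])
(OUT / "anodev.json").write_text(json.dumps(
    {"F": F, "pct_deviance": pct, "p": p}, indent=2))
print(f"\nANODEV: the density-dependence covariate explains {pct:.0%} of the "
      f"temporal deviance in tau (F = {F:.1f}, p = {p:.2e}); the published "
      f"analysis reported 56% for the real data")

best = fits["tau(group*cov)"]
est = tau_from_fit(best)
est.table.to_csv(OUT / "tau_estimates.csv", index=False)
for g in data.groups:
    sub = est.by_group(g)
    print(f"  tau for group {g:>5}: {sub.tau.min():.3f} - {sub.tau.max():.3f} "
          f"across the covariate support")
print(f"adult survival estimate: {best.phi_estimates[0]:.3f}; "
      f"detection: {best.p_estimates[0]:.3f}")
print(f"wrote {OUT / 'tau_estimates.csv'}, aic_table.csv, anodev.json")
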