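"""Tumor-static concentration (TSC) with a parametric-bootstrap 80% CI.

Loads the fitted growth/kill parameters of the three mouse xenograft
contexts, evaluates TSC = kg0*kc50/(kmax-kg0) for each, combines them into
a single efficacy threshold (Ceff), and bootstraps a confidence interval
for the best-characterized context.
"""

from trimerqsp import combined_ceff, load_parameters, tsc, tsc_confidence_interval

print(f"{'context':<20} {'TSC (pM)':>10}")
reported = []
for name in ("hct116_engrafted", "hct116_adoptive", "sum149_adoptive"):
    params = load_parameters(name)
    gk = params.growth
    value_pm = tsc(gk.kg0, gk.kmax, gk.kc50) * 1e3
    reported.append(params.extras["reported_tsc_pM"])
    print(f"{name:<20} {value_pm:>10.4f}")

ceff = combined_ceff(reported)
print(f"\nCeff across models: arithmetic mean {ceff['arithmetic_mean']:.4f} pM, "
      f"geometric mean {ceff['geometric_mean']:.4f} pM")

gk = load_parameters("hct116_adoptive").growth
ci = tsc_confidence_interval(
    {"kg0": gk.kg0, "kmax": gk.kmax, "kc50": gk.kc50},
    {"kg0": 3.0, "kmax": 7.0, "kc50": 7.0},
    n_boot=10_000, seed=1,
)
print(f"HCT-116 adoptive TSC {ci['tsc'] * 1e3:.4f} pM, "
      f"80% CI ({ci['lower'] * 1e3:.4f}, {ci['upper'] * 1e3:.4f}) pM")
# The TSC is the trimer concentration at which tumor kill balances growth:
# exposures above it are predicted to shrink the tumor.
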