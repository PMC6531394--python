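"""Simulate a mouse xenograft study arm and print the key time courses.

One animal given 0.5 mg/kg IV on days 0 and 7, with 5e6 activated T cells
adoptively transferred on day 1: drug PK, tumor trimer formation after the
T-cell lag, and the resulting tumor regression.
"""

from trimerqsp import MouseScenario, load_parameters, simulate_mouse

params = load_parameters("hct116_adoptive")
scenario = MouseScenario(dose_mg_per_kg=0.5, dose_times_h=(0.0, 168.0),
                         tcells_per_animal=5e6, tcell_time_h=24.0,
                         initial_tumor_volume_mm3=150.0)
df = simulate_mouse(scenario, params, t_end_h=35 * 24)

print(f"{'day':>5} {'serum (nM)':>11} {'trimer (pM)':>12} {'tumor (mm3)':>12}")
for day in (0, 3, 7, 10, 14, 21, 28, 35):
    row = df.iloc[(df["time_h"] - day * 24).abs().argmin()]
    print(f"{day:>5} {row['c1']:>11.3f} {row['trimer_pM']:>12.4f} "
          f"{row['tumor_volume_mm3']:>12.1f}")

# Trimer appears only after the 5-day T-cell lag (day ~6) and drives tumor
# regression; exposure is far above the ~0.012 pM tumor-static level, so
# the tumor shrinks rapidly once killing starts.
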