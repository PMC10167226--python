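"""Identify which microscopic aggregation step a chaperone inhibits.

Generates a ThT dilution series (chaperone:Aβ42 ratios 0/10/50/100%) in
which the secondary-nucleation rate constant k2 is progressively
suppressed, then (1) fits the empirical sigmoid per ratio to get half-time
delays and (2) runs the constrained global fit three times — k_n, k_+ or
k_2 free per condition, everything else shared — ranking the models by
residual sum of squares.  The winning free constant names the inhibited
step; its per-condition factors estimate the strength of inhibition.
"""
import loopchap as lc
from loopchap.plateio import group_traces, traces_from_plate

cfg = lc.GeneratorConfig(seed=7)  # truth: k_2 suppressed to 50/20/10%
plate, wmap, truth = lc.gen_tht_panel(cfg)

groups = group_traces(traces_from_plate(plate, wmap))
panel = {float(r): lc.normalize_tht(trs) for (_, r), trs in groups.items()}

fits = {r: lc.fit_sigmoid((nt.times, nt.signal)) for r, nt in panel.items()}
print("half-time delays (relative to the chaperone-free control):")
print(lc.halftime_delay(fits).to_string(index=False))

ranked = lc.rank_global_fits(panel, n_starts=4, seed=7)
print("\nconstrained global fits, best first:")
for fit in ranked:
    print(f"  free {fit.free_constant:7s} RSS = {fit.residual_sum_squares:.3f}")
best = ranked[0]
print(f"\nwinner: {best.free_constant} (truth: {truth['suppression_target']})")
print("recovered per-ratio suppression factors vs truth:")
for ratio in sorted(best.factors):
    print(f"  {ratio:5.0f}%  fitted {best.factors[ratio]:.3f}   "
          f"true {truth['factors'][ratio]:.3f}")
print("\nA factor of e.g. 0.1 at the 100% ratio means the chaperone cuts the"
      "\nidentified rate constant to a tenth of its chaperone-free value.")
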