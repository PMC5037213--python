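"""Terbinafine-style inhibition of ergosterol synthesis.

Sets the lumped sterol reaction's n_max to zero and compares perturbed vs
control ensembles: membranes keep growing (slower) but become depleted of
ergosterol; mobilized droplet steryl esters provide the only residual sterol
supply.
"""

import lipidsim as L

result = L.ergosterol_knockout_experiment(L.default_config(), n_runs=6, base_seed=0)

print("ES fraction per membrane (control -> knockout):")
for name in result.es_fraction_control:
    print(f"  {name:20s} {result.es_fraction_control[name]:.3f} -> "
          f"{result.es_fraction_perturbed[name]:.3f} "
          f"({result.reduction_per_membrane[name]:5.1f} % less)")
print(f"\nmean ergosterol-content reduction: "
      f"{result.mean_reduction_percent:.1f} %   (reported effect: ~30 %)")
print(f"total lipids: control {result.total_lipids_control:.0f}, "
      f"knockout {result.total_lipids_perturbed:.0f}  (slower growth, ~80000)")
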