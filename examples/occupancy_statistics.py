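"""Poisson occupancy statistics from droplet tallies.

Estimates the mean number of founder cells per droplet (lambda) from
presence/absence counts, and evaluates the single-cell cultivation design
point.
"""

import chemodrop as cd
from chemodrop.occupancy import OccupancyCount

# ~100-droplet tallies, as read out after incubation
weak = cd.estimate_lambda(OccupancyCount(n_total=1000, n_growth=15))
strong = cd.estimate_lambda(OccupancyCount(n_total=1000, n_growth=900))

print(f"1.5% growth-positive  -> lambda = {weak.lambda_hat:.3f} "
      f"(95% CI {weak.ci_low:.3f}-{weak.ci_high:.3f})")
print(f"90.0% growth-positive -> lambda = {strong.lambda_hat:.2f} "
      f"(95% CI {strong.ci_low:.2f}-{strong.ci_high:.2f})")
print(f"fold change: {strong.lambda_hat / weak.lambda_hat:.0f}x")
# The fold change in lambda is the chemotactic response: the same species,
# before and after exposure to its attractant gradient.

p1 = cd.single_cell_given_growth(0.1)
print(f"\nat lambda = 0.1: {100 * p1:.0f}% of growth-positive droplets are "
      f"single-cell founded; {100 * cd.empty_fraction(0.1):.1f}% of droplets stay empty")
# Dilute loading trades throughput (mostly empty droplets) for clonality.
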