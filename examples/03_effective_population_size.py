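"""Divisions per transfer and effective population size of MA lines.

A colony founded by one cell that reaches N colony-forming units has
gone through log2(N) doublings; the drift-effective population size
over that expansion is the harmonic mean of the exponentially growing
census sizes.
"""

from mastat import (
    divisions_per_transfer_from_cfu,
    effective_population_size,
    total_divisions,
)
from mastat.simulate import simulate_cfu_series

# noisy CFU counts from colonies that actually grew for T = 19.35 divisions
cfu = simulate_cfu_series(T=19.35, n_samples=10, sigma=0.2, seed=42)
T = divisions_per_transfer_from_cfu(list(cfu))
print(f"CFU counts: {[int(c) for c in cfu]}")
print(f"estimated divisions per transfer T = {T:.2f}")
print(f"total divisions over 46 transfers = {total_divisions(T, 46):.0f}")
ne = effective_population_size(T)
print(f"harmonic-mean Ne = {ne:.2f}")
print("-> Ne of order 10 means drift dominates selection during the "
      "experiment, so mutations accumulate nearly neutrally.")
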