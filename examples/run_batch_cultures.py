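"""Batch dFBA: sequential substrate exhaustion and the acetate switch.

Simulates the mixed five-substrate culture (0.4 g/L each) and a
glucose-only culture (2.0 g/L).  The mixed culture exhausts its substrates
in a strict order — glucose first, glycerol last — grows faster than any
single-substrate culture, and transiently accumulates acetate that is
re-consumed once the sugars are gone.  All of it falls out of the
crowding-constrained LP solved at each time step.
"""

from ccrsim import SUBSTRATES, BatchConfig, exhaustion_order, simulate_batch
from ccrsim import build_fixture_network

net = build_fixture_network()

mixed = simulate_batch(net, BatchConfig.mixed(SUBSTRATES, 0.4, dt=0.02, t_end=8.0))
print("mixed culture (0.4 g/L each):")
for rank, (s, t, _) in enumerate(exhaustion_order(mixed, 1e-4), start=1):
    print(f"  {rank}. {s:10s} exhausted at {t:.2f} hr")
print(f"  peak growth rate {mixed.peak_growth_rate():.3f}/hr, "
      f"peak acetate {mixed.acetate.max():.3f} g/L, "
      f"final acetate {mixed.acetate[-1]:.3f} g/L (reuptake)")

print("\nsingle-substrate peak growth rates (0.4 g/L):")
for s in SUBSTRATES:
    single = simulate_batch(net, BatchConfig.single_substrate(s, 0.4, dt=0.05, t_end=3.0))
    print(f"  {s:10s} {single.peak_growth_rate():.3f}/hr")
print("every one is below the mixed-culture peak: co-utilization pays.")
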