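"""Short-term memory capacity of one modular reservoir.

Trains lag-k readouts (k = 1..40) on a Bernoulli stream and prints the
squared-correlation profile and its sum (the memory capacity, MC), then
contrasts a few modularity levels.
"""

from modular_esn import MCConfig, mc_sweep, memory_capacity

result = memory_capacity(MCConfig(mu=0.2, r_sig=0.3), seed=1)
print("single reservoir at mu = 0.2, r_sig = 0.3")
print("r^2 by lag (1..10):", " ".join(f"{v:.2f}" for v in result.r2_by_lag[:10]))
print(f"memory capacity MC = {result.mc:.2f} (sum over lags 1..40)\n")

df = mc_sweep([0.05, 0.2, 0.45], [0.3], n_samples=8, seed=1)
print("mean MC over 8 reservoirs per mu:")
for _, row in df.iterrows():
    print(f"  mu = {row['mu']:4.2f}: MC = {row['mean_mc']:.2f} +- {row['sem']:.2f}")
print()
print("Early lags are recovered almost perfectly and the profile decays with")
print("delay; the sum MC is largest at intermediate mu, where communities")
print("hold echoes of the input longer than either isolated or random wiring.")
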