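"""Optimal modularity for signal spreading.

Drives 50-community threshold reservoirs with a constant input injected
into a quarter of the neurons and compares the equilibrium activation of
strongly modular, optimally modular, and random topologies.
"""

from modular_esn import multi_community_experiment

R_SIG = 0.25
print(f"constant drive into r_sig = {R_SIG} of the network, 16 reservoirs per mu\n")
print("  mu    total activation   (sem)")
for mu in [0.02, 0.1, 0.2, 0.25, 0.3, 0.5]:
    s = multi_community_experiment(mu, R_SIG, n_samples=16, seed=1)
    print(f" {mu:4.2f}       {s.total_mean:5.3f}        ({s.total_sem:.3f})")
print()
print("At mu near 0 the scattered signal cannot be reinforced inside any")
print("single community; at mu = 0.5 there is global reach but no local")
print("cohesion. In between, communities consolidate the subthreshold input")
print("and the bridges spread it — total activation peaks at intermediate mu.")
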