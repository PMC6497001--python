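"""Cued recall of one-hot sequences and the attractor census.

Trains reservoirs to reproduce 200 one-hot 4x5 sequences after an 80-step
distractor, and counts the distinct states available at the cue time.
"""

from modular_esn import RecallConfig, attractor_census, train_and_evaluate_recall

print("200 sequences, distractor delay 80, one reservoir per mu\n")
print("  mu    fraction perfect   attractors (eps = 0.1)")
for mu in [0.0, 0.1, 0.45]:
    cfg = RecallConfig(mu=mu)
    r = train_and_evaluate_recall(cfg, seed=1)
    c = attractor_census(cfg, seed=1)
    print(f" {mu:4.2f}        {r.fraction_perfect:5.3f}             {c.n_attractors}")
print()
print("Random wiring (mu = 0.45) folds every sequence into one global")
print("attractor, so nothing can be recalled. Isolated communities (mu = 0)")
print("store many states but the readout separates them poorly. Near")
print("mu = 0.1 the reservoir keeps many distinguishable attractors and")
print("recall peaks.")
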