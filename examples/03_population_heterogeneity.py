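"""Induced differentiation of a variable cell population and its heterogeneity.

Samples a 200-cell population around the symmetric model (every parameter
jittered with CV = 0.05), equilibrates it to the naive state, and applies
primary/polarizing signal combinations.  The heterogeneity score S_H
summarizes each outcome: ~1 for an even two-phenotype split, ~-1 for a
single dominating phenotype.
"""

from tcellfate import (
    get_model,
    PopulationConfig,
    SignalProtocol,
    sample_population,
    equilibrate_naive,
    run_protocol,
    composition,
    heterogeneity_score,
)

net = get_model("generic1").network
cfg = PopulationConfig(n_cells=200, cv=0.05, seed=2026)

for signals, label in [
    ({"S1": 1.5}, "primary signal alone (mid-bistable)"),
    ({"S1": 1.5, "S2": 0.8}, "primary + strong polarizing"),
    ({"S1": 0.3}, "sub-threshold primary"),
]:
    pop = sample_population(net, cfg)
    equilibrate_naive(pop)
    run_protocol(pop, SignalProtocol.simultaneous(signals))
    comp = composition(pop.states, net)
    score = heterogeneity_score(comp, ("XSP", "YSP")).score
    print(f"{label}: {dict(comp.counts)}  S_H(XSP,YSP) = {score:+.3f}")

print(
    "\nOn the axis the naive cells sit near the separatrix, so parameter\n"
    "noise splits the population between the two single-positive fates\n"
    "(S_H near 1); a polarizing signal biases every cell the same way\n"
    "(S_H near -1); below threshold nobody differentiates (S_H = 0)."
)

# sequential stimulation: polarizing-then-primary matches simultaneous,
# while primary-then-weak-polarizing is blocked by hysteresis
pop = sample_population(net, cfg)
equilibrate_naive(pop)
run_protocol(pop, SignalProtocol.sequential({"S2": 0.8}, {"S1": 1.5, "S2": 0.8}))
print("\npolarizing then primary:", dict(composition(pop.states, net).counts))

pop = sample_population(net, cfg)
equilibrate_naive(pop)
run_protocol(pop, SignalProtocol.sequential({"S1": 1.5}, {"S1": 1.5, "S2": 0.2}))
print("primary then weak polarizing:", dict(composition(pop.states, net).counts))
print("(the late polarizing signal cannot reprogram committed cells)")
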