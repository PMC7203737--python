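"""Simulate HT-SELEX-like reads from a homodimer mixture and learn the
model back with the ZOOPS EM algorithm.

Run: python examples/03_learn_from_simulated_reads.py   (~1 minute)
"""

from admotif import (
    SimulationSpec,
    TrainingConfig,
    build_sanity_model,
    generate_reads,
    hoxb13_standin,
    model_distance,
    run_em,
    select_submodel,
)
from admotif.dimer import assemble_cob
from admotif.simulate import example_bridging_deviation

# Generating mixture: background 0.70 plus five homodimer cells of a
# HOXB13-like monomer, one of them with a hand-injected deviation.
gen = build_sanity_model(
    hoxb13_standin(),
    deviations={("HH", 2): example_bridging_deviation(4)},
)
reads, truth = generate_reads(SimulationSpec(gen, n=10_000, length=40, seed=42))
print(f"simulated {len(reads)} reads; "
      f"{(truth['component'] != 'background').mean():.1%} carry a motif")

config = TrainingConfig(pairs=[(0, 0)], rho=3, maxiter=30)
result = run_em(reads, ["CYMRTAAAA"], config)
model = result.model
print(f"EM finished after {result.n_iter} iterations "
      f"(converged={result.converged})")
print(f"weighted-max-norm distance to the generating model: "
      f"{model_distance(model, gen):.4f}")

cob = assemble_cob(model.lam_dimer, (0, 0), pruned=model.pruned,
                   dmin=model.pairs[(0, 0)][0], dmax=model.pairs[(0, 0)][1])
print("\nCOB table (integer multiples of 0.001; blank = pruned):")
print(cob.display_frame().to_string())

sub = select_submodel(model, 0.85)
kept = [s.label() for s in sub.dimer_specs()]
print(f"\n85% submodel keeps: {kept}")
# The surviving cells should be the five generating cells (HT 4, HH 4,
# HH 2, TT 2, HH 5) with weights close to the generating profile.
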