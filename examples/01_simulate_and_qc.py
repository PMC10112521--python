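"""Simulate a small screening campaign and inspect plate quality.

Builds a 12-chemical campaign (3 independent experiments, agonist +
antagonist modes with the post-hoc viability read), checks the plate-design
invariants, and prints each plate's robust Z'-factor.
"""

from arscreen import validate_experiment
from arscreen.plate_qc import median_plate_zprime, robust_zprime
from arscreen.synthetic_plates import SimConfig, sample_truths, simulate_experiment

cfg = SimConfig(n_test_chemicals=12, noise_cv=0.10, seed=1)
exp, truth = simulate_experiment(sample_truths(12, seed=1), cfg)

print(f"simulated {len(exp.wells)} wells on {len(exp.plates())} plates")
print(f"design violations: {validate_experiment(exp) or 'none'}")

qc = [robust_zprime(wells) for wells in exp.plates().values()]
for q in qc[:4]:
    print(f"  {q.plate_id}: rZ' = {q.rz_prime:.3f} "
          f"(pmed {q.pmed:.0f}, dmed {q.dmed:.0f})")
print(f"median plate rZ' = {median_plate_zprime(qc):.3f}")
# rZ' > 0.5 means the positive-control and vehicle signal distributions are
# separated well enough for single-well hit detection.
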