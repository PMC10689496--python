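"""Rank cognate-evolution models by nested-sampling marginal likelihood.

Simulates cognate data under the binary covarion with rate variation
across branches, then estimates log marginal likelihoods for competing
model/clock configurations and prints a Bayes-factor table (best model
first; log BF >= 5 counts as very strong support).
"""

from urheimat.cognates import add_ascertainment_columns
from urheimat.model_selection import build_comparison_table, nested_sampling
from urheimat.phylo import ClockModel, SubstitutionModel
from urheimat.phylo.priors import kartvelian_calibrations
from urheimat.simulate import (SimConfig, kartvelian_reference_tree,
                               simulate_cognate_matrix)

cfg = SimConfig(seed=101)
# strong-persistence regime: words are conservative or labile and rarely
# change regime, the setting where the covarion is identifiable at 5 taxa
cfg.cognates.covarion_alpha = 0.02
cfg.cognates.covarion_switch = 0.02
cfg.cognates.branch_rate_sigma = 0.5
matrix = add_ascertainment_columns(
    simulate_cognate_matrix(kartvelian_reference_tree(), cfg))
cal = kartvelian_calibrations()

results = []
for kind, clock in [("covarion", "ucln"), ("covarion", "strict"),
                    ("ctmc", "ucln"), ("sdollo", "ucln")]:
    res = nested_sampling(
        matrix, SubstitutionModel(kind=kind), ClockModel(kind=clock), cal,
        n_particles=12, subchain_length=30, seed=9, label=f"{kind}+{clock}")
    print(f"{res.label:18s} logML {res.log_marginal_likelihood:9.2f} "
          f"(sd {res.sd:.2f}, {res.n_iterations} iterations)")
    results.append(res)

table = build_comparison_table(results)
print("\n", table.to_string(index=False))
print("\nThe generating model (covarion) should rank above the CTMC and the")
print("stochastic Dollo; a log BF above 5 is very strong support.")
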