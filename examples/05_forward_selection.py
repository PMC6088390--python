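"""Discover an unlisted protein-protein affinity by forward selection.

Generates data whose ground truth contains one interaction beyond the
'literature' set, then lets the likelihood-ratio forward selection search
all candidate pairs: a candidate is accepted when adding its beta drops the
weighted RSS by more than chi2_0.95(1) = 3.841.
"""

import sphericell as sc

species = ["DAPI", "A", "B", "C"]
known_pair = (0, 1)
hidden_pair = (2, 3)

truth = sc.make_ground_truth(
    species, [known_pair, hidden_pair], seed=7, beta_range=(1.0, 2.0)
)
known = truth.params.interactions.without_pair(hidden_pair)
totals = sc.simulate_cell_totals(truth, 80, seed=8)
dataset = sc.simulate_roi_dataset(truth, totals, with_noise=True, seed=9)

candidates = sc.all_candidate_pairs(
    len(species), known, include_homodimers=False
)
trace = sc.forward_select(
    dataset, known, candidates, sc.SelectionConfig(n_starts=3, seed=10)
)

print(f"threshold: delta chi2 > {sc.CHI2_95_DF1:.3f}")
for k, step in enumerate(trace.steps, 1):
    verdict = "ACCEPTED" if step.accepted else "rejected (stop)"
    print(f"step {k}: best candidate {species[step.pair[0]]}-"
          f"{species[step.pair[1]]}, delta chi2 = {step.delta_chi2:.1f} "
          f"-> {verdict}")
print(f"\nhidden pair was {species[hidden_pair[0]]}-{species[hidden_pair[1]]}")

# Withdrawal (contribution) test on the known pair of the final model:
result = sc.contribution_test(dataset, trace.final_fit, known_pair)
print(f"withdrawing {species[known_pair[0]]}-{species[known_pair[1]]}: "
      f"delta chi2 = {result.delta_chi2:.1f}, "
      f"significant = {result.significant}")
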