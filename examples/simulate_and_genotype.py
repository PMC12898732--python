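"""Genotype a simulated 30-sample market cohort.

Simulates two species groups at their product Tm ranges (24 + 6 samples,
four of the second species sold under the first species' label), runs
the full melt-curve pipeline and reports calls, confidences, detected
mislabels and the inter-group delta-Tm.
"""

import barhrm as b
from barhrm.simulate import market_cohort_spec

curves, truth = b.simulate_cohort(market_cohort_spec(seed=101))
refs = {
    "PG": truth[truth.true_label == "PG"].sample_id[:3].tolist(),
    "PN": truth[truth.true_label == "PN"].sample_id[:3].tolist(),
}
analysis = b.analyze_cohort(curves, refs, reference_label="PG")

truth_map = dict(zip(truth.sample_id, truth.true_label))
declared = dict(zip(truth.sample_id, truth.declared_label))
summary = b.concordance(analysis.calls, truth_map, declared=declared)

group_peaks = {
    lab: [analysis.peaks[s][0] for s in truth[truth.true_label == lab].sample_id]
    for lab in ("PG", "PN")
}
dtm = b.delta_tm(group_peaks)[("PG", "PN")]

print(f"samples: {len(analysis.calls)}; agreement with truth: "
      f"{summary.percent_agreement}%")
print(f"inter-group delta-Tm (group means): {dtm:.2f} degC")
print(f"minimum call confidence: "
      f"{min(c.confidence for c in analysis.calls):.1f}")
print(f"mislabeled products (call != declared): {summary.mislabeled}")
print()
print("The four PN-generated samples sold as 'PG' melt with the PN group and")
print("are flagged as adulterated; confidence ~99 reflects tight clusters.")
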