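"""From annotation tables to biomarker screening, end to end.

Mock disease-variant and drug-target tables (in the style of morbid-SNP
and drug-target database extracts) are cross-referenced against the
model's GPR genes; matched conditions become knockout perturbations,
which are screened for exchange-flux signatures.
"""

from fluxsig import (
    SyntheticSpec,
    crossref,
    make_mock_annotations,
    make_random_network,
    perturbations_from_records,
    screen_all,
    summarize_by_category,
)

model, _ = make_random_network(
    SyntheticSpec(seed=21, n_pathways=5, pathway_length=2, n_isozyme_reactions=2)
)
records, planted = make_mock_annotations(
    model, n_snps=30, n_drugs=30, match_rate=0.6, seed=22
)

result = crossref(model, records)
print(f"matched {len(result.matched)}/{len(records)} records "
      f"(planted: {planted['matched_snps'] + planted['matched_drugs']})")

snps = [r for r in result.matched if r.source == "morbid_snp"]
print("\nmorbid-SNP contingency table (category x causality):")
print(summarize_by_category(snps, value="causality"))

conditions = perturbations_from_records(result.matched)
screen = screen_all(model, conditions, theta=0.40)
print(f"\nscreened {len(conditions)} matched conditions: "
      f"detection {screen.detection_fraction:.0%}, "
      f"mean signature size {screen.mean_signature_size:.1f}")
# Only records whose gene sits in a GPR can perturb the network; the
# planted and recovered match counts agree by construction.
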