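"""Triangulate an MR finding against mined literature triples.

Builds two synthetic literature spaces — one around an exposure, one around
a cancer — sharing four directed-chain mediators, then overlaps them. A
mediator is a term reached from the exposure (as triple object) that also
leads into the cancer (as triple subject), suggesting a causal pathway.
Spaces with more than 50 triples are considered viable for triangulation.
"""

from mrphewas import overlap, simulate_triples, viability

exposure_space, cancer_space = simulate_triples(
    n_exposure_triples=80, n_cancer_triples=60, n_shared_mediators=4, seed=13,
    exposure_term="igf-1", cancer_term="colorectal cancer",
)
print(f"exposure space: {exposure_space.size} triples "
      f"(viable: {viability(exposure_space)})")
print(f"cancer space:   {cancer_space.size} triples "
      f"(viable: {viability(cancer_space)})")

report = overlap(exposure_space, cancer_space)
print(f"\nmediators linking igf-1 -> colorectal cancer (joint viable={report.viable}):")
print(report.mediators.to_string(index=False))
print("\nSankey edge list (for plotting):")
print(report.sankey.head(4).to_string(index=False))
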