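"""Simulate a two-condition count matrix and titrate its sequencing depth.

Generates a small NB count matrix with known DE structure, thins it to 50%
and 10% of reads, and shows how the library sizes scale.  Binomial thinning
of a fixed count matrix is statistically equivalent to subsampling mapped
reads, so the thinned matrices emulate shallower sequencing runs of the
same libraries.
"""

from dgerobust import SimulationConfig, generate_dataset, thin_counts

cm, truth = generate_dataset(
    SimulationConfig(n_genes=500, n_samples_per_group=(6, 6), seed=1)
)
print(f"simulated {cm.n_genes} genes x {cm.n_samples} samples "
      f"({truth.table.is_de.sum()} truly DE)")
full_depth = cm.counts.sum(axis=0)
print(f"library sizes: min={full_depth.min()}, max={full_depth.max()}")

for f in (0.5, 0.1):
    thinned = thin_counts(cm, f, seed=7)
    ratio = thinned.counts.sum(axis=0) / full_depth
    print(f"f={f}: retained count fraction per library "
          f"{ratio.min():.4f}-{ratio.max():.4f} (expectation {f})")
# Each retained fraction hovers around f: every cell is Binomial(count, f),
# so column sums concentrate tightly around f times the original depth.
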