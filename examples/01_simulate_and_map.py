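"""Simulate a 5'-tag library and map it back in color space.

Builds a two-scaffold toy genome with 40 genes, draws a 50k-tag library for
time point t0, removes low-information reads, and maps everything against
the 60-N-spacer concatenated reference allowing up to 2 color mismatches.
"""

import fivedge as f
from fivedge.colorspace import filter_low_information
from fivedge.mapping import ColorIndex, map_reads
from fivedge.pipeline import _count_unique
from fivedge.qc import mapping_stats
from fivedge.reference import concatenate_reference

genome, models = f.make_toy_genome(n_scaffolds=2, n_genes=40, seed=1)
truth = f.assign_expression_profiles(models, seed=2)
params = f.LibraryParams(depth=50_000, color_error_rate=0.01)
reads, truth_hits = f.simulate_tags(genome, models, truth, params, "t0", seed=3)

kept, removed, report = filter_low_information(reads, threshold=3)
reference = concatenate_reference(genome.scaffolds)
hits = map_reads(kept, ColorIndex(reference, tag_length=25, max_mismatches=2))

stats = mapping_stats(len(reads), report.removed, hits.mapped_read_count,
                      _count_unique(hits))
print(f"simulated reads:        {stats['total_reads']}")
print(f"low-information removed:{stats['low_information_removed']:>7} "
      f"({stats['pct_low_information']:.2f}%)")
print(f"mapped (<=2 mismatches):{stats['mapped_reads']:>7} "
      f"({stats['pct_mapped']:.2f}% of mappable)")
print(f"uniquely mapped:        {stats['unique_reads']:>7} "
      f"({stats['pct_unique_of_mapped']:.2f}% of mapped)")
# Unmapped reads are the ones that accumulated 3+ color errors; on this
# repeat-free toy genome essentially every mapped read is unique.
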