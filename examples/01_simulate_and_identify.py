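"""Generate a synthetic two-breed dataset and identify its lncRNAs.

Builds a seeded dataset with planted positional categories, runs the
candidate filter cascade and the four-tool coding-potential intersection,
classifies the survivors against the annotation, and prints the category
census.  At zero coding-call noise the census equals the planted one.
"""

import tempfile

from lincqtl import io as lio
from lincqtl.identify import (
    classify_all,
    filter_candidates,
    intersect_coding_calls,
    summarize_categories,
)
from lincqtl.simulate import SimConfig, generate_dataset

config = SimConfig(
    seed=42,
    coding_tool_error_rates={t: (0.0, 0.0) for t in ("CPC", "CNCI", "CPAT", "Pfam")},
)
ds = generate_dataset(config, tempfile.mkdtemp())

transcripts, _ = lio.read_gtf(ds.paths["transcripts_gtf"])
_, genes = lio.read_gtf(ds.paths["annotation_gtf"])
expr, _ = lio.read_expression(ds.paths["expression"], ds.paths["samples"])

retained, tally = filter_candidates(transcripts, expr)
print(f"filter cascade: {len(retained)}/{len(transcripts)} retained; "
      f"rejections by rule {tally}")

callsets, missing = lio.read_coding_calls(ds.paths["coding_calls"])
candidate_ids, venn = intersect_coding_calls(callsets)
print(f"coding-potential intersection: {len(candidate_ids)} transcripts "
      f"noncoding by all four tools ({len(missing)} unclassifiable)")

records = classify_all(
    [t for t in retained if t.transcript_id in set(candidate_ids)], genes
)
summary = summarize_categories(records)
for cat, n in summary.counts.items():
    print(f"  {cat:10s} {n:4d}  ({summary.percentages[cat]:5.2f}%)")
recovered = sum(
    1 for r in records if r.category == ds.truth.categories[r.transcript.transcript_id]
)
print(f"planted categories recovered: {recovered}/{len(records)}")
# The percentages are the positional census of the identified lncRNA set;
# at zero noise every planted label is recovered.
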