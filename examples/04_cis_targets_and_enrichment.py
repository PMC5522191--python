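"""Predict cis target genes of DE lncRNAs and test term enrichment.

Runs the synthetic pipeline far enough to get DE lncRNAs, assigns each a
set of protein-coding genes within 100 kb, and tests the target-gene set
for over-representation of annotation terms with the hypergeometric
upper-tail test (BH-corrected).
"""

import tempfile

from lincqtl import io as lio
from lincqtl.diffexpr import differential_expression
from lincqtl.enrich import hypergeom_enrich
from lincqtl.simulate import SimConfig, generate_dataset
from lincqtl.targets import assign_cis_targets

ds = generate_dataset(SimConfig(seed=42), tempfile.mkdtemp())
expr, sheet = lio.read_expression(ds.paths["expression"], ds.paths["samples"])
_, genes = lio.read_gtf(ds.paths["annotation_gtf"])

lncs = [t for t in ds.transcripts if t.transcript_id.startswith("TCONS_")]
lnc_expr_ids = [t.transcript_id for t in lncs]
lnc_de = differential_expression(
    lio.read_expression(ds.paths["expression"], ds.paths["samples"])[0],
    dict(zip(sheet["sample_id"], sheet["group"])),
).loc[lnc_expr_ids]
de_lnc_ids = set(lnc_de.index[lnc_de["status"] != "ns"])
print(f"{len(de_lnc_ids)} of {len(lncs)} lncRNAs are DE")

pairs = assign_cis_targets(
    [t for t in lncs if t.transcript_id in de_lnc_ids], genes, window=100_000
)
target_genes = sorted({p.gene_id for p in pairs})
print(f"{len(pairs)} cis pairs within 100 kb -> {len(target_genes)} target genes")

term_map = lio.read_term_map(ds.paths["term_map"])
annotated = set().union(*(g for _, g in term_map.values()))
results = hypergeom_enrich(sorted(set(target_genes) & annotated), term_map)
print(f"{'term':>5} {'k/K':>7} {'p':>9} {'q':>9}  name")
for r in results[:5]:
    print(f"{r.term_id:>5} {r.k:>3}/{r.K:<3} {r.p_value:>9.3g} {r.q_value:>9.3g}  "
          f"{r.term_name}")
# k of the K genes annotated to each term fall in the target set; small p
# marks terms over-represented among cis targets of DE lncRNAs.
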