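"""Generate a study-sized synthetic paired cohort and inspect it.

The default cohort mirrors a colorectal mucosal-biopsy study design:
61 healthy controls plus 47 adenoma and 52 carcinoma lesion/adjacent
pairs (259 biopsies), drawn from a five-component Dirichlet
multinomial mixture over 100 phylotypes, with phenotype-specific
marker taxa planted at a known fold change.
"""

import numpy as np

from metacomm import default_paper_like_spec, generate_cohort, rarefy

spec = default_paper_like_spec(seed=0)
table, records, truth = generate_cohort(spec)
print(f"cohort: {table.n_samples} samples x {table.n_taxa} taxa")
print(f"median raw depth: {np.median(table.depths()):.0f} reads")

rarefied, dropped = rarefy(table, depth=1000, seed=0)
print(f"rarefied to 1000 reads: kept {rarefied.n_samples}, dropped {len(dropped)}")

counts = np.bincount(list(truth.component_labels.values()), minlength=spec.K)
print("true metacommunity sizes:", dict(enumerate(counts.tolist())))
print(f"{len(truth.markers)} planted markers, e.g.",
      truth.markers[0])
# The component sizes approximate the (uniform) mixture weights; the
# planted markers are the taxa the downstream marker screen should find.
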