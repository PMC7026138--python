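"""Harmonize two pipelines' FPKM tables and convert them to TPM.

Builds two small FPKM matrices whose gene universes only partly overlap
(and carry different Ensembl version suffixes), intersects them, and
rescales each sample to transcripts-per-million over the shared genes.
"""

import numpy as np
import pandas as pd

from rnaconcord import ExpressionMatrix, Unit, dataset_to_tpm, harmonize

rng = np.random.default_rng(0)
samples = [f"s{i}" for i in range(4)]

gdc = ExpressionMatrix(
    data=pd.DataFrame(rng.uniform(1, 50, (4, 4)),
                      index=["ENSG01.4", "ENSG02.4", "ENSG03.4", "ENSG04.4"],
                      columns=samples),
    unit=Unit.FPKM, source="GDC")
toil = ExpressionMatrix(
    data=pd.DataFrame(rng.uniform(1, 50, (4, 4)),
                      index=["ENSG02.11", "ENSG03.11", "ENSG04.11", "ENSG05.11"],
                      columns=samples),
    unit=Unit.FPKM, source="Toil")

ds = harmonize([gdc, toil])
print("shared genes:", list(ds.gene_ids))
print("drop report:", ds.drop_report)

tpm = dataset_to_tpm(ds)
for m in tpm.sources:
    print(f"{m.source}: TPM column sums =", m.values.sum(axis=0).round(3))
# Each column sums to 1e6: abundances are now fractions of a fixed total,
# so values are comparable across pipelines and samples.
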