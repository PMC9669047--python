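import pandas as pd
import pytest


@pytest.fixture
def toy_utr_annotation():
    """Two genes on chrS, one with a CDS overlapping the other's 3'UTR."""
    return pd.DataFrame(
        {
            "gene_id": ["geneA", "geneA", "geneB"],
            "chrom": ["chrS", "chrS", "chrS"],
            "start": [0, 100, 150],
            "end": [100, 200, 300],
            "strand": ["+", "+", "+"],
            "feature": ["CDS", "3UTR", "3UTR"],
        }
    )
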