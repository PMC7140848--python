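"""mirpipe: small-RNA-seq miRNA discovery and two-library differential expression.

A self-contained re-implementation of a plant small-RNA analysis workflow:
read cleaning and tag collapsing, genome mapping and annotation-based read
classification, hairpin minimum-free-energy folding with MFEI statistics,
Meyers-criteria novel-miRNA calling, the exact two-library count test with
Benjamini-Hochberg FDR, consensus miRNA target scanning, hypergeometric term
enrichment and 2^-ddCt qPCR concordance — together with a synthetic-study
generator that plants a machine-readable answer key through every stage.
"""

__version__ = "0.1.0"


def _load_submodules():  # imported lazily at the end of the file
    from . import (classify, diffexpr, discovery, downstream, pipeline,
                   preprocess, rnafold, simdata)
    return locals()


globals().update(_load_submodules())
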