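"""Small helpers shared between test modules."""

import numpy as np
import pandas as pd

from ailqtl.crossio import Cross, GeneticMap


def chain_cross(codes_by_ind, positions_cm):
    """A one-chromosome Cross built from raw observation codes."""
    n_mark = len(positions_cm)
    markers = [f"m{k}" for k in range(n_mark)]
    gmap = GeneticMap(pd.DataFrame(
        {"chrom": ["1"] * n_mark, "cm": positions_cm},
        index=pd.Index(markers, name="marker")))
    geno = pd.DataFrame(np.array(codes_by_ind, dtype=np.int8),
                        columns=markers,
                        index=pd.RangeIndex(len(codes_by_ind), name="id"))
    pheno = pd.DataFrame(index=geno.index)
    covar = pd.DataFrame({"sex": ["male"] * len(geno),
                          "batch": ["b1"] * len(geno)}, index=geno.index)
    return Cross(gmap, geno, pheno, covar)
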