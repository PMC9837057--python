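import numpy as np
import pandas as pd
import pytest

from sexstrat.io_sumstats import SumStatsTable


def make_table(rows, trait_id="trait", stratum="combined", trait_type="quantitative"):
    """Build a SumStatsTable from a list of row dicts with sensible defaults."""
    defaults = {"effect_allele": "A", "other_allele": "G", "beta": 0.0,
                "se": 0.1, "pval": 0.5, "maf": 0.3, "n": 1000, "chrom": "1"}
    filled = []
    for i, row in enumerate(rows):
        r = {**defaults, **row}
        r.setdefault("pos", 1000 + i)
        r.setdefault(
            "variant_id", f"{r['chrom']}:{r['pos']}:{r['effect_allele']}:{r['other_allele']}")
        filled.append(r)
    df = pd.DataFrame(filled)
    return SumStatsTable(trait_id=trait_id, stratum=stratum, df=df, trait_type=trait_type)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
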