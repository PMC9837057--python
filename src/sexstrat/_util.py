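"""Small shared helpers: chromosome label handling, seeded RNG streams, p-value clamps."""

from __future__ import annotations

import numpy as np

#: floor applied to p-values before they reach log-space consumers
P_FLOOR = 1e-300

# Fixed per-component offsets for deriving independent RNG streams from one
# master seed.  Keeping these stable makes every generator bit-reproducible.
STREAM_MAF = 0
STREAM_GENO_MALE = 1
STREAM_GENO_FEMALE = 2
STREAM_PHENO_MALE = 3
STREAM_PHENO_FEMALE = 4
STREAM_H2 = 5
STREAM_MR = 6
STREAM_COLOC = 7
STREAM_ENRICH = 8


def derived_rng(seed: int, offset: int) -> np.random.Generator:
    """Independent Generator for component ``offset`` of master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(offset),)))


def normalize_chrom(chrom) -> str:
    """Strip a leading 'chr' prefix and surrounding whitespace."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def chrom_sort_key(chrom: str):
    """Sort numeric chromosomes numerically, others lexicographically after."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


def clamp_pvals(p):
    """Clamp p-values into (P_FLOOR, 1]; guards downstream log operations."""
    return np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0)
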