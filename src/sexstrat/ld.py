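"""Pairwise r^2 from dosages, greedy tagging loci, and independent-SNP counts.

r^2 here is the squared Pearson correlation of dosage columns (composite LD),
which is what genotype-panel simulators and imputed dosage data provide.
Tagging follows the standard clumping convention: repeatedly take the most
significant unassigned variant as the index SNP and sweep every unassigned
variant correlated with it above the threshold into its locus, so variants
within a locus share r^2 >= threshold with their tag and tags are mutually
below it.  Counting "independent SNPs" in a region is the number of loci this
partition produces at r^2 = 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

TAG_THRESHOLD = 0.2       # tagging loci: members share r^2 >= 0.2 with the tag
INDEPENDENT_THRESHOLD = 0.8


@dataclass
class LdMatrix:
    """Symmetric r^2 matrix with unit diagonal over an ordered variant list."""

    keys: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.keys)
        if self.r2.shape != (m, m):
            raise ValueError("r2 shape does not match key count")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-8 or self.r2.max() > 1 + 1e-8:
            raise ValueError("r2 entries must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.keys)

    def subset(self, keys: Sequence[str]) -> "LdMatrix":
        idx = [self.keys.index(k) for k in keys]
        return LdMatrix(list(keys), self.r2[np.ix_(idx, idx)])


def ld_from_genotypes(panel) -> LdMatrix:
    """r^2 matrix of a GenotypePanel's dosage columns."""
    g = panel.dosages.astype(float)
    var = g.var(axis=0)
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        names = panel.keys["variant_id"].iloc[bad[:5]].tolist()
        raise ValueError(f"zero-variance variant(s): {names}")
    r = np.corrcoef(g, rowvar=False)
    r2 = np.clip(r * r, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    return LdMatrix(panel.keys["variant_id"].tolist(), r2)


def greedy_tag(
    ld: LdMatrix,
    priority: Sequence[float] | None = None,
    threshold: float = TAG_THRESHOLD,
    positions: Sequence[int] | None = None,
) -> dict[int, np.ndarray]:
    """Partition variants into tagging loci; returns {tag index: member indices}.

    The next tag is the unassigned variant with the smallest ``priority``
    (p-value), ties broken by genomic position then key; with no priority the
    input order serves as both.  Every variant lands in exactly one locus; a
    tag always contains itself even when the threshold exceeds 1.
    """
    m = len(ld)
    prio = np.arange(m, dtype=float) if priority is None else np.asarray(priority, dtype=float)
    if prio.shape[0] != m:
        raise ValueError("priority length does not match matrix")
    pos = np.arange(m) if positions is None else np.asarray(positions)
    order = sorted(range(m), key=lambda i: (prio[i], pos[i], ld.keys[i]))

    unassigned = np.ones(m, dtype=bool)
    loci: dict[int, np.ndarray] = {}
    for tag in order:
        if not unassigned[tag]:
            continue
        members = np.flatnonzero(unassigned & (ld.r2[tag] >= threshold))
        members = np.union1d(members, [tag])
        unassigned[members] = False
        loci[tag] = members
    return loci


def count_independent(
    ld: LdMatrix,
    threshold: float = INDEPENDENT_THRESHOLD,
    priority: Sequence[float] | None = None,
    positions: Sequence[int] | None = None,
) -> int:
    """Number of tagging loci at ``threshold`` (default r^2 = 0.8)."""
    return len(greedy_tag(ld, priority=priority, threshold=threshold, positions=positions))


def write_ld_matrix(ld: LdMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=ld.keys, columns=ld.keys).to_csv(
        path, sep="\t", float_format="%.17g")


def read_ld_matrix(path) -> LdMatrix:
    """Load a TSV LD matrix; strict symmetry/diagonal check (tol 1e-8)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("row and column keys differ")
    return LdMatrix([str(k) for k in df.index], df.to_numpy(dtype=float))
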