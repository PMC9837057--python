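"""Sex-difference tests, FDR control, SDE calling and sex-aware eQTL classification.

Core statistics
---------------
For any per-sex estimate pair (heritability, GWAS beta, eQTL beta) with
standard errors, the sex difference is tested with

    z = (stat_female - stat_male) / sqrt(se_female^2 + se_male^2)

against the standard normal (two-sided).  Departure of a male-female genetic
correlation from 1 is tested with ``t = (rg - 1) / se_rg``, also referred to
the standard normal by default (a Wald test on a summary-level estimate; a
t reference with explicit df is available via ``df``).

A variant is called a sex-differentiated effect (SDE) when its z-test survives
BH-FDR < 0.05 across the trait's variants AND it is genome-wide significant
(p < 5e-8) in at least one sex.

eQTL scans use a 2-step correction: within each gene, Bonferroni over the
number of LD-independent SNPs applied to the minimum SNP p-value; across
genes, BH-FDR on the resulting gene-level p-values.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._util import P_FLOOR, clamp_pvals
from .io_sumstats import PairedSumStats
from .ld import LdMatrix, count_independent

logger = logging.getLogger(__name__)

SDE_FDR_ALPHA = 0.05
GWAS_ALPHA = 5e-8
EQTL_FDR_ALPHA = 0.1


def sex_difference_z(stat_f, se_f, stat_m, se_m):
    """Female-minus-male z and two-sided normal p; vectorized.

    Antisymmetric under sex swap; the p-value is swap-invariant.
    """
    stat_f, se_f = np.asarray(stat_f, float), np.asarray(se_f, float)
    stat_m, se_m = np.asarray(stat_m, float), np.asarray(se_m, float)
    if np.any(se_f <= 0) or np.any(se_m <= 0):
        raise ValueError("standard errors must be positive")
    z = (stat_f - stat_m) / np.sqrt(se_f**2 + se_m**2)
    p = clamp_pvals(2.0 * sps.norm.sf(np.abs(z)))
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def rg_vs_one_t(rg, se_rg, df: int | None = None):
    """Test a male-female genetic correlation against 1.

    ``t = (rg - 1) / se_rg``; two-sided p from the standard normal, or from
    a t reference when ``df`` is given.
    """
    rg, se_rg = np.asarray(rg, float), np.asarray(se_rg, float)
    if np.any(se_rg <= 0):
        raise ValueError("standard errors must be positive")
    t = (rg - 1.0) / se_rg
    sf = sps.t.sf(np.abs(t), df) if df is not None else sps.norm.sf(np.abs(t))
    p = clamp_pvals(2.0 * sf)
    if t.ndim == 0:
        return float(t), float(p)
    return t, p


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_sdes(
    paired: PairedSumStats,
    fdr_alpha: float = SDE_FDR_ALPHA,
    gwas_alpha: float = GWAS_ALPHA,
) -> pd.DataFrame:
    """Per-variant sex-difference test plus the SDE decision.

    FDR is controlled within the trait across all supplied (region-mapped)
    variants.  ``is_sde`` requires q < ``fdr_alpha`` and per-sex GWAS
    significance (min of the two sex p-values below ``gwas_alpha``).
    """
    df = paired.df
    out = df[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    if len(df) == 0:
        for col in ("beta_m", "beta_f", "z", "pval", "qval", "p_male", "p_female"):
            out[col] = pd.Series(dtype=float)
        out["is_sde"] = pd.Series(dtype=bool)
        return out
    z, p = sex_difference_z(df["beta_f"], df["se_f"], df["beta_m"], df["se_m"])
    q = bh_fdr(p)
    out["beta_m"] = df["beta_m"].to_numpy()
    out["beta_f"] = df["beta_f"].to_numpy()
    out["z"] = z
    out["pval"] = p
    out["qval"] = q
    out["p_male"] = df["pval_m"].to_numpy()
    out["p_female"] = df["pval_f"].to_numpy()
    out["is_sde"] = (q < fdr_alpha) & (np.minimum(out["p_male"], out["p_female"]) < gwas_alpha)
    return out


def call_sdes_global(
    paired_by_trait: Mapping[str, PairedSumStats],
    fdr_alpha: float = SDE_FDR_ALPHA,
    gwas_alpha: float = GWAS_ALPHA,
) -> pd.DataFrame:
    """SDE calling with one FDR pooled across all traits' variants.

    Alternative FDR scope to the default per-trait control of
    :func:`call_sdes`; returns the concatenated per-trait frames with an
    extra ``trait_id`` column and q-values recomputed over the pooled tests.
    """
    frames = []
    for trait_id, paired in paired_by_trait.items():
        frame = call_sdes(paired, fdr_alpha=fdr_alpha, gwas_alpha=gwas_alpha)
        frame.insert(0, "trait_id", trait_id)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    if len(out):
        out["qval"] = bh_fdr(out["pval"].to_numpy())
        out["is_sde"] = (out["qval"] < fdr_alpha) & (
            np.minimum(out["p_male"], out["p_female"]) < gwas_alpha)
    return out


def two_step_correction(
    per_gene: Mapping[str, tuple],
) -> pd.DataFrame:
    """Gene-level q-values from SNP p-values: Bonferroni-by-M then BH across genes.

    ``per_gene`` maps gene -> (snp_pvals, m_independent[, positions]).  For
    each gene ``p_gene = min(1, M * min(p))`` with the lead SNP the argmin
    (position breaks ties).  Returns a frame indexed by gene with columns
    ``m_indep, p_gene, q_gene, lead`` (lead is the index into the gene's SNP
    vector).  Genes with no SNPs are skipped with a log entry.
    """
    rows = []
    skipped = 0
    for gene, spec in per_gene.items():
        pvals = np.asarray(spec[0], dtype=float)
        m_indep = int(spec[1])
        positions = np.asarray(spec[2]) if len(spec) > 2 else np.arange(pvals.size)
        if pvals.size == 0:
            skipped += 1
            continue
        if m_indep < 1:
            raise ValueError(f"gene {gene}: independent SNP count must be >= 1")
        best = min(range(pvals.size), key=lambda i: (pvals[i], positions[i]))
        p_gene = min(1.0, m_indep * float(pvals[best]))
        rows.append((gene, m_indep, max(p_gene, P_FLOOR), best))
    if skipped:
        logger.warning("two_step_correction: skipped %d empty genes", skipped)
    frame = pd.DataFrame(rows, columns=["gene", "m_indep", "p_gene", "lead"]).set_index("gene")
    frame["q_gene"] = bh_fdr(frame["p_gene"].to_numpy()) if len(frame) else pd.Series(dtype=float)
    return frame[["m_indep", "p_gene", "q_gene", "lead"]]


def classify_eqtls(
    male: Mapping[str, pd.DataFrame],
    female: Mapping[str, pd.DataFrame],
    ld: Mapping[str, LdMatrix],
    fdr: float = EQTL_FDR_ALPHA,
) -> pd.DataFrame:
    """Sex-differentiated / sex-specific classification of gene-level eQTLs.

    ``male`` and ``female`` map gene -> per-SNP frame (index = variant ids,
    columns ``beta, se, pval`` and optional ``pos``) over the same gene set;
    ``ld`` maps gene -> LdMatrix covering the shared variants.

    Per sex, gene-level q-values come from the 2-step correction with M =
    independent SNPs at r^2 < 0.8.  Per gene, the overall lead variant (the
    one with the smallest of the two sex p-values) is z-tested for effect
    heterogeneity and BH-corrected across genes; ``sex_differentiated`` means
    that q < ``fdr``.  ``male_specific`` / ``female_specific`` mean q < fdr in
    exactly that sex and q > fdr in the other.  A gene meeting both rules is
    labeled sex_differentiated (effect heterogeneity is the stronger claim);
    both raw flags are retained.
    """
    if set(male) != set(female):
        raise ValueError("male and female inputs must cover the same genes")
    genes = sorted(male)

    per_gene_m, per_gene_f, aligned = {}, {}, {}
    for gene in genes:
        dm, df_ = male[gene], female[gene]
        shared = dm.index.intersection(df_.index)
        if len(shared) == 0:
            raise ValueError(f"gene {gene}: no shared variants between sexes")
        dm, df_ = dm.loc[shared], df_.loc[shared]
        aligned[gene] = (dm, df_)
        m_indep = count_independent(ld[gene].subset(list(shared))) if gene in ld else len(shared)
        pos = dm["pos"].to_numpy() if "pos" in dm.columns else np.arange(len(shared))
        per_gene_m[gene] = (dm["pval"].to_numpy(), m_indep, pos)
        per_gene_f[gene] = (df_["pval"].to_numpy(), m_indep, pos)

    gm = two_step_correction(per_gene_m)
    gf = two_step_correction(per_gene_f)

    rows = []
    for gene in genes:
        dm, df_ = aligned[gene]
        combined_min = np.minimum(dm["pval"].to_numpy(), df_["pval"].to_numpy())
        lead_i = int(np.argmin(combined_min))
        lead = dm.index[lead_i]
        z, p_diff = sex_difference_z(
            df_["beta"].iloc[lead_i], df_["se"].iloc[lead_i],
            dm["beta"].iloc[lead_i], dm["se"].iloc[lead_i])
        rows.append({
            "gene": gene, "lead_variant": lead,
            "beta_m": dm["beta"].iloc[lead_i], "se_m": dm["se"].iloc[lead_i],
            "pval_m": dm["pval"].iloc[lead_i],
            "beta_f": df_["beta"].iloc[lead_i], "se_f": df_["se"].iloc[lead_i],
            "pval_f": df_["pval"].iloc[lead_i],
            "q_m": gm.loc[gene, "q_gene"], "q_f": gf.loc[gene, "q_gene"],
            "z_diff": z, "p_diff": p_diff,
        })
    out = pd.DataFrame(rows).set_index("gene")
    out["q_diff"] = bh_fdr(out["p_diff"].to_numpy())
    out["sex_differentiated"] = out["q_diff"] < fdr
    out["male_specific"] = (out["q_m"] < fdr) & (out["q_f"] > fdr)
    out["female_specific"] = (out["q_f"] < fdr) & (out["q_m"] > fdr)

    def _label(row):
        if row["sex_differentiated"]:
            return "sex_differentiated"
        if row["male_specific"]:
            return "male_specific"
        if row["female_specific"]:
            return "female_specific"
        if row["q_m"] < fdr and row["q_f"] < fdr:
            return "shared"
        return "none"

    out["label"] = out.apply(_label, axis=1)
    return out
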