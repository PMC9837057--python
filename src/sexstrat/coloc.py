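"""Approximate-Bayes-factor colocalization of two summary-statistics sets.

Given per-SNP effect estimates for two traits (here: the two sexes, or a GWAS
trait and a sex-stratified eQTL) over one locus, the single-causal-variant
model assigns posterior probabilities to five hypotheses:

    H0 no association in either trait
    H1 association in trait 1 only      (sex pairing: male only)
    H2 association in trait 2 only      (sex pairing: female only)
    H3 both associated, different causal variants
    H4 both associated, one shared causal variant

Evidence per SNP is the Wakefield asymptotic Bayes factor.  With V = se^2,
W = prior effect variance, r = W/(V+W) and z = beta/se,

    log ABF = 0.5 * (log(1 - r) + r * z^2).

The prior effect SD is 0.2 on the log-odds scale for case-control traits; for
quantitative traits it is 0.15 * sdY with sdY estimated from MAF, N and SE
(sdY^2 ~= median over SNPs of se^2 * 2 * maf * (1 - maf) * n), since trait
units are rarely shipped with summary files.  An explicit sdY override exists.

All hypothesis arithmetic is in log space; the H3 sum over distinct causal
pairs uses the stable product-minus-diagonal identity, clamped to PPH3 = 0
with a diagnostic when rounding makes the log-difference argument nonpositive
(always the case for single-variant loci).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

from .io_sumstats import SumStatsTable, VariantKey

logger = logging.getLogger(__name__)

BINARY_PRIOR_SD = 0.2
QUANT_PRIOR_SD_FACTOR = 0.15
COLOC_WINDOW = 200_000
SEX_SPECIFIC_PPH4 = 0.5

HYPOTHESES = ("pph0", "pph1", "pph2", "pph3", "pph4")


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of causality (trait 1 only / 2 only / both)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self):
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ValueError("require 0 < p12 <= p1, p2 < 1")

    def check_locus(self, m: int) -> None:
        if m * (self.p1 + self.p2 + self.p12) >= 1:
            logger.warning("priors sum to >= 1 over %d snps; posteriors may be distorted", m)


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities plus per-SNP evidence for one locus."""

    pph: np.ndarray                 # PPH0..PPH4, sums to 1
    labf_a: np.ndarray
    labf_b: np.ndarray
    snp_h4_weights: np.ndarray      # per-SNP posterior weight under H4
    variant_ids: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def __getattr__(self, name):
        if name in HYPOTHESES:
            return float(self.pph[HYPOTHESES.index(name)])
        raise AttributeError(name)

    def as_dict(self) -> dict:
        return {h: float(v) for h, v in zip(HYPOTHESES, self.pph)}


def log_abf(beta, se, prior_sd) -> np.ndarray | float:
    """Wakefield log asymptotic Bayes factor; prior_sd = 0 gives 0 (no evidence)."""
    beta, se = np.asarray(beta, float), np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd < 0:
        raise ValueError("prior_sd must be nonnegative")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z * z)
    return float(out) if out.ndim == 0 else out


def estimate_sdy(se, maf, n) -> float:
    """Phenotype SD from summary fields: sdY^2 ~= median(se^2 * 2 maf (1-maf) n)."""
    se, maf, n = (np.asarray(x, float) for x in (se, maf, n))
    var_terms = se**2 * 2.0 * maf * (1.0 - maf) * n
    est = float(np.median(var_terms))
    if not np.isfinite(est) or est <= 0:
        raise ValueError("cannot estimate sdY from these summary statistics; "
                         "pass an explicit sdY")
    return float(np.sqrt(est))


def effective_prior_sd(table: SumStatsTable, sdy: float | None = None) -> float:
    """Prior effect SD for one trait: 0.2 (binary) or 0.15 * sdY (quantitative)."""
    if table.trait_type == "binary":
        return BINARY_PRIOR_SD
    if sdy is None:
        sdy = estimate_sdy(table.df["se"], table.df["maf"], table.df["n"])
    return QUANT_PRIOR_SD_FACTOR * sdy


def rescale_linear_prob_betas(table: SumStatsTable) -> SumStatsTable:
    """Convert linear-probability-scale case-control betas to log-odds scale.

    Some biobank pipelines fit linear models to 0/1 outcomes; their betas are
    on the linear-probability scale while the binary prior SD (0.2) assumes
    log-odds.  Dividing beta and SE by k(1-k), with k the case fraction,
    applies the standard first-order conversion.  Off by default — apply
    explicitly before colocalization when the source is a linear-model
    case-control scan.
    """
    if table.trait_type != "binary":
        raise ValueError("rescaling applies to case-control tables only")
    d = table.df.copy()
    k = d["n_cases"].astype(float) / d["n"].astype(float)
    factor = k * (1.0 - k)
    d["beta"] = d["beta"] / factor
    d["se"] = d["se"] / factor
    return SumStatsTable(table.trait_id, table.stratum, d, trait_type="binary")


def coloc_abf(
    stats_a: SumStatsTable,
    stats_b: SumStatsTable,
    priors: ColocPriors | None = None,
    prior_sd_a: float | None = None,
    prior_sd_b: float | None = None,
    sdy_a: float | None = None,
    sdy_b: float | None = None,
) -> ColocResult:
    """Colocalize two harmonized tables over the same locus.

    The tables must contain exactly the same variants in the same order
    (use ``io_sumstats.align_pair`` upstream).  ``prior_sd_*`` overrides the
    per-trait prior effect SD; otherwise it is derived by
    :func:`effective_prior_sd` (optionally from an explicit ``sdy_*``).
    """
    priors = priors or ColocPriors()
    ids_a, ids_b = stats_a.variant_ids.tolist(), stats_b.variant_ids.tolist()
    if ids_a != ids_b:
        raise ValueError("coloc_abf requires identical variant sets in identical order")
    m = len(ids_a)
    if m < 1:
        raise ValueError("empty locus")
    priors.check_locus(m)

    sd_a = prior_sd_a if prior_sd_a is not None else effective_prior_sd(stats_a, sdy=sdy_a)
    sd_b = prior_sd_b if prior_sd_b is not None else effective_prior_sd(stats_b, sdy=sdy_b)
    la = np.asarray(log_abf(stats_a.df["beta"], stats_a.df["se"], sd_a), float).reshape(m)
    lb = np.asarray(log_abf(stats_b.df["beta"], stats_b.df["se"], sd_b), float).reshape(m)

    sa = logsumexp(la)
    sb = logsumexp(lb)
    sab = logsumexp(la + lb)

    l0 = 0.0
    l1 = np.log(priors.p1) + sa
    l2 = np.log(priors.p2) + sb
    l4 = np.log(priors.p12) + sab

    diagnostics = {"prior_sd_a": sd_a, "prior_sd_b": sd_b, "h3_clamped": False}
    # sum over j != k of ABF_a[j] * ABF_b[k] = exp(sa) * exp(sb) - exp(sab)
    diff = sab - (sa + sb)
    if m == 1 or diff >= 0:
        l3 = -np.inf
        diagnostics["h3_clamped"] = m > 1
    else:
        l3 = np.log(priors.p1) + np.log(priors.p2) + sa + sb + np.log1p(-np.exp(diff))

    pph = softmax(np.array([l0, l1, l2, l3, l4]))
    h4_weights = softmax(la + lb)
    return ColocResult(pph=pph, labf_a=la, labf_b=lb, snp_h4_weights=h4_weights,
                       variant_ids=ids_a, diagnostics=diagnostics)


def sex_stratified_gwas_coloc(
    male: SumStatsTable,
    female: SumStatsTable,
    tag: VariantKey | str,
    window: int = COLOC_WINDOW,
    priors: ColocPriors | None = None,
    **prior_kwargs,
) -> ColocResult:
    """Colocalize the two sexes of one trait around a tagging variant.

    Both tables are restricted to ``[tag.pos - window, tag.pos + window]``,
    intersected and harmonized, then passed to :func:`coloc_abf` with trait 1
    = male and trait 2 = female; PPH1 therefore reads "male-only association"
    and PPH2 "female-only".
    """
    from .io_sumstats import align_pair

    if isinstance(tag, str):
        tag = VariantKey.from_string(tag)

    def _window(table):
        d = table.df
        mask = (d["chrom"] == tag.chrom) & (d["pos"] >= tag.pos - window) \
            & (d["pos"] <= tag.pos + window)
        return SumStatsTable(table.trait_id, table.stratum, d[mask].reset_index(drop=True),
                             trait_type=table.trait_type)

    m_w, f_w = _window(male), _window(female)
    for t in (m_w, f_w):
        if not ((t.df["chrom"] == tag.chrom) & (t.df["pos"] == tag.pos)).any():
            raise ValueError(f"tag {tag} absent from the {t.stratum} table")

    paired = align_pair(m_w, f_w)
    if len(paired) < 1:
        raise ValueError("no harmonized variants in the window")
    base = paired.df[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]]

    def _side(suffix, src):
        d = base.copy()
        for col in ("beta", "se", "pval", "maf", "n"):
            d[col] = paired.df[f"{col}_{suffix}"].to_numpy()
        return SumStatsTable(src.trait_id, src.stratum, d, trait_type=src.trait_type)

    return coloc_abf(_side("m", male), _side("f", female), priors=priors, **prior_kwargs)


def classify_sex_specific_coloc(
    result_male: ColocResult,
    result_female: ColocResult,
    threshold: float = SEX_SPECIFIC_PPH4,
) -> str:
    """Apply the single-sex PPH4 rule: > threshold in one sex, <= in the other."""
    m_hit = result_male.pph4 > threshold
    f_hit = result_female.pph4 > threshold
    if m_hit and not f_hit:
        return "male_specific"
    if f_hit and not m_hit:
        return "female_specific"
    if m_hit and f_hit:
        return "both"
    return "neither"
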