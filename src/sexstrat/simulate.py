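"""Synthetic genotype, phenotype and summary-statistics generators.

These generators stand in for biobank-scale GWAS and tissue eQTL inputs so
that every downstream stage (sex-difference tests, colocalization, MR,
enrichment) can be exercised end to end without any external data.

Model
-----
Genotypes: each individual carries two haplotypes; each haplotype is a
thresholded latent Gaussian with AR(1) correlation ``ld_rho`` between adjacent
variants inside an LD block (blocks are mutually independent).  Thresholds are
the per-variant MAF quantiles, so allele frequencies and a monotone LD-decay
pattern are reproduced with a single parameter.

Phenotypes: ``y = sum_j beta_sex[j] * g_j + eps`` with Gaussian residuals; for
binary traits the same linear predictor is a liability thresholded at the
requested prevalence, and reported summary betas come from per-variant
logistic fits (log-odds scale).

Associations: per-variant ordinary least squares with an intercept and an
optional explicit covariate matrix (surrogate-variable machinery is replaced
by explicit covariates); two-sided p-values from the t reference with
``n - k - 2`` degrees of freedom for ``k`` covariates.

All generators are pure functions of (config, master seed); per-component RNG
streams are derived at fixed offsets (see ``sexstrat._util``), so outputs are
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _util
from ._util import P_FLOOR, derived_rng
from .io_sumstats import SumStatsTable

logger = logging.getLogger(__name__)

#: non-palindromic allele pairs assigned to simulated variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class SimConfig:
    """Study conditions for one simulated locus or region.

    Defaults describe a generic well-powered biobank locus: 1,000 individuals
    per sex, 100 variants in blocks of 10 with moderate LD, unit residual SD.
    Scenario helpers override sizes explicitly.
    """

    n_male: int = 1000
    n_female: int = 1000
    m: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.6
    block_size: int = 10
    causal_spec: list[tuple[int, float, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    trait_type: str = "quantitative"
    prevalence: float | None = None
    seed: int = 0
    equalize_n: bool = False  # down-sample the larger sex (eQTL parity)
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 5_000

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        for idx, _, _ in self.causal_spec:
            if not (0 <= idx < self.m):
                raise ValueError(f"causal index {idx} out of range for m={self.m}")
        if self.trait_type == "binary" and self.prevalence is None:
            raise ValueError("binary traits require a prevalence")


@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x variants, entries 0/1/2) with variant keys."""

    dosages: np.ndarray
    keys: pd.DataFrame  # variant_id, chrom, pos, effect_allele, other_allele
    maf: np.ndarray     # realized minor allele frequency per variant

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]


@dataclass
class TruthTable:
    """Planted ground truth attached to a simulated scenario."""

    beta_male: np.ndarray | None = None
    beta_female: np.ndarray | None = None
    h2_male: float | None = None
    h2_female: float | None = None
    theta: float | None = None           # MR causal effect
    alpha: np.ndarray | None = None      # MR per-instrument pleiotropy
    gamma: np.ndarray | None = None      # MR true instrument effects
    causal_index_a: int | None = None
    causal_index_b: int | None = None
    mode: str | None = None


def _variant_keys(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=config.m)
    pos = config.pos_start + config.pos_step * np.arange(config.m)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    vid = [f"{config.chrom}:{p}:{a}:{b}" for p, a, b in zip(pos, ea, oa)]
    return pd.DataFrame({
        "variant_id": vid, "chrom": config.chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa,
    })


def _target_mafs(config: SimConfig) -> np.ndarray:
    rng = derived_rng(config.seed, _util.STREAM_MAF)
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.m)


def _latent_block_ar1(rng, n: int, m: int, rho: float, block_size: int) -> np.ndarray:
    """Latent Gaussian with AR(1) correlation within blocks, iid across blocks."""
    x = rng.standard_normal((n, m))
    if rho == 0:
        return x
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        if j % block_size != 0:  # block boundary resets the chain
            x[:, j] = rho * x[:, j - 1] + scale * x[:, j]
    return x


def simulate_genotypes(config: SimConfig, stream: int = _util.STREAM_GENO_MALE) -> GenotypePanel:
    """Draw a dosage panel for ``n_male`` individuals (use ``stream`` to vary sex).

    Two independent latent haplotype draws per individual are thresholded at
    the per-variant MAF quantile and summed, giving Hardy-Weinberg dosages
    with block-AR(1) LD.
    """
    mafs = _target_mafs(config)
    keys = _variant_keys(config, derived_rng(config.seed, _util.STREAM_MAF + 100))
    rng = derived_rng(config.seed, stream)
    n = config.n_male
    cut = sps.norm.ppf(1.0 - mafs)  # P(latent > cut) = maf
    hap1 = _latent_block_ar1(rng, n, config.m, config.ld_rho, config.block_size) > cut
    hap2 = _latent_block_ar1(rng, n, config.m, config.ld_rho, config.block_size) > cut
    dosages = (hap1.astype(np.int8) + hap2.astype(np.int8))
    freq = dosages.mean(axis=0) / 2.0
    realized = np.minimum(freq, 1.0 - freq)
    return GenotypePanel(dosages=dosages, keys=keys, maf=realized)


def marginal_association(
    y: np.ndarray,
    panel: GenotypePanel,
    covariates: np.ndarray | None = None,
    trait_id: str = "sim_trait",
    stratum: str = "combined",
) -> SumStatsTable:
    """Single-variant linear model ``Y ~ b0 + bG * genotype + covariates``.

    Each variant is fit marginally by OLS after projecting out the intercept
    and covariates; SE and two-sided p come from the t reference with
    ``n - k - 2`` df.  Zero-variance variants are excluded and counted in the
    log.  Perfect fits clamp SE and p at the floating floor rather than zero.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n != panel.n:
        raise ValueError("phenotype length does not match panel")
    g = panel.dosages.astype(float)

    k = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    design = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.atleast_2d(covariates)]
    )
    q, _ = np.linalg.qr(design)
    y_r = y - q @ (q.T @ y)
    g_r = g - q @ (q.T @ g)

    gg = np.einsum("ij,ij->j", g_r, g_r)
    keep = gg > 1e-12
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("marginal_association: excluded %d zero-variance variants", n_excluded)

    df_resid = n - k - 2
    if df_resid < 1:
        raise ValueError("not enough observations for the requested covariates")

    gy = g_r.T @ y_r
    beta = np.full(panel.m, np.nan)
    beta[keep] = gy[keep] / gg[keep]
    yy = float(y_r @ y_r)
    rss = np.maximum(yy - beta**2 * gg, 0.0)
    sigma2 = rss / df_resid
    se = np.sqrt(np.maximum(sigma2 / np.where(keep, gg, np.nan), 0.0))
    se = np.maximum(se, P_FLOOR)  # perfect-fit limit
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pval = np.clip(2.0 * sps.t.sf(np.abs(tstat), df_resid), P_FLOOR, 1.0)

    out = panel.keys.copy()
    out["beta"] = beta
    out["se"] = se
    out["pval"] = pval
    out["maf"] = np.maximum(panel.maf, 1e-12)
    out["n"] = n
    out = out[keep].reset_index(drop=True)
    return SumStatsTable(trait_id=trait_id, stratum=stratum, df=out)


def _true_betas(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    bm = np.zeros(config.m)
    bf = np.zeros(config.m)
    for idx, b_m, b_f in config.causal_spec:
        bm[idx] = b_m
        bf[idx] = b_f
    return bm, bf


def _logistic_fit(y: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Per-variant logistic regression (intercept + genotype) via IRLS."""
    import statsmodels.api as sm

    x = sm.add_constant(g.astype(float))
    res = sm.Logit(y, x).fit(disp=0, maxiter=100)
    return float(res.params[1]), float(res.bse[1])


def _simulate_one_sex(
    config: SimConfig, n: int, betas: np.ndarray, geno_stream: int, pheno_stream: int,
    trait_id: str, stratum: str,
) -> tuple[SumStatsTable, GenotypePanel]:
    cfg = replace(config, n_male=n)
    panel = simulate_genotypes(cfg, stream=geno_stream)
    rng = derived_rng(config.seed, pheno_stream)
    liability = panel.dosages.astype(float) @ betas + rng.normal(0, config.noise_sd, size=n)
    if config.trait_type == "quantitative":
        return marginal_association(liability, panel, trait_id=trait_id, stratum=stratum), panel

    # liability threshold at the empirical prevalence quantile
    cut = np.quantile(liability, 1.0 - config.prevalence)
    y = (liability > cut).astype(float)
    n_cases = int(y.sum())
    if n_cases < 10:
        raise ValueError(f"binary trait yields only {n_cases} cases (< 10)")
    rows = []
    for j in range(panel.m):
        g = panel.dosages[:, j].astype(float)
        if g.var() <= 0:
            continue
        try:
            beta, se = _logistic_fit(y, g)
        except Exception:  # separation etc.
            continue
        z = beta / se if se > 0 else np.inf
        pval = float(np.clip(2.0 * sps.norm.sf(abs(z)), P_FLOOR, 1.0))
        rows.append((j, beta, max(se, P_FLOOR), pval))
    idx = [r[0] for r in rows]
    out = panel.keys.iloc[idx].reset_index(drop=True)
    out["beta"] = [r[1] for r in rows]
    out["se"] = [r[2] for r in rows]
    out["pval"] = [r[3] for r in rows]
    out["maf"] = np.maximum(panel.maf[idx], 1e-12)
    out["n"] = n
    out["n_cases"] = n_cases
    table = SumStatsTable(trait_id=trait_id, stratum=stratum, df=out, trait_type="binary")
    return table, panel


def simulate_sex_stratified_gwas(
    config: SimConfig, trait_id: str = "sim_trait"
) -> tuple[SumStatsTable, SumStatsTable, TruthTable]:
    """Simulate male and female GWAS over a shared variant set.

    Both sexes share keys, target MAFs and LD structure but have independent
    genotype panels and residuals; per-sex causal effects come from
    ``config.causal_spec``.  With ``equalize_n`` the larger sex is down-sampled
    to the smaller one's size (sample-size parity as used for eQTL scans).
    """
    bm, bf = _true_betas(config)
    n_m, n_f = config.n_male, config.n_female
    if config.equalize_n:
        n_m = n_f = min(n_m, n_f)
    male, panel_m = _simulate_one_sex(
        config, n_m, bm, _util.STREAM_GENO_MALE, _util.STREAM_PHENO_MALE, trait_id, "male")
    female, panel_f = _simulate_one_sex(
        config, n_f, bf, _util.STREAM_GENO_FEMALE, _util.STREAM_PHENO_FEMALE, trait_id, "female")

    def _h2(betas, panel):
        var_g = float(np.var(panel.dosages.astype(float) @ betas))
        return var_g / (var_g + config.noise_sd**2) if var_g > 0 else 0.0

    truth = TruthTable(beta_male=bm, beta_female=bf,
                       h2_male=_h2(bm, panel_m), h2_female=_h2(bf, panel_f))
    return male, female, truth


def simulate_h2_estimates(
    truth: tuple[float, float],
    se: tuple[float, float],
    n_traits: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian-perturbed heritability-estimate pairs, clamped to [0, 1].

    Emulates externally produced per-trait (h2, SE) pairs for the male and
    female strata; the sex-difference z-test consumes these directly.
    """
    h2_m, h2_f = truth
    se_m, se_f = se
    if not (0 <= h2_m <= 1 and 0 <= h2_f <= 1):
        raise ValueError("true h2 must lie in [0, 1]")
    if se_m < 0 or se_f < 0:
        raise ValueError("SEs must be nonnegative")
    rng = derived_rng(seed, _util.STREAM_H2)
    est_m = np.clip(h2_m + rng.normal(0, se_m, size=n_traits), 0, 1)
    est_f = np.clip(h2_f + rng.normal(0, se_f, size=n_traits), 0, 1)
    return pd.DataFrame({
        "trait_id": [f"trait_{i}" for i in range(n_traits)],
        "h2_m": est_m, "se_m": max(se_m, P_FLOOR),
        "h2_f": est_f, "se_f": max(se_f, P_FLOOR),
        "true_h2_m": h2_m, "true_h2_f": h2_f,
    })


def simulate_mr_scenario(
    theta: float,
    gamma_sd: float = 0.1,
    pleiotropy_mode: str = "none",
    alpha_sd: float = 0.01,
    n_inst: int = 50,
    se_x: float = 0.01,
    se_y: float = 0.01,
    seed: int = 0,
    alpha_mean: float = 0.05,
    n_nominal: int = 50_000,
) -> tuple[SumStatsTable, SumStatsTable, TruthTable]:
    """Instrument-level two-sample MR scenario.

    True instrument effects ``gamma_j = |N(0, gamma_sd^2)|`` — instruments are
    emitted pre-oriented to the exposure-increasing allele, the convention
    under which Egger's directional pleiotropy is defined.  Outcome effects
    ``b_j = theta * gamma_j + alpha_j + noise(se_y)`` with pleiotropy
    ``alpha_j`` equal to 0 (``none``), zero-mean (``balanced``) or shifted to
    ``alpha_mean`` (``directional``).  Observed exposure betas are
    ``gamma_j + noise(se_x)``.
    """
    if n_inst < 3:
        raise ValueError("Egger regression needs at least 3 instruments")
    if pleiotropy_mode not in ("none", "balanced", "directional"):
        raise ValueError(f"unknown pleiotropy mode {pleiotropy_mode!r}")
    rng = derived_rng(seed, _util.STREAM_MR)
    gamma = np.abs(rng.normal(0, gamma_sd, size=n_inst))
    if pleiotropy_mode == "none":
        alpha = np.zeros(n_inst)
    elif pleiotropy_mode == "balanced":
        alpha = rng.normal(0, alpha_sd, size=n_inst)
    else:
        alpha = rng.normal(alpha_mean, alpha_sd, size=n_inst)
    bx = gamma + (rng.normal(0, se_x, size=n_inst) if se_x > 0 else 0.0)
    by = theta * gamma + alpha + (rng.normal(0, se_y, size=n_inst) if se_y > 0 else 0.0)

    pos = 1_000_000 + 1_000_000 * np.arange(n_inst)  # far apart: LD-free
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_inst)
    maf = rng.uniform(0.1, 0.5, size=n_inst)

    def _table(beta, se, trait_id):
        se_arr = np.full(n_inst, max(se, P_FLOOR))
        z = beta / se_arr
        df = pd.DataFrame({
            "variant_id": [f"1:{p}:{_ALLELE_PAIRS[i][0]}:{_ALLELE_PAIRS[i][1]}"
                           for p, i in zip(pos, pair_idx)],
            "chrom": "1", "pos": pos,
            "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
            "beta": beta, "se": se_arr,
            "pval": np.clip(2.0 * sps.norm.sf(np.abs(z)), P_FLOOR, 1.0),
            "maf": maf, "n": n_nominal,
        })
        return SumStatsTable(trait_id=trait_id, stratum="combined", df=df)

    truth = TruthTable(theta=theta, alpha=alpha, gamma=gamma, mode=pleiotropy_mode)
    return _table(bx, se_x, "exposure"), _table(by, se_y, "outcome"), truth


def simulate_coloc_scenario(
    mode: str,
    config: SimConfig,
    var_explained: float = 0.01,
) -> tuple[SumStatsTable, SumStatsTable, TruthTable]:
    """Two-stratum locus for colocalization with a planted causal structure.

    Modes: ``shared`` (same causal variant in both strata), ``distinct`` (one
    causal variant per stratum placed in different LD blocks, latent
    correlation 0 by construction), ``single_stratum`` (causal in stratum A
    only) and ``null`` (no causal variant).  Causal betas are scaled so the
    variant explains ``var_explained`` of phenotypic variance.
    """
    if config.m < 10:
        raise ValueError("coloc scenarios need m >= 10")
    if mode not in ("shared", "distinct", "single_stratum", "null"):
        raise ValueError(f"unknown coloc mode {mode!r}")

    mafs = _target_mafs(config)

    def _beta_for(idx):
        het = 2.0 * mafs[idx] * (1.0 - mafs[idx])
        return np.sqrt(var_explained * config.noise_sd**2 / ((1.0 - var_explained) * het))

    n_blocks = max(1, config.m // config.block_size)
    i_a = config.block_size // 2                       # middle of first block
    last_block_start = (n_blocks - 1) * config.block_size
    i_b = min(last_block_start + config.block_size // 2, config.m - 1)

    ca = cb = None
    beta_a = np.zeros(config.m)
    beta_b = np.zeros(config.m)
    if mode == "shared":
        ca = cb = i_a
        beta_a[i_a] = beta_b[i_a] = _beta_for(i_a)
    elif mode == "distinct":
        ca, cb = i_a, i_b
        beta_a[i_a] = _beta_for(i_a)
        beta_b[i_b] = _beta_for(i_b)
    elif mode == "single_stratum":
        ca = i_a
        beta_a[i_a] = _beta_for(i_a)

    cfg = replace(config, causal_spec=[])
    stats_a, _ = _simulate_one_sex(
        cfg, config.n_male, beta_a, _util.STREAM_GENO_MALE, _util.STREAM_PHENO_MALE,
        "coloc_locus", "male")
    stats_b, _ = _simulate_one_sex(
        cfg, config.n_female, beta_b, _util.STREAM_GENO_FEMALE, _util.STREAM_PHENO_FEMALE,
        "coloc_locus", "female")
    truth = TruthTable(beta_male=beta_a, beta_female=beta_b,
                       causal_index_a=ca, causal_index_b=cb, mode=mode)
    return stats_a, stats_b, truth
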