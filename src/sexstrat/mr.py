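"""Two-sample Mendelian randomization with an MR-Egger estimator.

MR-Egger regresses outcome effects on exposure effects across LD-independent
instruments with a free intercept; the slope estimates the causal effect and
the intercept absorbs directional pleiotropy.  Following the conventional
implementation, every instrument is first oriented so its exposure effect is
nonnegative, the fit is weighted least squares with weights 1/se_y^2, the
coefficient SEs carry a multiplicative residual-overdispersion factor floored
at 1, and p-values use the t reference with n_inst - 2 df.

Sex-aware execution runs the same estimator on sex-combined, male and female
summary statistics; a relationship is sex-specific when it is significant (on
the slope p-value) in exactly one sex and in neither the other sex nor the
combined model, at the Bonferroni threshold over the exposure-outcome grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from ._util import P_FLOOR
from .io_sumstats import SumStatsTable, harmonize_alleles
from .ld import LdMatrix, greedy_tag
from .regions import GeneRegion, RegionIndex

logger = logging.getLogger(__name__)

INSTRUMENT_P = 5e-8
CLUMP_R2 = 0.001
#: Bonferroni threshold for the published 186-outcome x 29-exposure grid
GRID_ALPHA = 0.05 / (186 * 29)


@dataclass
class InstrumentSet:
    """Harmonized instrument effects for one (exposure, outcome, stratum) cell.

    ``df`` columns: variant_id, chrom, pos, bx, bx_se, by, by_se — with bx and
    by referring to the same effect allele per row.
    """

    exposure_id: str
    outcome_id: str
    stratum: str
    df: pd.DataFrame

    def __post_init__(self):
        if len(self.df) and (np.any(self.df["bx_se"] <= 0) or np.any(self.df["by_se"] <= 0)):
            raise ValueError("instrument SEs must be positive")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MrResult:
    """MR-Egger slope (causal effect) and intercept (pleiotropy) estimates."""

    slope: float
    slope_se: float
    slope_p: float
    intercept: float
    intercept_se: float
    intercept_p: float
    n_inst: int
    stratum: str = "combined"
    exposure_id: str = ""
    outcome_id: str = ""


def mr_egger(inst: InstrumentSet) -> MrResult:
    """Weighted MR-Egger regression of outcome on exposure effects."""
    n = len(inst)
    if n < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    bx = inst.df["bx"].to_numpy(float)
    by = inst.df["by"].to_numpy(float)
    by_se = inst.df["by_se"].to_numpy(float)
    if np.allclose(bx, 0):
        raise ValueError("all exposure effects are zero; slope unidentified")

    sign = np.where(bx < 0, -1.0, 1.0)  # orient to nonnegative exposure effect
    bx, by = bx * sign, by * sign
    w = 1.0 / by_se**2
    x = sm.add_constant(bx)
    fit = sm.WLS(by, x, weights=w).fit()

    sigma = float(np.sqrt(fit.scale))  # residual overdispersion
    xtwx_inv = np.linalg.inv(x.T @ (w[:, None] * x))
    se_unit = np.sqrt(np.diag(xtwx_inv))
    se = se_unit * max(sigma, 1.0)
    se = np.maximum(se, P_FLOOR)
    tvals = fit.params / se
    pvals = np.clip(2.0 * sps.t.sf(np.abs(tvals), n - 2), P_FLOOR, 1.0)

    return MrResult(
        slope=float(fit.params[1]), slope_se=float(se[1]), slope_p=float(pvals[1]),
        intercept=float(fit.params[0]), intercept_se=float(se[0]),
        intercept_p=float(pvals[0]), n_inst=n,
        stratum=inst.stratum, exposure_id=inst.exposure_id, outcome_id=inst.outcome_id,
    )


def mr_ivw(inst: InstrumentSet) -> tuple[float, float]:
    """Inverse-variance-weighted ratio estimate (diagnostic only)."""
    bx = inst.df["bx"].to_numpy(float)
    by = inst.df["by"].to_numpy(float)
    w = bx**2 / inst.df["by_se"].to_numpy(float) ** 2
    ratio = np.divide(by, bx, out=np.zeros_like(by), where=bx != 0)
    est = float(np.sum(w * ratio) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return est, se


def select_instruments(
    exposure: SumStatsTable,
    p_threshold: float = INSTRUMENT_P,
    ld: LdMatrix | None = None,
    clump_r2: float = CLUMP_R2,
) -> list[str]:
    """Genome-wide-significant exposure variants, greedily clumped at ``clump_r2``.

    Returns the tag variant ids (ascending p within clumps).  With no LD
    matrix all significant variants are returned with a warning; an empty
    list simply means no instruments (the caller decides).
    """
    d = exposure.df
    sig = d[d["pval"] < p_threshold]
    if len(sig) == 0:
        return []
    ids = (sig["chrom"].astype(str) + ":" + sig["pos"].astype(str) + ":"
           + sig["effect_allele"] + ":" + sig["other_allele"]).tolist()
    if ld is None:
        logger.warning("select_instruments: no LD matrix supplied; skipping clumping")
        return ids
    sub = ld.subset(ids)
    loci = greedy_tag(sub, priority=sig["pval"].to_numpy(),
                      threshold=clump_r2, positions=sig["pos"].to_numpy())
    return [sub.keys[i] for i in sorted(loci, key=lambda i: sig["pval"].to_numpy()[i])]


def build_instrument_set(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    instrument_ids: Sequence[str],
    stratum: str = "combined",
) -> InstrumentSet:
    """Pair selected exposure variants with harmonized outcome records."""
    exp_idx = {vid: i for i, vid in enumerate(exposure.variant_ids)}
    out_by_pos: dict[tuple, list[int]] = {}
    for i, (c, p) in enumerate(zip(outcome.df["chrom"], outcome.df["pos"])):
        out_by_pos.setdefault((str(c), int(p)), []).append(i)

    rows = []
    for vid in instrument_ids:
        if vid not in exp_idx:
            continue
        e = exposure.df.iloc[exp_idx[vid]]
        for j in out_by_pos.get((str(e["chrom"]), int(e["pos"])), []):
            o = outcome.df.iloc[j]
            _, o_h, action = harmonize_alleles(e, o)
            if action == "drop":
                continue
            rows.append({
                "variant_id": vid, "chrom": e["chrom"], "pos": e["pos"],
                "bx": e["beta"], "bx_se": e["se"],
                "by": o_h["beta"], "by_se": o["se"],
            })
            break
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "bx", "bx_se", "by", "by_se"])
    return InstrumentSet(exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
                         stratum=stratum, df=df)


def run_mr_grid(
    exposures: Mapping[str, Mapping[str, SumStatsTable]],
    outcomes: Mapping[str, Mapping[str, SumStatsTable]],
    ld: Mapping[str, LdMatrix] | None = None,
    strata: Sequence[str] = ("combined", "male", "female"),
    p_threshold: float = INSTRUMENT_P,
    clump_r2: float = CLUMP_R2,
) -> pd.DataFrame:
    """MR-Egger over every (exposure, outcome, stratum) cell; failures recorded.

    ``exposures`` / ``outcomes`` map trait id -> stratum -> table.  Returns a
    frame with one row per cell: estimates for successful fits, a ``status``
    of ``no_instruments`` / ``too_few_instruments`` / ``missing_stratum`` /
    ``error`` otherwise.  The grid always completes.
    """
    rows = []
    for exp_id, exp_by_stratum in exposures.items():
        for out_id, out_by_stratum in outcomes.items():
            for stratum in strata:
                cell = {"exposure": exp_id, "outcome": out_id, "stratum": stratum,
                        "status": "ok", "n_inst": 0,
                        "slope": np.nan, "slope_se": np.nan, "slope_p": np.nan,
                        "intercept": np.nan, "intercept_se": np.nan, "intercept_p": np.nan}
                exp = exp_by_stratum.get(stratum)
                out = out_by_stratum.get(stratum)
                if exp is None or out is None:
                    cell["status"] = "missing_stratum"
                    rows.append(cell)
                    continue
                try:
                    inst_ids = select_instruments(
                        exp, p_threshold=p_threshold,
                        ld=(ld or {}).get(exp_id), clump_r2=clump_r2)
                    if not inst_ids:
                        cell["status"] = "no_instruments"
                        rows.append(cell)
                        continue
                    inst = build_instrument_set(exp, out, inst_ids, stratum=stratum)
                    if len(inst) < 3:
                        cell["status"] = "too_few_instruments"
                        cell["n_inst"] = len(inst)
                        rows.append(cell)
                        continue
                    res = mr_egger(inst)
                    cell.update(n_inst=res.n_inst,
                                slope=res.slope, slope_se=res.slope_se, slope_p=res.slope_p,
                                intercept=res.intercept, intercept_se=res.intercept_se,
                                intercept_p=res.intercept_p)
                except Exception as exc:  # grid never aborts
                    cell["status"] = f"error:{type(exc).__name__}"
                rows.append(cell)
    return pd.DataFrame(rows)


def call_sex_specific_mr(
    combined: MrResult | None,
    male: MrResult | None,
    female: MrResult | None,
    alpha: float = GRID_ALPHA,
) -> str:
    """Sex-specificity of one exposure-outcome relationship.

    Significance is evaluated on the Egger slope p-value; an absent result
    counts as not significant.  ``male_specific`` requires significance in
    males only (not in females, not in the combined model); symmetric for
    females.  ``not_sex_specific`` when the combined model or both sexes are
    significant; ``none`` when nothing is.
    """
    def _p(res):
        return res.slope_p if res is not None else 1.0

    p_c, p_m, p_f = _p(combined), _p(male), _p(female)
    sig_c, sig_m, sig_f = p_c < alpha, p_m < alpha, p_f < alpha
    if sig_m and not sig_f and not sig_c:
        return "male_specific"
    if sig_f and not sig_m and not sig_c:
        return "female_specific"
    if sig_c or (sig_m and sig_f):
        return "not_sex_specific"
    return "none"


def restrict_to_dmet(
    inst: InstrumentSet, regions: Sequence[GeneRegion]
) -> tuple[InstrumentSet | None, str]:
    """Keep instruments inside at least one gene region.

    Returns ``(subset, "ok")`` when >= 3 instruments survive, else
    ``(None, "underpowered")`` — too few instruments for a defensible Egger
    re-fit.  The caller re-runs ``mr_egger`` and re-tests at its
    Bonferroni-adjusted threshold.
    """
    index = RegionIndex(regions)
    keep = [bool(index.query(c, p)) for c, p in zip(inst.df["chrom"], inst.df["pos"])]
    sub = inst.df[np.asarray(keep, bool)].reset_index(drop=True)
    if len(sub) < 3:
        return None, "underpowered"
    return InstrumentSet(inst.exposure_id, inst.outcome_id, inst.stratum, sub), "ok"
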