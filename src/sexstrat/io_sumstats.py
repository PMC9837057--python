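"""Reading, validation, writing and pairwise alignment of GWAS/eQTL summary statistics.

The on-disk format is tab-separated text with required columns
``variant_id, chrom, pos, effect_allele, other_allele, beta, se, pval, maf, n``
and an optional ``n_cases`` column for case-control traits.  Column names can be
remapped at read time via a dialect mapping, so consortium files with their own
headers load without preprocessing.

Malformed rows never abort a load: every rejected row is counted by reason in a
:class:`LoadReport`, because large consortium summary files routinely contain a
handful of unparseable or out-of-range records.

Positions are 1-based throughout.  Chromosome labels are normalized by stripping
a leading ``chr``.  Serialization uses 17 significant digits so that a
write/read round trip is lossless for every float field.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import chrom_sort_key, normalize_chrom

logger = logging.getLogger(__name__)

#: canonical column order of the on-disk format
STD_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval", "maf", "n",
]
OPTIONAL_COLUMNS = ["n_cases"]

STRATA = ("combined", "male", "female")
TRAIT_TYPES = ("quantitative", "binary")

_VALID_BASES = set("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs that read the same on both strands
_PALINDROMES = ({"A", "T"}, {"C", "G"})
#: MAF band inside which a palindromic variant cannot be oriented reliably
AMBIGUITY_BAND = (0.42, 0.5)


class SumStatsFormatError(ValueError):
    """Raised when a summary-statistics file is structurally unreadable."""


class HarmonizeError(ValueError):
    """Raised on misuse of allele harmonization (e.g. different positions)."""


@dataclass(frozen=True)
class VariantKey:
    """Identity of one variant: chromosome, 1-based position, allele pair."""

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    rsid: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.effect_allele, self.other_allele):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"bad allele {allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.effect_allele}:{self.other_allele}"

    @classmethod
    def from_string(cls, s: str) -> "VariantKey":
        chrom, pos, ea, oa = s.split(":")
        return cls(normalize_chrom(chrom), int(pos), ea.upper(), oa.upper())


@dataclass
class LoadReport:
    """Counts of input, kept and per-reason rejected rows for one load."""

    n_input: int = 0
    n_kept: int = 0
    rejections: Counter = field(default_factory=Counter)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejections.values())

    def as_text(self) -> str:
        lines = [f"rows_input\t{self.n_input}", f"rows_kept\t{self.n_kept}"]
        for reason in sorted(self.rejections):
            lines.append(f"rejected_{reason}\t{self.rejections[reason]}")
        return "\n".join(lines)


@dataclass
class SumStatsTable:
    """Per-variant association records for one trait in one population stratum.

    ``df`` holds the canonical columns of :data:`STD_COLUMNS` (plus ``n_cases``
    for binary traits), sorted by (chrom, pos) with unique variant keys.
    """

    trait_id: str
    stratum: str
    df: pd.DataFrame
    trait_type: str = "quantitative"
    load_report: LoadReport | None = None

    def __post_init__(self):
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}, got {self.stratum!r}")
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"trait_type must be one of {TRAIT_TYPES}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> pd.Series:
        """chrom:pos:ea:oa key per row."""
        d = self.df
        return (
            d["chrom"].astype(str) + ":" + d["pos"].astype(str) + ":"
            + d["effect_allele"] + ":" + d["other_allele"]
        )


@dataclass
class PairedSumStats:
    """Male/female records aligned and allele-harmonized variant-by-variant.

    ``df`` carries the shared key columns plus ``{beta,se,pval,maf,n}_m`` and
    ``_f`` suffixed per-sex fields, all on the same effect allele.
    """

    trait_id: str
    df: pd.DataFrame
    report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)


def _sorted_unique(df: pd.DataFrame, report: LoadReport) -> pd.DataFrame:
    dup = df.duplicated(subset=["chrom", "pos", "effect_allele", "other_allele"], keep="first")
    if dup.any():
        report.rejections["duplicate_variant"] += int(dup.sum())
        df = df[~dup]
    rank = df["chrom"].map(chrom_sort_key)
    df = df.assign(_rank=rank).sort_values(["_rank", "pos"], kind="mergesort").drop(columns="_rank")
    return df.reset_index(drop=True)


def validate_sumstats_frame(
    df: pd.DataFrame, trait_type: str = "quantitative"
) -> tuple[pd.DataFrame, LoadReport]:
    """Validate and clean a raw frame; returns (clean sorted frame, report).

    Rows violating any record invariant (nonpositive SE, p outside (0,1],
    MAF outside (0,0.5], bad position or alleles, inconsistent case counts)
    are dropped and counted; they never raise.
    """
    report = LoadReport(n_input=len(df))
    df = df.copy()

    for col in STD_COLUMNS:
        if col not in df.columns:
            raise SumStatsFormatError(f"missing required column {col!r}")
    if "n_cases" not in df.columns:
        df["n_cases"] = np.nan

    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["variant_id"] = df["variant_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    for col in ("pos", "beta", "se", "pval", "maf", "n", "n_cases"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    def drop(mask: pd.Series, reason: str):
        nonlocal df
        mask = mask.fillna(False) if mask.dtype == object else mask
        n = int(mask.sum())
        if n:
            report.rejections[reason] += n
            df = df[~mask]

    core = ["pos", "beta", "se", "pval", "maf", "n"]
    drop(df[core].isna().any(axis=1), "missing_value")
    drop(~((df["pos"] >= 1) & (df["pos"] == df["pos"].round())), "bad_position")
    allele_ok = df.apply(
        lambda r: bool(r["effect_allele"]) and bool(r["other_allele"])
        and set(r["effect_allele"]) <= _VALID_BASES
        and set(r["other_allele"]) <= _VALID_BASES
        and r["effect_allele"] != r["other_allele"],
        axis=1,
    ) if len(df) else pd.Series(dtype=bool)
    if len(df):
        drop(~allele_ok, "bad_alleles")
    drop(~(df["se"] > 0), "nonpositive_se")
    drop(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval_out_of_range")
    drop(~((df["maf"] > 0) & (df["maf"] <= 0.5)), "maf_out_of_range")
    drop(~(df["n"] >= 1), "bad_n")
    if trait_type == "binary":
        drop(~(df["n_cases"].notna() & (df["n_cases"] > 0) & (df["n_cases"] < df["n"])),
             "bad_case_count")

    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    df["n_cases"] = df["n_cases"].astype("Int64")
    if trait_type != "binary" and df["n_cases"].isna().all():
        df = df.drop(columns="n_cases")

    df = _sorted_unique(df, report)
    report.n_kept = len(df)
    return df, report


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    stratum: str = "combined",
    trait_type: str | None = None,
) -> SumStatsTable:
    """Load one summary-statistics table from a delimited text file.

    Parameters
    ----------
    dialect
        Optional mapping from canonical column names to the names used in the
        file, e.g. ``{"pval": "p_value", "maf": "minor_AF"}``.
    trait_type
        ``"quantitative"`` or ``"binary"``; inferred from the presence of a
        populated ``n_cases`` column when omitted.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str, "variant_id": str},
                      float_precision="round_trip")
    if dialect:
        raw = raw.rename(columns={v: k for k, v in dialect.items()})
    if trait_type is None:
        trait_type = (
            "binary" if "n_cases" in raw.columns and raw["n_cases"].notna().any()
            else "quantitative"
        )
    df, report = validate_sumstats_frame(raw, trait_type=trait_type)
    logger.info("loaded %s:\n%s", path.name, report.as_text())
    return SumStatsTable(
        trait_id=trait_id or path.stem,
        stratum=stratum,
        df=df,
        trait_type=trait_type,
        load_report=report,
    )


def write_sumstats(table: SumStatsTable, path) -> None:
    """Write a table as TSV; floats at 17 significant digits (lossless)."""
    cols = [c for c in STD_COLUMNS + OPTIONAL_COLUMNS if c in table.df.columns]
    table.df[cols].to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="")


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in _PALINDROMES


def _revcomp(allele: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(allele))


def _in_band(maf: float, band) -> bool:
    lo, hi = band
    return lo < maf <= hi


def harmonize_alleles(a, b, ambiguity_band=AMBIGUITY_BAND):
    """Orient record ``b`` onto record ``a``'s effect allele.

    Both arguments are mapping-like rows (dict / pandas Series) with fields
    ``chrom, pos, effect_allele, other_allele, beta, maf``.  Returns
    ``(a, b', action)`` with action one of ``keep`` (alleles already agree),
    ``flip`` (b's alleles were swapped; its beta sign is inverted) or ``drop``
    (ambiguous palindrome or incompatible allele sets).  Strand-complement
    matches are relabeled onto ``a``'s alleles.  Idempotent.
    """
    if str(a["chrom"]) != str(b["chrom"]) or int(a["pos"]) != int(b["pos"]):
        raise HarmonizeError("records at different positions cannot be harmonized")

    ea_a, oa_a = a["effect_allele"], a["other_allele"]
    ea_b, oa_b = b["effect_allele"], b["other_allele"]

    if _is_palindromic(ea_a, oa_a) and _in_band(a["maf"], ambiguity_band) \
            and _in_band(b["maf"], ambiguity_band):
        return a, b, "drop"

    def _flipped(rec):
        out = dict(rec) if not isinstance(rec, pd.Series) else rec.copy()
        out["effect_allele"], out["other_allele"] = ea_a, oa_a
        out["beta"] = -rec["beta"]
        return out

    def _relabeled(rec):
        out = dict(rec) if not isinstance(rec, pd.Series) else rec.copy()
        out["effect_allele"], out["other_allele"] = ea_a, oa_a
        return out

    if (ea_b, oa_b) == (ea_a, oa_a):
        return a, b, "keep"
    if (ea_b, oa_b) == (oa_a, ea_a):
        return a, _flipped(b), "flip"
    if (_revcomp(ea_b), _revcomp(oa_b)) == (ea_a, oa_a):
        return a, _relabeled(b), "keep"
    if (_revcomp(ea_b), _revcomp(oa_b)) == (oa_a, ea_a):
        return a, _flipped(b), "flip"
    return a, b, "drop"


def align_pair(
    male: SumStatsTable,
    female: SumStatsTable,
    key: str = "cpra",
    ambiguity_band=AMBIGUITY_BAND,
) -> PairedSumStats:
    """Intersect and harmonize a male and a female table of the same trait.

    ``key`` selects the matching key: ``"cpra"`` (chrom:pos + allele
    harmonization, default) or ``"rsid"`` (the ``variant_id`` column).
    An empty intersection yields an empty result with a warning, not an error.
    """
    if male.trait_id != female.trait_id:
        raise ValueError("align_pair requires tables of the same trait")

    per_sex = ["beta", "se", "pval", "maf", "n"]
    m = male.df.copy()
    f = female.df.copy()
    if key == "rsid":
        merged = m.merge(f, on="variant_id", suffixes=("_m", "_f"))
        merged = merged[(merged["chrom_m"] == merged["chrom_f"])
                        & (merged["pos_m"] == merged["pos_f"])]
        merged = merged.rename(columns={"chrom_m": "chrom", "pos_m": "pos"})
    elif key == "cpra":
        merged = m.merge(f, on=["chrom", "pos"], suffixes=("_m", "_f"))
        if "variant_id_m" in merged.columns:
            merged = merged.rename(columns={"variant_id_m": "variant_id"})
    else:
        raise ValueError("key must be 'cpra' or 'rsid'")

    report = {"n_male_only": 0, "n_female_only": 0,
              "n_dropped_palindromic": 0, "n_dropped_incompatible": 0, "n_pairs": 0}

    rows = []
    for _, row in merged.iterrows():
        a = {"chrom": row["chrom"], "pos": row["pos"],
             "effect_allele": row["effect_allele_m"], "other_allele": row["other_allele_m"],
             "beta": row["beta_m"], "maf": row["maf_m"]}
        b = {"chrom": row["chrom"], "pos": row["pos"],
             "effect_allele": row["effect_allele_f"], "other_allele": row["other_allele_f"],
             "beta": row["beta_f"], "maf": row["maf_f"]}
        a, b, action = harmonize_alleles(a, b, ambiguity_band=ambiguity_band)
        if action == "drop":
            if _is_palindromic(a["effect_allele"], a["other_allele"]):
                report["n_dropped_palindromic"] += 1
            else:
                report["n_dropped_incompatible"] += 1
            continue
        out = {
            "variant_id": row.get("variant_id", ""),
            "chrom": row["chrom"], "pos": row["pos"],
            "effect_allele": a["effect_allele"], "other_allele": a["other_allele"],
        }
        for col in per_sex:
            out[f"{col}_m"] = row[f"{col}_m"]
        out["beta_f"] = b["beta"]
        for col in per_sex[1:]:
            out[f"{col}_f"] = row[f"{col}_f"]
        rows.append(out)

    columns = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"] \
        + [f"{c}_m" for c in per_sex] + [f"{c}_f" for c in per_sex]
    out_df = pd.DataFrame(rows, columns=columns)
    paired_keys = set(zip(out_df["chrom"], out_df["pos"])) if len(out_df) else set()
    report["n_male_only"] = int((~m.set_index(["chrom", "pos"]).index.isin(paired_keys)).sum())
    report["n_female_only"] = int((~f.set_index(["chrom", "pos"]).index.isin(paired_keys)).sum())
    report["n_pairs"] = len(out_df)
    if not len(out_df):
        logger.warning("align_pair: empty intersection for trait %s", male.trait_id)
    return PairedSumStats(trait_id=male.trait_id, df=out_df, report=report)
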