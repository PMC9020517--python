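"""Targeted quantification of the pS65-containing NEDD8 peptide.

Input is a table of peptide peak areas from selected-ion monitoring of
a tryptic NEDD8 digest, one row per (peptide, phospho state, condition,
biological replicate, technical replicate).  Per technical replicate:

1. baseline correction — every area is divided by the mean area of the
   NEDD8 peptides that do not span S65 (controls for pull-down yield);
2. occupancy normalization — the unmodified-S65 and pS65 areas of the
   site peptide are rescaled so their sum is 100 %, giving the relative
   intensity of the phosphorylated form.

Because the same baseline divides both site-peptide areas, it cancels
in the percentage; it matters only for the reported baseline-normalized
absolute areas.  Condition effects (e.g. mitochondrial depolarization
vs mock) are summarized as a fold change of biological-replicate means.
"""

from __future__ import annotations

import pandas as pd

from .errors import ParameterError, UndefinedFractionError, ValidationError

__all__ = [
    "validate_table",
    "ps65_relative_intensity",
    "bio_replicate_means",
    "condition_fold_change",
]

REQUIRED_COLUMNS = [
    "peptide",
    "is_s65_site",
    "phosphorylated",
    "condition",
    "bio_replicate",
    "tech_replicate",
    "area",
]

_KEY = ["condition", "bio_replicate", "tech_replicate"]


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the targeted peak-area table's schema and invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"table lacks columns: {missing}")
    if (table["area"] < 0).any():
        raise ValidationError("peak areas must be >= 0")
    key = ["peptide", "phosphorylated"] + _KEY
    if table.duplicated(subset=key).any():
        dupes = table[table.duplicated(subset=key, keep=False)]
        raise ValidationError(f"duplicate rows for {key}: {dupes[key].head().to_dict('records')}")
    baseline_per_rep = (
        table[~table["is_s65_site"]].groupby(_KEY, sort=False).size()
    )
    reps = table.groupby(_KEY, sort=False).size()
    if not baseline_per_rep.reindex(reps.index).notna().all():
        raise ValidationError("every replicate needs at least one non-S65 baseline peptide")
    return table


def ps65_relative_intensity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-technical-replicate pS65 relative intensity.

    Returns one row per (condition, bio_replicate, tech_replicate) with
    the baseline mean, baseline-normalized site-peptide areas, and
    ``ps65_percent`` = 100 * pS65 / (S65 + pS65).
    """
    validate_table(table)
    rows = []
    for (cond, bio, tech), grp in table.groupby(_KEY, sort=False):
        baseline = grp.loc[~grp["is_s65_site"], "area"]
        baseline_mean = float(baseline.mean())
        if baseline_mean <= 0:
            raise ParameterError(
                f"baseline mean must be > 0 for replicate {(cond, bio, tech)}"
            )
        site = grp[grp["is_s65_site"]]
        s65 = float(site.loc[~site["phosphorylated"], "area"].sum()) / baseline_mean
        ps65 = float(site.loc[site["phosphorylated"], "area"].sum()) / baseline_mean
        if s65 + ps65 == 0:
            raise UndefinedFractionError(
                f"S65 + pS65 area is zero for replicate {(cond, bio, tech)}"
            )
        rows.append(
            {
                "condition": cond,
                "bio_replicate": bio,
                "tech_replicate": tech,
                "baseline_mean": baseline_mean,
                "s65_norm": s65,
                "ps65_norm": ps65,
                "ps65_percent": 100.0 * ps65 / (s65 + ps65),
            }
        )
    return pd.DataFrame(rows)


def bio_replicate_means(per_tech: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates within each biological replicate."""
    return (
        per_tech.groupby(["condition", "bio_replicate"], sort=False)["ps65_percent"]
        .mean()
        .reset_index()
    )


def condition_fold_change(
    per_tech: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    paired: bool = False,
) -> float:
    """Fold change of pS65 relative intensity, condition_a / condition_b.

    Unpaired (default): ratio of the means over biological replicates.
    Paired: mean of per-bio-replicate ratios (requires matching
    bio_replicate ids across conditions).
    """
    bio = bio_replicate_means(per_tech)
    a = bio[bio["condition"] == condition_a]
    b = bio[bio["condition"] == condition_b]
    if a.empty or b.empty:
        raise ParameterError(
            f"both conditions need >= 1 biological replicate "
            f"({condition_a!r}: {len(a)}, {condition_b!r}: {len(b)})"
        )
    if paired:
        merged = a.merge(b, on="bio_replicate", suffixes=("_a", "_b"))
        if merged.empty:
            raise ParameterError("paired mode needs matching bio_replicate ids")
        if (merged["ps65_percent_b"] == 0).any():
            raise UndefinedFractionError("zero denominator in paired fold change")
        return float((merged["ps65_percent_a"] / merged["ps65_percent_b"]).mean())
    denom = float(b["ps65_percent"].mean())
    if denom == 0:
        raise UndefinedFractionError(f"mean ps65_percent of {condition_b!r} is zero")
    return float(a["ps65_percent"].mean()) / denom
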