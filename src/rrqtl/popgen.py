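"""Population-frequency annotation of markers and mapped QTL.

Markers are classified rare/common against a population panel MAF cutoff
(0.01 by default, with the boundary assigned to common) and, where an
outgroup allele is available, oriented into ancestral/derived states: the
allele not shared with the outgroup is the derived (recent) allele and the
unfolded (derived) allele frequency is its panel frequency.  Summaries mirror
the standard views of frequency-coupled architectures: mean |effect| in
equal-count frequency bins, 2x2 enrichment tests (Fisher exact), and counts
of trait-decreasing vs -increasing derived alleles by age class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import UNKNOWN_ALLELE

__all__ = [
    "classify_rare_common",
    "classify_derived",
    "annotate_markers",
    "bin_effects_by_frequency",
    "enrichment_test",
    "effect_threshold_from_variance",
    "direction_summary",
]


def classify_rare_common(maf: float, cutoff: float = 0.01) -> str:
    """'rare' below the cutoff, 'common' at or above it, 'unknown' if missing."""
    if maf is None or (isinstance(maf, float) and math.isnan(maf)):
        return "unknown"
    if not 0.0 <= maf <= 0.5:
        raise ValueError("maf must lie in [0, 0.5]")
    return "rare" if maf < cutoff else "common"


def classify_derived(ref_allele: str, alt_allele: str, panel_maf: float,
                     outgroup_allele: str) -> tuple[float, str]:
    """Derived-allele frequency and age class from the outgroup state.

    ``ref_allele`` is the panel major allele (frequency 1 − maf) and
    ``alt_allele`` the minor (frequency maf).  The non-outgroup allele is
    derived; a variant whose minor allele matches the outgroup is 'ancient'
    (the derived allele has drifted to high frequency), otherwise 'recent'.
    Returns (nan, 'unknown') when the outgroup matches neither allele.
    """
    if outgroup_allele == ref_allele:
        return float(panel_maf), "recent"
    if outgroup_allele == alt_allele:
        return float(1.0 - panel_maf), "ancient"
    return float("nan"), "unknown"


def annotate_markers(markers: pd.DataFrame, cutoff: float = 0.01) -> pd.DataFrame:
    """Add class / derived_freq / age_class columns to a marker table."""
    cls, dfreq, age = [], [], []
    for _, row in markers.iterrows():
        cls.append(classify_rare_common(row["panel_maf"], cutoff))
        d, a = classify_derived(row["ref_allele"], row["alt_allele"],
                                row["panel_maf"], row["ancestral_allele"])
        dfreq.append(d)
        age.append(a)
    return markers.assign(**{"class": cls, "derived_freq": dfreq, "age_class": age})


def bin_effects_by_frequency(qtls: pd.DataFrame, bin_size: int = 100,
                             maf_col: str = "panel_maf",
                             effect_col: str = "mean_beta") -> pd.DataFrame:
    """Mean |effect| with s.e.m. in consecutive equal-count frequency bins."""
    df = qtls.dropna(subset=[maf_col, effect_col]).sort_values(maf_col, kind="stable")
    n_bins = max(int(np.ceil(len(df) / bin_size)), 1)
    rows = []
    for b, chunk in enumerate(np.array_split(np.arange(len(df)), n_bins)):
        eff = np.abs(df[effect_col].to_numpy(float)[chunk])
        maf = df[maf_col].to_numpy(float)[chunk]
        rows.append({
            "bin": b,
            "n": len(chunk),
            "mean_maf": maf.mean(),
            "mean_abs_effect": eff.mean(),
            "sem": eff.std(ddof=1) / np.sqrt(len(eff)) if len(eff) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def enrichment_test(table) -> dict:
    """Sample odds ratio and two-sided Fisher exact p for a 2x2 count table.

    A zero cell leaves the sample OR undefined (or infinite); a
    Haldane-corrected OR (+0.5 per cell) is reported alongside and flagged.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.rint(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    a, b, c, d = t.ravel()
    _, p = stats.fisher_exact(t, alternative="two-sided")
    zero_cell = (t == 0).any()
    out = {
        "odds_ratio": (a * d) / (b * c) if b * c > 0 else float("nan"),
        "p_value": float(p),
        "zero_margin": bool((t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any()),
        "zero_cell_corrected": bool(zero_cell),
    }
    if zero_cell:
        out["odds_ratio_haldane"] = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return out


def effect_threshold_from_variance(var_frac: float) -> float:
    """SD-unit effect whose standardized genotype explains ``var_frac`` of variance."""
    if not 0.0 <= var_frac <= 1.0:
        raise ValueError("var_frac must lie in [0, 1]")
    return math.sqrt(var_frac)


def direction_summary(qtls: pd.DataFrame, effect_col: str = "derived_effect",
                      age_col: str = "age_class") -> dict:
    """Counts of trait-decreasing vs -increasing derived alleles by age class.

    ``effect_col`` must be signed on the derived allele.  Returns the 2x2
    counts (rows recent/ancient, columns decrease/increase), the excluded
    unknown count, and the enrichment test when both classes are populated.
    """
    known = qtls[qtls[age_col].isin(["recent", "ancient"])]
    n_excluded = len(qtls) - len(known)
    counts = {}
    for age in ("recent", "ancient"):
        sub = known[known[age_col] == age]
        eff = sub[effect_col].to_numpy(float)
        counts[age] = {"decrease": int((eff < 0).sum()),
                       "increase": int((eff >= 0).sum())}
    table = [[counts["recent"]["decrease"], counts["recent"]["increase"]],
             [counts["ancient"]["decrease"], counts["ancient"]["increase"]]]
    out = {"counts": counts, "n_excluded_unknown": n_excluded, "table": table}
    if min(sum(r) for r in table) > 0:
        out["enrichment"] = enrichment_test(table)
    else:
        out["enrichment"] = {"odds_ratio": float("nan"), "p_value": float("nan"),
                             "undefined": True}
    rec = counts["recent"]
    tot = rec["decrease"] + rec["increase"]
    out["recent_decrease_fraction"] = rec["decrease"] / tot if tot else float("nan")
    return out
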