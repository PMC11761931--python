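"""Gait and leg-health classification of individual broilers.

Raw scores follow standard 0-5 visual rubrics: gait score (GS, Bristol-style
walking-ability rating), hock burn (HB) and footpad dermatitis (FPD), the
latter two scored per leg/foot. The analysis classes are:

* GS class: GS1, GS2, GS3+ (raw 3 and 4 merged; raw 0 and 5, absent from
  the study population, are rejected unless explicitly remapped),
* HB class: binary — HB0 iff both hocks score 0, else HB1,
* FPD class: from the two-foot mean m — FPD0 iff both feet score 0,
  FPD1 iff 0 < m < 2, FPD2 iff m >= 2.

Phenotype CSV schema: ``bird_id,gs,hb_left,hb_right,fpd_left,fpd_right,weight_g``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

GS_CLASSES = ["GS1", "GS2", "GS3+"]
HB_CLASSES = ["HB0", "HB1"]
FPD_CLASSES = ["FPD0", "FPD1", "FPD2"]

PHENOTYPE_COLUMNS = ["bird_id", "gs", "hb_left", "hb_right", "fpd_left", "fpd_right", "weight_g"]


@dataclass
class ClassifiedBird:
    bird_id: str
    gs_class: str
    hb_class: str
    fpd_class: str
    weight_g: float


def _check_score(value, name: str) -> int:
    v = int(value)
    if v != value or not 0 <= v <= 5:
        raise ValueError(f"{name} score {value!r} outside the 0-5 scale")
    return v


def classify_hb(left, right) -> str:
    """HB0 iff both hocks score zero, otherwise HB1."""
    l, r = _check_score(left, "hb_left"), _check_score(right, "hb_right")
    return "HB0" if l == 0 and r == 0 else "HB1"


def classify_fpd(left, right) -> str:
    """FPD class from the two-foot mean (boundary m = 2 belongs to FPD2)."""
    l, r = _check_score(left, "fpd_left"), _check_score(right, "fpd_right")
    if l == 0 and r == 0:
        return "FPD0"
    m = (l + r) / 2
    return "FPD1" if m < 2 else "FPD2"


def classify_gs(gs_raw, allow_extremes: bool = False) -> str:
    """Map a raw 0-5 gait score to GS1 / GS2 / GS3+.

    Raw scores 0 and 5 did not occur in the study population and are
    rejected by default; with ``allow_extremes`` they fold into the nearest
    class (0 -> GS1, 5 -> GS3+) with a warning.
    """
    g = _check_score(gs_raw, "gs")
    if g in (0, 5):
        if not allow_extremes:
            raise ValueError(f"unsupported gait score {g}: only raw scores 1-4 are classed")
        warnings.warn(f"gait score {g} folded into {'GS1' if g == 0 else 'GS3+'}")
        return "GS1" if g == 0 else "GS3+"
    return {1: "GS1", 2: "GS2", 3: "GS3+", 4: "GS3+"}[g]


def classify_population(phenotypes: pd.DataFrame, allow_extremes: bool = False) -> pd.DataFrame:
    """Classify every bird of a phenotype table.

    Returns a DataFrame ``bird_id,gs_class,hb_class,fpd_class,weight_g``.
    """
    missing = set(PHENOTYPE_COLUMNS) - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    out = pd.DataFrame({
        "bird_id": phenotypes["bird_id"],
        "gs_class": [classify_gs(g, allow_extremes) for g in phenotypes["gs"]],
        "hb_class": [classify_hb(l, r) for l, r in zip(phenotypes["hb_left"], phenotypes["hb_right"])],
        "fpd_class": [classify_fpd(l, r) for l, r in zip(phenotypes["fpd_left"], phenotypes["fpd_right"])],
        "weight_g": phenotypes["weight_g"].astype(float),
    })
    if (out["weight_g"] <= 0).any():
        raise ValueError("non-positive body weight in phenotype table")
    return out


def summarize_population(classified: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary per GS class: n, %, weight mean +/- SE, and
    HB-/FPD-class counts with within-GS-class percentages.

    One row per (GS class, variable, level); percentages within a GS class
    sum to 100 for each variable.
    """
    if classified.empty:
        raise ValueError("empty classified table")
    n_total = len(classified)
    rows = []
    for gs in GS_CLASSES:
        sub = classified[classified["gs_class"] == gs]
        n = len(sub)
        rows.append({
            "gs_class": gs, "variable": "n", "level": "", "count": n,
            "percent": 100 * n / n_total,
            "mean": np.nan, "se": np.nan,
        })
        if n:
            w = sub["weight_g"].to_numpy(float)
            rows.append({
                "gs_class": gs, "variable": "weight_g", "level": "", "count": n,
                "percent": np.nan,
                "mean": w.mean(),
                "se": w.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            })
        for var, levels in (("hb_class", HB_CLASSES), ("fpd_class", FPD_CLASSES)):
            for lev in levels:
                k = int((sub[var] == lev).sum())
                rows.append({
                    "gs_class": gs, "variable": var, "level": lev, "count": k,
                    "percent": 100 * k / n if n else np.nan,
                    "mean": np.nan, "se": np.nan,
                })
    return pd.DataFrame(rows)


def format_summary(summary: pd.DataFrame) -> str:
    """Aligned-text rendering of :func:`summarize_population` output."""
    lines = [f"{'GS':6} {'variable':10} {'level':6} {'count':>6} {'percent':>8} {'mean':>9} {'se':>7}"]
    for _, r in summary.iterrows():
        pct = f"{r['percent']:.1f}" if np.isfinite(r["percent"]) else ""
        mean = f"{r['mean']:.1f}" if np.isfinite(r["mean"]) else ""
        se = f"{r['se']:.1f}" if np.isfinite(r["se"]) else ""
        lines.append(
            f"{r['gs_class']:6} {r['variable']:10} {r['level']:6} {int(r['count']):>6} {pct:>8} {mean:>9} {se:>7}"
        )
    return "\n".join(lines)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns: {sorted(missing)}")
    return df


def write_classified(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
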