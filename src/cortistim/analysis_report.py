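"""Summary products of a threshold campaign.

Region minima tables, excited-fraction (empirical CDF) curves, sensitivity
comparisons between campaign arms, spatial threshold maps along the cortical
path and initiation-site frequency tables.  All operations consume the
record table produced by the threshold pipeline (one row per neuron x
polarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ComparisonError, InputError
from .scenario_geometry import REGION_LABELS

__all__ = [
    "RegionSummary",
    "ExcitedFractionCurve",
    "SensitivityReport",
    "summarize_regions",
    "excited_fraction",
    "crossing_amplitudes",
    "compare_sensitivity",
    "spatial_extent_map",
    "asymmetry_index",
    "initiation_summary",
]

CLINICAL_LIMIT_MA = 20.0


@dataclass
class RegionSummary:
    """Minimum thresholds per region x layer x polarity."""

    table: pd.DataFrame  # columns: layer, polarity, region, min_threshold_ma,
    # n_excitable, n_under_20ma
    overall: pd.DataFrame  # per layer x polarity: min + argmin region(s)


def summarize_regions(records: pd.DataFrame,
                      clinical_limit_ma: float = CLINICAL_LIMIT_MA
                      ) -> RegionSummary:
    """Per-cell minima and the region(s) attaining the overall minimum."""
    rows = []
    overall = []
    for (layer, pol), g in records.groupby(["layer", "polarity"]):
        for region in REGION_LABELS:
            sel = g[(g["region"] == region) & g["excitable"]]
            rows.append({
                "layer": layer, "polarity": pol, "region": region,
                "min_threshold_ma": (float(sel["threshold_ma"].min())
                                     if len(sel) else np.nan),
                "n_excitable": int(len(sel)),
                "n_under_20ma": int(
                    (sel["threshold_ma"] <= clinical_limit_ma).sum()),
            })
        exc = g[g["excitable"]]
        if len(exc):
            mn = float(exc["threshold_ma"].min())
            argmin = sorted(set(
                exc.loc[exc["threshold_ma"] == mn, "region"]))
            overall.append({"layer": layer, "polarity": pol,
                            "min_threshold_ma": mn,
                            "regions": "/".join(argmin)})
        else:
            overall.append({"layer": layer, "polarity": pol,
                            "min_threshold_ma": np.nan, "regions": ""})
    return RegionSummary(table=pd.DataFrame(rows),
                         overall=pd.DataFrame(overall))


@dataclass
class ExcitedFractionCurve:
    """Fraction of neurons with threshold <= amplitude, per layer/polarity."""

    amplitudes: np.ndarray
    fractions: dict  # (layer, polarity) -> np.ndarray

    def fraction_at(self, layer: str, polarity: str, amplitude: float) -> float:
        f = self.fractions[(layer, polarity)]
        return float(np.interp(amplitude, self.amplitudes, f))


def excited_fraction(records: pd.DataFrame,
                     amplitudes: np.ndarray | None = None
                     ) -> ExcitedFractionCurve:
    """Empirical CDF of thresholds; non-excitable neurons never count."""
    if amplitudes is None:
        amplitudes = np.arange(0.0, 101.0, 1.0)
    amplitudes = np.asarray(amplitudes, float)
    fractions = {}
    for (layer, pol), g in records.groupby(["layer", "polarity"]):
        thr = g["threshold_ma"].to_numpy()
        n = len(g)
        if n == 0:
            continue
        frac = np.array([
            np.sum(thr[np.isfinite(thr)] <= a) / n for a in amplitudes])
        fractions[(layer, pol)] = frac
    return ExcitedFractionCurve(amplitudes=amplitudes, fractions=fractions)


def crossing_amplitudes(curve: ExcitedFractionCurve, layer: str,
                        pol_a: str = "anodal", pol_b: str = "cathodal"
                        ) -> np.ndarray:
    """Amplitudes where the two polarity curves cross (b overtakes a)."""
    fa = curve.fractions.get((layer, pol_a))
    fb = curve.fractions.get((layer, pol_b))
    if fa is None or fb is None:
        raise InputError(f"missing curves for layer {layer!r}")
    d = fb - fa
    sign_change = np.flatnonzero((d[:-1] <= 0) & (d[1:] > 0))
    return curve.amplitudes[sign_change + 1]


@dataclass
class SensitivityReport:
    """Percent threshold differences between two matched campaign arms."""

    mean_percent: float
    max_percent: float
    n_compared: int
    n_discordant: int  # excitability flags that disagree between arms
    per_neuron: pd.DataFrame = field(repr=False, default=None)


def compare_sensitivity(records_a: pd.DataFrame, records_b: pd.DataFrame,
                        symmetric: bool = False) -> SensitivityReport:
    """|t_a - t_b| / t_a * 100 averaged over co-excitable neurons.

    ``symmetric=True`` uses the mean of both thresholds as the denominator
    instead of arm A (the baseline convention is a documented choice).
    """
    keys = ["neuron", "layer", "polarity"]
    a = records_a.set_index(keys)
    b = records_b.set_index(keys)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ComparisonError("record sets share no neuron ids")
    a = a.loc[common]
    b = b.loc[common]
    both = a["excitable"].to_numpy() & b["excitable"].to_numpy()
    discordant = int((a["excitable"].to_numpy()
                      != b["excitable"].to_numpy()).sum())
    ta = a["threshold_ma"].to_numpy()[both]
    tb = b["threshold_ma"].to_numpy()[both]
    denom = 0.5 * (ta + tb) if symmetric else ta
    pct = np.abs(ta - tb) / denom * 100.0
    per = pd.DataFrame({"threshold_a": ta, "threshold_b": tb,
                        "percent": pct},
                       index=common[both])
    return SensitivityReport(
        mean_percent=float(pct.mean()) if len(pct) else np.nan,
        max_percent=float(pct.max()) if len(pct) else np.nan,
        n_compared=int(both.sum()), n_discordant=discordant, per_neuron=per)


def spatial_extent_map(records: pd.DataFrame,
                       clinical_limit_ma: float = CLINICAL_LIMIT_MA
                       ) -> pd.DataFrame:
    """Threshold per soma arc position with the sub-20 mA contour flag."""
    out = records.copy()
    out["under_clinical"] = (out["excitable"]
                             & (out["threshold_ma"] <= clinical_limit_ma))
    return out[["neuron", "layer", "polarity", "region", "arc", "x", "y", "z",
                "threshold_ma", "under_clinical"]]


def map_mirror_asymmetry(records: pd.DataFrame, layer: str,
                         polarity: str) -> float:
    """Max relative threshold mismatch between mirror-paired somata.

    Pairs are formed by arc position s <-> L - s (same plane); only pairs
    excitable on both sides participate.
    """
    g = records[(records["layer"] == layer)
                & (records["polarity"] == polarity)].copy()
    if len(g) == 0:
        raise InputError("no records for the requested layer/polarity")
    total = g["arc"].max() + g["arc"].min()
    worst = 0.0
    for _, row in g.iterrows():
        mirror_arc = total - row["arc"]
        cand = g[(np.abs(g["arc"] - mirror_arc) < 1e-6)
                 & (g["plane"] == row["plane"])]
        if len(cand) != 1:
            continue
        other = cand.iloc[0]
        if not (row["excitable"] and other["excitable"]):
            if row["excitable"] != other["excitable"]:
                worst = max(worst, 1.0)
            continue
        rel = abs(row["threshold_ma"] - other["threshold_ma"]) / max(
            row["threshold_ma"], other["threshold_ma"])
        worst = max(worst, float(rel))
    return worst


def asymmetry_index(records: pd.DataFrame, layer: str, polarity: str) -> float:
    """Ratio of minimum thresholds on the two sides of the fold.

    Far side (OB/OL/OC, standing in for the central-sulcus bank of a
    realistic model) over near side (C/L/B).  Exactly 1 for a symmetric slab
    campaign with a centred electrode; departs from 1 for the asymmetric
    surrogate.
    """
    g = records[(records["layer"] == layer)
                & (records["polarity"] == polarity) & records["excitable"]]
    near = g[g["region"].isin(("C", "L", "B"))]["threshold_ma"]
    far = g[g["region"].isin(("OB", "OL", "OC"))]["threshold_ma"]
    if len(near) == 0 or len(far) == 0:
        return np.nan
    return float(far.min() / near.min())


def initiation_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Normalized initiation-category frequencies per layer/polarity/region."""
    fired = records[records["excitable"] & (records["init_category"] != "")]
    if len(fired) == 0:
        return pd.DataFrame(columns=["layer", "polarity", "region",
                                     "category", "count", "fraction",
                                     "dominant"])
    rows = []
    for (layer, pol, region), g in fired.groupby(
            ["layer", "polarity", "region"]):
        counts = g["init_category"].value_counts()
        dominant = counts.index[0]
        for cat, cnt in counts.items():
            rows.append({"layer": layer, "polarity": pol, "region": region,
                         "category": cat, "count": int(cnt),
                         "fraction": float(cnt / len(g)),
                         "dominant": cat == dominant})
    return pd.DataFrame(rows)


def dominant_initiation(records: pd.DataFrame, layer: str,
                        polarity: str | None = None,
                        region: str | None = None) -> str:
    """Most frequent initiation category over the selected records."""
    sel = records[records["excitable"] & (records["init_category"] != "")
                  & (records["layer"] == layer)]
    if polarity is not None:
        sel = sel[sel["polarity"] == polarity]
    if region is not None:
        sel = sel[sel["region"] == region]
    if len(sel) == 0:
        return ""
    return sel["init_category"].value_counts().index[0]
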