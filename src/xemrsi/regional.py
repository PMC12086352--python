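"""Ventilation defect percentage, lobe-wise summaries, and group statistics.

The porcine lung has six lobes — R1 right cranial, R2 right middle, R3
right caudal, R4 right accessory, L1 left cranial, L2 left caudal —
given as an integer atlas volume.  Regional tables hold one row per
(animal, fio2, lobe, metric); group comparisons are a paired t-test
between the two oxygen levels and a two-factor ANOVA (region x oxygen,
with interaction) on lobe-level animal means.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .maps import QuantMaps
from .synthetic import LOBE_LABELS

__all__ = [
    "LobeAtlas",
    "segment_ventilated",
    "compute_vdp",
    "regional_summaries",
    "paired_t",
    "two_way_anova",
]


@dataclass
class LobeAtlas:
    """Integer label volume with a label -> lobe-name map."""

    labels: np.ndarray
    label_map: dict = field(default_factory=lambda: dict(LOBE_LABELS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.label_map)
        if unknown:
            raise ValueError(f"atlas contains unknown labels {sorted(unknown)}")

    def lobes(self):
        return list(self.label_map.items())


def segment_ventilated(vent: np.ndarray, threshold_frac: float = 0.10) -> np.ndarray:
    """Ventilated voxels: intensity >= threshold_frac * max intensity."""
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    vent = np.asarray(vent, dtype=float)
    vmax = vent.max()
    if vmax <= 0:
        raise ValueError("ventilation volume is empty (all-zero)")
    return vent >= threshold_frac * vmax


def compute_vdp(vv_voxels: int, tcv_voxels: int) -> float:
    """Ventilation defect percentage: (1 - VV/TCV) * 100.

    VV is expected to be the ventilated volume already intersected with
    the thoracic cavity mask, so the result lies in [0, 100].
    """
    if tcv_voxels <= 0:
        raise ValueError("TCV must be positive")
    if vv_voxels > tcv_voxels:
        raise ValueError("VV exceeds TCV; intersect VV with the cavity mask first")
    return (1.0 - vv_voxels / tcv_voxels) * 100.0


def vdp_from_volumes(vent: np.ndarray, tcv_mask: np.ndarray,
                     threshold_frac: float = 0.10) -> float:
    """VDP directly from a ventilation volume and an anatomical mask."""
    vv = segment_ventilated(vent, threshold_frac) & tcv_mask
    return compute_vdp(int(vv.sum()), int(tcv_mask.sum()))


def regional_summaries(
    qmaps: QuantMaps | dict,
    atlas: LobeAtlas,
    mask: np.ndarray | None = None,
    extra: dict | None = None,
) -> pd.DataFrame:
    """Per-lobe mean/SD/voxel-count for every metric, within the mask.

    Empty lobes yield a row with ``n_voxels`` 0 and NaN statistics.
    ``qmaps`` may be a QuantMaps or a plain {metric: volume} dict.
    """
    maps = qmaps.maps if isinstance(qmaps, QuantMaps) else qmaps
    if mask is None:
        mask = qmaps.mask if isinstance(qmaps, QuantMaps) else np.ones(
            next(iter(maps.values())).shape, dtype=bool
        )
    if atlas.labels.shape != mask.shape:
        raise ValueError("atlas geometry does not match the maps")
    rows = []
    for lab, name in atlas.lobes():
        sel = (atlas.labels == lab) & mask
        for metric, vol in maps.items():
            vals = vol[sel]
            vals = vals[np.isfinite(vals)]
            rows.append(
                dict(
                    lobe=name,
                    metric=metric,
                    mean=float(vals.mean()) if vals.size else np.nan,
                    sd=float(vals.std(ddof=1)) if vals.size > 1 else (0.0 if vals.size else np.nan),
                    n_voxels=int(vals.size),
                    **(extra or {}),
                )
            )
    return pd.DataFrame(rows)


def paired_t(a, b):
    """Two-sided paired t-test; returns (t, p, df).

    Zero variance of the differences is flagged with t=0 (identical
    vectors) or +-inf (constant nonzero difference), p accordingly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    df = len(d) - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0, df
        return float(np.sign(d.mean()) * np.inf), 0.0, df
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), df


def two_way_anova(
    table: pd.DataFrame,
    value: str = "mean",
    region: str = "lobe",
    oxygen: str = "fio2",
):
    """Two-factor ANOVA with interaction on a long-format table.

    Balanced designs use the closed-form decomposition; unbalanced ones
    fall back to statsmodels OLS with partial (type II) sums of squares.
    Returns a dict with F and p for region, oxygen, and the interaction.
    Raises if any cell is empty or if the interaction is untestable
    (single observation per cell → zero residual df).
    """
    df = table[[region, oxygen, value]].dropna()
    counts = df.groupby([region, oxygen], observed=True)[value].count()
    regions = df[region].unique()
    oxygens = df[oxygen].unique()
    if len(regions) < 2 or len(oxygens) < 2:
        raise ValueError("need at least two levels of each factor")
    full = {(r, o) for r in regions for o in oxygens}
    missing = full - set(counts.index)
    if missing:
        raise ValueError(f"empty design cell(s): {sorted(missing)}")
    n_cell = counts.unique()
    N = len(df)
    a, b = len(regions), len(oxygens)
    df_e = N - a * b
    if df_e <= 0:
        raise ValueError(
            "single observation per cell: interaction untestable (zero residual df)"
        )

    if len(n_cell) == 1:
        # balanced closed form
        y = df[value].to_numpy()
        grand = y.mean()
        mr = df.groupby(region, observed=True)[value].mean()
        mo = df.groupby(oxygen, observed=True)[value].mean()
        mc = df.groupby([region, oxygen], observed=True)[value].mean()
        n = int(n_cell[0])
        ss_r = n * b * float(((mr - grand) ** 2).sum())
        ss_o = n * a * float(((mo - grand) ** 2).sum())
        cell_dev = mc - mr.reindex(mc.index.get_level_values(0)).to_numpy() \
                      - mo.reindex(mc.index.get_level_values(1)).to_numpy() + grand
        ss_i = n * float((cell_dev**2).sum())
        fitted = mc.loc[list(zip(df[region], df[oxygen]))].to_numpy()
        ss_e = float(((y - fitted) ** 2).sum())
        df_r, df_o, df_i = a - 1, b - 1, (a - 1) * (b - 1)
        mse = ss_e / df_e
        out = {}
        for name, ss, dfn in (("region", ss_r, df_r), ("oxygen", ss_o, df_o),
                              ("interaction", ss_i, df_i)):
            if mse <= 0:
                out[f"F_{name}"] = np.inf if ss > 0 else 0.0
                out[f"p_{name}"] = 0.0 if ss > 0 else 1.0
                out["degenerate"] = True
            else:
                F = (ss / dfn) / mse
                out[f"F_{name}"] = float(F)
                out[f"p_{name}"] = float(stats.f.sf(F, dfn, df_e))
        out.setdefault("degenerate", False)
        out["df_error"] = df_e
        return out

    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    d2 = df.rename(columns={value: "y", region: "reg", oxygen: "oxy"})
    model = smf.ols("y ~ C(reg) * C(oxy)", data=d2).fit()
    tab = anova_lm(model, typ=2)
    return {
        "F_region": float(tab.loc["C(reg)", "F"]),
        "p_region": float(tab.loc["C(reg)", "PR(>F)"]),
        "F_oxygen": float(tab.loc["C(oxy)", "F"]),
        "p_oxygen": float(tab.loc["C(oxy)", "PR(>F)"]),
        "F_interaction": float(tab.loc["C(reg):C(oxy)", "F"]),
        "p_interaction": float(tab.loc["C(reg):C(oxy)", "PR(>F)"]),
        "degenerate": False,
        "df_error": int(model.df_resid),
    }
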