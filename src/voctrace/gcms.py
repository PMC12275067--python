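"""Kovats retention indexing, internal-standard quantification, rOAV scoring
and the three-criterion differential-marker screen.

The screen flags a compound as an origin-discriminating flavor marker when it
simultaneously (i) carries multivariate discriminative weight (VIP > 1 from an
OPLS-DA model of the concentration matrix), (ii) is odor-active (class-mean
rOAV >= 1 in at least one origin), and (iii) differs significantly across
origins (Welch one-way ANOVA p <= alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import VocTable

#: Retention-index agreement window against reference values (index units).
RI_TOLERANCE = 30.0


@dataclass(frozen=True)
class InternalStandard:
    """Spiked isotope internal standard used for relative quantification.

    v_s: volume added (uL); c_s: concentration (ug/mL); mass_g: analyzed
    sample mass (g); i_s: internal-standard peak area (scalar shared by all
    samples, or a mapping sample_id -> area).
    """

    v_s: float = 20.0
    c_s: float = 10.0
    mass_g: float = 0.5
    i_s: float | dict[str, float] = 1.0e6

    def __post_init__(self) -> None:
        if self.v_s <= 0 or self.c_s <= 0 or self.mass_g <= 0:
            raise ValueError("internal-standard parameters must be positive")

    def area_for(self, sample_id: str) -> float:
        if isinstance(self.i_s, dict):
            return self.i_s[sample_id]
        return float(self.i_s)


@dataclass(frozen=True)
class AlkaneLadder:
    """Retention times of the C7–C40 n-alkane reference blend."""

    carbon_numbers: np.ndarray
    rt_min: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.carbon_numbers, dtype=int)
        rt = np.asarray(self.rt_min, dtype=float)
        object.__setattr__(self, "carbon_numbers", z)
        object.__setattr__(self, "rt_min", rt)
        if z.size != rt.size or z.size < 2:
            raise ValueError("ladder needs matching carbon numbers and rts")
        if (np.diff(z) <= 0).any() or (np.diff(rt) <= 0).any():
            raise ValueError("ladder must be strictly increasing")
        if z.min() < 7:
            raise ValueError("carbon numbers start at C7")


def retention_index(rt_x: float, ladder: AlkaneLadder) -> float:
    """Kovats-style retention index by linear interpolation between the
    bracketing n-alkanes: RI = 100*Z + 100*(TRx - TRz)/(TRz+1 - TRz)."""
    rt = ladder.rt_min
    if rt_x < rt[0] or rt_x > rt[-1]:
        raise ValueError(f"rt {rt_x} min outside ladder span [{rt[0]}, {rt[-1]}]")
    j = int(np.searchsorted(rt, rt_x, side="right"))
    if j == rt.size:  # exactly at the last alkane
        return 100.0 * ladder.carbon_numbers[-1]
    z = ladder.carbon_numbers[j - 1] if j > 0 else ladder.carbon_numbers[0]
    if j == 0 or rt_x == rt[j - 1]:
        return 100.0 * float(z)
    frac = (rt_x - rt[j - 1]) / (rt[j] - rt[j - 1])
    return 100.0 * float(z) + 100.0 * frac


def ri_match(ri_obs: float, ri_ref: float, tolerance: float = RI_TOLERANCE) -> bool:
    """True when an observed RI agrees with a reference within +/-tolerance."""
    if not (np.isfinite(ri_obs) and np.isfinite(ri_ref)):
        raise ValueError("retention indices must be finite")
    return abs(ri_obs - ri_ref) <= tolerance


def quantify(voc: VocTable, istd: InternalStandard) -> VocTable:
    """Internal-standard relative quantification, ug/g:

    X_i = (V_s * C_s / m) * (I_i / I_s) * 1e-3
    """
    data = voc.data.copy()
    i_s = np.array([istd.area_for(s) for s in data["sample_id"]])
    bad = sorted(set(data.loc[i_s <= 0, "sample_id"]))
    if bad:
        raise ZeroDivisionError(f"internal-standard area <= 0 for samples: {bad}")
    factor = istd.v_s * istd.c_s / istd.mass_g * 1e-3
    data["conc"] = factor * data["peak_area"].to_numpy() / i_s
    return VocTable(data)


def roav(conc: float | np.ndarray, threshold: float | np.ndarray) -> float | np.ndarray:
    """Relative odor activity value: concentration over odor threshold."""
    threshold = np.asarray(threshold, dtype=float)
    if (threshold <= 0).any():
        raise ValueError("odor threshold must be > 0")
    out = np.asarray(conc, dtype=float) / threshold
    return out.item() if out.ndim == 0 else out


def classify_contribution(roav_value: float) -> str:
    """Flavor-contribution category: >=1 contributes, >=100 dominates."""
    if roav_value < 0:
        raise ValueError("rOAV must be >= 0")
    if roav_value >= 100:
        return "key_contributor"
    if roav_value >= 1:
        return "contributor"
    return "none"


def welch_anova_p(groups: list[np.ndarray]) -> float:
    """p-value of Welch's heteroscedastic one-way ANOVA."""
    from scipy import stats

    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    # guard against numerically-zero variance (identical replicate values)
    tiny = (1e-12 * np.maximum(1.0, np.abs(m))) ** 2
    if (v <= tiny).all():
        raise ValueError("zero variance in every group")
    w = n / v
    mw = (w * m).sum() / w.sum()
    k = len(groups)
    a = ((w * (m - mw) ** 2).sum()) / (k - 1)
    lam = 3.0 * ((1 - w / w.sum()) ** 2 / (n - 1)).sum() / (k**2 - 1)
    f = a / (1.0 + 2.0 * lam * (k - 2) / 3.0)
    df2 = 1.0 / lam
    return float(stats.f.sf(f, k - 1, df2))


@dataclass
class MarkerScreenResult:
    """Per-compound screening table plus the flagged marker list."""

    table: pd.DataFrame  # compound_id, vip, p_value, roav per class, flags
    flagged: list[str]  # compound ids passing all three criteria, by VIP desc
    alpha: float


def screen_markers(
    voc: VocTable,
    vip: pd.Series,
    alpha: float = 0.05,
    bh: bool = False,
    conc_column: str = "conc",
) -> MarkerScreenResult:
    """Three-criterion differential-marker screen.

    ``vip`` holds per-compound VIP scores from a fitted OPLS-DA model of the
    samples-x-compounds concentration matrix.  rOAV is computed on the class
    mean concentration; the overall flag is the conjunction VIP > 1 AND
    max-class rOAV >= 1 AND p <= alpha.  ``bh=True`` applies
    Benjamini–Hochberg correction to the ANOVA p-values before thresholding.
    """
    data = voc.data
    if conc_column not in data.columns:
        raise ValueError(f"no {conc_column!r} column; run quantify first")
    classes = list(dict.fromkeys(data["origin"]))
    if len(classes) < 2:
        raise ValueError("need >= 2 origin classes")
    counts = data.groupby("origin")["sample_id"].nunique()
    if (counts < 3).any():
        raise ValueError("need >= 3 samples per class")

    rows = []
    for cid, grp in data.groupby("compound_id", sort=False):
        threshold = grp["threshold"].iloc[0]
        groups = [grp.loc[grp["origin"] == c, conc_column].to_numpy() for c in classes]
        row = {"compound_id": cid, "vip": float(vip.get(cid, np.nan))}
        try:
            row["p_value"] = welch_anova_p(groups)
        except ValueError as exc:
            warnings.warn(f"{cid}: p-value undefined ({exc}); compound excluded")
            row["p_value"] = np.nan
        for c, g in zip(classes, groups):
            row[f"roav_{c}"] = float(roav(g.mean(), threshold))
        row["roav_max"] = max(row[f"roav_{c}"] for c in classes)
        rows.append(row)
    table = pd.DataFrame(rows)

    p = table["p_value"].to_numpy()
    if bh:
        from statsmodels.stats.multitest import multipletests

        ok = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if ok.any():
            adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        table["p_adj"] = adj
        p_crit = adj
    else:
        p_crit = p

    table["pass_vip"] = table["vip"] > 1.0
    table["pass_roav"] = table["roav_max"] >= 1.0
    table["pass_p"] = np.where(np.isfinite(p_crit), p_crit <= alpha, False)
    table["flagged"] = table["pass_vip"] & table["pass_roav"] & table["pass_p"]

    flagged = (
        table.loc[table["flagged"]]
        .sort_values("vip", ascending=False)["compound_id"]
        .tolist()
    )
    return MarkerScreenResult(table=table, flagged=flagged, alpha=alpha)
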