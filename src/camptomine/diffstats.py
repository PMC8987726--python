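"""Differential screening of metabolites and genes.

Implements the study's threshold rules — fold change ≥ 2 or ≤ 0.5 with
VIP > 2 and P < 0.05 for discriminating metabolites (a VIP > 1 preset for
the counted up/down lists), |log2FC| > 0 with BH-adjusted P < 0.05 for
differential genes — plus PLS-DA VIP scoring, ratio-based pathway
enrichment with a one-sided hypergeometric test, and 2^-ΔΔCt expression
ratios.

Intensities are natural-log transformed (log(x+1)) before the Welch
t-test and autoscaled before PLS-DA.  Gene expression uses log2(x+1).
The gene screen substitutes a Welch test on log2 counts for a negative
binomial model: the threshold rule and downstream mining are the point
here, and externally computed per-gene statistics can be supplied
instead (see :func:`screen_from_stats`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 1e-9


@dataclass(frozen=True)
class ScreenThresholds:
    """Cutoffs for the metabolite and gene screens.

    ``fc_high``/``fc_low`` of None disable the fold-change magnitude
    criterion (direction then follows the FC sign alone), as in the
    counted up/down metabolite lists; ``vip_min`` of None disables the
    VIP criterion.
    """

    fc_high: Optional[float] = 2.0
    fc_low: Optional[float] = 0.5
    vip_min: Optional[float] = 2.0
    p_max: float = 0.05
    deg_abs_log2fc: float = 0.0
    deg_padj: float = 0.05

    def __post_init__(self) -> None:
        if (self.fc_high is None) != (self.fc_low is None):
            raise ValueError("set both or neither of fc_high/fc_low")
        if self.fc_high is not None and not (self.fc_low < 1.0 < self.fc_high):
            raise ValueError("need fc_low < 1 < fc_high")
        if not (0.0 < self.p_max < 1.0):
            raise ValueError("p_max must lie in (0, 1)")


#: Discriminating metabolites: FC ≥ 2 or ≤ 0.5, VIP > 2, P < 0.05.
DISCRIMINATING = ScreenThresholds(vip_min=2.0)
#: The counted up/down lists: VIP > 1, P < 0.05, direction by FC sign.
COUNTED_LISTS = ScreenThresholds(fc_high=None, fc_low=None, vip_min=1.0)


def _split(m: pd.DataFrame, conditions: Mapping[str, str],
           cond_a: str, cond_b: str) -> Tuple[pd.DataFrame, pd.DataFrame]:
    cols_a = [c for c in m.columns if conditions.get(c) == cond_a]
    cols_b = [c for c in m.columns if conditions.get(c) == cond_b]
    if not cols_a or not cols_b:
        missing = cond_a if not cols_a else cond_b
        raise ValueError(f"condition {missing!r} has no samples in the matrix")
    return m[cols_a], m[cols_b]


def fold_change(m: pd.DataFrame, conditions: Mapping[str, str],
                cond_a: str, cond_b: str) -> pd.DataFrame:
    """Per-feature FC = mean(a)/mean(b) on raw intensities, plus log2FC.

    A pseudocount guards zero denominators (and the log of zero ratios).
    """
    a, b = _split(m, conditions, cond_a, cond_b)
    fc = (a.mean(axis=1) + 0) / (b.mean(axis=1) + PSEUDOCOUNT)
    log2fc = np.log2(fc + PSEUDOCOUNT)
    return pd.DataFrame({"fc": fc, "log2fc": log2fc})


def welch_t(m: pd.DataFrame, conditions: Mapping[str, str],
            cond_a: str, cond_b: str,
            log_transform: bool = True) -> pd.Series:
    """Two-sided Welch t-test per feature on log(x+1) intensities.

    Features constant in both groups get p = 1 with a warning.
    """
    a, b = _split(m, conditions, cond_a, cond_b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 samples per condition")
    xa, xb = (np.log1p(a.values), np.log1p(b.values)) if log_transform \
        else (a.values.astype(float), b.values.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(xa, xb, axis=1, equal_var=False)
    p = pd.Series(p, index=m.index, name="p_value")
    const = (np.ptp(xa, axis=1) == 0) & (np.ptp(xb, axis=1) == 0)
    if const.any():
        warnings.warn(f"{const.sum()} features constant in both groups; p=1")
        p[const] = 1.0
    return p.fillna(1.0)


def plsda_vip(m: pd.DataFrame, labels: Mapping[str, str],
              n_components: int = 2) -> pd.Series:
    """Variable importance in projection from a PLS-DA fit.

    Features are autoscaled; the response is the centered class indicator
    matrix.  VIP_j = sqrt(p · Σ_a SS_a w_ja² / Σ_a SS_a) with per-component
    unit-norm weights w, so Σ_j VIP_j² = p exactly.  Zero-variance features
    are excluded (VIP reported as 0) with a warning.
    """
    classes = sorted(set(labels[c] for c in m.columns))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    X = m.T.values.astype(float)  # samples × features
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} zero-variance features excluded "
                      "from PLS-DA (VIP set to 0)")
    Xs = (X[:, keep] - X[:, keep].mean(0)) / sd[keep]
    y = np.array([labels[c] for c in m.columns])
    if len(classes) == 2:
        Y = (y == classes[1]).astype(float)[:, None]
    else:
        Y = np.column_stack([(y == c).astype(float) for c in classes])
    Y = Y - Y.mean(0)
    ncomp = min(n_components, Xs.shape[1], Xs.shape[0] - 1)
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(Xs, Y)
    T = pls.x_scores_          # n × a
    W = pls.x_weights_         # p × a, unit-norm columns
    Q = pls.y_loadings_        # q × a
    ss = np.sum(T ** 2, axis=0) * np.sum(Q ** 2, axis=0)  # Y-variance per comp
    p_feat = W.shape[0]
    vip_kept = np.sqrt(p_feat * (W ** 2 @ ss) / ss.sum())
    vip = np.zeros(m.shape[0])
    vip[keep] = vip_kept
    return pd.Series(vip, index=m.index, name="vip")


def screen(stats: pd.DataFrame,
           thresholds: ScreenThresholds = DISCRIMINATING) -> pd.DataFrame:
    """Apply the metabolite screening rule to a per-feature stats table.

    ``stats`` needs columns fc and p_value, plus vip unless the threshold
    preset disables it.  Adds a ``direction`` column in {up, down, ns}.
    """
    out = stats.copy()
    ok = out["p_value"] < thresholds.p_max
    if thresholds.vip_min is not None:
        ok &= out["vip"] > thresholds.vip_min
    if thresholds.fc_high is not None:
        up = ok & (out["fc"] >= thresholds.fc_high)
        down = ok & (out["fc"] <= thresholds.fc_low)
    else:
        up = ok & (out["fc"] > 1.0)
        down = ok & (out["fc"] < 1.0)
    out["direction"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out


def metabolite_screen(m: pd.DataFrame, conditions: Mapping[str, str],
                      cond_a: str, cond_b: str,
                      thresholds: ScreenThresholds = DISCRIMINATING,
                      n_components: int = 2) -> pd.DataFrame:
    """FC + Welch + PLS-DA VIP + threshold rule, in one call."""
    sub_conditions = {c: conditions[c] for c in m.columns
                      if conditions.get(c) in (cond_a, cond_b)}
    cols = list(sub_conditions)
    stats = fold_change(m[cols], sub_conditions, cond_a, cond_b)
    stats["p_value"] = welch_t(m[cols], sub_conditions, cond_a, cond_b)
    stats["vip"] = plsda_vip(m[cols], sub_conditions, n_components)
    return screen(stats, thresholds)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def deg_screen(expr: pd.DataFrame, conditions: Mapping[str, str],
               cond_a: str, cond_b: str,
               thresholds: ScreenThresholds = ScreenThresholds()
               ) -> pd.DataFrame:
    """Differential-gene screen: |log2FC| > 0 and BH-adjusted p < 0.05.

    Welch test on log2(x+1) expression with BH adjustment across genes.
    """
    stats = fold_change(expr, conditions, cond_a, cond_b)
    a, b = _split(expr, conditions, cond_a, cond_b)
    xa, xb = np.log2(a.values + 1.0), np.log2(b.values + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sps.ttest_ind(xa, xb, axis=1, equal_var=False)
    stats["p_value"] = pd.Series(p, index=expr.index).fillna(1.0)
    stats["adjusted_p"] = bh_adjust(stats["p_value"].values)
    sig = ((stats["adjusted_p"] < thresholds.deg_padj)
           & (stats["log2fc"].abs() > thresholds.deg_abs_log2fc))
    stats["direction"] = np.where(
        sig & (stats["log2fc"] > 0), "up",
        np.where(sig & (stats["log2fc"] < 0), "down", "ns"))
    return stats


def screen_from_stats(stats: pd.DataFrame,
                      thresholds: ScreenThresholds = ScreenThresholds()
                      ) -> pd.DataFrame:
    """Apply the gene threshold rule to externally computed statistics
    (columns log2fc and adjusted_p), e.g. from a negative-binomial fit."""
    out = stats.copy()
    sig = ((out["adjusted_p"] < thresholds.deg_padj)
           & (out["log2fc"].abs() > thresholds.deg_abs_log2fc))
    out["direction"] = np.where(
        sig & (out["log2fc"] > 0), "up",
        np.where(sig & (out["log2fc"] < 0), "down", "ns"))
    return out


# ---------------------------------------------------------------------------
# Pathway enrichment
# ---------------------------------------------------------------------------

def read_gmt(path) -> Dict[str, List[str]]:
    """Parse a GMT file: name <tab> description <tab> member ids...."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [p for p in parts[2:] if p]
    return sets


def enrich(differential_ids: Iterable[str], background_ids: Iterable[str],
           pathway_sets: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Ratio-based pathway enrichment with a hypergeometric tail test.

    A pathway passes the ratio criterion when the differential features it
    contains are over-represented relative to background
    (N_MPDM/N_DM > N_MPBM/N_BM); significance is the one-sided
    hypergeometric tail P(X ≥ N_MPDM).  ``enriched`` requires both the
    ratio criterion and p < 0.05.
    """
    diff = set(differential_ids)
    bg = set(background_ids)
    if not diff <= bg:
        raise ValueError("differential ids must be a subset of background")
    n_dm, n_bm = len(diff), len(bg)
    rows = []
    for name, members in pathway_sets.items():
        in_path = set(members) & bg
        n_mpbm = len(in_path)
        n_mpdm = len(in_path & diff)
        ratio_pass = (n_dm > 0 and n_bm > 0
                      and n_mpdm / n_dm > n_mpbm / n_bm)
        p = float(sps.hypergeom.sf(n_mpdm - 1, n_bm, n_mpbm, n_dm)) \
            if n_mpbm else 1.0
        rows.append({"pathway": name, "N_MPDM": n_mpdm, "N_DM": n_dm,
                     "N_MPBM": n_mpbm, "N_BM": n_bm,
                     "ratio_pass": ratio_pass, "p_value": p,
                     "enriched": bool(ratio_pass and p < 0.05)})
    return pd.DataFrame(rows)


def ddct(ct_target: float, ct_ref: float,
         ct_target_cal: float, ct_ref_cal: float) -> float:
    """Relative expression 2^-ΔΔCt against a reference gene and calibrator."""
    ddct_val = (ct_target - ct_ref) - (ct_target_cal - ct_ref_cal)
    return float(2.0 ** (-ddct_val))
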