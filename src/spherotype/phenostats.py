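"""Replicate-stratified phenotype statistics and time-chunk summaries.

Classified object-frames are aggregated into 6-hour time chunks.  For
each (condition, phenotype, chunk) the association between condition and
phenotype is tested with the Cochran-Mantel-Haenszel (CMH) chi-square
over 2x2 tables stratified by biological replicate, so a comparison is
only significant when the effect is present across independent
experiments.  Effect-size homogeneity across replicates is assessed with
the Breslow-Day statistic around the Mantel-Haenszel common odds ratio;
a non-significant result marks a reproducible effect magnitude (the
"black dot" in bubble heatmaps).  Both p-value families receive a
Bonferroni adjustment.  Effects are reported as log2 fold change of the
pooled phenotype proportion relative to control, with the control
condition itself summarized as z-scores across chunks.

CMH uses no continuity correction and Breslow-Day no Tarone adjustment,
matching the defaults of the R routines this readout is modelled on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthgen import HYPER

logger = logging.getLogger(__name__)

DEFAULT_CHUNK_HOURS = 6
DEFAULT_ALPHA = 0.05

SUMMARY_COLUMNS = [
    "condition", "phenotype", "chunk_start", "chunk_end", "p_ctrl",
    "z_ctrl", "log2fc", "cmh_stat", "p_raw", "p_adj", "psi_mh",
    "bd_stat", "bd_p", "bd_p_adj", "homogeneous",
]


@dataclass
class StratTable:
    """2x2xK counts: condition vs control by phenotype, one stratum per
    biological replicate.

    Cell layout per stratum k: a_k = (condition, phenotype+),
    b_k = (condition, phenotype-), c_k = (control, phenotype+),
    d_k = (control, phenotype-).
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    strata: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.a, self.b, self.c, self.d = (
            np.asarray(v, dtype=float) for v in (self.a, self.b, self.c,
                                                 self.d))
        if not (len(self.a) == len(self.b) == len(self.c) == len(self.d)):
            raise ValueError("stratum count vectors differ in length")
        if min(self.a.min(initial=0), self.b.min(initial=0),
               self.c.min(initial=0), self.d.min(initial=0)) < 0:
            raise ValueError("counts must be >= 0")
        keep = self.totals > 0
        if not keep.all():
            logger.info("dropping %d empty stratum/strata",
                        int((~keep).sum()))
            self.a, self.b = self.a[keep], self.b[keep]
            self.c, self.d = self.c[keep], self.d[keep]
            if self.strata:
                self.strata = [s for s, k in zip(self.strata, keep) if k]
        if len(self.a) < 1:
            raise ValueError("need at least one non-empty stratum")

    @property
    def totals(self) -> np.ndarray:
        return self.a + self.b + self.c + self.d

    @property
    def n_strata(self) -> int:
        return len(self.a)


@dataclass
class CMHResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


@dataclass
class BreslowDayResult:
    statistic: float
    pvalue: float
    psi_mh: float
    haldane: bool = False


def cmh_test(table: StratTable) -> CMHResult:
    """Cochran-Mantel-Haenszel chi-square (1 df, no continuity correction).

    statistic = [sum_k (a_k - E_k)]^2 / sum_k V_k with hypergeometric
    mean E_k and variance V_k of the a-cell under the null of no
    association within every stratum.  Degenerate margins (zero total
    variance) give statistic 0 and p = 1, flagged.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    t = table.totals
    r = a + b          # condition row total
    s = a + c          # phenotype+ column total
    e = r * s / t
    with np.errstate(divide="ignore", invalid="ignore"):
        v = r * (c + d) * s * (b + d) / (t ** 2 * (t - 1))
    v = np.where(t > 1, v, 0.0)
    vsum = float(v.sum())
    if vsum <= 0:
        logger.warning("CMH: degenerate margins, returning p = 1")
        return CMHResult(0.0, 1.0, degenerate=True)
    stat = float((a - e).sum() ** 2 / vsum)
    return CMHResult(stat, float(stats.chi2.sf(stat, 1)))


def mantel_haenszel_or(table: StratTable) -> float:
    """Mantel-Haenszel common odds ratio psi-hat."""
    t = table.totals
    num = float((table.a * table.d / t).sum())
    den = float((table.b * table.c / t).sum())
    if den == 0:
        return np.inf if num > 0 else np.nan
    return num / den


def _fitted_a(r: float, s: float, t: float, psi: float) -> float:
    """Fitted a-cell with odds ratio psi and fixed margins (r, s, t).

    Root of (1-psi)*x^2 + [(t-r-s) + psi*(r+s)]*x - psi*r*s = 0 lying in
    the open interval (max(0, r+s-t), min(r, s)).
    """
    lo, hi = max(0.0, r + s - t), min(r, s)
    if psi == 1.0:
        return r * s / t
    qa = 1.0 - psi
    qb = (t - r - s) + psi * (r + s)
    qc = -psi * r * s
    disc = qb * qb - 4 * qa * qc
    sq = np.sqrt(max(disc, 0.0))
    for x in ((-qb + sq) / (2 * qa), (-qb - sq) / (2 * qa)):
        if lo < x < hi:
            return float(x)
    # numerical edge: clamp to the nearest feasible interior point
    return float(np.clip((-qb + sq) / (2 * qa), lo + 1e-9, hi - 1e-9))


def breslow_day(table: StratTable) -> BreslowDayResult:
    """Breslow-Day test of odds-ratio homogeneity across strata.

    Fits the Mantel-Haenszel common odds ratio, computes the fitted
    a-cell per stratum at that odds ratio, and sums the squared
    standardized deviations; chi-square with K-1 df.  No Tarone
    correction.  A degenerate psi-hat (zero denominator or numerator)
    triggers a Haldane 0.5 correction of all cells, flagged in the
    result.
    """
    if table.n_strata < 2:
        raise ValueError("Breslow-Day requires >= 2 strata")
    a, b, c, d = table.a, table.b, table.c, table.d
    psi = mantel_haenszel_or(table)
    haldane = False
    if not np.isfinite(psi) or psi == 0:
        logger.warning("Breslow-Day: degenerate MH odds ratio, applying "
                       "Haldane 0.5 correction")
        haldane = True
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        t = a + b + c + d
        psi = float((a * d / t).sum() / (b * c / t).sum())
    t = a + b + c + d
    r = a + b
    s = a + c
    stat = 0.0
    for k in range(len(a)):
        ak = _fitted_a(float(r[k]), float(s[k]), float(t[k]), psi)
        denom = (1.0 / ak + 1.0 / (r[k] - ak) + 1.0 / (s[k] - ak)
                 + 1.0 / (t[k] - r[k] - s[k] + ak))
        var = 1.0 / denom
        stat += (float(a[k]) - ak) ** 2 / var
    df = table.n_strata - 1
    return BreslowDayResult(float(stat), float(stats.chi2.sf(stat, df)),
                            float(psi), haldane)


def adjust_bonferroni(pvalues, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(pvalues, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of p-values")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# chunk aggregation
# ---------------------------------------------------------------------------

def bin_chunks(labelled: pd.DataFrame,
               chunk_hours: int = DEFAULT_CHUNK_HOURS,
               phenotype: str = HYPER,
               label_column: str = "phenotype_label") -> pd.DataFrame:
    """Aggregate classified object-frames into time chunks per replicate.

    Two layers are produced for each (condition, experiment, chunk):

    * counts ``n_pos`` / ``n_neg`` — each tracked object contributes its
      majority phenotype once per chunk (the counting unit of the CMH
      strata; avoids frame-level pseudo-replication; frame-count ties go
      to the positive phenotype);
    * ``mean_prop`` — the within-chunk mean of per-frame phenotype
      proportions (the displayed quantity).

    Rows without a phenotype label (out-of-focus) are ignored.  A final
    partial chunk is kept and flagged in the log.
    """
    df = labelled.dropna(subset=[label_column]).copy()
    if df.empty:
        return pd.DataFrame(columns=[
            "condition", "experiment", "chunk", "chunk_start", "chunk_end",
            "n_pos", "n_neg", "mean_prop"])
    df["_pos"] = (df[label_column] == phenotype).astype(int)
    max_frame = int(df["frame"].max())
    if max_frame % chunk_hours:
        logger.info("movie length %d h is not a multiple of %d h; final "
                    "partial chunk kept", max_frame, chunk_hours)
    df["chunk"] = (df["frame"] - 1) // chunk_hours

    # counting layer: majority phenotype per tracked object per chunk
    obj = (df.groupby(["condition", "experiment", "well", "chunk",
                       "track_id"], sort=True)["_pos"]
             .agg(["sum", "count"]).reset_index())
    obj["maj_pos"] = (2 * obj["sum"] >= obj["count"]).astype(int)
    counts = (obj.groupby(["condition", "experiment", "chunk"], sort=True)
                 ["maj_pos"].agg(n_pos="sum", n_neg=lambda x: (1 - x).sum())
                 .reset_index())

    # display layer: mean of per-frame proportions within the chunk
    per_frame = (df.groupby(["condition", "experiment", "chunk", "frame"],
                            sort=True)["_pos"].mean().reset_index())
    props = (per_frame.groupby(["condition", "experiment", "chunk"],
                               sort=True)["_pos"].mean()
             .reset_index().rename(columns={"_pos": "mean_prop"}))

    out = counts.merge(props, on=["condition", "experiment", "chunk"])
    out["chunk_start"] = out["chunk"] * chunk_hours + 1
    out["chunk_end"] = np.minimum((out["chunk"] + 1) * chunk_hours,
                                  max_frame)
    out["n_neg"] = out["n_neg"].astype(int)
    return out[["condition", "experiment", "chunk", "chunk_start",
                "chunk_end", "n_pos", "n_neg", "mean_prop"]]


def build_strat_table(binned: pd.DataFrame, condition: str, control: str,
                      chunk: int) -> StratTable:
    """2x2xK table for one condition-vs-control comparison in one chunk."""
    sel = binned[binned["chunk"] == chunk]
    cond = sel[sel["condition"] == condition].set_index("experiment")
    ctrl = sel[sel["condition"] == control].set_index("experiment")
    strata = sorted(set(cond.index) & set(ctrl.index))
    if not strata:
        raise ValueError(
            f"no shared replicates for {condition!r} vs {control!r} "
            f"in chunk {chunk}")
    return StratTable(
        a=[cond.loc[e, "n_pos"] for e in strata],
        b=[cond.loc[e, "n_neg"] for e in strata],
        c=[ctrl.loc[e, "n_pos"] for e in strata],
        d=[ctrl.loc[e, "n_neg"] for e in strata],
        strata=list(strata))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(binned: pd.DataFrame, control: str,
              phenotype: str = HYPER,
              alpha: float = DEFAULT_ALPHA,
              bonferroni_m: int | None = None) -> pd.DataFrame:
    """Per (condition, chunk) statistical summary against control.

    For the control condition only the z-score layer is meaningful: the
    pooled per-replicate proportions are averaged per chunk and z-scored
    across chunks.  For every other condition: pooled log2 fold change,
    CMH statistic and p (Bonferroni-adjusted over the
    conditions x chunks family; the two complementary phenotypes count
    once), MH common odds ratio, Breslow-Day homogeneity (its p adjusted
    over the same family size).
    """
    conditions = sorted(binned["condition"].unique())
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not in data")
    others = [c for c in conditions if c != control]
    chunks = sorted(binned["chunk"].unique())

    ctrl = binned[binned["condition"] == control].copy()
    ctrl["prop"] = ctrl["n_pos"] / (ctrl["n_pos"] + ctrl["n_neg"])
    p_ctrl_chunk = ctrl.groupby("chunk")["prop"].mean()
    mu = p_ctrl_chunk.mean()
    sd = p_ctrl_chunk.std(ddof=1)
    z_ctrl = ((p_ctrl_chunk - mu) / sd if sd > 0
              else p_ctrl_chunk * 0.0)

    if bonferroni_m is None:
        bonferroni_m = max(len(others) * len(chunks), 1)

    pooled = (binned.groupby(["condition", "chunk"])[["n_pos", "n_neg"]]
                    .sum())
    rows = []
    for cond in others:
        for ch in chunks:
            try:
                tab = build_strat_table(binned, cond, control, ch)
            except ValueError:
                logger.warning("no data for %s vs %s in chunk %d; skipped",
                               cond, control, ch)
                continue
            cmh = cmh_test(tab)
            if tab.n_strata >= 2:
                bd = breslow_day(tab)
                psi = bd.psi_mh
                bd_stat, bd_p = bd.statistic, bd.pvalue
            else:
                psi = mantel_haenszel_or(tab)
                bd_stat = bd_p = np.nan
            np_c, nn_c = pooled.loc[(cond, ch)]
            np_0, nn_0 = pooled.loc[(control, ch)]
            p_cond = np_c / (np_c + nn_c)
            p_ctrl_pool = np_0 / (np_0 + nn_0)
            if p_cond > 0 and p_ctrl_pool > 0:
                log2fc = float(np.log2(p_cond / p_ctrl_pool))
            else:
                log2fc = np.nan
                logger.info("log2FC undefined for %s chunk %d "
                            "(zero proportion)", cond, ch)
            sub = binned[(binned["condition"] == cond)
                         & (binned["chunk"] == ch)]
            rows.append({
                "condition": cond, "phenotype": phenotype,
                "chunk": ch,
                "chunk_start": int(sub["chunk_start"].iloc[0]),
                "chunk_end": int(sub["chunk_end"].iloc[0]),
                "p_ctrl": float(p_ctrl_chunk.get(ch, np.nan)),
                "z_ctrl": float(z_ctrl.get(ch, np.nan)),
                "log2fc": log2fc,
                "cmh_stat": cmh.statistic, "p_raw": cmh.pvalue,
                "psi_mh": psi, "bd_stat": bd_stat, "bd_p": bd_p,
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    out["p_adj"] = adjust_bonferroni(out["p_raw"].to_numpy(), bonferroni_m)
    out["bd_p_adj"] = np.where(np.isnan(out["bd_p"]), np.nan,
                               np.minimum(1.0, bonferroni_m * out["bd_p"]))
    out["homogeneous"] = pd.Series(
        [pd.NA if np.isnan(p) else bool(p >= alpha)
         for p in out["bd_p_adj"]], dtype="boolean")
    return out[SUMMARY_COLUMNS + ["chunk"]]


def area_summary(labelled: pd.DataFrame, control: str,
                 chunk_hours: int = DEFAULT_CHUNK_HOURS,
                 area_column: str = "Area",
                 label_column: str = "phenotype_label") -> pd.DataFrame:
    """Mean control-normalized z-score of object area per condition/chunk.

    Each retained object-frame's area is z-scored against the control
    distribution of the same chunk; a zero-variance control chunk gives
    z = 0 (flagged in the log).
    """
    df = labelled.dropna(subset=[label_column]).copy()
    df["chunk"] = (df["frame"] - 1) // chunk_hours
    rows = []
    for ch, sub in df.groupby("chunk"):
        ctrl_vals = sub.loc[sub["condition"] == control, area_column]
        mu = ctrl_vals.mean()
        sd = ctrl_vals.std(ddof=1)
        if not sd > 0:
            logger.warning("area z-score: control SD = 0 in chunk %d", ch)
        for cond, csub in sub.groupby("condition"):
            z = ((csub[area_column] - mu) / sd if sd > 0
                 else csub[area_column] * 0.0)
            rows.append({"condition": cond, "chunk": int(ch),
                         "mean_z_area": float(z.mean()),
                         "n": int(len(csub))})
    return pd.DataFrame(rows)


def bubble_heatmap(summary: pd.DataFrame, path=None, alpha: float = 0.05):
    """Bubble heatmap: log2FC as colour, -log10 adjusted p as size,
    black centre dot where the effect is homogeneous across replicates."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conds = sorted(summary["condition"].unique())
    chunks = sorted(summary["chunk"].unique())
    fig, ax = plt.subplots(
        figsize=(max(6, 0.55 * len(chunks)), max(2.5, 0.6 * len(conds) + 1)))
    vmax = np.nanmax(np.abs(summary["log2fc"])) or 1.0
    for _, row in summary.iterrows():
        x = chunks.index(row["chunk"])
        y = conds.index(row["condition"])
        size = 30 + 60 * min(-np.log10(max(row["p_adj"], 1e-10)), 10)
        sc = ax.scatter(x, y, s=size, c=[row["log2fc"]], cmap="coolwarm",
                        vmin=-vmax, vmax=vmax, edgecolors="k",
                        linewidths=0.4)
        if row["homogeneous"] is True and row["p_adj"] < alpha:
            ax.scatter(x, y, s=8, c="k")
    ax.set_xticks(range(len(chunks)))
    ax.set_xticklabels([f"{int(summary[summary['chunk'] == c]['chunk_start'].iloc[0])}-"
                        f"{int(summary[summary['chunk'] == c]['chunk_end'].iloc[0])}h"
                        for c in chunks], rotation=45, ha="right")
    ax.set_yticks(range(len(conds)))
    ax.set_yticklabels(conds)
    fig.colorbar(sc, ax=ax, label="log2 fold change vs control")
    ax.set_xlabel("time chunk")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
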