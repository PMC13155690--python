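"""Binned behavioral summaries, computed identically for data and model samples.

These are the statistics behind the standard figures of this paradigm:

* UV/UA: response histograms (3-degree bins, one centered at r = 0), mean bias
  and response SD per stimulus bin (the 7 speaker locations for UA; 7 equal
  partitions of [-20, 20] for UV), each as group mean +/- SEM.
* BC: fraction of "same" responses in 9 disparity (sA - sV) bins, stratified
  by reliability and a center/periphery median split of |sA + sV|.
* BV/BA: mean bias (r - s_target) in 7 disparity bins (percentile edges over
  all trials), stratified by reliability and left/center/right terciles of
  sA + sV (25th/75th percentiles).

A model's "ribbon" is produced by running the same functions on predictive
samples simulated at the fitted parameters; pass a ``source`` tag to label the
output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

RESPONSE_BIN_WIDTH = 3.0


def response_bin_edges(width: float = RESPONSE_BIN_WIDTH, half_range: float = 45.0) -> np.ndarray:
    """Response-histogram bin edges with one bin centered at r = 0."""
    n = int(np.ceil((half_range - width / 2.0) / width))
    return np.arange(-width / 2.0 - n * width, half_range + width, width)


def uv_stimulus_bins() -> np.ndarray:
    """7 equal partitions of the visual stimulus range [-20, 20]."""
    return np.linspace(-20.0, 20.0, 8)


def _group_mean_sem(per_participant: pd.DataFrame, value: str) -> pd.DataFrame:
    g = per_participant.groupby([c for c in per_participant.columns
                                 if c not in (value, "participant")], dropna=False)[value]
    out = g.agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
    return out.reset_index()


def unisensory_summary(table: pd.DataFrame, task: str,
                       reliability: str | None = None, source: str = "data") -> dict:
    """Distribution, bias, and SD summaries for UV or UA localization trials.

    Returns {"distribution": ..., "bias": ..., "sd": ...} DataFrames with
    per-bin group mean +/- SEM across participants.  Empty stimulus bins are
    skipped for that participant.
    """
    if task not in ("UV", "UA"):
        raise ValueError("task must be UV or UA")
    sel = table["task"] == task
    if task == "UV":
        if reliability is None:
            raise ValueError("UV summaries require a reliability level")
        sel &= table["reliability"] == reliability
        sub = table.loc[sel]
        s = sub["s_V"].to_numpy(dtype=float)
        edges = uv_stimulus_bins()
        bin_id = np.clip(np.digitize(s, edges) - 1, 0, 6)
        centers = 0.5 * (edges[:-1] + edges[1:])
    else:
        sub = table.loc[sel]
        s = sub["s_A"].to_numpy(dtype=float)
        centers = np.unique(s)
        bin_id = np.searchsorted(centers, s)
    r = sub["response_loc"].to_numpy(dtype=float)
    part = sub["participant"].to_numpy()
    df = pd.DataFrame({"participant": part, "stim_bin": bin_id, "s": s, "r": r})

    redges = response_bin_edges()
    rcenters = 0.5 * (redges[:-1] + redges[1:])
    dist_rows, bias_rows, sd_rows = [], [], []
    for (p, sb), grp in df.groupby(["participant", "stim_bin"]):
        if len(grp) == 0:
            continue
        hist, _ = np.histogram(grp["r"], bins=redges)
        hist = hist / hist.sum() if hist.sum() else hist.astype(float)
        for rc, h in zip(rcenters, hist):
            dist_rows.append({"participant": p, "stim_bin_center": centers[sb],
                              "r_bin_center": rc, "p": h})
        # bias = per-trial (r - s), then averaged within the bin
        bias_rows.append({"participant": p, "stim_bin_center": centers[sb],
                          "bias": float((grp["r"] - grp["s"]).mean())})
        sd_rows.append({"participant": p, "stim_bin_center": centers[sb],
                        "sd": float(grp["r"].std(ddof=1)) if len(grp) > 1 else np.nan})
    out = {
        "distribution": _group_mean_sem(pd.DataFrame(dist_rows), "p"),
        "bias": _group_mean_sem(pd.DataFrame(bias_rows), "bias"),
        "sd": _group_mean_sem(pd.DataFrame(sd_rows), "sd"),
    }
    for v in out.values():
        v.attrs["source"] = source
    return out


def _percentile_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.linspace(0.0, 100.0, n_bins + 1)
    edges = np.percentile(values, qs)
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    return edges


def bc_summary(table: pd.DataFrame, source: str = "data") -> pd.DataFrame:
    """Fraction of "same" (rC = 1) responses per disparity bin, stratified by
    reliability and center/periphery (median split of |sA + sV| over all BC
    trials of all participants).  Disparity bin edges are the 0th..100th
    percentiles (9 bins) within each stratum."""
    sub = table.loc[table["task"] == "BC"].copy()
    if len(sub) == 0:
        raise ValueError("no BC trials")
    abs_sum = (sub["s_A"] + sub["s_V"]).abs()
    median = abs_sum.median()
    sub["eccentricity"] = np.where(abs_sum <= median, "center", "periphery")
    sub["disparity"] = sub["s_A"] - sub["s_V"]
    rows = []
    for (rel, ecc), grp in sub.groupby(["reliability", "eccentricity"]):
        edges = _percentile_edges(grp["disparity"].to_numpy(), 9)
        bin_id = np.clip(np.digitize(grp["disparity"], edges) - 1, 0, 8)
        centers = 0.5 * (edges[:-1] + edges[1:])
        g = grp.assign(disp_bin=bin_id)
        for (p, b), cell in g.groupby(["participant", "disp_bin"]):
            rows.append({"reliability": rel, "eccentricity": ecc, "participant": p,
                         "disp_bin_center": centers[b],
                         "p_same": float((cell["response_cat"] == 1).mean())})
    out = _group_mean_sem(pd.DataFrame(rows), "p_same")
    out.attrs["source"] = source
    return out


def bisensory_localization_summary(table: pd.DataFrame, target: str,
                                   source: str = "data") -> pd.DataFrame:
    """Mean bias (r - s_target) per disparity bin for BV (target 'V') or BA
    (target 'A'), stratified by reliability and left/center/right position
    (25th/75th percentiles of sA + sV over all trials of the task).  The 7
    disparity bin edges are percentiles over all trials regardless of stratum."""
    task = "BV" if target == "V" else "BA"
    sub = table.loc[table["task"] == task].copy()
    if len(sub) == 0:
        raise ValueError(f"no {task} trials")
    pos = sub["s_A"] + sub["s_V"]
    q25, q75 = np.percentile(pos, [25.0, 75.0])
    sub["position"] = np.select([pos < q25, pos > q75], ["left", "right"], "center")
    sub["disparity"] = sub["s_A"] - sub["s_V"]
    edges = _percentile_edges(sub["disparity"].to_numpy(), 7)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sub["disp_bin"] = np.clip(np.digitize(sub["disparity"], edges) - 1, 0, 6)
    s_target = sub["s_V"] if target == "V" else sub["s_A"]
    sub["bias"] = sub["response_loc"] - s_target
    rows = []
    for (rel, posname, p, b), cell in sub.groupby(
            ["reliability", "position", "participant", "disp_bin"]):
        rows.append({"reliability": rel, "position": posname, "participant": p,
                     "disp_bin_center": centers[b], "bias": float(cell["bias"].mean())})
    out = _group_mean_sem(pd.DataFrame(rows), "bias")
    out.attrs["source"] = source
    return out


def one_sample_t(values, popmean: float = 1.0, alternative: str = "two-sided"):
    """One-sample t-test across participants (e.g., beta_V > 1, rho_A vs 4/3)."""
    res = stats.ttest_1samp(np.asarray(values, dtype=float), popmean,
                            alternative=alternative)
    return float(res.statistic), float(res.pvalue)
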