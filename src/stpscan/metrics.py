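"""Detection-performance metrics over groups of simulated datasets.

Each injected dataset yields one outcome row; metrics aggregate outcomes
within groups keyed by (resolution, RR, cluster-size bin):

* power        - share of datasets with any significant cluster;
* PSP          - power with spatial precision: some significant cluster's
                 circle contains the true cluster center;
* sensitivity  - share of injected treatment cases captured by the
                 significant clusters (observation level);
* PPV          - share of captured cases that are treatment cases.

Sensitivity and PPV pool numerators and denominators across the datasets
of a group by default (``mean_of_ratios`` is available as an
alternative); capture means membership in a significant cluster's
cylinder -- its location set and month interval -- with a space-only
switch for sensitivity analysis. PSP <= power holds by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .injection import SimulatedDataset
from .scan import ScanResult

SIZE_BINS = ("small", "intermediate", "large")  # 0-16, 17-32, 33-48 km


def size_bin(r_km: float) -> str:
    if r_km <= 16.0:
        return "small"
    if r_km <= 32.0:
        return "intermediate"
    return "large"


def evaluate_dataset(
    result: ScanResult,
    dataset: SimulatedDataset,
    membership: str = "space_time",
    dataset_id: int = 0,
) -> dict:
    """Reduce one scan to the outcome row the metrics need.

    Capture counts are unions over all significant clusters, so a case
    lying in two reported cylinders is counted once.
    """
    if membership not in ("space_time", "space_only"):
        raise ValueError("membership must be 'space_time' or 'space_only'")
    truth = dataset.truth
    rec = dataset.records
    months = rec["month"].to_numpy(int)
    is_treat = rec["is_treatment"].to_numpy(bool)
    case_loc = result.counts.case_loc

    sig = result.significant_clusters()
    member = np.zeros(len(rec), dtype=bool)
    psp = False
    tx, ty = truth.center
    for cl in sig:
        in_space = np.isin(case_loc, cl.locations)
        if membership == "space_time":
            in_time = (months >= cl.t_start) & (months <= cl.t_end)
            member |= in_space & in_time
        else:
            member |= in_space
        dx = cl.center_xy[0] - tx
        dy = cl.center_xy[1] - ty
        if np.hypot(dx, dy) <= cl.radius_km:
            psp = True

    return {
        "dataset_id": dataset_id,
        "resolution": dataset.resolution,
        "rr": truth.rr,
        "r_km": truth.r_km,
        "size_bin": size_bin(truth.r_km),
        "C": truth.C,
        "n_t": truth.n_t,
        "onset_month": truth.onset_month,
        "detected": len(sig) > 0,
        "psp_success": psp,
        "n_significant": len(sig),
        "treat_captured": int((member & is_treat).sum()),
        "members_captured": int(member.sum()),
        "primary_p": result.p_value,
        "primary_log_glr": result.primary.log_glr if result.primary else 0.0,
        "sum_sig_radius": float(sum(cl.radius_km for cl in sig)),
        "sum_sig_interval": int(sum(cl.interval_length for cl in sig)),
    }


def _group_metrics(g: pd.DataFrame, estimator: str) -> dict:
    n = len(g)
    out = {
        "n_datasets": n,
        "power": g["detected"].mean(),
        "psp": g["psp_success"].mean(),
    }
    with_t = g[g["n_t"] > 0]
    if estimator == "pooled":
        out["sensitivity"] = (
            with_t["treat_captured"].sum() / with_t["n_t"].sum()
            if with_t["n_t"].sum() > 0
            else np.nan
        )
        denom = g["members_captured"].sum()
        out["ppv"] = g["treat_captured"].sum() / denom if denom > 0 else np.nan
    else:  # mean of per-dataset ratios
        out["sensitivity"] = (
            (with_t["treat_captured"] / with_t["n_t"]).mean() if len(with_t) else np.nan
        )
        with_m = g[g["members_captured"] > 0]
        out["ppv"] = (
            (with_m["treat_captured"] / with_m["members_captured"]).mean()
            if len(with_m)
            else np.nan
        )
    n_sig = g["n_significant"].sum()
    out["mean_detected_radius_km"] = (
        g["sum_sig_radius"].sum() / n_sig if n_sig > 0 else np.nan
    )
    return out


def metrics_table(outcomes: pd.DataFrame, estimator: str = "pooled") -> pd.DataFrame:
    """Per-(resolution, RR, size bin) metrics, one row per group."""
    if estimator not in ("pooled", "mean_of_ratios"):
        raise ValueError("estimator must be 'pooled' or 'mean_of_ratios'")
    rows = []
    for (res, rr, sb), g in outcomes.groupby(["resolution", "rr", "size_bin"]):
        row = {"resolution": res, "rr": rr, "size_bin": sb}
        row.update(_group_metrics(g, estimator))
        rows.append(row)
    df = pd.DataFrame(rows)
    order = {s: i for i, s in enumerate(SIZE_BINS)}
    return df.sort_values(
        ["resolution", "size_bin", "rr"],
        key=lambda c: c.map(order) if c.name == "size_bin" else c,
    ).reset_index(drop=True)


def resolution_summary(outcomes: pd.DataFrame, estimator: str = "pooled") -> pd.DataFrame:
    """Average pairwise metric differences versus the address level.

    For each coarser resolution, the mean over matched (RR, size-bin)
    groups of (metric_at_resolution - metric_at_address), plus the mean
    detected radius -- the style of headline summary used to report
    aggregation effects.
    """
    table = metrics_table(outcomes, estimator)
    if "address" not in set(table["resolution"]):
        raise ValueError("resolution summary needs address-level outcomes")
    base = table[table["resolution"] == "address"].set_index(["rr", "size_bin"])
    rows = []
    for res in sorted(set(table["resolution"])):
        sub = table[table["resolution"] == res].set_index(["rr", "size_bin"])
        common = sub.index.intersection(base.index)
        row = {"resolution": res, "n_groups": len(common)}
        for m in ("power", "psp", "sensitivity", "ppv"):
            row[f"delta_{m}"] = (sub.loc[common, m] - base.loc[common, m]).mean()
        n_sig = outcomes[outcomes["resolution"] == res]["n_significant"].sum()
        row["mean_detected_radius_km"] = (
            outcomes[outcomes["resolution"] == res]["sum_sig_radius"].sum() / n_sig
            if n_sig > 0
            else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_metric(outcomes: pd.DataFrame, metric: str) -> float:
    """Pooled sensitivity or PPV over an arbitrary subset of outcomes."""
    if metric == "sensitivity":
        sub = outcomes[outcomes["n_t"] > 0]
        denom = sub["n_t"].sum()
        return float(sub["treat_captured"].sum() / denom) if denom > 0 else np.nan
    if metric == "ppv":
        denom = outcomes["members_captured"].sum()
        return float(outcomes["treat_captured"].sum() / denom) if denom > 0 else np.nan
    raise ValueError("metric must be 'sensitivity' or 'ppv'")


def plot_metric_curves(table: pd.DataFrame, metric: str, path, title: str | None = None):
    """Line plots per size bin: RR on the abscissa, one series per
    resolution (the layout used for power/PSP/sensitivity/PPV curves)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = [b for b in SIZE_BINS if b in set(table["size_bin"])]
    fig, axes = plt.subplots(1, len(bins), figsize=(4 * len(bins), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    styles = {"address": "s-", "zip": "o--", "county": "^:"}
    for ax, sb in zip(axes, bins):
        for res in ("address", "zip", "county"):
            sub = table[(table["size_bin"] == sb) & (table["resolution"] == res)]
            if len(sub):
                ax.plot(sub["rr"], sub[metric], styles.get(res, "-"), label=res,
                        fillstyle="none")
        ax.set_xlabel("relative risk")
        ax.set_title(sb)
        ax.set_ylim(-0.02, 1.02)
    axes[0].set_ylabel(metric)
    axes[-1].legend(frameon=False)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
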