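"""Per-CpG two-group testing on M values with beta-scale effect sizes.

Each probe gets a two-sided t-test (pooled-variance by default, Welch
optional) on M values between the HC and RA groups, a beta-scale effect
size delta_beta = mean_beta_ra - mean_beta_hc, a significance tier on the
raw p-value — high (p <= 1e-4), medium (1e-4 < p <= 1e-3), low
(1e-3 < p <= 1e-2), ns otherwise — and a direction call (hyper for
delta_beta > 0, i.e. hypermethylated in the patient group). Benjamini-
Hochberg q-values are computed and reported but tiers deliberately use the
raw p-value: the prioritization is exploratory and uncorrected by design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import analysis_sample_mask, beta_to_m

__all__ = [
    "TIER_BOUNDS",
    "ttest_per_probe",
    "classify_tiers",
    "manhattan_data",
    "volcano_data",
]

# tier upper bounds on the raw p-value, inclusive
TIER_BOUNDS = (("high", 1e-4), ("medium", 1e-3), ("low", 1e-2))
P_DM = 1e-2   # a probe is differentially methylated iff p <= P_DM

_TINY_P = np.nextafter(0.0, 1.0)


def _group_columns(samplesheet: pd.DataFrame, matrix: pd.DataFrame):
    sheet = samplesheet[samplesheet["sample_id"].isin(matrix.columns)]
    sheet = sheet[analysis_sample_mask(sheet).to_numpy()]
    hc = sheet.loc[sheet["group"] == "HC", "sample_id"].tolist()
    ra = sheet.loc[sheet["group"] == "RA", "sample_id"].tolist()
    for name, cols in (("HC", hc), ("RA", ra)):
        if len(cols) < 2:
            raise ValueError(
                f"group {name} has {len(cols)} analysis samples; need >= 2")
    return hc, ra


def assign_tier(p: np.ndarray) -> np.ndarray:
    """Vectorized tier assignment with inclusive upper bounds."""
    p = np.asarray(p, dtype=float)
    tier = np.full(p.shape, "ns", dtype=object)
    tier[p <= 1e-2] = "low"
    tier[p <= 1e-3] = "medium"
    tier[p <= 1e-4] = "high"
    return tier


def ttest_per_probe(matrix: pd.DataFrame, samplesheet: pd.DataFrame,
                    variance_mode: str = "pooled",
                    epsilon: float = 1e-3) -> pd.DataFrame:
    """Row-wise two-sided t-tests on M values between HC and RA.

    Parameters
    ----------
    matrix
        Beta matrix (probes x samples). M values are computed internally
        with clipping margin ``epsilon``.
    samplesheet
        Sample sheet; technical replicates beyond the first sample of each
        replicate set are excluded from testing.
    variance_mode
        ``"pooled"`` (equal-variance, df = n1 + n2 - 2; the classical
        row-t-test) or ``"welch"``.

    Returns
    -------
    DataFrame indexed by probe_id with columns mean_beta_hc, mean_beta_ra,
    delta_beta, t_stat, p_value, q_value, tier, direction, zero_variance.

    Notes
    -----
    Zero within-group variance in both groups with equal means yields
    t = 0, p = 1; with unequal means the p-value is set to the smallest
    positive float and the probe is flagged ``zero_variance`` — the data
    carry no internal noise estimate there, so the p-value is a sentinel,
    not an inference.
    """
    if variance_mode not in ("pooled", "welch"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    hc_cols, ra_cols = _group_columns(samplesheet, matrix)

    beta_hc = matrix[hc_cols].to_numpy(dtype=float)
    beta_ra = matrix[ra_cols].to_numpy(dtype=float)
    m_hc = beta_to_m(beta_hc, epsilon)
    m_ra = beta_to_m(beta_ra, epsilon)
    n1, n2 = m_hc.shape[1], m_ra.shape[1]

    mean1 = m_hc.mean(axis=1)
    mean2 = m_ra.mean(axis=1)
    var1 = m_hc.var(axis=1, ddof=1)
    var2 = m_ra.var(axis=1, ddof=1)
    diff = mean2 - mean1

    if variance_mode == "pooled":
        sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(se, float(n1 + n2 - 2))
    else:
        se2 = var1 / n1 + var2 / n2
        se = np.sqrt(se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2 ** 2 / (var1 ** 2 / (n1 ** 2 * (n1 - 1))
                             + var2 ** 2 / (n2 ** 2 * (n2 - 1)))
        df = np.where(np.isfinite(df), df, float(n1 + n2 - 2))

    zero_var = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, diff / np.where(zero_var, 1.0, se))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.minimum(p, 1.0)
    # zero-variance sentinel handling
    degenerate_equal = zero_var & (diff == 0)
    degenerate_diff = zero_var & (diff != 0)
    t[degenerate_equal] = 0.0
    p[degenerate_equal] = 1.0
    p[degenerate_diff] = _TINY_P
    t[degenerate_diff] = np.sign(diff[degenerate_diff]) * np.inf

    mean_beta_hc = beta_hc.mean(axis=1)
    mean_beta_ra = beta_ra.mean(axis=1)
    delta = mean_beta_ra - mean_beta_hc

    q = multipletests(p, method="fdr_bh")[1]

    # direction: hyper iff delta_beta > 0; exact zeros are called hypo by a
    # fixed tie rule and flagged via direction_tie
    direction = np.where(delta > 0, "hyper", "hypo")

    return pd.DataFrame({
        "mean_beta_hc": mean_beta_hc,
        "mean_beta_ra": mean_beta_ra,
        "delta_beta": delta,
        "t_stat": t,
        "p_value": p,
        "q_value": q,
        "tier": assign_tier(p),
        "direction": direction,
        "direction_tie": delta == 0,
        "zero_variance": zero_var | degenerate_diff,
    }, index=matrix.index.copy())


def classify_tiers(diff: pd.DataFrame,
                   manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Count DM probes (p <= 0.01) per (tier, direction[, island_relation]).

    Returns a tidy count table; counts over tiers sum to the DM total.
    """
    dm = diff[diff["p_value"] <= P_DM].copy()
    keys = ["tier", "direction"]
    if manifest is not None:
        rel = manifest.set_index("probe_id")["island_relation"]
        dm["island_relation"] = rel.reindex(dm.index).to_numpy()
        keys.append("island_relation")
    out = (dm.groupby(keys, observed=True).size()
             .rename("n").reset_index())
    return out


def manhattan_data(diff: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-probe (chrom, pos, -log10 p, cumulative genome coordinate) table.

    Rows are ordered by chromosome then position; the cumulative coordinate
    offsets each chromosome by the spans of all preceding ones, so it is
    strictly increasing genome-wide.
    """
    ann = manifest.set_index("probe_id").loc[diff.index, ["chrom", "pos"]]
    tab = pd.DataFrame({
        "probe_id": diff.index,
        "chrom": ann["chrom"].to_numpy(),
        "pos": ann["pos"].to_numpy(),
        "neg_log10_p": -np.log10(diff["p_value"].to_numpy()),
    }).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    offset = 0
    cum = np.empty(len(tab), dtype=np.int64)
    for _, g in tab.groupby("chrom", sort=False):
        cum[g.index] = g["pos"].to_numpy() + offset
        offset += int(g["pos"].max())
    tab["cum_pos"] = cum
    return tab


def volcano_data(diff: pd.DataFrame,
                 list2_probes=None, list3_probes=None) -> pd.DataFrame:
    """Per-probe (delta_beta, -log10 p) with gene-list membership tags."""
    tab = pd.DataFrame({
        "probe_id": diff.index,
        "delta_beta": diff["delta_beta"].to_numpy(),
        "neg_log10_p": -np.log10(diff["p_value"].to_numpy()),
    })
    tab["in_list2"] = tab["probe_id"].isin(list2_probes) if list2_probes is not None else False
    tab["in_list3"] = tab["probe_id"].isin(list3_probes) if list3_probes is not None else False
    return tab
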