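"""Per-timepoint differential statistics for two-color and one-color data.

Two-color arrays co-hybridize test (Cy5) and reference (Cy3) samples, so
each replicate array yields one log2 ratio per probe and the natural test
is a one-sample t against zero.  One-color comparisons contrast log2
intensities between groups of separate arrays with a two-sample t.

Multiple testing is corrected with the Benjamini-Hochberg step-up
procedure, applied across probes separately for each contrast and
timepoint (gene lists are extracted per timepoint).  A probe/gene is
*called* differential under the default ``union`` rule when its absolute
fold change reaches ``fc_threshold`` or its adjusted p-value is at most
``p_threshold``; ``intersection`` and ``p_only`` variants are available.

Fold change is reported signed on the linear scale:
``FC = sign(mean_log2_ratio) * 2 ** |mean_log2_ratio|``, so repressions are
negative (an FC of -1.82 is a 1.82-fold repression).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .algebra import DirectionalGeneList
from .tables import CONTRAST_BY_EXPERIMENT, CONTRAST_ONECOLOR, ProbeTable

log = logging.getLogger(__name__)

CALL_RULES = ("union", "intersection", "p_only")


class TTestResult(NamedTuple):
    t_stat: float
    p_raw: float
    degenerate: bool = False


# --------------------------------------------------------------------------
# elementary tests
# --------------------------------------------------------------------------

def one_sample_t(values) -> TTestResult:
    """Two-sided one-sample t test against a zero mean.

    Degenerate (zero-variance) inputs do not raise: a constant zero vector
    gives p = 1, a constant non-zero vector gives p = 0, both flagged.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("one_sample_t requires >= 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in t test input")
    if np.ptp(x) == 0.0:
        if x[0] == 0.0:
            return TTestResult(0.0, 1.0, True)
        return TTestResult(np.sign(x[0]) * np.inf, 0.0, True)
    t, p = sps.ttest_1samp(x, 0.0)
    return TTestResult(float(t), float(p), False)


def two_group_t(group_a, group_b, equal_var: bool = True) -> TTestResult:
    """Two-sided two-sample t test (pooled variance; Welch optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in t test input")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a[0] == b[0]:
            return TTestResult(0.0, 1.0, True)
        return TTestResult(np.sign(a[0] - b[0]) * np.inf, 0.0, True)
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(t), float(p), False)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(mean_log2_ratio) -> np.ndarray:
    m = np.asarray(mean_log2_ratio, dtype=float)
    return np.sign(m) * np.exp2(np.abs(m))


# --------------------------------------------------------------------------
# probe-level contrast tables
# --------------------------------------------------------------------------

def _one_sample_matrix(values: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized one-sample t against 0 over rows, with the degenerate
    conventions of :func:`one_sample_t`."""
    n = values.shape[1]
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    t = np.zeros(len(mean))
    p = np.ones(len(mean))
    degen = sd == 0.0
    ok = ~degen
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df=n - 1)
    nz = degen & (mean != 0.0)
    t[nz] = np.sign(mean[nz]) * np.inf
    p[nz] = 0.0
    return mean, t, p, degen


def two_color_probe_stats(table: ProbeTable, design: pd.DataFrame,
                          experiment: int) -> pd.DataFrame:
    """Per probe x timepoint one-sample t statistics for one experiment."""
    contrast = CONTRAST_BY_EXPERIMENT[experiment]
    sel = design[(design["experiment"] == experiment)
                 & (design["channel"] == "ratio")
                 & design["sample_id"].isin(table.samples)]
    if sel.empty:
        raise ValueError(f"no ratio samples for experiment {experiment}")
    frames = []
    for tp, grp in sel.groupby("timepoint", sort=False):
        cols = grp["sample_id"].tolist()
        if len(cols) < 2:
            raise ValueError(
                f"experiment {experiment} timepoint {tp}: <2 replicates")
        mean, t, p, degen = _one_sample_matrix(table.signal[cols].to_numpy())
        frames.append(pd.DataFrame({
            "probe_id": table.probe_ids, "contrast": contrast,
            "timepoint": tp, "n": len(cols), "mean_log2_ratio": mean,
            "FC": signed_fold_change(mean), "t_stat": t, "p_raw": p,
            "degenerate": degen}))
    return pd.concat(frames, ignore_index=True)


def one_color_probe_stats(table: ProbeTable, design: pd.DataFrame,
                          reference_condition: str = "Ctrl",
                          test_condition: str = "MgHI",
                          equal_var: bool = True) -> pd.DataFrame:
    """Per probe x timepoint two-group t statistics on log2 intensities.

    Reference arrays are pooled across experiments (control arrays from the
    treatment-only and insult-only experiments jointly define the baseline).
    """
    sel = design[(design["channel"] == "one_color")
                 & design["sample_id"].isin(table.samples)]
    frames = []
    logsig = np.log2(table.signal)
    for tp, grp in sel.groupby("timepoint", sort=False):
        a_cols = grp.loc[grp["condition"] == reference_condition,
                         "sample_id"].tolist()
        b_cols = grp.loc[grp["condition"] == test_condition,
                         "sample_id"].tolist()
        if len(a_cols) < 2 or len(b_cols) < 2:
            raise ValueError(
                f"one-color timepoint {tp}: <2 replicates per group")
        a = logsig[a_cols].to_numpy()
        b = logsig[b_cols].to_numpy()
        diff = b.mean(axis=1) - a.mean(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = sps.ttest_ind(b, a, axis=1, equal_var=equal_var)
        degen = ~np.isfinite(t)
        if degen.any():
            t = np.asarray(t).copy()
            p = np.asarray(p).copy()
            zero = degen & (diff == 0.0)
            t[degen & (diff > 0)] = np.inf
            t[degen & (diff < 0)] = -np.inf
            t[zero] = 0.0
            p[degen] = 0.0
            p[zero] = 1.0
        frames.append(pd.DataFrame({
            "probe_id": table.probe_ids, "contrast": CONTRAST_ONECOLOR,
            "timepoint": tp, "n": len(a_cols) + len(b_cols),
            "mean_log2_ratio": diff, "FC": signed_fold_change(diff),
            "t_stat": t, "p_raw": p, "degenerate": degen}))
    return pd.concat(frames, ignore_index=True)


def add_bh(stats: pd.DataFrame) -> pd.DataFrame:
    """BH adjustment across probes, separately per contrast x timepoint."""
    out = stats.copy()
    out["p_bh"] = np.nan
    for _, idx in out.groupby(["contrast", "timepoint"]).groups.items():
        out.loc[idx, "p_bh"] = bh_adjust(out.loc[idx, "p_raw"].to_numpy())
    return out


def call_differential(stats: pd.DataFrame, fc_threshold: float = 2.0,
                      p_threshold: float = 0.05, rule: str = "union",
                      use_adjusted: bool = True) -> pd.DataFrame:
    """Apply the FC / adjusted-p selection rule and set directions."""
    if rule not in CALL_RULES:
        raise ValueError(f"rule must be one of {CALL_RULES}")
    out = stats.copy()
    pcol = "p_bh" if use_adjusted else "p_raw"
    if pcol not in out.columns:
        raise ValueError(f"{pcol} missing; run add_bh first")
    fc_ok = out["FC"].abs() >= fc_threshold
    p_ok = out[pcol] <= p_threshold
    if rule == "union":
        called = fc_ok | p_ok
    elif rule == "intersection":
        called = fc_ok & p_ok
    else:
        called = p_ok
    called &= out["mean_log2_ratio"] != 0.0
    out["called"] = called
    out["direction"] = np.where(
        ~called, "none",
        np.where(out["mean_log2_ratio"] > 0, "induced", "repressed"))
    return out


# --------------------------------------------------------------------------
# merging over timepoints, kinetics and amplitudes
# --------------------------------------------------------------------------

def merge_timepoints(gene_stats: pd.DataFrame, name: str
                     ) -> tuple[DirectionalGeneList, pd.DataFrame]:
    """Merge per-timepoint calls of one contrast into a directional list.

    A gene enters the list if called at any timepoint, in every direction
    in which it was called.  Genes called in opposite directions at
    different timepoints are flagged ``biphasic``; splice conflicts
    propagate from probe resolution.  The returned kinetics table carries
    one row per gene x timepoint with the direction and, at list level, the
    peak timepoint (the one with most called genes).
    """
    merged = DirectionalGeneList(name)
    called = gene_stats[gene_stats["called"]]
    if called.empty:
        return merged, pd.DataFrame(
            columns=["gene", "timepoint", "direction", "peak_timepoint",
                     "biphasic"])

    # biphasic: induced at one timepoint and repressed at a different one
    # (both directions at a single timepoint is a splice conflict instead)
    dirs_by_gene = called.groupby("gene")["direction"].agg(set)
    per_tp = called.groupby(["gene", "timepoint"])["direction"].agg(set)
    biphasic_genes = set()
    for gene, dirs in dirs_by_gene.items():
        if len(dirs) > 1:
            tps = per_tp.loc[gene]
            up = {tp for tp, v in tps.items() if "induced" in v}
            down = {tp for tp, v in tps.items() if "repressed" in v}
            if up - down or down - up:
                biphasic_genes.add(gene)

    splice_genes = set()
    if "splice_conflict" in called.columns:
        splice_genes = set(called.loc[called["splice_conflict"], "gene"])

    for row in called.itertuples():
        flags = set()
        if row.gene in biphasic_genes:
            flags.add("biphasic")
        if row.gene in splice_genes and getattr(row, "splice_conflict", False):
            flags.add("splice_conflict")
        merged.add(row.gene, row.direction, flags=flags, source=name)

    tp_counts = called.groupby("timepoint")["gene"].nunique()
    peak_tp = tp_counts.index[tp_counts.to_numpy().argmax()]
    kinetics = (called[["gene", "timepoint", "direction"]]
                .drop_duplicates().reset_index(drop=True))
    kinetics["peak_timepoint"] = peak_tp
    kinetics["biphasic"] = kinetics["gene"].isin(biphasic_genes)
    return merged, kinetics


@dataclasses.dataclass
class AmplitudeSummary:
    direction: str
    n: int
    median_FC: float
    Q1: float
    Q3: float
    ranksum_p: float


def amplitude_summary(gene_fc: pd.DataFrame
                      ) -> dict[str, AmplitudeSummary]:
    """Median and quartiles of signed FC per direction, plus a two-sided
    Mann-Whitney comparison of |FC| between inductions and repressions.

    ``gene_fc`` needs columns ``direction`` and ``FC``.  Quartiles use
    linear interpolation.  If one direction is empty its summary is
    omitted (with a warning) and the rank-sum p is NaN.
    """
    out: dict[str, AmplitudeSummary] = {}
    groups = {}
    for direction in ("induced", "repressed"):
        fc = gene_fc.loc[gene_fc["direction"] == direction, "FC"].to_numpy()
        if len(fc) == 0:
            log.warning("amplitude_summary: no %s genes", direction)
            continue
        groups[direction] = fc
    ranksum_p = np.nan
    if len(groups) == 2:
        ranksum_p = float(sps.mannwhitneyu(
            np.abs(groups["induced"]), np.abs(groups["repressed"]),
            alternative="two-sided").pvalue)
    for direction, fc in groups.items():
        q1, med, q3 = np.percentile(fc, [25, 50, 75])
        out[direction] = AmplitudeSummary(direction, len(fc), float(med),
                                          float(q1), float(q3), ranksum_p)
    return out


def equivalent_genes(onecolor_gene_stats: pd.DataFrame,
                     p_greater_than: float = 0.05,
                     band_log2: float = np.log2(1.5)) -> set[str]:
    """Genes whose one-color comparison shows *no difference*.

    Absence of significance alone is weak evidence of equivalence, so both
    conditions must hold at every timepoint: unadjusted p above
    ``p_greater_than`` and absolute mean log2 difference inside the band.
    """
    df = onecolor_gene_stats
    ok = (df["p_raw"] > p_greater_than) & \
        (df["mean_log2_ratio"].abs() < band_log2)
    per_gene = ok.groupby(df["gene"]).all()
    return set(per_gene.index[per_gene])
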