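"""Probe quality control and multi-probe resolution.

Three steps, applied before any differential statistics:

1. :func:`filter_probes` — every spot must be uniform; one-color probes must
   additionally be detected (signal strictly above ``detection_factor`` times
   the local background) in at least ``min_detected`` replicate arrays of
   each condition-by-timepoint group.
2. :func:`exclude_nongene_probes` — only probes annotated to a validated
   gene symbol are analysed; RIKEN-clone and control probes are dropped.
3. :func:`resolve_multiprobe` — when several probes report one gene, the
   probe with the largest absolute mean log2 ratio represents the gene in
   each contrast and timepoint; genes whose distinct probes give significant
   calls in opposite directions at one timepoint are flagged as putative
   splice variants and kept in both direction lists.
"""

from __future__ import annotations

import logging

import pandas as pd

from .tables import ONE_COLOR, ProbeTable

log = logging.getLogger(__name__)


def filter_probes(table: ProbeTable, design: pd.DataFrame | None = None,
                  detection_factor: float = 2.0, min_detected: int = 2
                  ) -> tuple[ProbeTable, pd.DataFrame]:
    """Apply uniformity and (one-color) detection filters.

    Returns the filtered table and a log of removed probes with reasons.
    ``design`` is required for one-color tables to define the replicate
    groups; two-color tables are filtered on uniformity only.
    """
    if detection_factor <= 0:
        raise ValueError("detection_factor must be positive")
    removed: dict[str, str] = {}

    nonuniform = ~table.uniform.all(axis=1)
    for pid in table.probe_ids[nonuniform]:
        removed[pid] = "non_uniform"

    if table.kind == ONE_COLOR:
        if table.background is None:
            raise ValueError("one-color filtering requires background values")
        if design is None:
            raise ValueError("one-color filtering requires a design table")
        detected = table.signal > detection_factor * table.background
        groups = design[design["sample_id"].isin(table.samples)]
        for (_, _, _), grp in groups.groupby(
                ["experiment", "condition", "timepoint"]):
            cols = [s for s in grp["sample_id"] if s in table.samples]
            if not cols:
                continue
            ok = detected[cols].sum(axis=1) >= min_detected
            for pid in table.probe_ids[~ok]:
                removed.setdefault(pid, "below_detection")

    keep = [p for p in table.probe_ids if p not in removed]
    report = pd.DataFrame(sorted(removed.items()),
                          columns=["probe_id", "reason_removed"])
    log.info("filter_probes(%s): %d/%d probes retained", table.name,
             len(keep), len(table.probe_ids))
    return table.subset(keep), report


def exclude_nongene_probes(table: ProbeTable, annotation: pd.DataFrame
                           ) -> tuple[ProbeTable, dict[str, int]]:
    """Keep only probes annotated to a validated gene symbol.

    Raises if any probe lacks an annotation row, naming the offender.
    """
    ann = annotation.set_index("probe_id")
    missing = [p for p in table.probe_ids if p not in ann.index]
    if missing:
        raise ValueError(f"probes without annotation: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    status = ann.loc[table.probe_ids, "status"]
    counts = status.value_counts().to_dict()
    keep = table.probe_ids[(status == "gene").to_numpy()]
    if len(keep) == 0:
        log.warning("exclude_nongene_probes(%s): no gene probes remain",
                    table.name)
    excluded = {k: int(v) for k, v in counts.items() if k != "gene"}
    log.info("exclude_nongene_probes(%s): excluded %s", table.name, excluded)
    return table.subset(keep), excluded


def resolve_multiprobe(probe_stats: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level contrast statistics to gene level.

    ``probe_stats`` must carry columns ``probe_id, gene, contrast, timepoint,
    mean_log2_ratio, FC, t_stat, p_raw, p_bh, direction, called``.  Per
    (gene, contrast, timepoint) the probe with the largest
    ``|mean_log2_ratio|`` is chosen (ties broken by lexicographically
    smallest probe id).  If called probes of one gene disagree in direction
    at one timepoint, the gene is flagged ``splice_conflict`` and both
    directions are reported (the strongest probe of each direction).
    """
    if probe_stats.empty:
        out = probe_stats.copy()
        out["chosen_probe"] = pd.Series(dtype=str)
        out["splice_conflict"] = pd.Series(dtype=bool)
        out["n_probes"] = pd.Series(dtype=int)
        return out

    keys = ["gene", "contrast", "timepoint"]
    df = probe_stats.copy()
    df["_abs"] = df["mean_log2_ratio"].abs()
    df = df.sort_values(keys + ["_abs", "probe_id"],
                        ascending=[True, True, True, False, True],
                        kind="stable")

    sizes = df.groupby(keys, sort=False).size().rename("n_probes")
    best = df.drop_duplicates(keys, keep="first")

    called = df[df["called"] & (df["direction"] != "none")]
    ndir = called.groupby(keys, sort=False)["direction"].nunique()
    conflict_keys = set(ndir[ndir > 1].index)

    best = best.merge(sizes.reset_index(), on=keys)
    key_tuples = list(map(tuple, best[keys].to_numpy()))
    best["splice_conflict"] = [k in conflict_keys for k in key_tuples]

    extra = []
    if conflict_keys:
        # strongest called probe of the direction opposite to the chosen one
        best_dir = best.set_index(keys)["direction"]
        grouped = called.groupby(keys, sort=False)
        for key in conflict_keys:
            grp = grouped.get_group(key)
            for direction in grp["direction"].unique():
                if direction == best_dir.loc[key]:
                    continue
                row = grp[grp["direction"] == direction].iloc[0].copy()
                row["n_probes"] = int(sizes.loc[key])
                row["splice_conflict"] = True
                extra.append(row)
    out = pd.concat([best, pd.DataFrame(extra)], ignore_index=True) \
        if extra else best.reset_index(drop=True)
    out = out.rename(columns={"probe_id": "chosen_probe"})
    return out.drop(columns="_abs").reset_index(drop=True)
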