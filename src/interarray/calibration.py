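"""Empirical false-discovery calibration of the BH-adjusted replicate t rule.

Simulates the direct treated-insult contrast as a mixture of null genes and
genes with a planted log2 effect, calls genes whose BH-adjusted one-sample
t p-value is at most the threshold, and measures the realized
false-discovery proportion against the planted truth.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

from .simulate import SimulationConfig, generate_experiment
from .stats import add_bh, call_differential, two_color_probe_stats


def empirical_fdp(seeds: Iterable[int], n_genes: int = 2000,
                  frac_nonnull: float = 0.1, effect_size_log2: float = 2.0,
                  noise_sd_log2: float = 0.25, n_replicates: int = 3,
                  p_threshold: float = 0.05) -> tuple[float, list[float]]:
    """Mean false-discovery proportion of the BH rule over replicate runs.

    Each seed generates an independent study in which ``frac_nonnull`` of
    the genes carry a +/- ``effect_size_log2`` effect in the treated-insult
    contrast.  Calls use the p-only rule on BH-adjusted p-values at
    ``p_threshold``.  Returns the mean FDP and the per-replicate values
    (a replicate with no calls contributes an FDP of 0).
    """
    fdps = []
    for seed in seeds:
        config = SimulationConfig(
            seed=int(seed), n_genes=n_genes,
            class_proportions={"NULL": 1.0 - frac_nonnull,
                               "DE_NOVO": frac_nonnull},
            effect_size_log2=effect_size_log2,
            noise_sd_log2=noise_sd_log2, n_replicates=n_replicates,
            probes_per_gene={1: 1.0}, frac_riken=0.0, frac_control=0.0)
        ds = generate_experiment(config)
        stats = two_color_probe_stats(ds.tables["exp2"], ds.design, 2)
        tp = config.timepoints_exp23[0]
        sub = stats[stats["timepoint"] == tp].copy()
        sub = add_bh(sub)
        sub = call_differential(sub, rule="p_only", p_threshold=p_threshold)
        gene_map = ds.annotation.set_index("probe_id")["gene_symbol"]
        called_genes = gene_map.loc[sub.loc[sub["called"],
                                            "probe_id"]].to_numpy()
        truth = ds.truth.set_index("gene")["planted_class"]
        n_called = len(called_genes)
        if n_called == 0:
            fdps.append(0.0)
            continue
        n_false = int((truth.loc[called_genes] == "NULL").sum())
        fdps.append(n_false / n_called)
    return float(np.mean(fdps)), fdps
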