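"""Synthetic factorial microarray experiments with planted ground truth.

The generator emulates a three-experiment treatment-by-insult design on a
5-day-old mouse brain: experiment 1 measures the treatment effect alone
(Mg vs. vehicle control, five timepoints), experiment 2 the treatment's
modulation of the insult response (MgHI vs. HI, two timepoints), and
experiment 3 the insult effect alone (HI vs. control, two timepoints), all
as two-color log2 ratios with three replicate arrays per contrast and
timepoint.  One-color intensity arrays for the Ctrl, Mg, HI and MgHI groups
support the pooled MgHI-vs-Ctrl comparison.

Every gene carries a planted interaction class that fixes its expected
log2 effect in each contrast; downstream stages can therefore be tested
for exact recovery.  The underlying model is a per-gene group mean on the
log2 scale: Ctrl = b, Mg = b + m, HI = b + h, MgHI = b + x, so the four
contrasts measure m, x - h, h and x respectively.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (ONE_COLOR, TWO_COLOR, CONTRAST_HI, CONTRAST_MG,
                     CONTRAST_MGHI_HI, CONTRAST_ONECOLOR, ProbeTable,
                     read_annotation, read_design, write_tsv)

log = logging.getLogger(__name__)

NULL = "NULL"
MG_ONLY = "MG_ONLY"
HI_ONLY = "HI_ONLY"
DE_NOVO = "DE_NOVO"
REVERSED = "REVERSED"
AMPLIFIED = "AMPLIFIED"
INSENSITIVE = "INSENSITIVE"
BIPHASIC = "BIPHASIC"
SPLICE_DISCORDANT = "SPLICE_DISCORDANT"

PLANTED_CLASSES = (NULL, MG_ONLY, HI_ONLY, DE_NOVO, REVERSED, AMPLIFIED,
                   INSENSITIVE, BIPHASIC, SPLICE_DISCORDANT)

#: interaction category each planted class should receive downstream
EXPECTED_CATEGORY = {
    NULL: "UNAFFECTED",
    MG_ONLY: "MG_ONLY",
    HI_ONLY: "INSENSITIVE",
    DE_NOVO: "DE_NOVO",
    REVERSED: "REVERSED",
    AMPLIFIED: "AMPLIFIED",
    INSENSITIVE: "INSENSITIVE",
    BIPHASIC: "MG_ONLY",
    SPLICE_DISCORDANT: "MG_ONLY",
}

DEFAULT_PROPORTIONS = {
    NULL: 0.55, MG_ONLY: 0.10, HI_ONLY: 0.05, DE_NOVO: 0.08, REVERSED: 0.06,
    AMPLIFIED: 0.05, INSENSITIVE: 0.06, BIPHASIC: 0.025,
    SPLICE_DISCORDANT: 0.025,
}


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one simulated study.

    ``seed`` is mandatory: every stochastic choice flows from a single
    :class:`numpy.random.Generator`, so identical configs give
    byte-identical outputs.
    """

    seed: int
    n_genes: int = 2000
    probes_per_gene: dict[int, float] = dataclasses.field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1})
    n_replicates: int = 3
    timepoints_exp1: tuple[str, ...] = ("1.5h", "3h", "6h", "12h", "24h")
    timepoints_exp23: tuple[str, ...] = ("3h", "12h")
    class_proportions: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    effect_size_log2: float = 2.0
    noise_sd_log2: float = 0.25
    baseline_log2_range: tuple[float, float] = (10.0, 15.0)
    background_level: float = 16.0
    frac_low_quality: float = 0.0
    frac_below_detection: float = 0.0
    frac_riken: float = 0.05
    frac_control: float = 0.01
    deterministic_allocation: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is required for reproducibility")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be at least 2")
        if self.effect_size_log2 <= 0:
            raise ConfigurationError("effect_size_log2 must be positive")
        if self.noise_sd_log2 < 0:
            raise ConfigurationError("noise_sd_log2 must be non-negative")
        if self.background_level <= 0:
            raise ConfigurationError("background_level must be positive")
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(
                f"class proportions sum to {total}, expected 1")
        unknown = set(self.class_proportions) - set(PLANTED_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown planted classes {unknown}")
        for frac_name in ("frac_low_quality", "frac_below_detection",
                          "frac_riken", "frac_control"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{frac_name}={v} outside [0, 1]")
        if not math.isclose(sum(self.probes_per_gene.values()), 1.0,
                            abs_tol=1e-9):
            raise ConfigurationError("probes_per_gene must sum to 1")
        if set(self.probes_per_gene) - {1, 2, 3}:
            raise ConfigurationError("probes_per_gene keys must be in {1,2,3}")
        if len(self.timepoints_exp1) < 1 or len(self.timepoints_exp23) < 1:
            raise ConfigurationError("each experiment needs >= 1 timepoint")


@dataclasses.dataclass
class SimulatedDataset:
    """Everything one simulated study produces."""

    config: SimulationConfig
    tables: dict[str, ProbeTable]
    design: pd.DataFrame
    annotation: pd.DataFrame
    truth: pd.DataFrame
    artifact_log: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for table in self.tables.values():
            table.write_tsv(outdir)
        write_tsv(self.design, outdir / "design.tsv")
        write_tsv(self.annotation, outdir / "probe_annotation.tsv")
        write_tsv(self.truth, outdir / "truth.tsv")
        write_tsv(self.artifact_log, outdir / "artifact_log.tsv")

    @classmethod
    def read(cls, outdir: str | Path,
             config: SimulationConfig | None = None) -> "SimulatedDataset":
        outdir = Path(outdir)
        tables = {
            "exp1": ProbeTable.read_tsv(outdir, "exp1", TWO_COLOR),
            "exp2": ProbeTable.read_tsv(outdir, "exp2", TWO_COLOR),
            "exp3": ProbeTable.read_tsv(outdir, "exp3", TWO_COLOR),
            "onecolor": ProbeTable.read_tsv(outdir, "onecolor", ONE_COLOR),
        }
        design = read_design(outdir / "design.tsv")
        annotation = read_annotation(outdir / "probe_annotation.tsv")
        truth = pd.read_csv(outdir / "truth.tsv", sep="\t")
        artifact_log = pd.read_csv(outdir / "artifact_log.tsv", sep="\t")
        return cls(config, tables, design, annotation, truth, artifact_log)


# --------------------------------------------------------------------------
# class allocation and true effects
# --------------------------------------------------------------------------

def allocate_classes(config: SimulationConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Assign a planted class to each gene.

    With ``deterministic_allocation`` (default), class counts are exact
    quotas via the largest-remainder method; otherwise they are multinomial.
    Gene order is shuffled either way so classes interleave across the array.
    """
    classes = [c for c in PLANTED_CLASSES if config.class_proportions.get(c, 0) > 0]
    props = np.array([config.class_proportions[c] for c in classes])
    n = config.n_genes
    if config.deterministic_allocation:
        raw = props * n
        counts = np.floor(raw).astype(int)
        rem = n - counts.sum()
        if rem:
            order = np.argsort(-(raw - counts), kind="stable")
            counts[order[:rem]] += 1
    else:
        counts = rng.multinomial(n, props)
    labels = np.repeat(classes, counts)
    return labels[rng.permutation(n)]


def _true_effects(planted: str, sign: int, config: SimulationConfig
                  ) -> dict[tuple[str, str], float]:
    """Per contrast x timepoint expected log2 effect for one gene.

    Splice-discordant genes carry a zero gene-level expectation here; their
    opposite-sign effects are planted at the probe level.
    """
    e = config.effect_size_log2 * sign
    tp1 = config.timepoints_exp1
    tp23 = config.timepoints_exp23
    eff: dict[tuple[str, str], float] = {}
    for tp in tp1:
        eff[(CONTRAST_MG, tp)] = 0.0
    for tp in tp23:
        eff[(CONTRAST_MGHI_HI, tp)] = 0.0
        eff[(CONTRAST_HI, tp)] = 0.0
        eff[(CONTRAST_ONECOLOR, tp)] = 0.0

    if planted == MG_ONLY:
        for tp in tp1:
            eff[(CONTRAST_MG, tp)] = e
    elif planted == BIPHASIC:
        # opposite effects at two successive treatment timepoints
        up_tp = tp1[min(1, len(tp1) - 1)]
        down_tp = tp1[min(2, len(tp1) - 1)]
        eff[(CONTRAST_MG, up_tp)] = e
        eff[(CONTRAST_MG, down_tp)] = -e
    elif planted == HI_ONLY:
        tp = tp23[0]
        eff[(CONTRAST_HI, tp)] = e
        eff[(CONTRAST_ONECOLOR, tp)] = e
    elif planted == DE_NOVO:
        for tp in tp23:
            eff[(CONTRAST_MGHI_HI, tp)] = e
            eff[(CONTRAST_ONECOLOR, tp)] = e
    elif planted == REVERSED:
        for tp in tp23:
            eff[(CONTRAST_HI, tp)] = e
            eff[(CONTRAST_MGHI_HI, tp)] = -e
    elif planted == AMPLIFIED:
        for tp in tp23:
            eff[(CONTRAST_HI, tp)] = e
            eff[(CONTRAST_MGHI_HI, tp)] = e
            eff[(CONTRAST_ONECOLOR, tp)] = 2 * e
    elif planted == INSENSITIVE:
        for tp in tp23:
            eff[(CONTRAST_HI, tp)] = e
            eff[(CONTRAST_ONECOLOR, tp)] = e
    return eff


def _group_means(eff: dict[tuple[str, str], float], tp: str
                 ) -> dict[str, float]:
    """One-color group offsets (relative to Ctrl) at a pooled timepoint."""
    m = eff.get((CONTRAST_MG, tp), 0.0)
    h = eff[(CONTRAST_HI, tp)]
    x = eff[(CONTRAST_ONECOLOR, tp)]
    return {"Ctrl": 0.0, "Mg": m, "HI": h, "MgHI": x}


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def generate_experiment(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full three-experiment dataset with planted truth."""
    rng = np.random.default_rng(config.seed)

    planted = allocate_classes(config, rng)
    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    signs = rng.choice([-1, 1], size=config.n_genes)

    # probe layout ---------------------------------------------------------
    ks = sorted(config.probes_per_gene)
    probs = np.array([config.probes_per_gene[k] for k in ks])
    n_probes_per_gene = rng.choice(ks, size=config.n_genes, p=probs)
    n_probes_per_gene[planted == SPLICE_DISCORDANT] = 2

    probe_rows = []   # (probe_id, gene, status, probe_sign_multiplier)
    for gene, cls, npr in zip(genes, planted, n_probes_per_gene):
        for k in range(1, npr + 1):
            mult = 1.0
            if cls == SPLICE_DISCORDANT and k == 2:
                mult = -1.0
            probe_rows.append((f"{gene}_p{k}", gene, "gene", mult))
    n_riken = round(config.frac_riken * config.n_genes)
    n_ctrlp = round(config.frac_control * config.n_genes)
    for i in range(1, n_riken + 1):
        probe_rows.append((f"RIK{i:04d}_p1", f"{i:07d}Rik", "riken", 0.0))
    for i in range(1, n_ctrlp + 1):
        probe_rows.append((f"CTL{i:04d}_p1", "", "control", 0.0))

    annotation = pd.DataFrame(probe_rows,
                              columns=["probe_id", "gene_symbol", "status",
                                       "_mult"])
    probe_ids = annotation["probe_id"].tolist()
    gene_of_probe = annotation["gene_symbol"].tolist()
    mult = annotation["_mult"].to_numpy()

    # per-gene truth -------------------------------------------------------
    effects = {g: _true_effects(c, s, config)
               for g, c, s in zip(genes, planted, signs)}

    truth_rows = []
    all_keys = sorted({k for e in effects.values() for k in e})
    for g, cls in zip(genes, planted):
        row = {"gene": g, "planted_class": cls,
               "expected_category": EXPECTED_CATEGORY[cls]}
        for (contrast, tp) in all_keys:
            row[f"{contrast}:{tp}"] = effects[g].get((contrast, tp), 0.0)
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    # probe-level expected effect matrix builder ---------------------------
    splice_tp = config.timepoints_exp1[min(2, len(config.timepoints_exp1) - 1)]
    gene_index = {g: i for i, g in enumerate(genes)}

    def probe_effect(contrast: str, tp: str) -> np.ndarray:
        vals = np.zeros(len(probe_ids))
        for i, (g, st, mu) in enumerate(zip(gene_of_probe,
                                            annotation["status"], mult)):
            if st != "gene":
                continue
            gi = gene_index[g]
            cls = planted[gi]
            if cls == SPLICE_DISCORDANT:
                if contrast == CONTRAST_MG and tp == splice_tp:
                    vals[i] = config.effect_size_log2 * signs[gi] * mu
            else:
                vals[i] = effects[g].get((contrast, tp), 0.0)
        return vals

    design_rows = []
    tables: dict[str, ProbeTable] = {}

    # two-color experiments ------------------------------------------------
    exp_specs = [(1, CONTRAST_MG, config.timepoints_exp1, "Mg"),
                 (2, CONTRAST_MGHI_HI, config.timepoints_exp23, "MgHI"),
                 (3, CONTRAST_HI, config.timepoints_exp23, "HI")]
    for exp, contrast, tps, cond in exp_specs:
        cols = {}
        for tp in tps:
            eff = probe_effect(contrast, tp)
            for r in range(1, config.n_replicates + 1):
                sid = f"e{exp}_{tp}_r{r}"
                noise = rng.normal(0.0, config.noise_sd_log2, len(probe_ids))
                cols[sid] = eff + noise
                design_rows.append((sid, exp, cond, tp, r, "ratio"))
        signal = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"))
        uniform = pd.DataFrame(True, index=signal.index,
                               columns=signal.columns)
        tables[f"exp{exp}"] = ProbeTable(f"exp{exp}", TWO_COLOR, signal,
                                         uniform)

    # one-color arrays -----------------------------------------------------
    baseline = rng.uniform(*config.baseline_log2_range, size=len(probe_ids))
    oc_cols = {}
    oc_groups = [("Ctrl", 1), ("Ctrl", 3), ("Mg", 1), ("HI", 3), ("MgHI", 2)]
    for tp in config.timepoints_exp23:
        for cond, exp in oc_groups:
            eff = np.zeros(len(probe_ids))
            for i, (g, st, mu) in enumerate(zip(gene_of_probe,
                                                annotation["status"], mult)):
                if st != "gene":
                    continue
                gi = gene_index[g]
                cls = planted[gi]
                if cls == SPLICE_DISCORDANT:
                    continue  # exp1-only probe-level effect
                eff[i] = _group_means(effects[g], tp)[cond]
            for r in range(1, config.n_replicates + 1):
                sid = f"oc_{cond}{exp}_{tp}_r{r}"
                noise = rng.normal(0.0, config.noise_sd_log2, len(probe_ids))
                oc_cols[sid] = np.exp2(baseline + eff + noise)
                design_rows.append((sid, exp, cond, tp, r, "one_color"))
    oc_signal = pd.DataFrame(oc_cols, index=pd.Index(probe_ids,
                                                     name="probe_id"))
    oc_uniform = pd.DataFrame(True, index=oc_signal.index,
                              columns=oc_signal.columns)
    oc_background = pd.DataFrame(config.background_level,
                                 index=oc_signal.index,
                                 columns=oc_signal.columns)
    tables["onecolor"] = ProbeTable("onecolor", ONE_COLOR, oc_signal,
                                    oc_uniform, oc_background)

    design = pd.DataFrame(design_rows,
                          columns=["sample_id", "experiment", "condition",
                                   "timepoint", "replicate", "channel"])
    annotation = annotation.drop(columns="_mult")

    # quality / detection artifacts ---------------------------------------
    logs = []
    for key in ("exp1", "exp2", "exp3", "onecolor"):
        tables[key], tlog = inject_artifacts(tables[key], config, rng)
        logs.append(tlog)
    artifact_log = pd.concat(logs, ignore_index=True) if logs else \
        pd.DataFrame(columns=["table", "probe_id", "sample_id", "artifact"])

    return SimulatedDataset(config, tables, design, annotation, truth,
                            artifact_log)


def inject_artifacts(table: ProbeTable, config: SimulationConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[ProbeTable, pd.DataFrame]:
    """Flag low-quality spots and push one-color spots below detection.

    Each probe is independently selected with probability
    ``frac_low_quality`` and marked non-uniform in one randomly chosen
    sample (a localized spot defect); each one-color spot is independently
    pushed to ``<= 2 x background`` with probability ``frac_below_detection``.
    All injections are recorded so that QC recovery can be audited.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    table = table.copy()
    records = []

    if config.frac_low_quality > 0:
        hit = rng.random(len(table.probe_ids)) < config.frac_low_quality
        sample_idx = rng.integers(0, table.signal.shape[1],
                                  size=len(table.probe_ids))
        for i in np.flatnonzero(hit):
            pid = table.probe_ids[i]
            sid = table.samples[sample_idx[i]]
            table.uniform.loc[pid, sid] = False
            records.append((table.name, pid, sid, "low_quality"))

    if config.frac_below_detection > 0 and table.kind == ONE_COLOR:
        hit = rng.random(table.signal.shape) < config.frac_below_detection
        factors = rng.uniform(0.2, 2.0, size=table.signal.shape)
        new = table.background.to_numpy() * factors
        sig = table.signal.to_numpy()
        sig[hit] = new[hit]
        table.signal = pd.DataFrame(sig, index=table.signal.index,
                                    columns=table.signal.columns)
        for i, j in zip(*np.nonzero(hit)):
            records.append((table.name, table.probe_ids[i],
                            table.samples[j], "below_detection"))

    log_df = pd.DataFrame(records, columns=["table", "probe_id", "sample_id",
                                            "artifact"])
    return table, log_df
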