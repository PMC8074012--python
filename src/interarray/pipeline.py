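"""End-to-end orchestration: QC -> differential calls -> list algebra ->
enrichment -> report, with a JSON run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import decimal
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .algebra import (DirectionalGeneList, assemble_B, build_A1, build_B1,
                      build_B2, build_B3, build_C, build_list8, build_list9,
                      build_list10, build_list_A, classify_genes,
                      direction_tallies, venn_counts)
from .enrich import (FilterProfile, GeneSetCollection, enrich,
                     ontogeny_concordance, read_gmt, regulator_zscore)
from .qc import exclude_nongene_probes, filter_probes, resolve_multiprobe
from .simulate import SimulatedDataset
from .stats import (add_bh, amplitude_summary, call_differential,
                    equivalent_genes, merge_timepoints, one_color_probe_stats,
                    two_color_probe_stats)
from .tables import write_tsv

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineParams:
    """Thresholds of the analysis, defaulting to the study rules."""

    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    rule: str = "union"
    use_adjusted: bool = True
    detection_factor: float = 2.0
    min_detected: int = 2
    equivalence_p: float = 0.05
    equivalence_band_log2: float = float(np.log2(1.5))
    equal_var: bool = True

    def __post_init__(self) -> None:
        for field in ("fc_threshold", "p_threshold", "detection_factor",
                      "equivalence_p", "equivalence_band_log2"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if self.rule not in ("union", "intersection", "p_only"):
            raise ValueError(f"unknown call rule {self.rule!r}")


@dataclasses.dataclass
class PipelineResult:
    lists: dict[str, DirectionalGeneList]
    classification: pd.DataFrame
    gene_stats: pd.DataFrame
    kinetics: dict[str, pd.DataFrame]
    qc_report: pd.DataFrame
    venn: pd.DataFrame
    summary: pd.DataFrame
    amplitude: pd.DataFrame
    universe: set[str]
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, lst in self.lists.items():
            write_tsv(lst.to_frame(), outdir / f"list_{name}.tsv")
        write_tsv(self.classification, outdir / "classification.tsv")
        write_tsv(self.gene_stats, outdir / "contrast_stats.tsv")
        for name, kin in self.kinetics.items():
            write_tsv(kin, outdir / f"kinetics_{name}.tsv")
        write_tsv(self.qc_report, outdir / "qc_report.tsv")
        write_tsv(self.venn, outdir / "venn_counts.tsv")
        write_tsv(self.summary, outdir / "summary.tsv")
        write_tsv(self.amplitude, outdir / "amplitude_A.tsv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True,
                      default=str)


def _round_half_up(value: float, ndigits: int = 1) -> float:
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(value)).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def analyze(tables, design, annotation, params: PipelineParams | None = None
            ) -> PipelineResult:
    """Run the full in-memory analysis on probe tables.

    ``tables`` maps ``exp1/exp2/exp3/onecolor`` to :class:`ProbeTable`s.
    """
    params = params or PipelineParams()
    timings = {}
    t0 = time.perf_counter()

    # ---- QC --------------------------------------------------------------
    qc_reports = []
    clean = {}
    for name, table in tables.items():
        filtered, report = filter_probes(
            table, design=design, detection_factor=params.detection_factor,
            min_detected=params.min_detected)
        report.insert(0, "table", name)
        qc_reports.append(report)
        clean[name], _ = exclude_nongene_probes(filtered, annotation)
    qc_report = pd.concat(qc_reports, ignore_index=True)
    timings["qc"] = time.perf_counter() - t0

    # ---- differential statistics ----------------------------------------
    t0 = time.perf_counter()
    gene_map = annotation.set_index("probe_id")["gene_symbol"]
    probe_frames = []
    for exp in (1, 2, 3):
        probe_frames.append(two_color_probe_stats(clean[f"exp{exp}"],
                                                  design, exp))
    probe_frames.append(one_color_probe_stats(clean["onecolor"], design,
                                              equal_var=params.equal_var))
    probe_stats = pd.concat(probe_frames, ignore_index=True)
    probe_stats = add_bh(probe_stats)
    probe_stats = call_differential(
        probe_stats, fc_threshold=params.fc_threshold,
        p_threshold=params.p_threshold, rule=params.rule,
        use_adjusted=params.use_adjusted)
    probe_stats["gene"] = probe_stats["probe_id"].map(gene_map)
    gene_stats = resolve_multiprobe(probe_stats)
    timings["stats"] = time.perf_counter() - t0

    # ---- merged directional lists ---------------------------------------
    t0 = time.perf_counter()
    lists: dict[str, DirectionalGeneList] = {}
    kinetics: dict[str, pd.DataFrame] = {}
    for contrast, name in (("mg_vs_ctrl", "L1"), ("mghi_vs_hi", "L2"),
                           ("hi_vs_ctrl", "L3"), ("mghi_vs_ctrl_1c", "L7")):
        sub = gene_stats[gene_stats["contrast"] == contrast]
        lists[name], kinetics[name] = merge_timepoints(sub, name)

    onecolor_gene = gene_stats[gene_stats["contrast"] == "mghi_vs_ctrl_1c"]
    equivalent = equivalent_genes(onecolor_gene,
                                  p_greater_than=params.equivalence_p,
                                  band_log2=params.equivalence_band_log2)

    # ---- list algebra ----------------------------------------------------
    l1, l2, l3, l7 = (lists[k] for k in ("L1", "L2", "L3", "L7"))
    lists["A"] = build_list_A(l1)
    lists["A1"] = build_A1(l1, l2)
    lists["C"] = build_C(l3, l7, l2)
    l10 = build_list10(l3, l7, l2)
    l8 = build_list8(l3, l2)
    l9 = build_list9(l3, equivalent)
    lists["B1"] = build_B1(l2, l3, l1, l7, lists["A1"], lists["C"],
                           l10=l10, extra_subtract=(l8, l9))
    lists["B2"] = build_B2(l2, l3, l7, lists["A1"], equivalent)
    lists["B3"] = build_B3(l3, l7, l2, lists["A1"])
    lists["B"] = assemble_B(lists["B1"], lists["B2"], lists["B3"])

    universe = set()
    for table in clean.values():
        universe |= set(gene_map.loc[table.probe_ids])
    classification = classify_genes(lists, universe)
    timings["algebra"] = time.perf_counter() - t0

    # ---- reporting -------------------------------------------------------
    t0 = time.perf_counter()
    venn = venn_counts({k: lists[k] for k in ("L1", "L2", "L3", "L7")})
    called_a = gene_stats[(gene_stats["contrast"] == "mg_vs_ctrl")
                          & gene_stats["called"]]
    amp = amplitude_summary(called_a)
    amplitude = pd.DataFrame([dataclasses.asdict(v) for v in amp.values()])
    summary = report_summary(lists, kinetics)
    timings["report"] = time.perf_counter() - t0

    manifest = {
        "version": __version__,
        "params": dataclasses.asdict(params),
        "list_sizes": {k: len(v) for k, v in lists.items()},
        "n_universe_genes": len(universe),
        "stage_seconds": {k: round(v, 4) for k, v in timings.items()},
    }
    return PipelineResult(lists, classification, gene_stats, kinetics,
                          qc_report, venn, summary, amplitude, universe,
                          manifest)


def report_summary(lists: dict[str, DirectionalGeneList],
                   kinetics: dict[str, pd.DataFrame] | None = None
                   ) -> pd.DataFrame:
    """Per-list tallies plus headline percentages.

    ``n_distinct = n_induced + n_repressed - n_dual`` always holds, with
    induced/repressed counts inclusive of dual-direction genes.  When
    kinetics are available the treatment list's peak-timepoint share and
    the insult-insensitive retention fraction are appended, rounded
    half-up to one decimal.
    """
    tallies = direction_tallies(lists)
    extras = []
    if kinetics and "L1" in kinetics and not kinetics["L1"].empty \
            and "A" in lists and len(lists["A"]):
        kin = kinetics["L1"]
        peak = kin["peak_timepoint"].iloc[0]
        at_peak = kin.loc[kin["timepoint"] == peak, "gene"].nunique()
        total = len(lists["A"].genes())
        extras.append({"metric": "peak_timepoint_A", "value": peak})
        extras.append({"metric": "pct_A_at_peak",
                       "value": _round_half_up(100.0 * at_peak / total)})
    if "C" in lists and "L3" in lists and len(lists["L3"]):
        pct = 100.0 * len(lists["C"].genes()) / len(lists["L3"].genes())
        extras.append({"metric": "pct_HI_effects_insensitive",
                       "value": _round_half_up(pct)})
    tallies["metric"] = "list_tally"
    if extras:
        tallies = pd.concat([tallies, pd.DataFrame(extras)],
                            ignore_index=True)
    return tallies


# --------------------------------------------------------------------------
# file-based run
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """File-based pipeline configuration (mirrors the YAML schema)."""

    data_dir: str
    outdir: str
    params: PipelineParams = dataclasses.field(default_factory=PipelineParams)
    gene_sets: str | None = None
    network: str | None = None
    dev_table: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load inputs, run the analysis, write all outputs and the manifest."""
    data_dir = Path(config.data_dir)
    dataset = SimulatedDataset.read(data_dir)
    result = analyze(dataset.tables, dataset.design, dataset.annotation,
                     config.params)

    checksums = {p.name: _checksum(p)
                 for p in sorted(data_dir.glob("*.tsv"))}
    result.manifest["input_checksums"] = checksums
    result.manifest["config"] = {
        "data_dir": str(config.data_dir), "outdir": str(config.outdir),
        "gene_sets": config.gene_sets, "network": config.network,
        "dev_table": config.dev_table}

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.gene_sets:
        collection = GeneSetCollection(read_gmt(config.gene_sets),
                                       result.universe)
        for name in ("A", "B"):
            if len(lst := result.lists[name]):
                table = enrich(lst, collection, FilterProfile.keyword())
                write_tsv(table, outdir / f"enrichment_{name}.tsv")
    if config.network:
        network = pd.read_csv(config.network, sep="\t")
        for name in ("A", "B"):
            if len(lst := result.lists[name]):
                table = regulator_zscore(lst, network, result.universe)
                write_tsv(table, outdir / f"regulators_{name}.tsv")
    if config.dev_table:
        dev = pd.read_csv(config.dev_table, sep="\t")
        records, counts = ontogeny_concordance(result.lists["A"], dev)
        write_tsv(records, outdir / "ontogeny_A.tsv")
        result.manifest["ontogeny_counts_A"] = counts

    result.write(outdir)
    log.info("pipeline complete: %s", result.manifest["list_sizes"])
    return result
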