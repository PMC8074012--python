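"""Shared tabular containers and TSV I/O.

A :class:`ProbeTable` bundles the probe-level measurement matrix with its
per-spot uniformity flags and, for one-color data, the per-spot background
estimates.  Two-color tables hold normalized log2 test/reference ratios;
one-color tables hold linear-scale intensities so that the detection rule
(signal vs. a multiple of background) can be applied on the scale on which
scanners report it.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

TWO_COLOR = "two_color"
ONE_COLOR = "one_color"

#: canonical contrast names used throughout the pipeline
CONTRAST_MG = "mg_vs_ctrl"          # experiment 1, two-color  (list L1)
CONTRAST_MGHI_HI = "mghi_vs_hi"     # experiment 2, two-color  (list L2)
CONTRAST_HI = "hi_vs_ctrl"          # experiment 3, two-color  (list L3)
CONTRAST_ONECOLOR = "mghi_vs_ctrl_1c"  # pooled one-color comparison (list L7)

CONTRAST_BY_EXPERIMENT = {1: CONTRAST_MG, 2: CONTRAST_MGHI_HI, 3: CONTRAST_HI}

DESIGN_COLUMNS = ["sample_id", "experiment", "condition", "timepoint",
                  "replicate", "channel"]
ANNOTATION_COLUMNS = ["probe_id", "gene_symbol", "status"]
PROBE_STATUSES = ("gene", "riken", "control")


@dataclasses.dataclass
class ProbeTable:
    """Probe-level measurements for one hybridization batch.

    Parameters
    ----------
    name
        Batch label (e.g. ``"exp1"`` or ``"onecolor"``).
    kind
        ``"two_color"`` (values are log2 ratios) or ``"one_color"``
        (values are linear intensities; ``background`` is required).
    signal
        probes x samples matrix, indexed by probe_id.
    uniform
        Boolean matrix of spot-uniformity flags, same shape as ``signal``.
    background
        Positive background matrix for one-color tables, same shape.
    """

    name: str
    kind: str
    signal: pd.DataFrame
    uniform: pd.DataFrame
    background: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in (TWO_COLOR, ONE_COLOR):
            raise ValueError(f"unknown table kind {self.kind!r}")
        if not self.signal.index.is_unique:
            dups = self.signal.index[self.signal.index.duplicated()].unique()
            raise ValueError(f"duplicate probe ids: {list(dups)[:5]}")
        if self.uniform.shape != self.signal.shape:
            raise ValueError("uniform flags must match signal shape")
        if self.kind == ONE_COLOR:
            if self.background is None:
                raise ValueError(
                    f"one-color table {self.name!r} requires background values")
            if self.background.shape != self.signal.shape:
                raise ValueError("background must match signal shape")
            if (self.background <= 0).any().any():
                raise ValueError("background must be positive")

    @property
    def probe_ids(self) -> pd.Index:
        return self.signal.index

    @property
    def samples(self) -> pd.Index:
        return self.signal.columns

    def subset(self, probe_ids) -> "ProbeTable":
        bg = None if self.background is None else self.background.loc[probe_ids]
        return ProbeTable(self.name, self.kind, self.signal.loc[probe_ids],
                          self.uniform.loc[probe_ids], bg)

    def copy(self) -> "ProbeTable":
        bg = None if self.background is None else self.background.copy()
        return ProbeTable(self.name, self.kind, self.signal.copy(),
                          self.uniform.copy(), bg)

    # ------------------------------------------------------------- I/O ----
    def write_tsv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.signal.to_csv(outdir / f"{self.name}_signal.tsv", sep="\t",
                           index_label="probe_id")
        self.uniform.astype(int).to_csv(
            outdir / f"{self.name}_uniform.tsv", sep="\t",
            index_label="probe_id")
        if self.background is not None:
            self.background.to_csv(outdir / f"{self.name}_background.tsv",
                                   sep="\t", index_label="probe_id")

    @classmethod
    def read_tsv(cls, outdir: str | Path, name: str, kind: str) -> "ProbeTable":
        outdir = Path(outdir)
        signal = pd.read_csv(outdir / f"{name}_signal.tsv", sep="\t",
                             index_col="probe_id")
        uniform = pd.read_csv(outdir / f"{name}_uniform.tsv", sep="\t",
                              index_col="probe_id").astype(bool)
        background = None
        bg_path = outdir / f"{name}_background.tsv"
        if bg_path.exists():
            background = pd.read_csv(bg_path, sep="\t", index_col="probe_id")
        return cls(name, kind, signal, uniform, background)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"timepoint": str})
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design file {path} lacks columns {sorted(missing)}")
    return design


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(
            f"annotation file {path} lacks columns {sorted(missing)}")
    bad = set(ann["status"].unique()) - set(PROBE_STATUSES)
    if bad:
        raise ValueError(f"unknown probe status values {sorted(bad)}")
    return ann


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
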