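"""Gene-set over-representation, regulator direction and ontogeny statistics.

Over-representation follows the classical 2x2 layout: a query list of *n*
genes drawn from a universe of *N*, a gene set of *K* members, *k* of which
occur in the query.  ``fisher_exact`` is the right-tailed hypergeometric
tail P(X >= k); ``ease_score`` is its conservative jackknifed variant that
removes one overlapping gene before computing the tail (so singleton
overlaps are never significant).  Fold enrichment is (k/n)/(K/N).

Filter profiles mirror common annotation-tool practice: a keyword/GO
profile (count >= 10 and either Bonferroni < 1e-4 or EASE < 1e-4 with
FE > 2) and a pathway profile (count >= 10, Bonferroni < 0.05, FDR < 10%).

The regulator z-score tests sign-consistency of a signed regulator->target
network against observed directions: with ``n_c`` consistent and ``n_i``
inconsistent targets, z = (n_c - n_i) / sqrt(n_c + n_i); |z| > 2 (strict)
predicts activation or inhibition.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .algebra import DirectionalGeneList
from .stats import bh_adjust

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# elementary statistics
# --------------------------------------------------------------------------

def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and 0 < n <= N and 0 < K <= N):
        raise ValueError(
            f"inconsistent contingency counts k={k}, n={n}, K={K}, N={N}")


def fisher_exact(k: int, n: int, K: int, N: int) -> float:
    """Right-tailed Fisher exact test: P(overlap >= k)."""
    _check_counts(k, n, K, N)
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """Jackknifed Fisher tail with the overlap penalized by one gene."""
    _check_counts(k, n, K, N)
    if k <= 1:
        return 1.0
    return fisher_exact(k - 1, n, K, N)


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    _check_counts(k, n, K, N)
    return (k / n) / (K / N)


# --------------------------------------------------------------------------
# gene-set collections (GMT)
# --------------------------------------------------------------------------

@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets harmonized against a universe of analysable genes."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        harmonized = {}
        for name, members in self.sets.items():
            inter = set(members) & self.universe
            if not inter:
                log.warning("gene set %s has no genes in the universe; "
                            "dropped", name)
                continue
            harmonized[name] = inter
        self.sets = harmonized

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: per line, set name, description, then genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs at least "
                                 "name, description and one gene")
            genes = {g for g in fields[2:] if g}
            sets[fields[0]] = genes
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# --------------------------------------------------------------------------
# enrichment over a collection
# --------------------------------------------------------------------------

@dataclasses.dataclass
class FilterProfile:
    """Significance filter applied to each enrichment row.

    ``rule="bonferroni_or_ease"`` reproduces the keyword/GO profile
    (Bonferroni < bonferroni_max OR EASE < ease_max with FE > min_fe);
    ``rule="bonferroni_and_fdr"`` the pathway profile.  ``min_count``
    always applies.
    """

    name: str = "keyword"
    rule: str = "bonferroni_or_ease"
    min_count: int = 10
    bonferroni_max: float = 1e-4
    ease_max: float = 1e-4
    min_fe: float = 2.0
    fdr_max: float = 0.10

    @classmethod
    def keyword(cls) -> "FilterProfile":
        return cls()

    @classmethod
    def pathway(cls) -> "FilterProfile":
        return cls(name="pathway", rule="bonferroni_and_fdr",
                   bonferroni_max=5e-2, fdr_max=0.10)

    def passes(self, k: int, p_ease: float, fe: float, bonferroni: float,
               fdr: float) -> bool:
        if k < self.min_count:
            return False
        if self.rule == "bonferroni_or_ease":
            return (bonferroni < self.bonferroni_max
                    or (p_ease < self.ease_max and fe > self.min_fe))
        if self.rule == "bonferroni_and_fdr":
            return bonferroni < self.bonferroni_max and fdr < self.fdr_max
        raise ValueError(f"unknown filter rule {self.rule!r}")


def enrich(query: DirectionalGeneList | Iterable[str],
           collection: GeneSetCollection,
           profile: FilterProfile | None = None) -> pd.DataFrame:
    """Over-representation of every set of the collection in the query.

    Directional queries are flattened to gene level: set membership is
    direction-blind.  Bonferroni and BH-FDR columns adjust the EASE
    p-value over the collection (one family per call).
    """
    if isinstance(query, DirectionalGeneList):
        query_genes = query.genes()
    else:
        query_genes = set(query)
    query_genes &= collection.universe
    if not query_genes:
        raise ValueError("query has no genes in the universe")
    profile = profile or FilterProfile.keyword()

    N = len(collection.universe)
    n = len(query_genes)
    m = len(collection.sets)
    rows = []
    for set_name in sorted(collection.sets):
        members = collection.sets[set_name]
        K = len(members)
        k = len(members & query_genes)
        p_f = fisher_exact(k, n, K, N)
        p_e = ease_score(k, n, K, N)
        fe = fold_enrichment(k, n, K, N)
        rows.append({"set_name": set_name, "k": k, "n": n, "K": K, "N": N,
                     "p_fisher": p_f, "p_ease": p_e, "FE": fe})
    out = pd.DataFrame(rows)
    if out.empty:
        for col in ("p_bonferroni", "fdr", "passes_filter"):
            out[col] = []
        return out
    out["p_bonferroni"] = np.minimum(1.0, out["p_ease"] * m)
    out["fdr"] = bh_adjust(out["p_ease"].to_numpy())
    out["passes_filter"] = [
        profile.passes(r.k, r.p_ease, r.FE, r.p_bonferroni, r.fdr)
        for r in out.itertuples()]
    return out.sort_values("p_ease", kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# signed-network regulator statistic
# --------------------------------------------------------------------------

def regulator_zscore(query: DirectionalGeneList, network: pd.DataFrame,
                     universe: Iterable[str]) -> pd.DataFrame:
    """Activation z-score per regulator of a signed target network.

    ``network`` needs columns ``regulator, target, sign`` with sign in
    {+1, -1}.  A target counted as consistent supports activation:
    edge sign times observed direction (+1 induced / -1 repressed) is +1.
    Genes carrying both directions are ambiguous and skipped.  Regulators
    with no overlapping directed target are omitted.  ``p_overlap`` is the
    right-tailed Fisher test of the target-set overlap with the query.
    """
    required = {"regulator", "target", "sign"}
    if not required <= set(network.columns):
        raise ValueError(f"network needs columns {sorted(required)}")
    if network.duplicated(["regulator", "target"]).any():
        raise ValueError("duplicate (regulator, target) edges")
    if not set(network["sign"].unique()) <= {1, -1}:
        raise ValueError("edge signs must be +1 or -1")

    universe = set(universe)
    direction_num: dict[str, int] = {}
    for gene in query.genes():
        dirs = query.directions_of(gene)
        if len(dirs) == 1:
            direction_num[gene] = 1 if "induced" in dirs else -1
    query_genes = query.genes() & universe
    N = len(universe)

    rows = []
    for regulator, edges in network.groupby("regulator"):
        targets = set(edges["target"]) & universe
        if not targets:
            continue
        overlap = targets & query_genes
        directed = [t for t in overlap if t in direction_num]
        if not overlap:
            continue
        n_c = n_i = 0
        sign_of = dict(zip(edges["target"], edges["sign"]))
        for t in directed:
            if sign_of[t] * direction_num[t] == 1:
                n_c += 1
            else:
                n_i += 1
        total = n_c + n_i
        z = (n_c - n_i) / math.sqrt(total) if total else 0.0
        if z > 2:
            state = "activated"
        elif z < -2:
            state = "inhibited"
        else:
            state = "undetermined"
        p_overlap = fisher_exact(len(overlap), len(query_genes),
                                 len(targets), N)
        rows.append({"regulator": regulator, "n_targets": len(targets),
                     "n_overlap": len(overlap), "n_consistent": n_c,
                     "n_inconsistent": n_i, "z": z, "p_overlap": p_overlap,
                     "predicted_state": state})
    return pd.DataFrame(rows, columns=["regulator", "n_targets", "n_overlap",
                                       "n_consistent", "n_inconsistent", "z",
                                       "p_overlap", "predicted_state"])


# --------------------------------------------------------------------------
# ontogeny concordance
# --------------------------------------------------------------------------

def ontogeny_concordance(query: DirectionalGeneList, dev_table: pd.DataFrame
                         ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Compare effect directions with spontaneous developmental trajectories.

    ``dev_table`` needs columns ``gene, direction`` with direction in
    {increasing, decreasing}.  An induced gene on an increasing trajectory
    (or repressed on a decreasing one) *anticipates* ontogeny; otherwise it
    is antagonistic.  Query genes absent from the table are skipped and
    counted.
    """
    allowed = {"increasing", "decreasing"}
    bad = set(dev_table["direction"].unique()) - allowed
    if bad:
        raise ValueError(f"developmental directions must be in {allowed}, "
                         f"got {sorted(bad)}")
    dev = dict(zip(dev_table["gene"], dev_table["direction"]))
    rows = []
    counts = {"anticipating_increase": 0, "anticipating_decrease": 0,
              "antagonistic": 0, "skipped": 0}
    skipped_genes = set()
    for gene, direction in sorted(query.pairs()):
        if gene not in dev:
            skipped_genes.add(gene)
            continue
        dev_dir = dev[gene]
        anticipating = ((direction == "induced" and dev_dir == "increasing")
                        or (direction == "repressed"
                            and dev_dir == "decreasing"))
        concordance = "anticipating" if anticipating else "antagonistic"
        if anticipating:
            counts["anticipating_increase" if dev_dir == "increasing"
                   else "anticipating_decrease"] += 1
        else:
            counts["antagonistic"] += 1
        rows.append({"gene": gene, "effect_direction": direction,
                     "developmental_direction": dev_dir,
                     "concordance": concordance})
    counts["skipped"] = len(skipped_genes)
    records = pd.DataFrame(rows, columns=["gene", "effect_direction",
                                          "developmental_direction",
                                          "concordance"])
    return records, counts
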