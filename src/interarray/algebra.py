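"""Directional gene-list set algebra for treatment-by-insult designs.

The four primary contrasts produce directional gene lists:

* ``L1`` — treatment vs. control (two-color, treatment-only experiment)
* ``L2`` — treated-insult vs. insult (two-color)
* ``L3`` — insult vs. control (two-color)
* ``L7`` — treated-insult vs. pooled control (one-color)

From these, intermediate lists and final categories are derived:

* ``A``  = L1: proper treatment effects.
* ``A1`` (= L4): same-direction overlap of L1 and L2 — treatment effects
  unchanged by the insult.
* ``L5`` = L2 minus L3 genes; ``L6`` = opposite overlap of L1 and L2.
* ``B1`` = (L5 + L6 + L7) − A1 − L11 − L10: effects of the insult appearing
  *de novo* under pretreatment.
* ``L8`` = opposite overlap of L3 and L2; ``L9`` = L3 genes whose one-color
  comparison shows no difference; ``B2`` = (L8 + L9) − A1: insult effects
  reversed by the treatment (direction = the treatment's modulation,
  opposite to the L3 direction).
* ``L10`` = same-direction overlap of L3 and L7 with a same-sign L2 call
  (the direct treated-insult vs. insult contrast evidences amplification);
  ``B3`` = L10 − A1: amplified insult effects.
* ``C``  (= L11): same-direction overlap of L3 and L7 with L2 silent —
  insult effects insensitive to the treatment.

Subtraction removes matching (gene, direction) entries when the subtrahend
is directional, and whole genes when it is direction-free.
"""

from __future__ import annotations

import itertools
import logging
from collections.abc import Iterable

import pandas as pd

log = logging.getLogger(__name__)

DIRECTIONS = ("induced", "repressed")
OPPOSITE = {"induced": "repressed", "repressed": "induced"}

CATEGORIES = ("MG_ONLY", "SHARED", "DE_NOVO", "REVERSED", "AMPLIFIED",
              "INSENSITIVE", "UNAFFECTED")


class DirectionalGeneList:
    """A named set of (gene, direction) entries with flags and provenance.

    A (gene, direction) pair appears at most once; a gene may legitimately
    carry both directions only when flagged ``biphasic`` or
    ``splice_conflict`` (or when the list is an intermediate overlap whose
    semantics allow it, e.g. an ``opposite``-mode overlap).
    """

    def __init__(self, name: str, entries: Iterable[tuple[str, str]] = ()):
        self.name = name
        self._flags: dict[tuple[str, str], set[str]] = {}
        self._sources: dict[tuple[str, str], set[str]] = {}
        for gene, direction in entries:
            self.add(gene, direction)

    # ------------------------------------------------------------ basics --
    def add(self, gene: str, direction: str, flags: Iterable[str] = (),
            source: str | None = None) -> None:
        if direction not in DIRECTIONS:
            raise ValueError(f"invalid direction {direction!r}")
        key = (gene, direction)
        self._flags.setdefault(key, set()).update(flags)
        src = self._sources.setdefault(key, set())
        if source:
            src.add(source)

    def pairs(self) -> set[tuple[str, str]]:
        return set(self._flags)

    def genes(self) -> set[str]:
        return {g for g, _ in self._flags}

    def directions_of(self, gene: str) -> set[str]:
        return {d for g, d in self._flags if g == gene}

    def flags(self, gene: str, direction: str) -> set[str]:
        return set(self._flags.get((gene, direction), set()))

    def sources(self, gene: str, direction: str) -> set[str]:
        return set(self._sources.get((gene, direction), set()))

    def dual_direction_genes(self) -> set[str]:
        return {g for g in self.genes() if len(self.directions_of(g)) == 2}

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._flags

    def __len__(self) -> int:
        return len(self._flags)

    def __iter__(self):
        return iter(sorted(self._flags))

    def __repr__(self) -> str:
        return f"<DirectionalGeneList {self.name}: {len(self)} entries>"

    def rename(self, name: str) -> "DirectionalGeneList":
        out = self.copy()
        out.name = name
        return out

    def copy(self) -> "DirectionalGeneList":
        out = DirectionalGeneList(self.name)
        out._flags = {k: set(v) for k, v in self._flags.items()}
        out._sources = {k: set(v) for k, v in self._sources.items()}
        return out

    def validate(self) -> None:
        """Dual-direction genes must be explained by a flag."""
        for gene in self.dual_direction_genes():
            ok = any(self._flags[(gene, d)] & {"biphasic", "splice_conflict"}
                     for d in self.directions_of(gene))
            if not ok:
                raise ValueError(
                    f"list {self.name}: gene {gene} carries both directions "
                    "without a biphasic/splice_conflict flag")

    # --------------------------------------------------------- set algebra --
    def union(self, *others: "DirectionalGeneList",
              name: str | None = None) -> "DirectionalGeneList":
        out = self.copy()
        out.name = name or self.name
        for other in others:
            for key, flags in other._flags.items():
                out._flags.setdefault(key, set()).update(flags)
                out._sources.setdefault(key, set()).update(
                    other._sources.get(key, set()) or {other.name})
        return out

    def subtract_pairs(self, other: "DirectionalGeneList",
                       name: str | None = None) -> "DirectionalGeneList":
        """Remove (gene, direction) entries present in ``other``."""
        out = DirectionalGeneList(name or self.name)
        drop = other.pairs()
        out._flags = {k: set(v) for k, v in self._flags.items()
                      if k not in drop}
        out._sources = {k: set(v) for k, v in self._sources.items()
                        if k not in drop}
        return out

    def subtract_genes(self, other: "DirectionalGeneList",
                       name: str | None = None) -> "DirectionalGeneList":
        """Remove whole genes present in ``other`` (direction-free)."""
        out = DirectionalGeneList(name or self.name)
        drop = other.genes()
        out._flags = {k: set(v) for k, v in self._flags.items()
                      if k[0] not in drop}
        out._sources = {k: set(v) for k, v in self._sources.items()
                        if k[0] not in drop}
        return out

    # ------------------------------------------------------------ frames --
    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene": g, "direction": d,
                 "flags": ";".join(sorted(self._flags[(g, d)])),
                 "provenance": ";".join(sorted(self._sources[(g, d)]))}
                for g, d in sorted(self._flags)]
        return pd.DataFrame(rows, columns=["gene", "direction", "flags",
                                           "provenance"])

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame
                   ) -> "DirectionalGeneList":
        out = cls(name)
        for row in frame.itertuples():
            flags = [f for f in str(getattr(row, "flags", "") or "").split(";")
                     if f and f != "nan"]
            out.add(row.gene, row.direction, flags=flags)
        return out


def directional_overlap(x: DirectionalGeneList, y: DirectionalGeneList,
                        mode: str, name: str | None = None,
                        keep: str = "both") -> DirectionalGeneList:
    """Overlap of two directional lists.

    ``mode="same"`` keeps pairs with equal direction in both lists;
    ``"opposite"`` keeps genes whose directions disagree, reporting the
    direction(s) selected by ``keep`` (``"x"``, ``"y"`` or ``"both"``);
    ``"any"`` intersects at gene level, keeping x's entries.
    """
    if mode not in ("same", "opposite", "any"):
        raise ValueError(f"invalid overlap mode {mode!r}")
    out = DirectionalGeneList(name or f"{x.name}&{y.name}")
    if mode == "same":
        for gene, d in x.pairs() & y.pairs():
            out.add(gene, d, flags=x.flags(gene, d) | y.flags(gene, d),
                    source=f"{x.name}&{y.name}")
    elif mode == "opposite":
        for gene, d in x.pairs():
            if (gene, OPPOSITE[d]) in y:
                dirs = {"x": (d,), "y": (OPPOSITE[d],),
                        "both": (d, OPPOSITE[d])}[keep]
                for dd in dirs:
                    out.add(gene, dd, source=f"{x.name}~{y.name}")
    else:
        shared = x.genes() & y.genes()
        for gene, d in x.pairs():
            if gene in shared:
                out.add(gene, d, flags=x.flags(gene, d),
                        source=f"{x.name}&{y.name}")
    return out


# --------------------------------------------------------------------------
# named list constructions
# --------------------------------------------------------------------------

def build_list_A(exp1_merged: DirectionalGeneList) -> DirectionalGeneList:
    """Proper treatment effects: the merged treatment-only list."""
    a = exp1_merged.rename("A")
    a.validate()
    return a


def build_A1(l1: DirectionalGeneList, l2: DirectionalGeneList
             ) -> DirectionalGeneList:
    """Treatment effects persisting in the insult context (same direction)."""
    return directional_overlap(l1, l2, "same", name="A1")


def build_list5(l2: DirectionalGeneList, l3: DirectionalGeneList
                ) -> DirectionalGeneList:
    """Effects under pretreatment absent from the insult-only experiment."""
    return l2.subtract_genes(l3, name="L5")


def build_list6(l1: DirectionalGeneList, l2: DirectionalGeneList
                ) -> DirectionalGeneList:
    """Treatment effects inverted in the insult context (L2's direction)."""
    return directional_overlap(l1, l2, "opposite", name="L6", keep="y")


def build_list8(l3: DirectionalGeneList, l2: DirectionalGeneList
                ) -> DirectionalGeneList:
    """Insult effects inverted by the treatment (direction = modulation)."""
    return directional_overlap(l3, l2, "opposite", name="L8", keep="y")


def build_list9(l3: DirectionalGeneList, equivalent: set[str]
                ) -> DirectionalGeneList:
    """Insult effects levelled back to control in one-color data.

    Entries take the direction of the treatment's modulation, i.e. the
    opposite of the insult-only direction.
    """
    out = DirectionalGeneList("L9")
    for gene, d in l3.pairs():
        if gene in equivalent:
            out.add(gene, OPPOSITE[d], source="L9")
    return out


def build_list10(l3: DirectionalGeneList, l7: DirectionalGeneList,
                 l2: DirectionalGeneList) -> DirectionalGeneList:
    """Amplified insult effects: same sense in L3 and L7 with a same-sign
    call in the direct treated-insult vs. insult contrast."""
    base = directional_overlap(l3, l7, "same", name="L10")
    out = DirectionalGeneList("L10")
    for gene, d in base.pairs():
        if (gene, d) in l2:
            out.add(gene, d, flags=base.flags(gene, d), source="L10")
    return out


def build_C(l3: DirectionalGeneList, l7: DirectionalGeneList,
            l2: DirectionalGeneList) -> DirectionalGeneList:
    """Insult effects insensitive to the treatment (L11): same sense in L3
    and L7 while the treated-insult vs. insult contrast is silent."""
    base = directional_overlap(l3, l7, "same", name="C")
    out = DirectionalGeneList("C")
    silent = base.genes() - l2.genes()
    for gene, d in base.pairs():
        if gene in silent:
            out.add(gene, d, flags=base.flags(gene, d), source="L11")
    return out


def build_B1(l2: DirectionalGeneList, l3: DirectionalGeneList,
             l1: DirectionalGeneList, l7: DirectionalGeneList,
             l4: DirectionalGeneList, l11: DirectionalGeneList,
             l10: DirectionalGeneList | None = None,
             extra_subtract: Iterable[DirectionalGeneList] = ()
             ) -> DirectionalGeneList:
    """De novo effects: (L5 + L6 + L7) − A1 − L11 [− L10 − extras].

    L10 (amplified) entries are also removed whenever available: they reach
    L7 by construction, but they belong to the amplification list, and the
    final categories must partition the (gene, direction) entries.
    ``extra_subtract`` lets the pipeline remove reversal-claimed entries
    (L8, L9) the same way.
    """
    l5 = build_list5(l2, l3)
    l6 = build_list6(l1, l2)
    b1 = l5.union(l6, l7, name="B1")
    b1 = b1.subtract_pairs(l4).subtract_pairs(l11)
    if l10 is not None:
        b1 = b1.subtract_pairs(l10)
    for other in extra_subtract:
        b1 = b1.subtract_pairs(other)
    b1.name = "B1"
    return b1


def build_B2(l2: DirectionalGeneList, l3: DirectionalGeneList,
             l7: DirectionalGeneList, l4: DirectionalGeneList,
             equivalent: set[str]) -> DirectionalGeneList:
    """Reversed effects: (L8 + L9) − A1."""
    l8 = build_list8(l3, l2)
    l9 = build_list9(l3, equivalent)
    b2 = l8.union(l9, name="B2").subtract_pairs(l4)
    b2.name = "B2"
    return b2


def build_B3(l3: DirectionalGeneList, l7: DirectionalGeneList,
             l2: DirectionalGeneList, l4: DirectionalGeneList
             ) -> DirectionalGeneList:
    """Amplified effects: L10 − A1."""
    b3 = build_list10(l3, l7, l2).subtract_pairs(l4)
    b3.name = "B3"
    return b3


def assemble_B(b1: DirectionalGeneList, b2: DirectionalGeneList,
               b3: DirectionalGeneList) -> DirectionalGeneList:
    """Concatenate the three modulation sub-lists; they must be disjoint."""
    for x, y in itertools.combinations((b1, b2, b3), 2):
        overlap = x.pairs() & y.pairs()
        if overlap:
            raise AssertionError(
                f"sub-lists {x.name} and {y.name} overlap on "
                f"{sorted(overlap)[:5]}")
    b = b1.union(b2, b3, name="B")
    for gene, d in b.pairs():
        for sub in (b1, b2, b3):
            if (gene, d) in sub:
                b.add(gene, d, source=sub.name)
    return b


# --------------------------------------------------------------------------
# classification and overlap counts
# --------------------------------------------------------------------------

def classify_genes(lists: dict[str, DirectionalGeneList],
                   universe: Iterable[str]) -> pd.DataFrame:
    """Assign each (gene, direction) entry to its final category.

    ``lists`` must contain A, A1, B1, B2, B3 and C.  Genes of the universe
    absent from every list are reported once as UNAFFECTED.  Precedence is
    B1/B2/B3/C (disjoint by construction), then SHARED (A1), then MG_ONLY
    (A outside A1); provenance records every list the entry belongs to.
    """
    category_of = [("B1", "DE_NOVO"), ("B2", "REVERSED"),
                   ("B3", "AMPLIFIED"), ("C", "INSENSITIVE"),
                   ("A1", "SHARED"), ("A", "MG_ONLY")]
    rows = []
    seen_genes = set()
    all_pairs = set()
    for key, _ in category_of:
        all_pairs |= lists[key].pairs()
    for gene, direction in sorted(all_pairs):
        provenance = [key for key, _ in category_of
                      if (gene, direction) in lists[key]]
        category = next(cat for key, cat in category_of
                        if (gene, direction) in lists[key])
        flags = set()
        for key, _ in category_of:
            if (gene, direction) in lists[key]:
                flags |= lists[key].flags(gene, direction)
        rows.append({"gene": gene, "direction": direction,
                     "category": category,
                     "provenance": ";".join(provenance),
                     "flags": ";".join(sorted(flags))})
        seen_genes.add(gene)
    for gene in sorted(set(universe) - seen_genes):
        rows.append({"gene": gene, "direction": "none",
                     "category": "UNAFFECTED", "provenance": "",
                     "flags": ""})
    return pd.DataFrame(rows, columns=["gene", "direction", "category",
                                       "provenance", "flags"])


def venn_counts(lists: dict[str, DirectionalGeneList]) -> pd.DataFrame:
    """Gene-level sizes and all pairwise/triple overlap counts."""
    names = list(lists)
    gene_sets = {n: lists[n].genes() for n in names}
    rows = [{"lists": n, "n_genes": len(gene_sets[n])} for n in names]
    for r in (2, 3):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(gene_sets[n] for n in combo))
            rows.append({"lists": "&".join(combo), "n_genes": len(inter)})
    return pd.DataFrame(rows)


def direction_tallies(lists: dict[str, DirectionalGeneList]) -> pd.DataFrame:
    """Induction/repression/dual tallies per list.

    ``distinct`` counts genes, with dual-direction genes counted once:
    distinct = induced + repressed − dual.
    """
    rows = []
    for name, lst in lists.items():
        induced = sum(1 for g in lst.genes()
                      if "induced" in lst.directions_of(g))
        repressed = sum(1 for g in lst.genes()
                        if "repressed" in lst.directions_of(g))
        dual = len(lst.dual_direction_genes())
        rows.append({"list": name, "n_induced": induced,
                     "n_repressed": repressed, "n_dual": dual,
                     "n_distinct": induced + repressed - dual})
    return pd.DataFrame(rows)
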