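"""Single-gene-tree ancestry binning.

Given an unrooted gene tree with bootstrap supports and leaves labelled
``TAXONID_seqid``, a tree is assigned to a taxonomic bin when some
bipartition with support at or above a threshold (default 75) separates a
clan consisting of the focal taxon's sequences plus members of exactly one
defined taxonomic group — the sister-clade evidence used to detect
endosymbiotic / lateral gene transfer in mosaic genomes. A tree contained
in two such bipartitions for two different groups is assigned to both bins.

Upstream prefilters (minimum homolog count at a BLAST E-value cutoff,
minimum trimmed-alignment length with all sequences determined) are
implemented here as table filters; running the external search, alignment
and tree-inference tools is out of scope — their outputs are the inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

#: Default thresholds of the classification funnel.
DEFAULT_EVALUE_MAX = 1e-2
DEFAULT_MIN_HITS = 3
DEFAULT_MIN_ALN_LEN = 74  # retained iff length strictly greater
DEFAULT_SUPPORT_MIN = 75.0


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

class TaxonGroupMap:
    """Disjoint taxonomic groups plus a focal taxon.

    Parameters
    ----------
    groups
        Mapping of group name to the set of taxon identifiers it contains.
    focal_taxon
        The taxon whose gene ancestry is being classified; it must not be
        a member of any group.
    """

    def __init__(self, groups: Mapping[str, Iterable[str]], focal_taxon: str):
        self.groups: dict[str, frozenset[str]] = {
            name: frozenset(taxa) for name, taxa in groups.items()
        }
        self.focal_taxon = focal_taxon
        seen: dict[str, str] = {}
        for name, taxa in self.groups.items():
            if not taxa:
                raise ValueError(f"group {name!r} is empty")
            for t in taxa:
                if t in seen:
                    raise ValueError(
                        f"taxon {t!r} in both {seen[t]!r} and {name!r}; "
                        "groups must be disjoint"
                    )
                seen[t] = name
        if focal_taxon in seen:
            raise ValueError(f"focal taxon {focal_taxon!r} belongs to group "
                             f"{seen[focal_taxon]!r}")
        self._taxon_to_group = seen

    def group_of(self, taxon: str) -> str | None:
        """Group name for ``taxon``, or None if unmapped / focal."""
        return self._taxon_to_group.get(taxon)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self._taxon_to_group)

    @classmethod
    def from_tsv(cls, path: str | Path, focal_taxon: str) -> "TaxonGroupMap":
        """Read a two-column TSV ``taxon_id<TAB>group_name``."""
        groups: dict[str, set[str]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, group = line.split("\t")[:2]
            groups.setdefault(group, set()).add(taxon)
        return cls(groups, focal_taxon)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for group in sorted(self.groups):
                for taxon in sorted(self.groups[group]):
                    fh.write(f"{taxon}\t{group}\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Clan:
    """One bipartition of the leaf set, induced by an internal edge."""
    side: frozenset[str]
    complement: frozenset[str]
    support: float | None


def leaf_taxon(label: str) -> str:
    """Taxon identifier of a leaf: the first underscore-delimited field."""
    return label.split("_", 1)[0]


class SupportTree:
    """An unrooted gene tree with support-annotated internal edges.

    Supports are bootstrap percentages in [0, 100]; trees whose supports
    all lie in [0, 1] are auto-rescaled (fractions from some tools) with a
    warning unless ``autoscale=False``, in which case they are an error.
    """

    def __init__(self, tree: dendropy.Tree, name: str = "", *,
                 autoscale: bool = True):
        self.name = name
        self._tree = tree
        self.leaf_labels: list[str] = [
            lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()
        ]
        if len(self.leaf_labels) < 3:
            raise ValueError(f"tree {name!r} has fewer than 3 leaves")
        if len(set(self.leaf_labels)) != len(self.leaf_labels):
            raise ValueError(f"tree {name!r} has duplicate leaf labels")
        self._clans = self._extract_clans()
        self._rescale_supports(autoscale)

    @classmethod
    def from_newick(cls, newick: str, name: str = "", *,
                    autoscale: bool = True) -> "SupportTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls(tree, name, autoscale=autoscale)

    @property
    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels)

    def taxa(self) -> set[str]:
        return {leaf_taxon(l) for l in self.leaf_labels}

    def _extract_clans(self) -> list[Clan]:
        all_leaves = self.leaf_set
        by_split: dict[frozenset[frozenset[str]], float | None] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(
                lf.taxon.label.replace(" ", "_")
                for lf in node.leaf_iter()
            )
            comp = all_leaves - side
            if len(side) < 2 or len(comp) < 2:
                continue  # terminal edge: not a bipartition of interest
            support = _parse_support(node.label)
            key = frozenset((side, comp))
            # a bifurcating root shows the same split twice; keep the
            # annotated / larger support
            prev = by_split.get(key, None)
            if key not in by_split or _support_key(support) > _support_key(prev):
                by_split[key] = support
        clans = []
        for key, support in by_split.items():
            side, comp = sorted(key, key=lambda s: (len(s), sorted(s)))
            clans.append(Clan(side=side, complement=comp, support=support))
        clans.sort(key=lambda c: sorted(c.side))
        return clans

    def _rescale_supports(self, autoscale: bool) -> None:
        vals = [c.support for c in self._clans if c.support is not None]
        if not vals:
            return
        if any(v < 0 or v > 100 for v in vals):
            raise ValueError(f"tree {self.name!r}: support outside [0, 100]")
        # fractional scale is only inferred when some support is strictly
        # between 0 and 1; integer supports that happen to be 0/1 are kept
        if max(vals) <= 1.0 and any(0 < v < 1 for v in vals):
            if not autoscale:
                raise ValueError(
                    f"tree {self.name!r}: supports look fractional "
                    "(all <= 1.0) but scale [0, 100] was declared"
                )
            logger.warning(
                "tree %s: supports all <= 1.0, interpreting as fractions "
                "and rescaling to percent", self.name,
            )
            self._clans = [
                Clan(c.side, c.complement,
                     None if c.support is None else c.support * 100)
                for c in self._clans
            ]

    def clans(self) -> list[Clan]:
        """All non-trivial bipartitions with their supports, rooting-free."""
        return list(self._clans)


def _parse_support(label: str | None) -> float | None:
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError:
        return None


def _support_key(s: float | None) -> float:
    return -1.0 if s is None else s


def enumerate_clans(tree: SupportTree) -> list[Clan]:
    """Bipartitions induced by the internal edges of an unrooted tree.

    One entry per internal edge regardless of how the input Newick was
    rooted; a star tree (single polytomy) yields an empty list.
    """
    return tree.clans()


def read_trees(source: str | Path) -> list[SupportTree]:
    """Read Newick trees from a file (one per line allowed) or directory."""
    source = Path(source)
    paths = sorted(source.glob("*.nwk")) + sorted(source.glob("*.tre")) \
        if source.is_dir() else [source]
    trees = []
    for path in paths:
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            name = path.stem if i == 0 and len(paths) > 1 else f"{path.stem}:{i}"
            trees.append(SupportTree.from_newick(line, name=name))
    return trees


# ---------------------------------------------------------------------------
# prefilters
# ---------------------------------------------------------------------------

def filter_homologs(table: pd.DataFrame,
                    e_max: float = DEFAULT_EVALUE_MAX,
                    min_hits: int = DEFAULT_MIN_HITS) -> set[str]:
    """Proteins with at least ``min_hits`` homologs at E-value < ``e_max``.

    ``table`` needs columns ``protein_id`` and ``evalue`` (one row per
    hit). Proteins below the hit count cannot yield an unrooted tree and
    are excluded from the phylogenetic funnel. The E-value comparison is
    strict. An empty table gives an empty set.
    """
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    if table.empty:
        return set()
    if (table["evalue"] < 0).any():
        raise ValueError("negative E-value in homolog table")
    good = table[table["evalue"] < e_max]
    counts = good.groupby("protein_id").size()
    return set(counts.index[counts >= min_hits])


def filter_alignments(meta: pd.DataFrame,
                      min_len: int = DEFAULT_MIN_ALN_LEN) -> set[str]:
    """Proteins whose trimmed alignment is longer than ``min_len`` positions
    with every sequence determined.

    ``meta`` needs columns ``protein_id``, ``length`` and
    ``all_determined``; the length comparison is strict (> ``min_len``).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    for col in ("protein_id", "length", "all_determined"):
        if col not in meta.columns:
            raise ValueError(f"alignment metadata missing column {col!r}")
    if meta["all_determined"].isna().any():
        raise ValueError("all_determined flag missing for some alignments")
    keep = meta[(meta["length"] > min_len) & meta["all_determined"].astype(bool)]
    return set(keep["protein_id"])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class AncestryCall:
    """Outcome of classifying one gene tree."""
    protein_id: str
    status: str                       # excluded_prefilter | unclassified | classified | flagged
    bins: frozenset[str] = frozenset()
    best_support: float | None = None

    def __post_init__(self):
        if self.status == "classified" and not self.bins:
            raise ValueError("classified call must have bins")


def classify_tree(tree: SupportTree, taxmap: TaxonGroupMap,
                  support_min: float = DEFAULT_SUPPORT_MIN) -> AncestryCall:
    """Classify one gene tree by the single-group sister rule.

    Every bipartition with support >= ``support_min`` is examined; the
    clan containing focal-taxon leaves qualifies for group G when it holds
    at least one leaf of G, any number of focal leaves, and nothing else
    (no second group, no unmapped taxon). The set of qualifying groups
    forms the bins: one or two groups classify the tree (a dual assignment
    for two), none leaves it unclassified, more than two is flagged for
    inspection rather than truncated.
    """
    focal = taxmap.focal_taxon
    focal_leaves = {l for l in tree.leaf_labels if leaf_taxon(l) == focal}
    if not focal_leaves:
        raise ValueError(f"tree {tree.name!r} contains no {focal!r} leaf")

    bins: set[str] = set()
    best: float | None = None
    for clan in tree.clans():
        if clan.support is None or clan.support < support_min:
            continue
        for side in (clan.side, clan.complement):
            group = _qualifying_group(side, focal_leaves, taxmap, tree.name)
            if group is not None:
                bins.add(group)
                if best is None or clan.support > best:
                    best = clan.support

    if not bins:
        status = "unclassified"
    elif len(bins) <= 2:
        status = "classified"
    else:
        status = "flagged"
        logger.warning("tree %s qualifies for %d groups: %s",
                       tree.name, len(bins), sorted(bins))
    return AncestryCall(tree.name, status, frozenset(bins), best)


def _qualifying_group(side: frozenset[str], focal_leaves: set[str],
                      taxmap: TaxonGroupMap, tree_name: str) -> str | None:
    """Group G such that ``side`` = focal leaves + G members only, else None."""
    if not side & focal_leaves:
        return None
    others = side - focal_leaves
    if not others:
        return None  # focal-only clan carries no donor evidence
    groups: set[str] = set()
    for label in others:
        g = taxmap.group_of(leaf_taxon(label))
        if g is None:
            logger.debug("tree %s: unmapped taxon %r disqualifies clan",
                         tree_name, label)
            return None
        groups.add(g)
    return groups.pop() if len(groups) == 1 else None


def classify_trees(trees: Iterable[SupportTree], taxmap: TaxonGroupMap,
                   support_min: float = DEFAULT_SUPPORT_MIN) -> list[AncestryCall]:
    return [classify_tree(t, taxmap, support_min) for t in trees]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class BinSummary:
    """Per-group tree counts over the classified trees.

    ``counts`` sum to ``n_classified + n_dual`` because a dual-bin tree
    contributes to two groups but counts once in the denominator.
    ``rollup_counts`` aggregates groups into user-defined supergroups.
    """
    counts: dict[str, int]
    percentages: dict[str, int]
    n_input: int
    n_classified: int
    n_unclassified: int
    n_flagged: int
    n_dual: int
    rollup_counts: dict[str, int] = field(default_factory=dict)
    rollup_percentages: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def summarize_bins(calls: Sequence[AncestryCall],
                   rollups: Mapping[str, Iterable[str]] | None = None
                   ) -> BinSummary:
    """Count classified trees per bin and express each as an integer percent
    of all classified trees.

    ``rollups`` optionally maps a supergroup name to the bins it covers
    (e.g. all excavate lineages); a tree in two covered bins still counts
    once toward the supergroup.
    """
    classified = [c for c in calls if c.status == "classified"]
    n_classified = len(classified)
    n_unclassified = sum(c.status == "unclassified" for c in calls)
    n_flagged = sum(c.status == "flagged" for c in calls)
    n_dual = sum(len(c.bins) == 2 for c in classified)

    counts: dict[str, int] = {}
    for call in classified:
        for b in call.bins:
            counts[b] = counts.get(b, 0) + 1

    if n_classified == 0 and calls:
        logger.warning("no classified trees; percentages reported as 0")

    def pct(n: int) -> int:
        return round(100 * n / n_classified) if n_classified else 0

    percentages = {g: pct(n) for g, n in counts.items()}

    rollup_counts: dict[str, int] = {}
    rollup_percentages: dict[str, int] = {}
    if rollups:
        for name, members in rollups.items():
            members = set(members)
            n = sum(1 for c in classified if c.bins & members)
            rollup_counts[name] = n
            rollup_percentages[name] = pct(n)

    return BinSummary(
        counts=counts, percentages=percentages,
        n_input=len(calls), n_classified=n_classified,
        n_unclassified=n_unclassified, n_flagged=n_flagged, n_dual=n_dual,
        rollup_counts=rollup_counts, rollup_percentages=rollup_percentages,
    )


def calls_to_frame(calls: Sequence[AncestryCall]) -> pd.DataFrame:
    """Tabulate calls: protein_id, status, semicolon-joined bins, support."""
    return pd.DataFrame({
        "protein_id": [c.protein_id for c in calls],
        "status": [c.status for c in calls],
        "bins": [";".join(sorted(c.bins)) for c in calls],
        "best_support": [c.best_support for c in calls],
    })


def write_calls_tsv(calls: Sequence[AncestryCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
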