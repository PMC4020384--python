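"""Tree and taxon data model.

Trees are rooted, with node *heights* measured backwards in time from the
most recently sampled tip (height 0).  Larger heights are older.  A tree
may be calibrated in time units (heights are calendar times, branch
lengths are durations) or in substitution units (branch lengths are
expected substitutions per site; an implicit clock rate of 1 makes the
two interchangeable for the simulation engine, except for epoch models,
which require genuine time calibration).

Parsing of NEWICK and NEXUS input is delegated to :mod:`dendropy`; the
classes here are a deliberately small in-memory representation carrying
exactly what simulation needs: topology, branch lengths and heights.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional

import dendropy

__all__ = [
    "Taxon",
    "TaxonSet",
    "Node",
    "Phylogeny",
    "TreeError",
    "parse_tree",
    "read_taxa_table",
    "compute_heights",
    "write_newick",
]

#: numerical tolerance for the height / branch-length duality
HEIGHT_TOL = 1e-9
#: tolerance when reconciling user-supplied tip heights with branch lengths
TIP_HEIGHT_TOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed trees, taxa tables or inconsistent heights."""


@dataclass(frozen=True)
class Taxon:
    """A named sample with a sampling height (time before the youngest tip).

    ``height`` is 0 for the most recently sampled taxon; contemporaneous
    data sets have all heights 0.
    """

    name: str
    height: float = 0.0

    def __post_init__(self) -> None:
        if not self.name:
            raise TreeError("taxon name must be non-empty")
        h = float(self.height)
        if not (h >= 0.0) or h != h or h == float("inf"):
            raise TreeError(f"taxon {self.name!r}: height must be finite and >= 0, got {self.height}")


class TaxonSet:
    """Ordered collection of uniquely named taxa."""

    def __init__(self, taxa: Optional[List[Taxon]] = None):
        self._taxa: List[Taxon] = []
        self._names: Dict[str, int] = {}
        for t in taxa or []:
            self.add(t)

    def add(self, taxon: Taxon) -> None:
        if taxon.name in self._names:
            raise TreeError(f"duplicate taxon name {taxon.name!r}")
        self._names[taxon.name] = len(self._taxa)
        self._taxa.append(taxon)

    def __len__(self) -> int:
        return len(self._taxa)

    def __iter__(self) -> Iterator[Taxon]:
        return iter(self._taxa)

    def __getitem__(self, i: int) -> Taxon:
        return self._taxa[i]

    def __contains__(self, name: str) -> bool:
        return name in self._names

    @property
    def names(self) -> List[str]:
        return [t.name for t in self._taxa]

    def get(self, name: str) -> Taxon:
        return self._taxa[self._names[name]]


@dataclass(eq=False)
class Node:
    """A tree node: tips carry a taxon, internal nodes do not."""

    taxon: Optional[Taxon] = None
    children: List["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None
    height: Optional[float] = None
    #: branch length to the parent (None at the root)
    length: Optional[float] = None
    #: optional label (internal-node labels are preserved but unused)
    label: Optional[str] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = self.taxon.name if self.taxon else (self.label or "<internal>")
        return f"Node({tag}, h={self.height}, l={self.length})"


class Phylogeny:
    """A rooted phylogeny with heights and branch lengths reconciled.

    Parameters
    ----------
    root:
        Root node of a linked `Node` structure.
    time_calibrated:
        True if branch lengths are durations (time units); False if they
        are expected substitutions per site.
    """

    def __init__(self, root: Node, time_calibrated: bool = True):
        self.root = root
        self.time_calibrated = time_calibrated

    # -- traversals ---------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    @property
    def tips(self) -> List[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def taxa(self) -> TaxonSet:
        return TaxonSet([n.taxon for n in self.tips])

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.preorder() if n.is_tip)

    @property
    def root_height(self) -> float:
        if self.root.height is None:
            raise TreeError("heights not computed")
        return self.root.height

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.preorder())

    def validate(self) -> None:
        """Check structural invariants (parentage, heights, lengths)."""
        seen_names = set()
        for node in self.preorder():
            if node.is_tip:
                if node.taxon is None:
                    raise TreeError("tip without a taxon")
                if node.taxon.name in seen_names:
                    raise TreeError(f"duplicate tip label {node.taxon.name!r}")
                seen_names.add(node.taxon.name)
            for child in node.children:
                if child.parent is not node:
                    raise TreeError("broken parent link")
                if child.length is None:
                    raise TreeError("missing branch length")
                if node.height is not None and child.height is not None:
                    if abs((node.height - child.height) - child.length) > max(
                        HEIGHT_TOL, HEIGHT_TOL * abs(node.height)
                    ):
                        raise TreeError(
                            f"height/length mismatch at {child!r}: "
                            f"{node.height} - {child.height} != {child.length}"
                        )
            if node.height is not None and node.height < -HEIGHT_TOL:
                raise TreeError(f"negative height {node.height}")

    def rescale_to_height(self, target_root_height: float) -> "Phylogeny":
        """Return a copy linearly rescaled so the root sits at the target height."""
        if self.root.height is None:
            raise TreeError("heights not computed")
        if self.root.height <= 0:
            raise TreeError("cannot rescale a zero-height tree")
        f = target_root_height / self.root.height

        def clone(node: Node, parent: Optional[Node]) -> Node:
            new = Node(
                taxon=node.taxon,
                parent=parent,
                height=None if node.height is None else node.height * f,
                length=None if node.length is None else node.length * f,
                label=node.label,
            )
            new.children = [clone(c, new) for c in node.children]
            return new

        return Phylogeny(clone(self.root, None), time_calibrated=self.time_calibrated)

    def stretch_to_height(self, target_root_height: float) -> "Phylogeny":
        """Return a copy with internal heights scaled to put the root at the
        target height while tip sampling heights stay fixed.

        This deepens a genealogy without distorting the sampling times —
        the natural way to condition on an older tMRCA.  Only stretching
        (factor >= 1) is supported: shrinking could pull an internal node
        below one of its sampled descendants.
        """
        if self.root.height is None:
            raise TreeError("heights not computed")
        if self.root.height <= 0:
            raise TreeError("cannot stretch a zero-height tree")
        f = target_root_height / self.root.height
        if f < 1.0:
            raise TreeError(
                f"stretch factor {f:.3f} < 1 would reorder nodes; "
                "use rescale_to_height to shrink"
            )

        def clone(node: Node, parent: Optional[Node]) -> Node:
            new = Node(
                taxon=node.taxon,
                parent=parent,
                height=node.height if node.is_tip else node.height * f,
                label=node.label,
            )
            if parent is not None:
                new.length = parent.height - new.height
            new.children = [clone(c, new) for c in node.children]
            return new

        out = Phylogeny(clone(self.root, None), time_calibrated=self.time_calibrated)
        out.validate()
        return out


# ---------------------------------------------------------------------------
# parsing


def _from_dendropy(dtree: "dendropy.Tree") -> Node:
    def convert(dnode, parent: Optional[Node]) -> Node:
        node = Node(parent=parent)
        if dnode.parent_node is not None:
            if dnode.edge.length is None:
                raise TreeError(
                    "missing branch length on an internal edge; branch lengths are mandatory"
                )
            node.length = float(dnode.edge.length)
            if node.length < 0:
                raise TreeError(f"negative branch length {node.length}")
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise TreeError("unlabelled tip")
            node.taxon = Taxon(dnode.taxon.label)  # height reconciled later
        else:
            node.label = dnode.label
        node.children = [convert(c, node) for c in dnode.child_nodes()]
        return node

    return convert(dtree.seed_node, None)


def parse_tree(
    text: str,
    tip_heights: Optional[Dict[str, float]] = None,
    time_calibrated: bool = True,
) -> Phylogeny:
    """Parse a NEWICK string or NEXUS TREES block into a `Phylogeny`.

    Branch lengths are mandatory.  Node heights are reconciled with the
    branch lengths: the minimum tip height is pinned at 0 unless
    ``tip_heights`` supplies explicit sampling heights, which must then be
    consistent with the branch lengths (discrepancy > 1e-6 is an error).
    """
    stripped = text.strip()
    schema = "nexus" if stripped.lower().startswith("#nexus") else "newick"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"could not parse {schema} input: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        if dtree.seed_node is not None and dtree.seed_node.taxon is not None:
            # single-tip degenerate tree
            root = Node(taxon=Taxon(dtree.seed_node.taxon.label), height=0.0)
            return Phylogeny(root, time_calibrated=time_calibrated)
        raise TreeError("empty tree")
    root = _from_dendropy(dtree)
    tree = Phylogeny(root, time_calibrated=time_calibrated)
    compute_heights(tree, tip_heights=tip_heights)
    tree.validate()
    return tree


def read_taxa_table(text: str, skip_header: bool = False) -> TaxonSet:
    """Read a tab-delimited ``name<TAB>height`` table into a `TaxonSet`.

    Heights are non-negative times before the most recent sample; setting
    every height to 0 describes contemporaneous sampling.
    """
    taxa = TaxonSet()
    lines = io.StringIO(text).readlines()
    if skip_header and lines:
        lines = lines[1:]
    for lineno, line in enumerate(lines, start=2 if skip_header else 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise TreeError(
                f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        name, height_text = fields[0].strip(), fields[1].strip()
        try:
            height = float(height_text)
        except ValueError as exc:
            raise TreeError(f"line {lineno}: height {height_text!r} is not a number") from exc
        if height < 0:
            raise TreeError(f"line {lineno}: negative height {height}")
        taxa.add(Taxon(name, height))
    return taxa


def compute_heights(
    tree: Phylogeny, tip_heights: Optional[Dict[str, float]] = None
) -> Phylogeny:
    """Assign node heights consistent with branch lengths (in place).

    Root-to-node path lengths fix relative depths; the minimum tip height
    is pinned at 0, or tip heights are taken from ``tip_heights`` and
    checked against the branch lengths.  Idempotent.
    """
    depth: Dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node is tree.root:
            continue
        if node.length is None:
            raise TreeError("missing branch length")
        depth[id(node)] = depth[id(node.parent)] + node.length

    tips = tree.tips
    if not tips:
        raise TreeError("tree has no tips")
    max_depth = max(depth[id(t)] for t in tips)

    if tip_heights is not None:
        missing = [t.taxon.name for t in tips if t.taxon.name not in tip_heights]
        if missing:
            raise TreeError(f"tip_heights missing entries for {missing}")
        # each tip implies root_height = supplied_height + depth; all must agree
        implied = [tip_heights[t.taxon.name] + depth[id(t)] for t in tips]
        root_height = implied[0]
        for t, h in zip(tips, implied):
            if abs(h - root_height) > TIP_HEIGHT_TOL * max(1.0, abs(root_height)):
                raise TreeError(
                    f"supplied tip heights inconsistent with branch lengths "
                    f"(tip {t.taxon.name!r} implies root height {h}, expected {root_height})"
                )
    else:
        root_height = max_depth  # pins the deepest tip at height 0

    for node in tree.preorder():
        node.height = root_height - depth[id(node)]
        if abs(node.height) < HEIGHT_TOL:
            node.height = 0.0
    for t in tips:
        t.taxon = Taxon(t.taxon.name, t.height)
    return tree


def write_newick(tree: Phylogeny) -> str:
    """Serialize to NEWICK with branch lengths at full precision.

    Round-trips through `parse_tree` reproduce topology, branch lengths
    (to 1e-9) and tip heights.
    """

    def fmt(node: Node) -> str:
        if node.is_tip:
            core = _quote_label(node.taxon.name)
        else:
            inner = ",".join(fmt(c) for c in node.children)
            core = f"({inner})" + (_quote_label(node.label) if node.label else "")
        if node.length is not None:
            core += f":{node.length!r}"
        return core

    if tree.root.is_tip:
        return f"{_quote_label(tree.root.taxon.name)}:0;"
    return fmt(tree.root) + ";"


def _quote_label(label: str) -> str:
    if any(c in label for c in " \t()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label
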