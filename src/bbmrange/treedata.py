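"""Chronograms, area alphabets and taxon->range codings.

All ages are measured backward from the present in millions of years
(Myr): the present is 0 and the root carries the crown age.  Every
downstream statistic (sliding windows, event times, lineage counts)
uses this convention.

Newick/NEXUS parsing is delegated to :mod:`dendropy`; this module wraps
the parsed tree in a validated, array-backed :class:`Chronogram` whose
integer node ids are stable under a write/parse round trip.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

#: Relative tolerance for the ultrametricity check: the largest absolute
#: tip age may not exceed ``ULTRAMETRIC_RTOL * root_age``.  Absorbs float
#: noise left behind by upstream dating tools without masking real errors.
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Invalid chronogram input."""


class ParseError(TreeError):
    """Syntactically invalid newick/NEXUS text."""


class PolytomyError(TreeError):
    """An internal node with more than two children."""


class NotUltrametricError(TreeError):
    """Tip depths differ by more than the tolerance."""

    def __init__(self, deviation: float, tolerance: float):
        self.deviation = deviation
        self.tolerance = tolerance
        super().__init__(
            f"tree is not ultrametric: max tip-age deviation {deviation:g} Myr "
            f"exceeds tolerance {tolerance:g} Myr"
        )


class CodingError(ValueError):
    """Invalid taxon->areas coding table."""


@dataclass(frozen=True)
class AreaAlphabet:
    """Ordered alphabet of single-letter area codes (at most 10).

    The declared order is significant: it fixes output column order and
    the lexicographic leg of MAP-range tie-breaking.
    """

    letters: tuple[str, ...]

    def __post_init__(self):
        if not self.letters:
            raise ValueError("area alphabet must be non-empty")
        if len(self.letters) > 10:
            raise ValueError(f"at most 10 areas supported, got {len(self.letters)}")
        if any(len(c) != 1 for c in self.letters):
            raise ValueError("area codes must be single characters")
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("duplicate area codes in alphabet")

    @classmethod
    def from_string(cls, s: str) -> "AreaAlphabet":
        return cls(tuple(s))

    def __len__(self) -> int:
        return len(self.letters)

    def __iter__(self):
        return iter(self.letters)

    def __contains__(self, letter: str) -> bool:
        return letter in self.letters

    def index(self, letter: str) -> int:
        return self.letters.index(letter)

    def sort_range(self, areas: Iterable[str]) -> tuple[str, ...]:
        """Return the areas ordered by alphabet position."""
        return tuple(sorted(set(areas), key=self.index))

    def range_key(self, areas: Iterable[str]) -> tuple[int, ...]:
        """Lexicographic key of a range in alphabet order."""
        return tuple(sorted(self.index(a) for a in areas))

    def format_range(self, areas: Iterable[str]) -> str:
        return "|".join(self.sort_range(areas))


@dataclass(frozen=True)
class RegionCoding:
    """Mapping taxon label -> non-empty frozenset of area letters."""

    assignments: Mapping[str, frozenset]

    def __post_init__(self):
        for taxon, areas in self.assignments.items():
            if not areas:
                raise CodingError(f"taxon {taxon!r} has an empty area set")

    def __getitem__(self, taxon: str) -> frozenset:
        return self.assignments[taxon]

    def __len__(self) -> int:
        return len(self.assignments)

    def taxa(self) -> set:
        return set(self.assignments)

    def observed_letters(self) -> set:
        out: set = set()
        for areas in self.assignments.values():
            out |= areas
        return out

    def presence_matrix(self, tip_labels: Sequence[str], alphabet: AreaAlphabet) -> np.ndarray:
        """0/1 matrix of shape (len(tip_labels), len(alphabet))."""
        X = np.zeros((len(tip_labels), len(alphabet)), dtype=np.int8)
        for i, taxon in enumerate(tip_labels):
            try:
                areas = self.assignments[taxon]
            except KeyError:
                raise CodingError(f"no coding for taxon {taxon!r}") from None
            for a in areas:
                X[i, alphabet.index(a)] = 1
        return X


class Chronogram:
    """Rooted, binary, ultrametric time tree.

    Node ids are integers assigned in postorder (children before their
    parent, left-to-right in input order), so ids are reproducible for a
    given newick string and survive a write/parse round trip.
    """

    def __init__(
        self,
        parent: np.ndarray,
        children: list[tuple[int, ...]],
        lengths: np.ndarray,
        labels: list,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = children
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = labels
        self._validate_topology()
        self.ages = self._compute_ages()
        self._plan_cache = None  # lazily built pruning plan (see bbm module)

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Chronogram":
        nodes = list(tree.ageorder_node_iter()) if False else list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        children: list[tuple[int, ...]] = [()] * n
        lengths = np.zeros(n, dtype=float)
        labels: list = [None] * n
        for i, nd in enumerate(nodes):
            kids = nd.child_nodes()
            children[i] = tuple(index[id(c)] for c in kids)
            for c in kids:
                parent[index[id(c)]] = i
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise TreeError("a non-root branch is missing its length")
                lengths[i] = float(nd.edge.length)
            if not kids:
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeError("a tip is missing its label")
                labels[i] = nd.taxon.label
            elif nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
        return cls(parent, children, lengths, labels)

    def _validate_topology(self):
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        for i, kids in enumerate(self.children):
            if len(kids) not in (0, 2):
                name = self.labels[i] if self.labels[i] else f"node {i}"
                raise PolytomyError(
                    f"polytomy at {name}: internal node has {len(kids)} children "
                    "(only strictly binary trees are supported)"
                )
            if i != self.root and not self.lengths[i] > 0:
                raise TreeError(f"non-positive branch length {self.lengths[i]} above node {i}")
        tips = [self.labels[i] for i in self.tip_ids]
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")

    def _compute_ages(self) -> np.ndarray:
        n = len(self.parent)
        depth = np.zeros(n, dtype=float)
        for i in self.preorder():
            if i != self.root:
                depth[i] = depth[self.parent[i]] + self.lengths[i]
        tip_ids = self.tip_ids
        max_depth = float(depth[tip_ids].max())
        ages = max_depth - depth
        deviation = float(np.abs(ages[tip_ids]).max())
        tolerance = ULTRAMETRIC_RTOL * max_depth
        if deviation > tolerance:
            raise NotUltrametricError(deviation, tolerance)
        ages[tip_ids] = 0.0  # snap float noise so boundary conventions are exact
        return ages

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_ids(self) -> np.ndarray:
        return np.flatnonzero([len(k) == 0 for k in self.children])

    @property
    def internal_ids(self) -> np.ndarray:
        return np.flatnonzero([len(k) == 2 for k in self.children])

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_ids]

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def is_tip(self, node: int) -> bool:
        return len(self.children[node]) == 0

    def preorder(self) -> list[int]:
        order = []
        stack = [int(np.flatnonzero(self.parent < 0)[0]) if not hasattr(self, "root") else self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> list[int]:
        return list(reversed([v for v in self._preorder_right_first()]))

    def _preorder_right_first(self):
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(self.children[v])

    def mrca(self, labels: Sequence[str]) -> int:
        """Most recent common ancestor of the named tips."""
        label_to_id = {self.labels[i]: int(i) for i in self.tip_ids}
        ids = []
        for lab in labels:
            if lab not in label_to_id:
                raise TreeError(f"unknown taxon {lab!r}")
            ids.append(label_to_id[lab])
        if len(ids) < 2:
            raise TreeError("MRCA needs at least two tips")
        paths = []
        for v in ids:
            path = []
            while v >= 0:
                path.append(v)
                v = int(self.parent[v])
            paths.append(path[::-1])
        anc = None
        for depth in range(min(len(p) for p in paths)):
            cand = paths[0][depth]
            if all(p[depth] == cand for p in paths):
                anc = cand
            else:
                break
        return int(anc)

    def clade_nodes(self, root: int) -> list[int]:
        """All node ids in the subtree rooted at ``root`` (preorder)."""
        order = []
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def lineages_at(self, t: float) -> int:
        """Number of branches crossing age ``t``.

        A branch parent->child is counted when
        ``age(parent) > t >= age(child)`` (half-open on the old side), so
        a node-age boundary is counted with the younger side exactly
        once.  Note the root itself carries no branch: at exactly the
        root age the count is 0.
        """
        if not (0.0 <= t <= self.root_age):
            raise TreeError(f"t={t} outside [0, root age {self.root_age}]")
        parent_ages = np.where(self.parent >= 0, self.ages[self.parent], np.inf)
        mask = self.parent >= 0
        return int(np.sum((parent_ages[mask] > t) & (t >= self.ages[mask])))

    # -- output --------------------------------------------------------

    def to_newick(
        self,
        annotations: Mapping[int, str] | None = None,
        precision: int = 10,
    ) -> str:
        """Serialize to newick; ``annotations[node_id]`` is emitted as a
        bracketed comment directly after the node (BEAST style)."""
        annotations = annotations or {}

        def fmt_node(v: int) -> str:
            if self.is_tip(v):
                core = _quote_label(self.labels[v])
            else:
                kids = ",".join(fmt_node(c) for c in self.children[v])
                core = f"({kids})"
            note = annotations.get(v, "")
            if note:
                core += f"[{note}]"
            if v != self.root:
                core += f":{self.lengths[v]:.{precision}g}"
            return core

        return fmt_node(self.root) + ";"


def _quote_label(label: str) -> str:
    if re.search(r"[\s(),:;\[\]']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_chronogram(text: str) -> Chronogram:
    """Parse newick or NEXUS text into a validated :class:`Chronogram`."""
    tree = _dendropy_tree(text)
    return Chronogram.from_dendropy(tree)


def parse_annotated_chronogram(text: str) -> tuple[Chronogram, dict[int, dict]]:
    """Parse newick carrying BEAST-style ``[&key=value,...]`` node comments.

    Returns the chronogram and a map node id -> {key: value} (dendropy
    exposes the bracketed comments as annotations; node ids follow the
    same postorder numbering as :func:`parse_chronogram`).
    """
    tree = _dendropy_tree(text)
    chron = Chronogram.from_dendropy(tree)
    notes: dict[int, dict] = {}
    for i, nd in enumerate(tree.postorder_node_iter()):
        ann = {a.name: a.value for a in nd.annotations}
        if ann:
            notes[i] = ann
    return chron, notes


def _dendropy_tree(text: str) -> dendropy.Tree:
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        offset = _error_offset(exc)
        where = f" near character offset {offset}" if offset is not None else ""
        raise ParseError(f"could not parse {schema} tree{where}: {exc}") from exc
    return tree


def _error_offset(exc: Exception):
    for attr in ("col_num", "column", "pos"):
        val = getattr(exc, attr, None)
        if isinstance(val, int):
            return val
    m = re.search(r"column (\d+)", str(exc))
    return int(m.group(1)) if m else None


def read_region_codings(rows, alphabet: AreaAlphabet) -> RegionCoding:
    """Read a two-column taxon/areas table into a :class:`RegionCoding`.

    ``rows`` may be the raw text of a CSV/TSV file (header ``taxon,areas``
    optional), a pandas DataFrame, or an iterable of ``(taxon, areas)``
    pairs where ``areas`` is a pipe-separated letter string like ``"D|E"``.
    """
    if isinstance(rows, pd.DataFrame):
        pairs = [(str(r[0]), str(r[1])) for r in rows.itertuples(index=False)]
    elif isinstance(rows, str):
        df = pd.read_csv(
            io.StringIO(rows), sep=None, engine="python", header=None,
            dtype=str, comment="#", skip_blank_lines=True,
        )
        if df.shape[1] < 2:
            raise CodingError("coding table needs two columns: taxon, areas")
        pairs = [(str(r[0]).strip(), str(r[1]).strip()) for r in df.itertuples(index=False)]
        if pairs and pairs[0][0].lower() == "taxon":
            pairs = pairs[1:]
    else:
        pairs = [(str(t).strip(), str(a).strip()) for t, a in rows]

    assignments: dict[str, frozenset] = {}
    for taxon, area_str in pairs:
        if taxon in assignments:
            raise CodingError(f"duplicate taxon {taxon!r} in coding table")
        letters = [c.strip() for c in area_str.split("|") if c.strip()]
        if not letters:
            raise CodingError(f"taxon {taxon!r} has an empty area set")
        for c in letters:
            if c not in alphabet:
                raise CodingError(
                    f"taxon {taxon!r} uses area {c!r} which is not in the alphabet "
                    f"{''.join(alphabet.letters)}"
                )
        assignments[taxon] = frozenset(letters)
    if not assignments:
        raise CodingError("empty coding table")
    return RegionCoding(assignments)


def write_region_codings(coding: RegionCoding, alphabet: AreaAlphabet) -> str:
    lines = ["taxon,areas"]
    for taxon in sorted(coding.assignments):
        lines.append(f"{taxon},{alphabet.format_range(coding[taxon])}")
    return "\n".join(lines) + "\n"


def validate_pair(chron: Chronogram, coding: RegionCoding) -> None:
    """Check that the coding's taxa and the chronogram's tips coincide."""
    tips = set(chron.tip_labels)
    coded = coding.taxa()
    missing = sorted(tips - coded)
    extra = sorted(coded - tips)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"tips without coding: {missing}")
        if extra:
            parts.append(f"coded taxa not in tree: {extra}")
        raise CodingError("; ".join(parts))
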