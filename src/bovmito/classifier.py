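"""Haplogroup assignment from diagnostic-marker motifs, with frequency tables.

Haplogroup T1 of taurine cattle is recognised by a control-region motif
(transitions at nps 16050, 16113 and 16255 relative to the reference), and is
dissected into sub-haplogroups by single diagnostic mutations: T1a (2055+C),
T1b (7542) with nested T1b1 (16022), T1c (16122) with nested T1c1 (16196),
T1c1a (16053) and T1c1a1 (1324, 11542, 16139), T1d (6235) with nested T1d1
(4856, 1600d), plus T1e (8, lacking 16050) and T1f (12492, lacking 16113).

Control-region positions revert and recur; the classifier therefore tolerates
one missing motif position when either a coding-region marker deeper on the
path vouches for the assignment, or the clade itself is defined by that
absence.  Near-misses are reported as ranked alternatives and close calls are
flagged ambiguous rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .reference_variants import (
    CONTROL_REGION,
    CoverageError,
    HaplotypeProfile,
    Region,
    VariantCall,
    parse_variant_label,
)

__all__ = [
    "Marker",
    "HaplogroupNode",
    "HaplogroupHierarchy",
    "ClassificationResult",
    "FrequencyTable",
    "default_hierarchy",
    "screen_T1",
    "classify",
    "aggregate_frequencies",
    "round_half_up",
]

T1_MOTIF_POSITIONS = (16050, 16113, 16255)

CODING_WEIGHT = 2.0
CONTROL_WEIGHT = 1.0
ABSENCE_WEIGHT = 0.5
AMBIGUITY_MARGIN = 1.0


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention of the printed tables."""
    from decimal import Decimal, ROUND_HALF_UP

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Marker:
    """One diagnostic marker of a haplogroup node.

    ``call.back_mutation`` means the clade is defined by the ABSENCE of the
    mutation (an ``@`` marker); otherwise the mutation must be present.
    """

    call: VariantCall
    region_class: str  # "control" | "coding"
    unstable: bool = False

    @property
    def required_absent(self) -> bool:
        return self.call.back_mutation

    @property
    def weight(self) -> float:
        if self.required_absent:
            return ABSENCE_WEIGHT
        return CODING_WEIGHT if self.region_class == "coding" else CONTROL_WEIGHT

    @property
    def label(self) -> str:
        return self.call.label()


@dataclass
class HaplogroupNode:
    name: str
    parent: Optional[str]
    markers: List[Marker] = field(default_factory=list)


class HierarchyError(ValueError):
    pass


class HaplogroupHierarchy:
    """A rooted tree of haplogroup definitions."""

    def __init__(
        self,
        nodes: Sequence[HaplogroupNode],
        root: str,
        unstable_positions: Iterable[int] = (),
        name: str = "hierarchy",
        control_region: Region = CONTROL_REGION,
    ):
        self.name = name
        self.root = root
        self.unstable_positions = frozenset(unstable_positions)
        self.control_region = control_region
        self.nodes: Dict[str, HaplogroupNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise HierarchyError(f"duplicate node {node.name!r}")
            self.nodes[node.name] = node
        self._validate()

    def _validate(self) -> None:
        if self.root not in self.nodes:
            raise HierarchyError(f"root {self.root!r} not among nodes")
        for node in self.nodes.values():
            if node.parent is None:
                if node.name != self.root:
                    raise HierarchyError(f"{node.name!r} has no parent but is not the root")
            elif node.parent not in self.nodes:
                raise HierarchyError(f"{node.name!r} has unknown parent {node.parent!r}")
        for name in self.nodes:  # cycle check: every path must reach the root
            seen = set()
            cur: Optional[str] = name
            while cur is not None:
                if cur in seen:
                    raise HierarchyError(f"cycle through {cur!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    @classmethod
    def from_yaml(cls, source, control_region: Region = CONTROL_REGION) -> "HaplogroupHierarchy":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        return cls.from_dict(doc, control_region=control_region)

    @classmethod
    def from_dict(cls, doc: Mapping, control_region: Region = CONTROL_REGION) -> "HaplogroupHierarchy":
        unstable = frozenset(int(p) for p in doc.get("unstable_positions", ()))
        nodes = []
        for spec in doc["nodes"]:
            markers = []
            for label in spec.get("markers", ()):
                call = parse_variant_label(str(label))
                region_class = "control" if call.position in control_region else "coding"
                markers.append(
                    Marker(call, region_class, unstable=call.position in unstable)
                )
            nodes.append(HaplogroupNode(spec["name"], spec.get("parent"), markers))
        return cls(
            nodes,
            root=doc["root"],
            unstable_positions=unstable,
            name=doc.get("name", "hierarchy"),
            control_region=control_region,
        )

    def path(self, name: str) -> List[HaplogroupNode]:
        """Nodes from the root down to ``name`` (inclusive)."""
        chain = []
        cur: Optional[str] = name
        while cur is not None:
            node = self.nodes[cur]
            chain.append(node)
            cur = node.parent
        return list(reversed(chain))

    def ancestors(self, name: str) -> List[str]:
        return [n.name for n in self.path(name)[:-1]]

    def children(self, name: str) -> List[str]:
        return sorted(n.name for n in self.nodes.values() if n.parent == name)

    def top_level(self, name: str) -> str:
        """The depth-1 ancestor (direct child of the root) containing ``name``."""
        path = self.path(name)
        if len(path) == 1:
            return name
        return path[1].name

    def top_level_names(self) -> List[str]:
        return self.children(self.root)

    def all_marker_positions(self) -> frozenset:
        return frozenset(
            m.call.position for n in self.nodes.values() for m in n.markers
        )

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __iter__(self):
        return iter(self.nodes.values())


def default_hierarchy() -> HaplogroupHierarchy:
    """The validated T1 hierarchy shipped with the package."""
    ref = resources.files("bovmito.data").joinpath("t1_haplogroups.yaml")
    with ref.open() as fh:
        return HaplogroupHierarchy.from_yaml(fh)


# ---------------------------------------------------------------------------
# Screening and classification
# ---------------------------------------------------------------------------


def screen_T1(profile: HaplotypeProfile) -> bool:
    """Control-region screen for haplogroup T1 membership.

    A profile passes when it carries all three motif transitions (16050,
    16113, 16255), or any two of them provided 16255 — the deepest, most
    stable anchor of the motif — is among them.  The 2-of-3 tolerance absorbs
    single reversions at the hypervariable positions 16050/16113.

    Raises :class:`CoverageError` when the profile's covered region does not
    span the motif (distinct from a negative screen).
    """
    for pos in T1_MOTIF_POSITIONS:
        if not profile.covers(pos):
            raise CoverageError(
                f"profile {profile.sample_id!r} does not cover np {pos}; "
                "cannot screen for the T1 motif"
            )
    present = {p for p in T1_MOTIF_POSITIONS if profile.substitution_at(p) is not None}
    if len(present) == 3:
        return True
    return len(present) == 2 and 16255 in present


@dataclass
class ClassificationResult:
    sample_id: str
    best_node: str  # haplogroup name or "unclassified"
    path: List[str] = field(default_factory=list)
    matched_markers: List[str] = field(default_factory=list)
    missing_expected: List[str] = field(default_factory=list)
    alternative_nodes: List[Tuple[str, float]] = field(default_factory=list)
    ambiguous: bool = False
    score: float = 0.0

    @property
    def classified(self) -> bool:
        return self.best_node != "unclassified"


@dataclass
class _Candidate:
    node: str
    matched: List[Marker]
    missing: List[Marker]
    satisfied: bool
    score: float


def _marker_matches(profile: HaplotypeProfile, marker: Marker) -> bool:
    call = marker.call
    if call.kind.is_substitution:
        return profile.substitution_at(call.position) is not None
    return profile.carries(call)


def _evaluate(profile: HaplotypeProfile, hierarchy: HaplogroupHierarchy, name: str) -> Optional[_Candidate]:
    """Score one node; None when a declared absence is violated."""
    path = hierarchy.path(name)
    matched: List[Marker] = []
    missing_root: List[Marker] = []
    missing_below: List[Tuple[int, Marker]] = []  # (depth, marker)
    coding_depths: List[int] = []

    declared_absent = {
        m.call.position for node in path for m in node.markers if m.required_absent
    }
    for depth, node in enumerate(path):
        for marker in node.markers:
            if marker.required_absent:
                if profile.carries_position(marker.call.position):
                    return None  # the clade is defined by lacking this mutation
                matched.append(marker)
                continue
            if _marker_matches(profile, marker):
                matched.append(marker)
                if marker.region_class == "coding":
                    coding_depths.append(depth)
            elif marker.call.position in declared_absent:
                continue  # definitional absence deeper on the path, not a miss
            elif depth == 0:
                missing_root.append(marker)  # root motif: screened separately
            else:
                missing_below.append((depth, marker))

    if len(missing_below) == 0:
        satisfied = True
    elif len(missing_below) == 1:
        # one missing marker is tolerated when a coding-region marker at the
        # same or a deeper node on the path backs the assignment
        miss_depth = missing_below[0][0]
        satisfied = any(d >= miss_depth for d in coding_depths)
    else:
        satisfied = False
        return _Candidate(name, matched, missing_root + [m for _, m in missing_below],
                          satisfied=False, score=float("-inf"))

    score = sum(m.weight for m in matched)
    missing = missing_root + [m for _, m in missing_below]
    return _Candidate(name, matched, missing, satisfied, score)


def classify(profile: HaplotypeProfile, hierarchy: Optional[HaplogroupHierarchy] = None) -> ClassificationResult:
    """Assign ``profile`` to the deepest haplogroup whose marker path holds.

    Always returns a result; profiles failing the root screen come back as
    ``"unclassified"``.  Candidate clades that are incomparable with the best
    assignment (neither ancestor nor descendant) and bring matching evidence
    of their own are listed in ``alternative_nodes``; the call is flagged
    ambiguous when the runner-up scores within one marker weight of the best.
    """
    hierarchy = hierarchy or default_hierarchy()

    if not screen_T1(profile):
        return ClassificationResult(profile.sample_id, "unclassified")

    candidates: Dict[str, _Candidate] = {}
    for node in hierarchy:
        cand = _evaluate(profile, hierarchy, node.name)
        if cand is not None and cand.score > float("-inf"):
            candidates[node.name] = cand

    satisfied = [c for c in candidates.values() if c.satisfied]
    if not satisfied:  # screen passed but even the root failed to evaluate
        return ClassificationResult(profile.sample_id, hierarchy.root)
    # deepest/highest-scoring satisfied node wins; ties broken by name for
    # determinism (both tied clades are then visible via alternative_nodes)
    best = max(satisfied, key=lambda c: (c.score, len(c.matched), c.node))

    best_path = set(hierarchy.ancestors(best.node)) | {best.node}
    best_path_marker_keys = {
        (m.call.key, m.required_absent)
        for nm in best_path
        for m in hierarchy.nodes[nm].markers
    }

    alternatives: List[Tuple[str, float]] = []
    for cand in candidates.values():
        if cand.node in best_path or best.node in hierarchy.ancestors(cand.node):
            continue
        # only near-misses with evidence beyond the best path are alternatives
        extra = [
            m for m in cand.matched
            if (m.call.key, m.required_absent) not in best_path_marker_keys
        ]
        if not extra:
            continue
        alternatives.append((cand.node, cand.score))
    alternatives.sort(key=lambda t: (-t[1], t[0]))

    ambiguous = bool(alternatives) and (best.score - alternatives[0][1]) <= AMBIGUITY_MARGIN

    return ClassificationResult(
        sample_id=profile.sample_id,
        best_node=best.node,
        path=[n.name for n in hierarchy.path(best.node)],
        matched_markers=[m.label for m in best.matched],
        missing_expected=[m.label for m in best.missing],
        alternative_nodes=alternatives,
        ambiguous=ambiguous,
        score=best.score,
    )


# ---------------------------------------------------------------------------
# Geographic frequency aggregation
# ---------------------------------------------------------------------------


@dataclass
class FrequencyTable:
    """Counts and percentages of sub-haplogroups by breed/country/continent.

    ``counts`` has one row per breed plus ``<country> total``, ``<continent>
    total`` and ``TOTAL`` rows; percentages are per-row (half-up, one
    decimal).  ``rejects`` lists sample ids excluded for missing metadata.
    """

    counts: pd.DataFrame
    percents: pd.DataFrame
    rejects: List[str] = field(default_factory=list)

    def count(self, row: str, column: str) -> int:
        return int(self.counts.loc[row, column])

    def percent(self, row: str, column: str) -> float:
        return float(self.percents.loc[row, column])

    def to_tsv(self, path) -> None:
        merged = self.counts.astype(str).copy()
        for col in self.counts.columns:
            if col == "Total":
                continue
            merged[col] = [
                f"{c} ({p}%)" for c, p in zip(self.counts[col], self.percents[col])
            ]
        merged.to_csv(path, sep="\t", index_label="group")


def aggregate_frequencies(
    results: Sequence[ClassificationResult],
    metadata: Mapping[str, Mapping[str, str]],
    hierarchy: Optional[HaplogroupHierarchy] = None,
) -> FrequencyTable:
    """Aggregate assignments into a survey-style frequency table.

    Deep clades are pooled into their top-level sub-haplogroup (T1b1 counts as
    T1b, T1c1a1 as T1c, ...).  ``metadata`` maps sample id to a mapping with
    ``breed``, ``country`` and ``continent`` keys; samples without metadata go
    to ``rejects`` and are excluded from every total.
    """
    hierarchy = hierarchy or default_hierarchy()
    top_names = hierarchy.top_level_names()

    rows = []
    rejects = []
    for res in results:
        meta = metadata.get(res.sample_id)
        if meta is None or any(k not in meta for k in ("breed", "country", "continent")):
            rejects.append(res.sample_id)
            continue
        if res.best_node == "unclassified":
            group = "unclassified"
        elif res.best_node in hierarchy.nodes:
            group = hierarchy.top_level(res.best_node)
        else:
            group = "unclassified"
        rows.append(
            {
                "continent": meta["continent"],
                "country": meta["country"],
                "breed": meta["breed"],
                "group": group,
            }
        )

    columns = list(top_names)
    if any(r["group"] == "unclassified" for r in rows):
        columns.append("unclassified")
    if any(r["group"] == hierarchy.root for r in rows):
        columns.append(hierarchy.root)

    df = pd.DataFrame(rows, columns=["continent", "country", "breed", "group"])
    table_rows: List[Tuple[str, pd.Series]] = []

    def tally(sub: pd.DataFrame) -> pd.Series:
        counts = sub["group"].value_counts()
        out = pd.Series({c: int(counts.get(c, 0)) for c in columns})
        out["Total"] = int(len(sub))
        return out

    if not df.empty:
        for continent in df["continent"].unique():
            cdf = df[df["continent"] == continent]
            for country in cdf["country"].unique():
                codf = cdf[cdf["country"] == country]
                for breed in codf["breed"].unique():
                    table_rows.append((breed, tally(codf[codf["breed"] == breed])))
                table_rows.append((f"{country} total", tally(codf)))
            table_rows.append((f"{continent} total", tally(cdf)))
    table_rows.append(("TOTAL", tally(df)))

    counts = pd.DataFrame(
        [row for _, row in table_rows], index=[name for name, _ in table_rows]
    )[columns + ["Total"]]
    counts.index.name = "group"

    percents = counts.copy().astype(float)
    for idx in counts.index:
        total = counts.loc[idx, "Total"]
        for col in columns:
            pct = 100.0 * counts.loc[idx, col] / total if total else 0.0
            percents.loc[idx, col] = round_half_up(pct, 1)
        percents.loc[idx, "Total"] = 100.0 if total else 0.0

    return FrequencyTable(counts=counts, percents=percents, rejects=rejects)


def assignments_table(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "best_node": r.best_node,
                "path": ">".join(r.path),
                "matched_markers": ",".join(r.matched_markers),
                "missing_expected": ",".join(r.missing_expected),
                "alternatives": ",".join(f"{n}:{s}" for n, s in r.alternative_nodes),
                "ambiguous": r.ambiguous,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "best_node",
            "path",
            "matched_markers",
            "missing_expected",
            "alternatives",
            "ambiguous",
        ],
    )
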