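"""Synthetic inputs: references, motif-bearing cohorts, and clade expansions.

Everything the pipeline consumes can be generated here without downloads:

* a random circular reference with the survey's named regions (control
  region nps 15718-517, coding region nps 364-15791 at the canonical
  16,338-bp length; proportionally scaled otherwise);
* sample cohorts whose members carry the full diagnostic-marker path of an
  assigned sub-haplogroup at specified breed/country counts — emulating the
  281-sample T1 survey — plus Poisson-distributed private mutations and
  optional reversion noise at control-region diagnostic positions;
* neutral clade expansions of a stated age, in which every root-to-tip path
  accumulates Poisson(age_years / rate) substitutions, for rho-recovery
  experiments.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classifier import HaplogroupHierarchy, default_hierarchy
from .parsimony_tree import AnnotatedTree, EdgeMutation, TreeNode
from .reference_variants import (
    CODING_REGION,
    CONTROL_REGION,
    BRS_LENGTH,
    HaplotypeProfile,
    ReferenceGenome,
    Region,
    VariantCall,
    VariantKind,
    apply_variants,
    transition_partner,
)

__all__ = [
    "CohortSpec",
    "CohortRow",
    "ExpansionSpec",
    "ExpansionResult",
    "generate_reference",
    "generate_cohort",
    "simulate_expansion",
    "survey_cohort_spec",
]

DEFAULT_RATE = 3172.0
HOTSPOT_POSITIONS = (16050, 16113, 16122)
HOTSPOT_WEIGHT = 20.0
TRANSITION_FRACTION = 0.95


def generate_reference(
    length: int = BRS_LENGTH,
    gc_fraction: float = 0.4,
    seed: Optional[int] = None,
    name: str = "synthetic-mitogenome",
) -> ReferenceGenome:
    """A random circular reference with control/coding regions declared.

    At the canonical length the regions use the published coordinates;
    otherwise each boundary is scaled proportionally.
    """
    if length < 1000:
        raise ValueError("reference length must be >= 1000 bp")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    bases = rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])
    if length == BRS_LENGTH:
        # the printed indel labels ("2055+C", "1600d") are the 5'-most
        # representations on the real reference; give the synthetic sequence
        # the same anchoring context so the labels stay canonical here too
        if bases[2054] == "C":  # np 2055 must not extend a C run leftward
            bases[2054] = "T"
        if bases[1598] == bases[1599]:  # np 1599 != np 1600 anchors the deletion
            bases[1598] = {"A": "G", "G": "A", "C": "T", "T": "C"}[bases[1599]]
        regions = {"control": CONTROL_REGION, "coding": CODING_REGION}
    else:
        scale = length / BRS_LENGTH

        def s(pos: int) -> int:
            return min(length, max(1, round(pos * scale)))

        regions = {
            "control": Region(s(CONTROL_REGION.start), s(CONTROL_REGION.end)),
            "coding": Region(s(CODING_REGION.start), s(CODING_REGION.end)),
        }
    return ReferenceGenome(name, "".join(bases), regions)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortRow:
    breed: str
    country: str
    continent: str
    haplogroup: str
    count: int

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class CohortSpec:
    """A breed-by-sub-haplogroup count specification for cohort synthesis."""

    rows: List[CohortRow]
    reversion_noise: float = 0.0
    reversion_positions: Optional[Tuple[int, ...]] = None  # None: any control-region diagnostic
    private_lambda: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.reversion_noise <= 1.0:
            raise ValueError("reversion_noise must lie in [0, 1]")

    @property
    def total(self) -> int:
        return sum(r.count for r in self.rows)


def survey_cohort_spec(
    reversion_noise: float = 0.0,
    private_lambda: float = 1.0,
    seed: Optional[int] = None,
) -> CohortSpec:
    """The shipped 281-sample breed/country count table as a cohort spec."""
    ref = resources.files("bovmito.data").joinpath("t1_survey_counts.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    rows = []
    group_cols = [c for c in df.columns if c not in ("continent", "country", "breed")]
    for _, rec in df.iterrows():
        for hg in group_cols:
            if int(rec[hg]) > 0:
                rows.append(
                    CohortRow(rec["breed"], rec["country"], rec["continent"], hg, int(rec[hg]))
                )
    return CohortSpec(rows, reversion_noise=reversion_noise,
                      private_lambda=private_lambda, seed=seed)


@dataclass
class Cohort:
    sequences: Dict[str, str]  # sample id -> full-genome sequence
    metadata: pd.DataFrame     # sample, breed, country, continent, true_haplogroup
    spec: CohortSpec

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.sequences.items():
                fh.write(f">{sid} seed={self.spec.seed}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.spec.seed}\n")
            self.metadata.to_csv(fh, sep="\t", index=False)


def _path_marker_calls(hierarchy: HaplogroupHierarchy, name: str) -> List[VariantCall]:
    """The variant calls a nodal haplotype of ``name`` carries.

    Declared-absence markers REMOVE the corresponding mutation from the
    accumulated path (e.g. a T1e haplotype lacks the 16050 motif transition).
    """
    carried: Dict[object, VariantCall] = {}
    for node in hierarchy.path(name):
        for marker in node.markers:
            call = replace(marker.call, back_mutation=False)
            if marker.required_absent:
                carried.pop(call.key, None)
            else:
                carried[call.key] = call
    return list(carried.values())


def generate_cohort(
    spec: CohortSpec,
    reference: ReferenceGenome,
    hierarchy: Optional[HaplogroupHierarchy] = None,
) -> Cohort:
    """Synthesise full-genome samples for every row of ``spec``.

    Each sample carries the complete marker path of its assigned node, plus
    ``k ~ Poisson(private_lambda)`` private neutral mutations at positions
    that are diagnostic for nothing, with control-region diagnostic positions
    independently reverted at rate ``reversion_noise``.
    """
    hierarchy = hierarchy or default_hierarchy()
    for row in spec.rows:
        if row.haplogroup not in hierarchy:
            raise KeyError(f"unknown haplogroup {row.haplogroup!r} in cohort spec")
    rng = np.random.default_rng(spec.seed)

    reserved = hierarchy.all_marker_positions()
    candidates = np.array(
        [p for p in range(1, reference.length + 1) if p not in reserved]
    )

    sequences: Dict[str, str] = {}
    meta_rows = []
    counter = 0
    for row in spec.rows:
        base_calls = _path_marker_calls(hierarchy, row.haplogroup)
        for _ in range(row.count):
            counter += 1
            sid = f"S{counter:04d}_{row.breed.replace(' ', '')}"
            calls = []
            for call in base_calls:
                control = call.position in hierarchy.control_region
                eligible = control and (
                    spec.reversion_positions is None
                    or call.position in spec.reversion_positions
                )
                if eligible and spec.reversion_noise > 0 and rng.random() < spec.reversion_noise:
                    continue  # reverted: the sample lacks this diagnostic
                calls.append(call)
            k = int(rng.poisson(spec.private_lambda))
            if k:
                for pos in rng.choice(candidates, size=k, replace=False):
                    pos = int(pos)
                    ref_base = reference.base(pos)
                    if rng.random() < TRANSITION_FRACTION:
                        calls.append(VariantCall(pos, VariantKind.TRANSITION))
                    else:
                        choices = sorted(set("ACGT") - {ref_base, transition_partner(ref_base)})
                        calls.append(
                            VariantCall(pos, VariantKind.TRANSVERSION,
                                        derived_base=str(rng.choice(choices)))
                        )
            sequences[sid] = apply_variants(reference, calls)
            meta_rows.append(
                {
                    "sample": sid,
                    "breed": row.breed,
                    "country": row.country,
                    "continent": row.continent,
                    "true_haplogroup": row.haplogroup,
                }
            )
    metadata = pd.DataFrame(
        meta_rows, columns=["sample", "breed", "country", "continent", "true_haplogroup"]
    )
    return Cohort(sequences, metadata, spec)


# ---------------------------------------------------------------------------
# Clade expansions
# ---------------------------------------------------------------------------


@dataclass
class ExpansionSpec:
    """A neutral clade expansion of known age for rho-recovery experiments."""

    n_tips: int
    age_ka: float
    rate_years_per_sub: float = DEFAULT_RATE
    topology: str = "star"  # "star" | "coalescent"
    hotspot_positions: Tuple[int, ...] = HOTSPOT_POSITIONS
    hotspot_weight: float = HOTSPOT_WEIGHT
    transition_fraction: float = TRANSITION_FRACTION
    region: Optional[Region] = None  # default: the reference coding region
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("an expansion needs at least two tips")
        if self.age_ka < 0:
            raise ValueError("age must be non-negative")
        if self.topology not in ("star", "coalescent"):
            raise ValueError("topology must be 'star' or 'coalescent'")

    @property
    def expected_substitutions(self) -> float:
        return self.age_ka * 1000.0 / self.rate_years_per_sub


@dataclass
class ExpansionResult:
    profiles: List[HaplotypeProfile]
    true_tree: AnnotatedTree
    spec: ExpansionSpec

    @property
    def mean_mutations(self) -> float:
        """Mean root-to-tip mutation count on the true genealogy."""
        from .dating import rho

        return rho(self.true_tree, region=None, substitutions_only=True)


def simulate_expansion(spec: ExpansionSpec, reference: ReferenceGenome) -> ExpansionResult:
    """Simulate an expansion: every root-to-tip path accumulates
    Poisson(age_years / rate) substitutions at (hotspot-weighted) random
    positions in the counting region.

    Returns both the tip profiles and the true genealogy as an annotated
    tree, so that estimation error of tree building can be isolated from the
    mutational noise itself.
    """
    rng = np.random.default_rng(spec.seed)
    region = spec.region or reference.regions.get("coding", reference.full_region)
    positions = np.array(list(region.positions(reference.length)))
    weights = np.ones(len(positions), dtype=float)
    hot = {p for p in spec.hotspot_positions if p in region}
    if hot:
        hot_mask = np.isin(positions, sorted(hot))
        weights[hot_mask] = spec.hotspot_weight
    weights /= weights.sum()

    import itertools

    counter = itertools.count(0)
    root = TreeNode(next(counter), frozenset())
    variant_index: Dict[object, VariantCall] = {}

    def mutate_path(profile_keys: set, n_events: int) -> List[EdgeMutation]:
        """Draw ``n_events`` substitutions, toggling presence per position."""
        events = []
        for pos in rng.choice(positions, size=n_events, replace=True, p=weights):
            pos = int(pos)
            existing = next((k for k in profile_keys if k[0] == pos), None)
            if existing is not None:
                # a second hit at a mutated position reverts it
                profile_keys.discard(existing)
                events.append(
                    EdgeMutation(replace(variant_index[existing], back_mutation=True))
                )
                continue
            ref_base = reference.base(pos)
            if rng.random() < spec.transition_fraction:
                call = VariantCall(pos, VariantKind.TRANSITION)
            else:
                choices = sorted(set("ACGT") - {ref_base, transition_partner(ref_base)})
                call = VariantCall(pos, VariantKind.TRANSVERSION,
                                   derived_base=str(rng.choice(choices)))
            variant_index[call.key] = call
            profile_keys.add(call.key)
            events.append(EdgeMutation(call))
        return events

    tips: List[TreeNode] = []

    if spec.topology == "star":
        counts = rng.poisson(spec.expected_substitutions, size=spec.n_tips)
        for i in range(spec.n_tips):
            keys: set = set()
            events = mutate_path(keys, int(counts[i]))
            tip = TreeNode(next(counter), frozenset(keys), (f"tip{i:03d}",), parent=root)
            tip.edge_mutations = events
            root.children.append(tip)
            tips.append(tip)
    else:
        mean_branch_subs = spec.expected_substitutions

        def grow(parent: TreeNode, tip_indices: List[int], age_ka: float) -> None:
            if len(tip_indices) == 1:
                n = int(rng.poisson(age_ka * 1000.0 / spec.rate_years_per_sub))
                keys = set(parent.profile)
                events = mutate_path(keys, n)
                tip = TreeNode(
                    next(counter), frozenset(keys),
                    (f"tip{tip_indices[0]:03d}",), parent=parent,
                )
                tip.edge_mutations = events
                parent.children.append(tip)
                tips.append(tip)
                return
            split_age = float(rng.uniform(0.0, age_ka))
            n = int(rng.poisson((age_ka - split_age) * 1000.0 / spec.rate_years_per_sub))
            keys = set(parent.profile)
            events = mutate_path(keys, n)
            mid = TreeNode(next(counter), frozenset(keys), parent=parent)
            mid.edge_mutations = events
            parent.children.append(mid)
            cut = int(rng.integers(1, len(tip_indices)))
            grow(mid, tip_indices[:cut], split_age)
            grow(mid, tip_indices[cut:], split_age)

        grow(root, list(range(spec.n_tips)), spec.age_ka)

    tree = AnnotatedTree(root, variant_index)
    from .parsimony_tree import mark_recurrences

    mark_recurrences(tree)

    profiles = [
        HaplotypeProfile(
            tip.sample_ids[0],
            frozenset(variant_index[k] for k in tip.profile),
            covered_region=reference.full_region,
            reference_name=reference.name,
        )
        for tip in tips
    ]
    return ExpansionResult(profiles, tree, spec)
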