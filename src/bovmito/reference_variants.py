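"""Circular mtDNA coordinate system, variant notation, and variant calling.

The bovine mitogenome is circular and, by convention, numbered 1-based against
a reference sequence (the 16,338-bp Bovine Reference Sequence in the original
survey work, but any circular reference is accepted).  Haplotypes are expressed
as sets of differences from that reference using the compact field notation:

* ``16050``   — transition at nucleotide position (np) 16050
* ``16057A``  — transversion to A at np 16057
* ``2055+C``  — insertion of a C after np 2055
* ``1600d``   — deletion of the reference base at np 1600
* ``8h``      — heteroplasmic transition at np 8
* ``@16050``  — back mutation (reversion to the reference/ancestral base)

Named regions may wrap the origin of the circle: the control region spans
nps 15718–517, i.e. an interval whose start exceeds its end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import edlib

__all__ = [
    "VariantKind",
    "Region",
    "ReferenceGenome",
    "VariantCall",
    "HaplotypeProfile",
    "VariantLabelError",
    "CoverageError",
    "ReferenceMismatchError",
    "parse_variant_label",
    "call_variants",
    "apply_variants",
    "profile_distance",
    "transition_partner",
    "is_transition",
    "CONTROL_REGION",
    "CODING_REGION",
    "BRS_LENGTH",
]

BRS_LENGTH = 16338

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}

# Two-base IUPAC ambiguity codes, used here to encode heteroplasmic positions.
IUPAC_PAIRS: Mapping[str, frozenset] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}


def transition_partner(base: str) -> str:
    """Return the purine<->purine / pyrimidine<->pyrimidine partner of ``base``."""
    try:
        return _TRANSITION[base.upper()]
    except KeyError:
        raise ValueError(f"no transition partner for base {base!r}")


def is_transition(ref_base: str, derived_base: str) -> bool:
    return _TRANSITION.get(ref_base.upper()) == derived_base.upper()


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


class VariantKind(str, Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    INSERTION = "insertion"
    DELETION = "deletion"

    @property
    def is_substitution(self) -> bool:
        return self in (VariantKind.TRANSITION, VariantKind.TRANSVERSION)


class VariantLabelError(ValueError):
    """A variant label does not match the notation grammar."""


class CoverageError(ValueError):
    """A sample or profile does not cover the coordinates an operation needs."""


class ReferenceMismatchError(ValueError):
    """Two profiles were called against different references."""


@dataclass(frozen=True)
class Region:
    """1-based inclusive interval on the circle; start > end wraps the origin."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"coordinates are 1-based: {self}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def contains(self, position: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    __contains__ = contains

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def positions(self, genome_length: int) -> Iterator[int]:
        if self.wraps:
            yield from range(self.start, genome_length + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.start}, {self.end}]"


CONTROL_REGION = Region(15718, 517)
CODING_REGION = Region(364, 15791)


@dataclass
class ReferenceGenome:
    """A circular 1-based reference with named coordinate regions."""

    name: str
    sequence: str
    regions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty reference sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def full_region(self) -> Region:
        return Region(1, self.length)

    def base(self, position: int) -> str:
        if not 1 <= position <= self.length:
            raise IndexError(f"np {position} outside reference of {self.length} bp")
        return self.sequence[position - 1]

    def region(self, name: str) -> Region:
        try:
            return self.regions[name]
        except KeyError:
            raise KeyError(f"reference {self.name!r} has no region {name!r}")

    def extract(self, region: Region) -> str:
        """Linearise ``region`` (wrapping the origin if needed)."""
        if region.wraps:
            return self.sequence[region.start - 1 :] + self.sequence[: region.end]
        return self.sequence[region.start - 1 : region.end]

    def with_sequence(self, sequence: str, name: Optional[str] = None) -> "ReferenceGenome":
        return ReferenceGenome(name or self.name, sequence, dict(self.regions))


_LABEL_RE = re.compile(
    r"^(?P<back>@?)(?P<pos>\d+)"
    r"(?:(?P<base>[ACGT])|\+(?P<ins>[ACGT]+)|(?P<del>d))?"
    r"(?P<het>h?)$"
)


@dataclass(frozen=True)
class VariantCall:
    """One annotated difference from the reference at a nucleotide position.

    ``derived_base`` is required for transversions and insertions; for a
    transition it may be omitted because the derived base is determined by the
    reference base.  ``back_mutation`` marks a reversion toward the
    reference/ancestral state and is meaningful only relative to a haplogroup
    or tree context (the ``@`` prefix of the field notation).
    """

    position: int
    kind: VariantKind
    derived_base: Optional[str] = None
    heteroplasmic: bool = False
    back_mutation: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based")
        if self.kind in (VariantKind.TRANSVERSION, VariantKind.INSERTION):
            if self.derived_base is None:
                raise ValueError(f"{self.kind.value} requires a derived base")
        if self.kind is VariantKind.DELETION and self.derived_base is not None:
            raise ValueError("deletions carry no derived base")

    @property
    def key(self):
        """Identity for set semantics.

        Transitions are keyed by position alone (the derived base is implied
        by the reference), so a marker parsed from a bare-number label matches
        the fully resolved call produced by the variant caller.  Flags
        (heteroplasmy, back mutation) are annotations, not identity.
        """
        if self.kind is VariantKind.TRANSITION:
            return (self.position, "transition", None)
        if self.kind is VariantKind.DELETION:
            return (self.position, "deletion", None)
        return (self.position, self.kind.value, self.derived_base)

    def label(self) -> str:
        parts = ["@" if self.back_mutation else "", str(self.position)]
        if self.kind is VariantKind.TRANSVERSION:
            parts.append(self.derived_base)
        elif self.kind is VariantKind.INSERTION:
            parts.append("+" + self.derived_base)
        elif self.kind is VariantKind.DELETION:
            parts.append("d")
        if self.heteroplasmic:
            parts.append("h")
        return "".join(parts)

    def __str__(self) -> str:
        return self.label()


def parse_variant_label(label: str) -> VariantCall:
    """Parse a field-notation label such as ``16050``, ``2055+C``, ``1600d``,
    ``@16113`` or ``16057Ah`` into a :class:`VariantCall`.

    The label round-trips: ``parse_variant_label(x).label() == x``.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        bad = re.sub(r"^@?\d*", "", label.strip()) or label
        raise VariantLabelError(f"malformed variant label {label!r} (offending token {bad!r})")
    position = int(m.group("pos"))
    if m.group("ins"):
        kind, base = VariantKind.INSERTION, m.group("ins")
    elif m.group("del"):
        kind, base = VariantKind.DELETION, None
    elif m.group("base"):
        kind, base = VariantKind.TRANSVERSION, m.group("base")
    else:
        kind, base = VariantKind.TRANSITION, None
    return VariantCall(
        position=position,
        kind=kind,
        derived_base=base,
        heteroplasmic=bool(m.group("het")),
        back_mutation=bool(m.group("back")),
    )


@dataclass
class HaplotypeProfile:
    """A sample's set of differences from the reference over a covered region."""

    sample_id: str
    variants: frozenset = frozenset()
    covered_region: Optional[Region] = None
    reference_name: Optional[str] = None

    def __post_init__(self) -> None:
        self.variants = frozenset(self.variants)
        subs_positions = [
            v.position for v in self.variants if v.kind.is_substitution
        ]
        if len(subs_positions) != len(set(subs_positions)):
            raise ValueError(
                f"profile {self.sample_id!r}: more than one substitution at one position"
            )
        if self.covered_region is not None:
            outside = [v for v in self.variants if v.position not in self.covered_region]
            if outside:
                raise ValueError(
                    f"profile {self.sample_id!r}: variants outside covered region: "
                    + ", ".join(v.label() for v in outside)
                )

    @classmethod
    def from_labels(
        cls,
        sample_id: str,
        labels: Iterable[str],
        covered_region: Optional[Region] = None,
        reference_name: Optional[str] = None,
    ) -> "HaplotypeProfile":
        return cls(
            sample_id,
            frozenset(parse_variant_label(s) for s in labels),
            covered_region,
            reference_name,
        )

    @property
    def keys(self) -> frozenset:
        return frozenset(v.key for v in self.variants)

    def carries(self, call: VariantCall) -> bool:
        """True if the profile carries ``call`` (ignoring annotation flags)."""
        return call.key in self.keys

    def carries_position(self, position: int) -> bool:
        return any(v.position == position for v in self.variants)

    def substitution_at(self, position: int) -> Optional[VariantCall]:
        for v in self.variants:
            if v.position == position and v.kind.is_substitution:
                return v
        return None

    def covers(self, position: int) -> bool:
        return self.covered_region is None or position in self.covered_region

    def labels(self) -> list:
        return sorted((v.label() for v in self.variants), key=_label_sort_key)

    def __len__(self) -> int:
        return len(self.variants)


def _label_sort_key(label: str):
    m = re.match(r"@?(\d+)", label)
    return (int(m.group(1)) if m else 0, label)


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def call_variants(
    sample_sequence: str,
    reference: ReferenceGenome,
    region: Optional[Region] = None,
    sample_id: str = "sample",
    indel_slack: int = 50,
) -> HaplotypeProfile:
    """Call the differences between ``sample_sequence`` and the reference.

    ``sample_sequence`` is the sample's sequence over ``region`` (default: the
    whole genome, in the reference's linearisation — mitogenomes assembled
    against the same reference share its origin, so no rotation search is
    performed).  Two-base IUPAC codes (R/Y/W/S/K/M) in the sample are read as
    heteroplasmic positions.  Indels are reported at their 5'-most equivalent
    coordinate.
    """
    region = region or reference.full_region
    ref_seq = reference.extract(region)
    sample = sample_sequence.upper().replace("U", "T")
    if len(sample) < len(ref_seq) - indel_slack:
        raise CoverageError(
            f"sample {sample_id!r} is {len(sample)} bp but region {region} "
            f"spans {len(ref_seq)} bp (allowed slack {indel_slack})"
        )

    equalities = [(code, b) for code, pair in IUPAC_PAIRS.items() for b in pair]
    result = edlib.align(sample, ref_seq, task="path", additionalEqualities=equalities)
    cigar = result["cigar"]
    if cigar is None:  # pragma: no cover - edlib always returns a path for NW
        raise RuntimeError("alignment failed")

    # offset (0-based in the linearised region) -> genome coordinate
    offsets = list(region.positions(reference.length))

    raw_subs = []  # (ref_offset, sample_base)
    raw_dels = []  # list of ref_offset runs
    raw_ins = []   # (ref_offset_of_preceding_base, inserted_bases)
    qi = ri = 0
    for count_s, op in _CIGAR_RE.findall(cigar):
        n = int(count_s)
        if op in "=XM":
            for k in range(n):
                sb, rb = sample[qi + k], ref_seq[ri + k]
                if sb != rb:
                    raw_subs.append((ri + k, sb))
            qi += n
            ri += n
        elif op == "I":  # present in sample, absent from reference
            raw_ins.append((ri - 1, sample[qi : qi + n]))
            qi += n
        elif op == "D":  # absent from sample
            raw_dels.append(list(range(ri, ri + n)))
            ri += n

    calls = []
    for off, sb in raw_subs:
        rb = ref_seq[off]
        het = False
        if sb in IUPAC_PAIRS:
            pair = IUPAC_PAIRS[sb]
            if rb in pair:
                sb = next(iter(pair - {rb}))
                het = True
            else:
                continue  # ambiguous base incompatible with reference: skip
        kind = VariantKind.TRANSITION if is_transition(rb, sb) else VariantKind.TRANSVERSION
        calls.append(
            VariantCall(
                offsets[off],
                kind,
                derived_base=None if kind is VariantKind.TRANSITION else sb,
                heteroplasmic=het,
            )
        )

    for run in raw_dels:
        start = _left_shift_deletion(ref_seq, run[0], len(run))
        for k in range(len(run)):
            calls.append(VariantCall(offsets[start + k], VariantKind.DELETION))

    for off, bases in raw_ins:
        off, bases = _left_shift_insertion(ref_seq, off, bases)
        # a multi-base insertion is a single entry ("2055+CC"): an extension of
        # the printed single-base convention that keeps set semantics intact
        calls.append(VariantCall(offsets[off] if off >= 0 else offsets[0],
                                 VariantKind.INSERTION, derived_base=bases))

    return HaplotypeProfile(
        sample_id, frozenset(calls), covered_region=region, reference_name=reference.name
    )


def _left_shift_deletion(ref_seq: str, start: int, length: int) -> int:
    """5'-normalise a deletion of ``ref_seq[start:start+length]``."""
    while start > 0 and ref_seq[start - 1] == ref_seq[start + length - 1]:
        start -= 1
    return start


def _left_shift_insertion(ref_seq: str, anchor: int, bases: str):
    """5'-normalise an insertion placed after ``ref_seq[anchor]``."""
    while anchor >= 0 and ref_seq[anchor] == bases[-1]:
        # sliding the run left past an identical base yields an equivalent placement
        bases = ref_seq[anchor] + bases[:-1]
        anchor -= 1
    return anchor, bases


def apply_variants(
    reference: ReferenceGenome,
    variants: Iterable[VariantCall],
    region: Optional[Region] = None,
) -> str:
    """Apply ``variants`` to the reference and return the sequence over ``region``.

    Inverse of :func:`call_variants` up to indel-placement normalisation.
    Back-mutation-flagged calls are skipped (they denote the reference state).
    Heteroplasmic substitutions are written as the derived base.
    """
    region = region or reference.full_region
    offsets = list(region.positions(reference.length))
    index = {pos: i for i, pos in enumerate(offsets)}
    chars = [[reference.base(pos)] for pos in offsets]
    for v in sorted(variants, key=lambda v: (v.position, v.kind.value)):
        if v.back_mutation or v.position not in index:
            continue
        i = index[v.position]
        if v.kind is VariantKind.TRANSITION:
            base = v.derived_base or transition_partner(reference.base(v.position))
            chars[i][0] = base
        elif v.kind is VariantKind.TRANSVERSION:
            chars[i][0] = v.derived_base
        elif v.kind is VariantKind.DELETION:
            chars[i][0] = ""
        elif v.kind is VariantKind.INSERTION:
            chars[i].append(v.derived_base)
    return "".join("".join(c) for c in chars)


def profile_distance(
    a: HaplotypeProfile,
    b: HaplotypeProfile,
    region: Optional[Region] = None,
    substitutions_only: bool = False,
) -> int:
    """Size of the symmetric difference of two variant sets within ``region``.

    With ``substitutions_only`` indels are ignored — the convention used when
    counting base substitutions in the coding region for dating.
    """
    if (
        a.reference_name is not None
        and b.reference_name is not None
        and a.reference_name != b.reference_name
    ):
        raise ReferenceMismatchError(
            f"profiles called against different references: "
            f"{a.reference_name!r} vs {b.reference_name!r}"
        )

    def qualify(profile: HaplotypeProfile):
        out = set()
        for v in profile.variants:
            if substitutions_only and not v.kind.is_substitution:
                continue
            if region is not None and v.position not in region:
                continue
            out.add(v.key)
        return out

    return len(qualify(a) ^ qualify(b))


def profile_table(profiles: Sequence[HaplotypeProfile]):
    """Long-format variant table (one row per call) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for p in profiles:
        for v in sorted(p.variants, key=lambda v: (v.position, v.kind.value)):
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "position": v.position,
                    "label": v.label(),
                    "kind": v.kind.value,
                    "heteroplasmic": v.heteroplasmic,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "position", "label", "kind", "heteroplasmic"])
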