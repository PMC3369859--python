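"""In-silico PCR-RFLP genotyping.

The survey assay for the T1b-diagnostic G>A transition at np 7542 amplifies a
235-bp fragment (nps 7335-7569) whose reverse primer carries a deliberate
mismatch at its third-from-last 3' base.  The mismatch is copied into the
product, so that an amplicon with the ancestral G at np 7542 contains a HinfI
recognition site (G/ANTC) there; the amplicon also contains one constitutive
HinfI site.  G-allele products are therefore cut twice (fragments 27, 62 and
146 bp) while A-allele products are cut once (62 and 173 bp).

This module simulates primer binding (with a configurable mismatch budget
that excludes the 3'-terminal bases), product formation with primer bases
incorporated, restriction digestion with degenerate recognition patterns, and
fragment-pattern genotype calling with a gel-resolution tolerance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .reference_variants import (
    ReferenceGenome,
    Region,
    reverse_complement,
)

__all__ = [
    "Primer",
    "RestrictionEnzyme",
    "Amplicon",
    "DigestResult",
    "AssayDesign",
    "AmplificationError",
    "in_silico_pcr",
    "digest",
    "genotype_from_fragments",
    "HINFI",
    "T1B_FORWARD_PRIMER",
    "T1B_REVERSE_PRIMER",
    "t1b_hinfi_assay",
    "engineer_assay_template",
]

T1B_FORWARD_PRIMER = "TCAAAGTTAAGTTACAAGTGAAAGTCC"
T1B_REVERSE_PRIMER = "TTCAGATTGTCTCTACTTCTTGTGAAT"

_IUPAC_REGEX = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "W": "[AT]", "S": "[CG]",
    "K": "[GT]", "M": "[AC]", "N": "[ACGT]",
}


class AmplificationError(ValueError):
    """A primer fails to bind, or binds at more than one site."""


@dataclass(frozen=True)
class Primer:
    """A PCR primer written 5'->3'.

    ``strand`` is "forward" when the primer sequence reads along the
    reference forward strand and "reverse" when it is the reverse complement
    of it.  Deliberate template mismatches (e.g. engineered restriction
    sites) are simply part of ``sequence``; they are incorporated into the
    product.
    """

    sequence: str
    strand: str = "forward"
    name: str = "primer"

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.strand not in ("forward", "reverse"):
            raise ValueError("strand must be 'forward' or 'reverse'")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def forward_strand_sequence(self) -> str:
        """The primer's footprint as it appears on the forward strand."""
        if self.strand == "forward":
            return self.sequence
        return reverse_complement(self.sequence)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme with a (possibly degenerate) recognition pattern.

    ``cut_offset`` counts bases after the pattern start on the forward
    strand: HinfI G/ANTC has offset 1 (cut between G and A).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        object.__setattr__(self, "recognition", self.recognition.upper())
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut offset outside recognition pattern")

    def pattern(self) -> re.Pattern:
        return re.compile("(?=" + "".join(_IUPAC_REGEX[b] for b in self.recognition) + ")")


HINFI = RestrictionEnzyme("HinfI", "GANTC", 1)


@dataclass
class Amplicon:
    """A linear PCR product with its reference coordinates."""

    sequence: str
    start: int  # reference coordinate of the first base (5' end of fwd primer)
    end: int    # reference coordinate of the last base

    def __len__(self) -> int:
        return len(self.sequence)

    def coordinate(self, offset: int) -> int:
        """Reference coordinate of 0-based ``offset`` (amplicons never wrap
        more than once, so a simple modular shift suffices)."""
        return self.start + offset  # callers handle circular templates upstream


@dataclass
class DigestResult:
    fragment_lengths: List[int]  # ascending
    cut_positions: List[int]     # 0-based offsets within the amplicon
    called_allele: Optional[str] = None

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_lengths)


def _binding_sites(template: str, footprint: str, max_mismatches: int,
                   three_prime_exact: int, three_prime_at_end: bool) -> List[int]:
    """0-based start offsets where ``footprint`` binds the circular template.

    ``three_prime_at_end`` says whether the primer's 3' terminus maps to the
    end (forward primer) or the start (reverse primer) of the footprint.
    """
    L = len(template)
    k = len(footprint)
    doubled = template + template[: k - 1]
    sites = []
    for i in range(L):
        window = doubled[i : i + k]
        mismatches = 0
        ok = True
        for j, (a, b) in enumerate(zip(window, footprint)):
            if a == b:
                continue
            dist_from_3prime = (k - 1 - j) if three_prime_at_end else j
            if dist_from_3prime < three_prime_exact:
                ok = False
                break
            mismatches += 1
            if mismatches > max_mismatches:
                ok = False
                break
        if ok:
            sites.append(i)
    return sites


def in_silico_pcr(
    template: Union[str, ReferenceGenome],
    fwd: Primer,
    rev: Primer,
    max_mismatches: int = 3,
    three_prime_exact: int = 2,
    max_product: int = 20000,
) -> Amplicon:
    """Amplify the circular ``template`` with a forward/reverse primer pair.

    The product spans the outer primer ends inclusive; the primer regions of
    the product carry the PRIMER bases, so engineered mismatches appear in
    the amplicon.  Raises :class:`AmplificationError` when a primer does not
    bind or binds more than once.
    """
    seq = template.sequence if isinstance(template, ReferenceGenome) else template.upper()
    L = len(seq)

    fwd_fp = fwd.forward_strand_sequence
    rev_fp = rev.forward_strand_sequence
    fwd_sites = _binding_sites(seq, fwd_fp, max_mismatches, three_prime_exact,
                               three_prime_at_end=True)
    rev_sites = _binding_sites(seq, rev_fp, max_mismatches, three_prime_exact,
                               three_prime_at_end=False)
    for name, sites in (("forward", fwd_sites), ("reverse", rev_sites)):
        if not sites:
            raise AmplificationError(f"{name} primer does not bind the template")
        if len(sites) > 1:
            raise AmplificationError(
                f"{name} primer binds at {len(sites)} sites: ambiguous product"
            )
    f0, r0 = fwd_sites[0], rev_sites[0]
    product_len = (r0 + len(rev_fp) - f0) % L
    if product_len == 0 or product_len > max_product:
        raise AmplificationError("primers do not define a product on the circle")

    doubled = seq + seq
    product = list(doubled[f0 : f0 + product_len])
    product[: len(fwd_fp)] = fwd_fp
    product[product_len - len(rev_fp) :] = rev_fp
    return Amplicon("".join(product), start=f0 + 1, end=((f0 + product_len - 1) % L) + 1)


def digest(amplicon: Union[Amplicon, str], enzyme: RestrictionEnzyme) -> DigestResult:
    """Cut a linear amplicon at every recognition-site match.

    Matching is on the forward strand with IUPAC degeneracy; palindromic
    patterns (GANTC is its own reverse complement under N) need no second
    pass.  Fragment lengths are returned in ascending order and always sum
    to the amplicon length.
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon.upper()
    if not seq:
        raise ValueError("empty amplicon")
    cuts = sorted(
        m.start() + enzyme.cut_offset
        for m in enzyme.pattern().finditer(seq)
        if 0 < m.start() + enzyme.cut_offset < len(seq)
    )
    bounds = [0] + cuts + [len(seq)]
    fragments = sorted(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(fragment_lengths=fragments, cut_positions=cuts)


@dataclass
class AssayDesign:
    """A PCR-RFLP assay: primer pair, enzyme, and expected fragments per allele."""

    name: str
    fwd: Primer
    rev: Primer
    enzyme: RestrictionEnzyme
    diagnostic_position: int
    expected_fragments: Dict[str, Tuple[int, ...]]
    tolerance_bp: int = 2

    def genotype(self, amplicon: Union[Amplicon, str]) -> DigestResult:
        result = digest(amplicon, self.enzyme)
        result.called_allele = genotype_from_fragments(result.fragment_lengths, self)
        return result


def genotype_from_fragments(observed: Sequence[int], assay: AssayDesign) -> str:
    """Call the allele whose expected fragment multiset matches ``observed``.

    Each observed fragment must pair with an expected one within the assay's
    length tolerance (default +/-2 bp, mimicking gel resolution); anything
    else is "inconclusive".
    """
    if not observed:
        raise ValueError("no fragments observed")
    observed = sorted(observed)
    for allele, expected in assay.expected_fragments.items():
        expected = sorted(expected)
        if len(expected) != len(observed):
            continue
        if all(abs(o - e) <= assay.tolerance_bp for o, e in zip(observed, expected)):
            return allele
    return "inconclusive"


# ---------------------------------------------------------------------------
# The np 7542 HinfI assay and its synthetic template
# ---------------------------------------------------------------------------

AMPLICON_START = 7335
AMPLICON_END = 7569
CONSTITUTIVE_SITE_POS = 7396  # inferred from the printed fragment sizes
DIAGNOSTIC_POS = 7542
PRIMER_MISMATCH_POS = 7545  # third-from-last 3' base of the reverse primer


def t1b_hinfi_assay() -> AssayDesign:
    """The np 7542 G>A PCR-RFLP assay (T1b diagnostic)."""
    return AssayDesign(
        name="T1b-7542-HinfI",
        fwd=Primer(T1B_FORWARD_PRIMER, "forward", "7335F"),
        rev=Primer(T1B_REVERSE_PRIMER, "reverse", "7569R"),
        enzyme=HINFI,
        diagnostic_position=DIAGNOSTIC_POS,
        expected_fragments={"G": (27, 62, 146), "A": (62, 173)},
    )


def engineer_assay_template(
    reference: ReferenceGenome, allele: str = "G", name: Optional[str] = None
) -> ReferenceGenome:
    """Write the synthetic np 7335-7569 assay locus into a copy of ``reference``.

    This is a synthetic stand-in for the true reference locus: primer
    binding sites are installed verbatim, the constitutive HinfI site is
    placed with its G at np 7396 (the position implied by the printed
    fragment sizes, not itself printed), np 7542 receives ``allele``, and the
    reverse-primer footprint carries the template base that the primer
    mismatches (so the engineered site exists only in the PCR product).  The
    filler between the fixed features is a CA repeat, which cannot form a
    GANTC site.
    """
    if allele not in ("G", "A"):
        raise ValueError("allele must be 'G' or 'A'")
    if reference.length < AMPLICON_END:
        raise ValueError("reference too short to host the assay locus")

    region = list("CA" * 200)[: AMPLICON_END - AMPLICON_START + 1]

    def put(position: int, bases: str) -> None:
        off = position - AMPLICON_START
        region[off : off + len(bases)] = list(bases)

    put(AMPLICON_START, T1B_FORWARD_PRIMER)
    put(CONSTITUTIVE_SITE_POS, "GATTC")  # a GANTC realisation
    put(DIAGNOSTIC_POS, allele)
    rev_fp = reverse_complement(T1B_REVERSE_PRIMER)
    put(DIAGNOSTIC_POS + 1, rev_fp)
    put(PRIMER_MISMATCH_POS, "C")  # template side of the engineered mismatch

    seq = list(reference.sequence)
    seq[AMPLICON_START - 1 : AMPLICON_END] = region
    out = reference.with_sequence("".join(seq), name=name or f"{reference.name}|rflp-{allele}")

    # the crafted locus must contain no stray recognition sites
    locus = "".join(region)
    stray = [
        m.start() + AMPLICON_START
        for m in HINFI.pattern().finditer(locus)
        if m.start() + AMPLICON_START not in (CONSTITUTIVE_SITE_POS, DIAGNOSTIC_POS)
    ]
    if stray:  # pragma: no cover - construction is deterministic
        raise AssertionError(f"unexpected HinfI sites at {stray}")
    return out
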