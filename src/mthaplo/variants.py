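"""Variant-level domain types: reference sequences, variant calls, sample profiles.

All coordinates are 1-based and inclusive, matching conventional human mtDNA
(rCRS) numbering. A sample is represented by the set of differences from the
reference ("variant profile"), the standard notation in mtDNA phylogenetics:
a bare position ("16189") denotes a transition, a position with an appended
base ("16183C") a transversion to that base, and a dotted/suffixed form an
insertion ("573.1C") or deletion ("523d"). Indels are recorded but excluded
from all clock computations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
NUCLEOTIDES = frozenset("ACGT")
#: characters accepted in input sequences beyond ACGT (treated as missing)
MISSING = frozenset("N-")

TRANSITION = "transition"
TRANSVERSION = "transversion"
INSERTION = "insertion"
DELETION = "deletion"


def substitution_class(ref_base: str, alt_base: str) -> str:
    """Classify a substitution as transition or transversion."""
    pair = {ref_base, alt_base}
    if pair <= PURINES or pair <= PYRIMIDINES:
        return TRANSITION
    return TRANSVERSION


@dataclass(frozen=True, order=True)
class VariantCall:
    """A single difference from the reference at a 1-based position."""

    position: int
    ref_base: str = ""
    alt_base: str = ""
    mclass: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.mclass:
            if self.ref_base in NUCLEOTIDES and self.alt_base in NUCLEOTIDES:
                object.__setattr__(
                    self, "mclass",
                    substitution_class(self.ref_base, self.alt_base))
            else:
                raise ValueError(
                    f"cannot infer mutation class at {self.position}")
        if self.mclass in (TRANSITION, TRANSVERSION):
            if self.ref_base == self.alt_base:
                raise ValueError(
                    f"substitution at {self.position} has identical bases")
            if self.ref_base not in NUCLEOTIDES or self.alt_base not in NUCLEOTIDES:
                raise ValueError(
                    f"substitution at {self.position} needs ACGT ref/alt bases, "
                    f"got {self.ref_base!r}>{self.alt_base!r}"
                )
            expected = substitution_class(self.ref_base, self.alt_base)
            if expected != self.mclass:
                raise ValueError(
                    f"{self.ref_base}>{self.alt_base} at {self.position} is a "
                    f"{expected}, not a {self.mclass}"
                )
        elif self.mclass == INSERTION:
            if not self.alt_base or any(b not in NUCLEOTIDES for b in self.alt_base):
                raise ValueError(f"insertion at {self.position} needs inserted bases")
        elif self.mclass == DELETION:
            pass
        else:
            raise ValueError(f"unknown mutation class {self.mclass!r}")

    @property
    def is_substitution(self) -> bool:
        return self.mclass in (TRANSITION, TRANSVERSION)

    @property
    def is_transition(self) -> bool:
        return self.mclass == TRANSITION

    def __str__(self) -> str:
        return format_mutation(self)


_MUT_RE = re.compile(
    r"^(?P<pos>\d+)(?:(?P<tv>[ACGT])|(?P<del>d)|\.(?P<insn>\d+)(?P<insb>[ACGT]+))?$"
)


def format_mutation(v: VariantCall) -> str:
    """Render a variant in field notation.

    Transitions print as the bare position ("16189"); transversions append the
    derived base ("16183C"); deletions append "d" ("523d"); insertions use a
    dotted index plus the inserted bases ("573.1C").
    """
    if v.mclass == TRANSITION:
        return str(v.position)
    if v.mclass == TRANSVERSION:
        return f"{v.position}{v.alt_base}"
    if v.mclass == DELETION:
        return f"{v.position}d"
    return f"{v.position}.1{v.alt_base}"


def parse_mutation(token: str, reference: Optional["ReferenceSequence"] = None) -> VariantCall:
    """Parse a mutation token back into a :class:`VariantCall`.

    A reference is needed to recover ref/alt bases for bare-position
    transitions (the notation leaves them implicit); without one, a
    transition's bases are filled with the canonical A<->G placeholder.
    """
    m = _MUT_RE.match(token.strip())
    if m is None:
        raise ValueError(f"cannot parse mutation token {token!r}")
    pos = int(m.group("pos"))
    if m.group("del"):
        ref = reference.base(pos) if reference is not None else ""
        return VariantCall(pos, ref, "", DELETION)
    if m.group("insb"):
        return VariantCall(pos, "", m.group("insb"), INSERTION)
    if m.group("tv"):
        alt = m.group("tv")
        if reference is not None:
            ref = reference.base(pos)
        else:
            # any base from the other chemical class reproduces the token
            ref = "A" if alt in PYRIMIDINES else "C"
        return VariantCall(pos, ref, alt, substitution_class(ref, alt))
    if reference is not None:
        ref = reference.base(pos)
    else:
        ref = "A"
    alt = _TRANSITION_PARTNER[ref]
    return VariantCall(pos, ref, alt, TRANSITION)


_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def transition_partner(base: str) -> str:
    """The unique base reachable from ``base`` by a transition."""
    return _TRANSITION_PARTNER[base]


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference against which variants are scored (1-based positions)."""

    bases: str
    name: str = "reference"

    def __post_init__(self):
        bad = set(self.bases) - NUCLEOTIDES
        if bad:
            raise ValueError(f"reference contains non-ACGT characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, position: int) -> str:
        if not 1 <= position <= len(self.bases):
            raise ValueError(
                f"position {position} outside reference 1..{len(self.bases)}"
            )
        return self.bases[position - 1]


def synthetic_reference(length: int = 16569, seed: int = 20211201,
                        name: str = "synthetic-rCRS-like") -> ReferenceSequence:
    """A deterministic synthetic reference sequence.

    This is a stand-in with the same length and coordinate conventions as the
    real human mtDNA reference (rCRS, 16,569 bp); the base content is random
    and carries no biological meaning. All analyses in this package are
    reference-agnostic, so results on synthetic data are unaffected by the
    choice.
    """
    rng = np.random.default_rng(seed)
    bases = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return ReferenceSequence(bases, name)


@dataclass
class SequenceProfile:
    """A sample's variant list relative to the reference, with metadata."""

    sample_id: str
    variants: frozenset[VariantCall] = frozenset()
    population: Optional[str] = None
    lon: Optional[float] = None
    lat: Optional[float] = None
    haplogroup: Optional[str] = None

    def __post_init__(self):
        self.variants = frozenset(self.variants)
        subs = [v.position for v in self.variants if v.is_substitution]
        if len(subs) != len(set(subs)):
            raise ValueError(
                f"{self.sample_id}: more than one substitution at a position"
            )

    @property
    def substitutions(self) -> frozenset[VariantCall]:
        return frozenset(v for v in self.variants if v.is_substitution)

    def tokens(self) -> list[str]:
        """Mutation tokens sorted by position (deterministic)."""
        return [format_mutation(v) for v in sorted(self.variants)]


def call_variants(sequence: str, reference: ReferenceSequence,
                  sample_id: str = "sample", **meta) -> SequenceProfile:
    """Score a sequence against the reference site by site.

    Sequences must already be the reference length (alignment is out of
    scope). Positions carrying missing data (N or -) are skipped.
    """
    seq = sequence.upper()
    if len(seq) != len(reference):
        raise ValueError(
            f"{sample_id}: sequence length {len(seq)} != reference length "
            f"{len(reference)}"
        )
    calls = []
    for i, (r, s) in enumerate(zip(reference.bases, seq), start=1):
        if s == r:
            continue
        if s in MISSING:
            continue
        if s not in NUCLEOTIDES:
            raise ValueError(f"{sample_id}: invalid character {s!r} at position {i}")
        calls.append(VariantCall(i, r, s, substitution_class(r, s)))
    return SequenceProfile(sample_id, frozenset(calls), **meta)


def apply_variants(profile: SequenceProfile | Iterable[VariantCall],
                   reference: ReferenceSequence) -> str:
    """Reconstruct the sequence implied by a substitution-only profile."""
    variants = profile.variants if isinstance(profile, SequenceProfile) else profile
    seq = list(reference.bases)
    for v in variants:
        if not v.is_substitution:
            continue  # indels excluded from sequence reconstruction
        seq[v.position - 1] = v.alt_base
    return "".join(seq)
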