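"""In-silico bisulfite conversion, primer localisation and CpG enumeration.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T by
sequencing) while 5-methylcytosine — in mammalian promoters essentially
confined to CpG dinucleotides — is left intact.  Bisulfite PCR therefore
amplifies a reduced-alphabet template, and every downstream coordinate in a
quantitative bisulfite sequencing (qBGS) pipeline is anchored to (a) where the
primers bind on the converted strand and (b) where the CpG sites of the
*original* sequence fall inside the predicted amplicon.

Conventions
-----------
* Coordinates are 1-based inclusive in all public types (matching how genomic
  intervals are printed); slicing is done 0-based internally.
* Only top-strand (sense) bisulfite PCR is modelled.
* A primer pair is interpreted as: forward primer == a segment of the
  converted sense strand; reverse primer == either the reverse complement of
  a converted-sense segment (the usual listing convention) or, failing that,
  the converted-sense segment itself (some publications print the reverse
  primer's binding site instead of the oligo).  The two conventions are
  distinguishable because a converted top strand cannot contain a non-CpG
  cytosine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Assumption",
    "ReferenceSequence",
    "PrimerPair",
    "AmpliconSpec",
    "CpGMap",
    "bisulfite_convert",
    "predict_amplicon",
    "enumerate_cpgs",
    "apply_exclusions",
    "read_fasta",
]

Assumption = Literal["fully_methylated", "fully_unmethylated"]

_ALPHABET = frozenset("ACGTN")


class PrimerNotFoundError(ValueError):
    """A primer has no exact-enough match on the converted strand."""


class PrimerAmbiguityError(ValueError):
    """A primer (or primer-orientation convention) matches more than once."""


@dataclass(frozen=True)
class ReferenceSequence:
    """An uppercase DNA reference over {A, C, G, T, N}.

    ``coordinate_offset`` is the 1-based genomic position of the first base
    (optional; purely annotational — all operations use local coordinates).
    """

    name: str
    sequence: str
    coordinate_offset: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("reference sequence must be non-empty")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"invalid symbols in reference: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """A bisulfite-PCR primer pair, as printed in a methods section."""

    forward: str
    reverse: str
    label: str = ""

    def __post_init__(self) -> None:
        for attr in ("forward", "reverse"):
            p = getattr(self, attr).upper()
            if len(p) < 10:
                raise ValueError(f"{attr} primer shorter than 10 nt")
            if set(p) - set("ACGT"):
                raise ValueError(f"{attr} primer has non-ACGT symbols")
            object.__setattr__(self, attr, p)


@dataclass(frozen=True)
class AmpliconSpec:
    """A predicted amplicon: 1-based inclusive interval on the reference."""

    start: int
    end: int
    assumption: Assumption
    primer_pair: PrimerPair
    reverse_convention: Literal["revcomp", "direct"] = "revcomp"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CpGMap:
    """Ordered registry of CpG sites: local integer labels -> 1-based positions.

    ``positions[i]`` is the reference position of the C of the CG dinucleotide
    labelled ``labels[i]`` (labels are "CpG<k>" conceptually; stored as ints).
    Excluded labels stay in the registry — labels are never renumbered, so
    site addressing (e.g. CpG51-CpG74) remains stable after exclusions.
    """

    labels: tuple[int, ...]
    positions: tuple[int, ...]
    excluded: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions differ in length")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("CpG positions must be strictly increasing")
        unknown = self.excluded - set(self.labels)
        if unknown:
            raise ValueError(f"excluded labels not in map: {sorted(unknown)}")

    @property
    def n_sites(self) -> int:
        return len(self.labels)

    @property
    def analyzed_labels(self) -> tuple[int, ...]:
        return tuple(l for l in self.labels if l not in self.excluded)

    @property
    def n_analyzed(self) -> int:
        return len(self.analyzed_labels)

    def position_of(self, label: int) -> int:
        try:
            return self.positions[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no CpG site labelled {label}") from None

    def analyzed_positions(self) -> tuple[int, ...]:
        return tuple(
            p for l, p in zip(self.labels, self.positions) if l not in self.excluded
        )


def _as_sequence(ref: ReferenceSequence | str) -> str:
    return ref.sequence if isinstance(ref, ReferenceSequence) else ref.upper()


def bisulfite_convert(ref: ReferenceSequence | str, assumption: Assumption) -> str:
    """Convert a top-strand sequence as bisulfite treatment would.

    Under ``fully_unmethylated`` every C reads T.  Under ``fully_methylated``
    a C that is immediately followed by G (a CpG cytosine) is protected and
    reads C; every other C reads T.  Length and non-C bases are preserved.
    """
    seq = _as_sequence(ref)
    if set(seq) - _ALPHABET:
        raise ValueError("invalid symbols in sequence")
    if assumption == "fully_unmethylated":
        return seq.replace("C", "T")
    if assumption == "fully_methylated":
        out = []
        n = len(seq)
        for i, b in enumerate(seq):
            if b == "C" and not (i + 1 < n and seq[i + 1] == "G"):
                out.append("T")
            else:
                out.append(b)
        return "".join(out)
    raise ValueError(f"unknown conversion assumption: {assumption!r}")


def _find_matches(haystack: str, needle: str, max_mismatch: int = 0) -> list[int]:
    """0-based start positions where ``needle`` matches with <= max_mismatch."""
    if max_mismatch == 0:
        hits, start = [], haystack.find(needle)
        while start != -1:
            hits.append(start)
            start = haystack.find(needle, start + 1)
        return hits
    k = len(needle)
    hits = []
    for i in range(len(haystack) - k + 1):
        window = haystack[i : i + k]
        mm = sum(a != b for a, b in zip(window, needle))
        if mm <= max_mismatch:
            hits.append(i)
    return hits


def predict_amplicon(
    ref: ReferenceSequence,
    primers: PrimerPair,
    assumption: Assumption,
    max_mismatch: int = 0,
) -> AmpliconSpec:
    """Locate a primer pair on the converted sense strand and return the amplicon.

    The forward primer must match the converted sense strand exactly once.
    The reverse primer is tried first as the reverse complement of a
    converted-sense segment and, if that finds nothing, in direct top-strand
    orientation (see module docstring); matching in both conventions, or more
    than once within a convention, is an ambiguity error.  The amplicon spans
    the forward primer's first base through the last base of the reverse
    primer's binding site, 1-based inclusive.
    """
    conv = bisulfite_convert(ref, assumption)
    f_hits = _find_matches(conv, primers.forward, max_mismatch)
    if not f_hits:
        raise PrimerNotFoundError(
            f"forward primer {primers.label or primers.forward!r} not found"
        )
    if len(f_hits) > 1:
        raise PrimerAmbiguityError(
            f"forward primer matches {len(f_hits)} times on converted strand"
        )
    rc = str(Seq(primers.reverse).reverse_complement())
    r_hits_rc = _find_matches(conv, rc, max_mismatch)
    r_hits_direct = _find_matches(conv, primers.reverse, max_mismatch)
    if r_hits_rc and r_hits_direct:
        raise PrimerAmbiguityError(
            "reverse primer matches under both orientation conventions"
        )
    if r_hits_rc:
        r_hits, convention, r_len = r_hits_rc, "revcomp", len(rc)
    elif r_hits_direct:
        r_hits, convention, r_len = r_hits_direct, "direct", len(primers.reverse)
    else:
        raise PrimerNotFoundError(
            f"reverse primer {primers.label or primers.reverse!r} not found"
        )
    if len(r_hits) > 1:
        raise PrimerAmbiguityError(
            f"reverse primer matches {len(r_hits)} times on converted strand"
        )
    start0, r0 = f_hits[0], r_hits[0]
    end0 = r0 + r_len - 1
    if end0 <= start0:
        raise PrimerNotFoundError("reverse primer site lies upstream of forward primer")
    return AmpliconSpec(
        start=start0 + 1,
        end=end0 + 1,
        assumption=assumption,
        primer_pair=primers,
        reverse_convention=convention,  # type: ignore[arg-type]
    )


def enumerate_cpgs(
    ref: ReferenceSequence,
    start: int = 1,
    end: int | None = None,
) -> CpGMap:
    """Enumerate CG dinucleotides of the ORIGINAL sequence in [start, end].

    Sites are labelled 1..n in 5'->3' order.  A C at the interval's last base
    is not a site even if the next reference base is G (the dinucleotide must
    lie inside the interval).
    """
    seq = _as_sequence(ref)
    if end is None:
        end = len(seq)
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(f"invalid interval [{start}, {end}] on length-{len(seq)} reference")
    positions = [
        i + 1
        for i in range(start - 1, end - 1)  # C must sit strictly before `end`
        if seq[i] == "C" and seq[i + 1] == "G"
    ]
    return CpGMap(
        labels=tuple(range(1, len(positions) + 1)),
        positions=tuple(positions),
    )


def apply_exclusions(cpg_map: CpGMap, excluded: Iterable[int]) -> CpGMap:
    """Flag labels as excluded from analysis without renumbering the rest."""
    excluded = frozenset(int(l) for l in excluded)
    unknown = excluded - set(cpg_map.labels)
    if unknown:
        raise ValueError(f"cannot exclude unknown labels: {sorted(unknown)}")
    return replace(cpg_map, excluded=cpg_map.excluded | excluded)


def load_primer_config(path) -> dict[str, PrimerPair]:
    """Load primer pairs from a small YAML file.

    Expected layout::

        pairs:
          msp_methylated: {forward: TTTCG..., reverse: GCACT...}
          ...
    """
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    pairs = payload.get("pairs", payload)
    return {
        str(label): PrimerPair(
            forward=spec["forward"], reverse=spec["reverse"], label=str(label)
        )
        for label, spec in pairs.items()
    }


def read_fasta(path, name: str | None = None) -> ReferenceSequence:
    """Read the first (or named) record of a FASTA file as a reference."""
    for rec in SeqIO.parse(str(path), "fasta"):
        if name is None or rec.id == name:
            return ReferenceSequence(name=rec.id, sequence=str(rec.seq))
    raise ValueError(f"no FASTA record {'named ' + name if name else ''} in {path}")
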