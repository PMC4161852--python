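"""Per-clone and per-read methylation calling and proportion matrices.

Two acquisition routes feed the same matrix:

* **clones** — Sanger-sequenced molecules of a bisulfite-PCR amplicon.  Each
  clone is aligned to the reference with conversion-aware scoring and read out
  at every CpG position (C = methylated, T = unmethylated); the per-sample
  methylation proportion at site *i* is the fraction of clones carrying a
  methylated C at that site among all clones with a readable base there.
* **reads** — amplicon deep-sequencing reads, aligned the same way and piled
  up per CpG column; the proportion is C/(C+T) where the column depth passes
  ``min_depth``.

Conversion-aware alignment treats reference-C versus read-T as a match class,
so both fully converted and methylated molecules align without penalty.  A
clone's conversion efficiency — the fraction of non-CpG reference cytosines
read as T — is the per-molecule QC statistic; incompletely converted
molecules would inflate apparent methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .reference import CpGMap, ReferenceSequence

__all__ = [
    "ClonePattern",
    "PileupCounts",
    "MethylationMatrix",
    "AlignmentQualityError",
    "call_clone_pattern",
    "filter_clones",
    "proportions_from_clones",
    "pileup_call",
    "matrix_from_reads",
    "read_clone_fasta",
]

logger = logging.getLogger(__name__)

M, U, MISSING = 1, 0, -1


class AlignmentQualityError(ValueError):
    """A clone/read aligns below the identity threshold."""


@dataclass
class ClonePattern:
    """Methylation calls of one sequenced molecule over the analyzed CpG sites.

    ``calls`` holds 1 (methylated), 0 (unmethylated) or -1 (unreadable) per
    analyzed label of the map, in map order.
    """

    sample_id: str
    clone_id: str
    labels: tuple[int, ...]
    calls: np.ndarray
    conversion_efficiency: float
    identity: float = 1.0

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.labels),):
            raise ValueError("calls length must equal analyzed site count")
        if not 0.0 <= self.conversion_efficiency <= 1.0:
            raise ValueError("conversion_efficiency outside [0, 1]")


@dataclass
class PileupCounts:
    """Per-CpG base counts from a read pileup."""

    labels: tuple[int, ...]
    n_methylated: np.ndarray  # C at the CpG column
    n_unmethylated: np.ndarray  # T at the CpG column
    n_other: np.ndarray

    @property
    def depth(self) -> np.ndarray:
        return self.n_methylated + self.n_unmethylated + self.n_other


@dataclass
class MethylationMatrix:
    """Samples x CpG-sites methylation proportions with per-cell denominators.

    ``proportions`` is a float DataFrame in [0, 1] (NaN = missing, never a
    silent 0); ``denominators`` the informative-molecule count per cell.
    Columns are integer CpG labels.
    """

    proportions: pd.DataFrame
    denominators: pd.DataFrame
    source: str = "clones"

    def __post_init__(self) -> None:
        p, d = self.proportions, self.denominators
        if not (p.index.equals(d.index) and p.columns.equals(d.columns)):
            raise ValueError("proportions and denominators must share axes")
        vals = p.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise ValueError("proportions outside [0, 1]")
        if ((d.to_numpy() == 0) & ~np.isnan(vals)).any():
            raise ValueError("non-missing cell with zero denominator")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def site_labels(self) -> list[int]:
        return list(self.proportions.columns)

    def subset(self, labels: Sequence[int]) -> "MethylationMatrix":
        labels = list(labels)
        return MethylationMatrix(
            self.proportions[labels].copy(), self.denominators[labels].copy(), self.source
        )

    def to_tsv(self, proportions_path, denominators_path=None) -> None:
        out = self.proportions.copy()
        out.columns = [f"CpG{c}" for c in out.columns]
        out.to_csv(proportions_path, sep="\t", index_label="sample_id")
        if denominators_path is not None:
            d = self.denominators.copy()
            d.columns = [f"CpG{c}" for c in d.columns]
            d.to_csv(denominators_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, proportions_path, denominators_path=None, source="clones"):
        p = pd.read_csv(proportions_path, sep="\t", index_col="sample_id")
        p.columns = [int(str(c).removeprefix("CpG")) for c in p.columns]
        if denominators_path is not None:
            d = pd.read_csv(denominators_path, sep="\t", index_col="sample_id")
            d.columns = [int(str(c).removeprefix("CpG")) for c in d.columns]
        else:
            d = pd.DataFrame(1, index=p.index, columns=p.columns)
            d[p.isna()] = 0
        return cls(p, d, source)


def _make_aligner() -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            mat[a, b] = 2.0 if a == b else -2.0
    for b in alphabet:  # N is uninformative either way
        mat["N", b] = 0.0
        mat[b, "N"] = 0.0
    mat["C", "T"] = 2.0  # bisulfite: reference C may legitimately read T
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -6.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def _align_oriented(target: str, query: str):
    """Globally align query (or its reverse complement) to target.

    Returns ``(ref_to_query, oriented_query, identity, flipped)`` where
    ``ref_to_query[i]`` is the query index aligned to target position ``i``
    (-1 at gaps) and identity is the match-class fraction over all alignment
    columns (conversion-aware; gaps count against identity).
    """
    best = None
    for flipped in (False, True):
        q = str(Seq(query).reverse_complement()) if flipped else query
        aln = _ALIGNER.align(target, q)[0]
        if best is None or aln.score > best[0].score:
            best = (aln, q, flipped)
    aln, q, flipped = best
    indices = aln.indices  # (2, n_columns); -1 at gaps
    tcols, qcols = indices[0], indices[1]
    ref_to_query = np.full(len(target), -1, dtype=np.int64)
    both = (tcols >= 0) & (qcols >= 0)
    ref_to_query[tcols[both]] = qcols[both]
    tarr = np.frombuffer(target.encode(), dtype="S1")[tcols[both]]
    qarr = np.frombuffer(q.encode(), dtype="S1")[qcols[both]]
    matches = (tarr == qarr) | ((tarr == b"C") & (qarr == b"T"))
    identity = float(matches.sum()) / max(len(tcols), 1)
    return ref_to_query, q, identity, flipped


def _non_cpg_c_positions(seq: str, cpg_positions: Iterable[int]) -> np.ndarray:
    cpg = set(cpg_positions)
    return np.array(
        [i for i, b in enumerate(seq, start=1) if b == "C" and i not in cpg],
        dtype=np.int64,
    )


def call_clone_pattern(
    clone_seq: str,
    ref: ReferenceSequence,
    cpg_map: CpGMap,
    sample_id: str = "",
    clone_id: str = "",
    min_identity: float = 0.8,
) -> ClonePattern:
    """Align one clone to the reference and read out its methylation pattern.

    At each analyzed CpG position: clone C -> methylated, clone T ->
    unmethylated, anything else (gap, A, G, N) -> missing.  Conversion
    efficiency is computed over the aligned non-CpG reference cytosines as
    T / (C + T).  Raises :class:`AlignmentQualityError` below ``min_identity``.
    """
    target = ref.sequence
    ref_to_query, q, identity, _ = _align_oriented(target, clone_seq.upper())
    if identity < min_identity:
        raise AlignmentQualityError(
            f"clone {clone_id or '<anon>'} aligns at identity {identity:.3f} "
            f"< {min_identity}"
        )
    labels = cpg_map.analyzed_labels
    calls = np.full(len(labels), MISSING, dtype=np.int8)
    for k, pos in enumerate(cpg_map.analyzed_positions()):
        qi = ref_to_query[pos - 1]
        if qi >= 0:
            base = q[qi]
            if base == "C":
                calls[k] = M
            elif base == "T":
                calls[k] = U
    conv_positions = _non_cpg_c_positions(target, cpg_map.positions)
    n_c = n_t = 0
    for pos in conv_positions:
        qi = ref_to_query[pos - 1]
        if qi >= 0:
            if q[qi] == "T":
                n_t += 1
            elif q[qi] == "C":
                n_c += 1
    efficiency = n_t / (n_t + n_c) if (n_t + n_c) else 1.0
    return ClonePattern(
        sample_id=sample_id,
        clone_id=clone_id,
        labels=labels,
        calls=calls,
        conversion_efficiency=efficiency,
        identity=identity,
    )


def filter_clones(
    patterns: Sequence[ClonePattern], min_conversion: float = 0.95
) -> list[ClonePattern]:
    """Drop clones with conversion efficiency below ``min_conversion``.

    Samples losing every clone are logged as flagged (they surface as absent
    rows downstream rather than silently zeroed ones).
    """
    if not 0.0 <= min_conversion <= 1.0:
        raise ValueError("min_conversion must lie in [0, 1]")
    kept = [p for p in patterns if p.conversion_efficiency >= min_conversion]
    n_removed = len(patterns) - len(kept)
    if n_removed:
        logger.info("filter_clones: removed %d of %d clones", n_removed, len(patterns))
    emptied = {p.sample_id for p in patterns} - {p.sample_id for p in kept}
    for sid in sorted(emptied):
        logger.warning("filter_clones: sample %s lost all clones", sid)
    return kept


def proportions_from_clones(patterns: Sequence[ClonePattern]) -> MethylationMatrix:
    """Per-sample, per-site fraction of methylated clones.

    Missing calls are excluded from numerator and denominator; a site with no
    readable clone in a sample is a missing cell (NaN) with denominator 0.
    """
    if not patterns:
        raise ValueError("no clone patterns supplied")
    labels = patterns[0].labels
    if any(p.labels != labels for p in patterns):
        raise ValueError("clone patterns disagree on site labels")
    by_sample: dict[str, list[ClonePattern]] = {}
    for p in patterns:
        by_sample.setdefault(p.sample_id, []).append(p)
    sample_ids = sorted(by_sample)
    props = np.full((len(sample_ids), len(labels)), np.nan)
    denoms = np.zeros((len(sample_ids), len(labels)), dtype=np.int64)
    for r, sid in enumerate(sample_ids):
        calls = np.stack([p.calls for p in by_sample[sid]])  # clones x sites
        n_m = (calls == M).sum(axis=0)
        n_u = (calls == U).sum(axis=0)
        denom = n_m + n_u
        denoms[r] = denom
        np.divide(n_m, denom, out=props[r], where=denom > 0)
    return MethylationMatrix(
        proportions=pd.DataFrame(props, index=sample_ids, columns=list(labels)),
        denominators=pd.DataFrame(denoms, index=sample_ids, columns=list(labels)),
        source="clones",
    )


def _record_fields(read) -> tuple[str, np.ndarray | None]:
    """Sequence string and optional per-base qualities from a read record."""
    if isinstance(read, str):
        return read, None
    seq = str(read.seq)
    quals = read.letter_annotations.get("phred_quality")
    return seq, (np.asarray(quals) if quals is not None else None)


def pileup_call(
    reads: Sequence,
    ref: ReferenceSequence,
    cpg_map: CpGMap,
    min_depth: int = 100,
    min_baseq: int = 20,
    min_identity: float = 0.8,
) -> tuple[PileupCounts, pd.Series, pd.Series]:
    """Pile one sample's reads over the CpG columns and call proportions.

    Returns ``(counts, proportions, depths)`` over the analyzed labels.
    A column's proportion is C/(C+T) when C+T >= ``min_depth``, else missing;
    bases below ``min_baseq`` and non-C/T bases are ignored (alignment or
    sequencing artifacts do not enter the fraction).  Low-identity reads are
    skipped; a sample whose reads all fail is flagged via logging and yields
    an all-missing row.
    """
    labels = cpg_map.analyzed_labels
    positions = np.asarray(cpg_map.analyzed_positions())
    n_m = np.zeros(len(labels), dtype=np.int64)
    n_u = np.zeros(len(labels), dtype=np.int64)
    n_o = np.zeros(len(labels), dtype=np.int64)
    n_used = 0
    for read in reads:
        seq, quals = _record_fields(read)
        ref_to_query, q, identity, flipped = _align_oriented(ref.sequence, seq.upper())
        if identity < min_identity:
            continue
        n_used += 1
        if flipped and quals is not None:
            quals = quals[::-1]
        for k, pos in enumerate(positions):
            qi = ref_to_query[pos - 1]
            if qi < 0:
                continue
            if quals is not None and quals[qi] < min_baseq:
                continue
            base = q[qi]
            if base == "C":
                n_m[k] += 1
            elif base == "T":
                n_u[k] += 1
            else:
                n_o[k] += 1
    if n_used == 0 and len(reads) > 0:
        logger.warning("pileup_call: no reads passed identity filter")
    counts = PileupCounts(labels, n_m, n_u, n_o)
    denom = n_m + n_u
    props = np.full(len(labels), np.nan)
    ok = denom >= max(min_depth, 1)
    np.divide(n_m, denom, out=props, where=ok)
    return (
        counts,
        pd.Series(props, index=list(labels)),
        pd.Series(np.where(ok, denom, 0), index=list(labels)),
    )


def matrix_from_reads(
    reads_by_sample: Mapping[str, Sequence],
    ref: ReferenceSequence,
    cpg_map: CpGMap,
    min_depth: int = 100,
    min_baseq: int = 20,
    min_identity: float = 0.8,
) -> MethylationMatrix:
    """Build a read-derived methylation matrix, one pileup per sample."""
    rows, denoms, sample_ids = [], [], []
    for sid in sorted(reads_by_sample):
        _, props, depth = pileup_call(
            reads_by_sample[sid], ref, cpg_map, min_depth, min_baseq, min_identity
        )
        sample_ids.append(sid)
        rows.append(props)
        denoms.append(depth)
    return MethylationMatrix(
        proportions=pd.DataFrame(rows, index=sample_ids),
        denominators=pd.DataFrame(denoms, index=sample_ids).astype(np.int64),
        source="reads",
    )


def export_clone_patterns(patterns: Sequence[ClonePattern], path) -> None:
    """Write a lollipop-style TSV: one row per clone, M / U / . per site."""
    symbol = {M: "M", U: "U", MISSING: "."}
    with open(path, "w") as fh:
        if patterns:
            header = "\t".join(f"CpG{l}" for l in patterns[0].labels)
            fh.write(f"sample_id\tclone_id\t{header}\n")
        for p in patterns:
            calls = "\t".join(symbol[int(c)] for c in p.calls)
            fh.write(f"{p.sample_id}\t{p.clone_id}\t{calls}\n")


def read_clone_fasta(path, sample_id: str | None = None):
    """Read clone sequences from FASTA.

    Headers of the form ``sample|clone`` assign clones to samples; otherwise
    all records belong to ``sample_id``.  Returns a list of
    ``(sample_id, clone_id, sequence)`` triples.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" in rec.id:
            sid, cid = rec.id.split("|", 1)
        elif sample_id is not None:
            sid, cid = sample_id, rec.id
        else:
            raise ValueError(
                f"record {rec.id!r} has no 'sample|clone' header and no sample_id given"
            )
        out.append((sid, cid, str(rec.seq)))
    return out
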