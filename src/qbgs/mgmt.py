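"""Study assets for the *MGMT* promoter qBGS assay.

This module carries the published primer sets of the *MGMT* promoter assay
(methylation-specific PCR, nested Sanger-qBGS, and the nested MiSeq amplicon)
and a SYNTHETIC stand-in promoter reference.

The stand-in reference
----------------------
The true assay reference is the GenBank accession X61657.1
(chr10:131,155,100-131,155,761 for the sequenced fragment).  That sequence is
not redistributable here and cannot be fetched in an offline environment, so
:func:`synthetic_mgmt_reference` deterministically constructs a SYNTHETIC
sequence with the assay's published geometry:

* the nested qBGS primer pair brackets a 662-bp amplicon containing exactly
  78 CpG sites, with a CpG-sparse middle segment spanning sites CpG28-CpG50;
* the methylated / unmethylated MSP pairs yield 81-bp and 93-bp amplicons
  inside the CpG-dense 5' segment;
* the MiSeq second-round pair yields a 216-bp amplicon whose 24 CpG sites are
  the classifier window CpG51-CpG74;
* first-round (outer) primer binding sites flank the nested amplicons.

Every base outside the primer binding sites is synthetic filler.  The stand-in
exercises the full primer-matching and CpG-enumeration machinery at the
published geometry, but it is NOT the natural promoter sequence.
"""

from __future__ import annotations

import re

import numpy as np

from .reference import (
    PrimerPair,
    ReferenceSequence,
    bisulfite_convert,
    enumerate_cpgs,
    predict_amplicon,
)

__all__ = [
    "STUDY_PRIMERS",
    "CLASSIFIER_SITES",
    "MIDDLE_SEGMENT_SITES",
    "synthetic_mgmt_reference",
    "study_cpg_map",
]

#: Primer pairs as printed in the assay description (5'->3').
STUDY_PRIMERS: dict[str, PrimerPair] = {
    "msp_unmethylated": PrimerPair(
        forward="TTTGTGTTTTGATGTTTGTAGGTTTTTGT",
        reverse="AACTCCACACTCTTCCAAAAACAAAACA",
        label="msp_unmethylated",
    ),
    "msp_methylated": PrimerPair(
        forward="TTTCGACGTTCGTAGGTTTTCGC",
        reverse="GCACTCTTCCGAAAACGAAACG",
        label="msp_methylated",
    ),
    "qbgs_first_round": PrimerPair(
        forward="TGGTAAATTAAGGTATAGAGTTTTAGG",
        reverse="GGTTAGGTGTTAGTGATGTT",
        label="qbgs_first_round",
    ),
    "qbgs_second_round": PrimerPair(
        forward="TGGTAAATTAAGGTATAGAGTTTTAGG",
        reverse="TTGGATTAGGTTTTTGGGGTT",
        label="qbgs_second_round",
    ),
    "miseq_first_round": PrimerPair(
        forward="GGATATGTTGGGATAGTT",
        reverse="CCAAAAACCCCAAACCC",
        label="miseq_first_round",
    ),
    "miseq_second_round": PrimerPair(
        forward="GGATATGTTGGGATAGTT",
        reverse="AAATAAATAAAAATCAAAAC",
        label="miseq_second_round",
    ),
}

#: Classifier window: the 24 CpG sites covered by the MiSeq amplicon.
CLASSIFIER_SITES: tuple[int, ...] = tuple(range(51, 75))

#: CpG-sparse middle segment of the promoter amplicon.
MIDDLE_SEGMENT_SITES: tuple[int, ...] = tuple(range(28, 51))

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def _filler(rng: np.random.Generator, length: int, n_cpg: int = 0) -> str:
    """Deterministic filler over {A,T,G} with exactly ``n_cpg`` CG dinucleotides."""
    base_len = length - 2 * n_cpg
    if base_len < 0:
        raise ValueError("filler too short for requested CpG count")
    base = "".join(rng.choice(list("ATG"), size=base_len))
    if n_cpg == 0:
        return base
    cuts = np.linspace(0, base_len, n_cpg + 1).astype(int)
    parts = [base[cuts[i] : cuts[i + 1]] for i in range(n_cpg)]
    return "".join(p + "CG" for p in parts) + base[cuts[-1] :]


def _seed_cpgs_into_tg(site: str, occurrences: tuple[int, ...]) -> str:
    """Turn selected TG dinucleotides of a converted-strand segment into CG.

    This reconstructs a plausible *original* (pre-conversion) sequence for a
    primer binding site printed in bisulfite-converted space: an original CpG
    reads TG after unmethylated conversion.
    """
    s = list(site)
    hits = [m.start() for m in re.finditer("TG", site)]
    for k in occurrences:
        s[hits[k]] = "C"
    return "".join(s)


def synthetic_mgmt_reference() -> ReferenceSequence:
    """Build the SYNTHETIC stand-in promoter reference (see module docstring).

    Deterministic; asserts its own geometry (four predicted amplicons of
    93/81/662/216 bp and 78 CpG sites in the qBGS amplicon) before returning.
    """
    rng = np.random.default_rng(20140830)
    P = STUDY_PRIMERS

    f1 = P["qbgs_second_round"].forward                 # 27 nt, C-free
    r2_site = P["qbgs_second_round"].reverse            # printed in top-strand orientation
    fm = P["msp_methylated"].forward                    # all C's are CpG C's
    rm_site = _revcomp(P["msp_methylated"].reverse)     # converted-sense binding site
    fu_site = _seed_cpgs_into_tg(P["msp_unmethylated"].forward, (0, 2))
    ru_site = _seed_cpgs_into_tg(_revcomp(P["msp_unmethylated"].reverse), (0, 1))
    ft = P["miseq_second_round"].forward                # C-free
    rt_site = _revcomp(P["miseq_second_round"].reverse)  # C-free
    rt1_site = _revcomp(P["miseq_first_round"].reverse)  # C-free, 17 nt
    r1_site = P["qbgs_first_round"].reverse             # top-strand orientation, C-free

    msp_u = fu_site + _filler(rng, 36, n_cpg=2) + ru_site            # 93 bp
    msp_m = fm + "G" + _filler(rng, 35, n_cpg=3) + rm_site           # 81 bp
    early_fixed = _count_cg(msp_u) + _count_cg(msp_m) + 1            # +1: rm_site 3'C + B's G
    filler_a = _filler(rng, 34, n_cpg=27 - early_fixed)
    middle = _filler(rng, 120, n_cpg=23)
    test_amp = ft + _filler(rng, 178, n_cpg=24) + rt_site            # 216 bp
    tail = "ACGTCGTACGTCG" + rt1_site                                # 4 CpGs + outer site

    amplicon = (
        f1
        + filler_a
        + msp_u
        + msp_m
        + "G"                      # completes rm_site's trailing CpG
        + _filler(rng, 19)
        + middle
        + _filler(rng, 20)
        + test_amp
        + tail
        + r2_site
    )
    ref = ReferenceSequence(
        name="MGMT_promoter_synthetic",
        sequence=_filler(rng, 40) + amplicon + _filler(rng, 6) + r1_site + _filler(rng, 30),
        coordinate_offset=None,
    )

    # Self-check the published geometry.
    qbgs = predict_amplicon(ref, P["qbgs_second_round"], "fully_methylated")
    assert qbgs.length == 662, qbgs.length
    assert predict_amplicon(ref, P["msp_methylated"], "fully_methylated").length == 81
    assert predict_amplicon(ref, P["msp_unmethylated"], "fully_unmethylated").length == 93
    assert predict_amplicon(ref, P["miseq_second_round"], "fully_methylated").length == 216
    assert enumerate_cpgs(ref, qbgs.start, qbgs.end).n_sites == 78
    return ref


def _count_cg(s: str) -> int:
    return len(re.findall("CG", s))


def study_cpg_map(ref: ReferenceSequence | None = None):
    """CpG map of the 662-bp qBGS amplicon (labels CpG1..CpG78), plus the amplicon.

    Returns ``(amplicon_spec, cpg_map)``.  Labels are global: the MiSeq test
    amplicon's sites are addressed by these labels (CpG51-CpG74), never
    renumbered.
    """
    if ref is None:
        ref = synthetic_mgmt_reference()
    amp = predict_amplicon(ref, STUDY_PRIMERS["qbgs_second_round"], "fully_methylated")
    return amp, enumerate_cpgs(ref, amp.start, amp.end)
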