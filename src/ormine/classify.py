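"""Functional / sub-7TM / pseudogene classification of OR candidates.

An OR sequence is called a pseudogene if it carries a premature stop
codon, a frameshift-inducing indel, or is shorter than the 650 nt needed
to encode seven transmembrane (TM) helices. Disruption-free sequences are
then screened for the canonical 7-TM topology with a deterministic
Kyte-Doolittle hydropathy scanner (a stand-in for trained TM predictors;
pluggable via the ``tm_counter`` argument of :func:`classify_status`).
Sequences passing all disruption checks but lacking exactly seven
predicted helices are labelled ``sub7TM`` and excluded from the
functional set.

Stop and frameshift evidence is anchored on a reference coding sequence
(typically the best-matching family seed): the candidate is globally
aligned to the reference, interior indels with length not divisible by 3
count as frameshifts, and codons are read in the reference frame so that
post-frameshift stops are assessed in the biologically relevant frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "ORRecord",
    "FrameshiftEvidence",
    "PseudogeneEvidence",
    "TMTopology",
    "detect_pseudogene_features",
    "count_tm_domains",
    "classify_status",
    "trim_alignment",
    "STATUS_FUNCTIONAL",
    "STATUS_SUB7TM",
    "STATUS_PSEUDOGENE",
    "STATUS_REMOVED",
    "MIN_FUNCTIONAL_NT",
]

STATUS_FUNCTIONAL = "functional"
STATUS_SUB7TM = "sub7TM"
STATUS_PSEUDOGENE = "pseudogene"
STATUS_REMOVED = "removed_nonOR"

#: minimum nucleotide length able to encode the 7-TM fold; shorter
#: sequences are nonfunctional. The bound is inclusive: 650 nt passes.
MIN_FUNCTIONAL_NT = 650

STOP_CODONS = {"TAA", "TAG", "TGA"}  # standard genetic code (table 1)

# Kyte-Doolittle hydropathy scale
KD_SCALE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# harsh gap penalties: between diverged but co-linear coding sequences a
# gap must reflect a real indel, not a cheap escape from mismatch runs
_NT_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=2,
    mismatch_score=-3,
    open_gap_score=-16,
    extend_gap_score=-4,
)


@dataclass
class FrameshiftEvidence:
    """Interior coding-alignment indels; a frameshift is any indel with
    length not divisible by 3."""

    reference_id: str
    indel_positions: list[int]   # candidate coordinates of interior indels
    indel_lengths: list[int]

    @property
    def has_frameshift(self) -> bool:
        return any(l % 3 != 0 for l in self.indel_lengths)


@dataclass
class PseudogeneEvidence:
    has_premature_stop: bool
    frameshift: FrameshiftEvidence
    length_nt: int
    anchored: bool = True     # False when no reference aligned at >= 30% identity

    @property
    def has_frameshift(self) -> bool:
        return self.frameshift.has_frameshift


@dataclass
class TMTopology:
    """Ordered, non-overlapping predicted helix intervals (0-based half-open)."""

    helices: list[tuple[int, int]]

    @property
    def tm_count(self) -> int:
        return len(self.helices)


@dataclass
class ORRecord:
    """One classified OR candidate."""

    id: str
    nt: str
    status: str
    family_id: str | None = None
    protein: str | None = None
    evidence: PseudogeneEvidence | None = None
    tm_count: int | None = None


# ----------------------------------------------------------------------


def _longest_orf_frame(nt: str) -> int:
    """Frame (0/1/2) with the longest stop-free codon run."""
    best_frame, best_run = 0, -1
    for f in range(3):
        sub = nt[f:]
        sub = sub[: len(sub) // 3 * 3]
        run = cur = 0
        for i in range(0, len(sub), 3):
            if sub[i : i + 3] in STOP_CODONS:
                cur = 0
            else:
                cur += 1
                run = max(run, cur)
        if run > best_run:
            best_frame, best_run = f, run
    return best_frame


def detect_pseudogene_features(
    nt_sequence: str,
    reference_cds: str | None = None,
    reference_id: str = "",
    min_anchor_identity: float = 0.50,
) -> PseudogeneEvidence:
    """Detect premature stops and frameshifts in a candidate locus.

    ``reference_cds`` is the coding nucleotide sequence of the candidate's
    best-matching reference (e.g. a family seed). When no reference aligns
    at ``min_anchor_identity`` (identity per alignment column; unrelated
    sequences align near 0.40 under these penalties, homologs above 0.6)
    the evidence is unanchored: the stop check falls back to the
    longest-ORF frame and frameshifts are not assessed.
    """
    nt = nt_sequence.strip().upper()
    length_nt = len(nt)
    if length_nt == 0:
        raise ValueError("empty candidate sequence")

    if reference_cds:
        ref = reference_cds.strip().upper()
        # anchor on the reference's coding part only: a trailing stop
        # codon otherwise forces a 3-nt imbalance that the aligner can
        # split into spurious interior gaps near the end
        if len(ref) >= 6 and ref[-3:] in STOP_CODONS:
            ref = ref[:-3]
        aln = _NT_ALIGNER.align(ref, nt)[0]
        counts = aln.counts()
        identity = counts.identities / aln.length
        if identity >= min_anchor_identity:
            return _anchored_evidence(aln, ref, nt, reference_id)

    # unanchored fallback
    frame = _longest_orf_frame(nt)
    sub = nt[frame:]
    sub = sub[: len(sub) // 3 * 3]
    codons = [sub[i : i + 3] for i in range(0, len(sub), 3)]
    premature = any(c in STOP_CODONS for c in codons[:-1])
    return PseudogeneEvidence(
        premature,
        FrameshiftEvidence(reference_id or "unanchored", [], []),
        length_nt,
        anchored=False,
    )


_TERMINAL_SLACK = 12  # nt; indels this close to the aligned core's ends are
# terminal raggedness (boundary fuzz, stop handling), not coding frameshifts


def _anchored_evidence(aln, ref: str, nt: str, reference_id: str) -> PseudogeneEvidence:
    ref_blocks, cand_blocks = aln.aligned
    # interior indels between consecutive aligned blocks
    core_start = int(ref_blocks[0][0])
    core_end = int(ref_blocks[-1][1])
    positions, lengths = [], []
    for k in range(1, len(ref_blocks)):
        ref_gap = int(ref_blocks[k][0] - ref_blocks[k - 1][1])
        cand_gap = int(cand_blocks[k][0] - cand_blocks[k - 1][1])
        indel = abs(ref_gap - cand_gap)
        q = int(ref_blocks[k - 1][1])
        if indel > 0 and (q - core_start) >= _TERMINAL_SLACK and (
            core_end - q
        ) >= _TERMINAL_SLACK:
            positions.append(int(cand_blocks[k - 1][1]))
            lengths.append(indel)

    # read candidate bases in the reference frame
    slots: list[str | None] = [None] * len(ref)
    for (rs, re_), (cs, _ce) in zip(ref_blocks, cand_blocks):
        for off in range(int(re_) - int(rs)):
            slots[int(rs) + off] = nt[int(cs) + off]
    n_codons = len(ref) // 3
    premature = False
    for ci in range(n_codons - 1):  # exclude the reference's final codon
        triple = slots[3 * ci : 3 * ci + 3]
        if None in triple or len(triple) < 3:
            continue
        if "".join(triple) in STOP_CODONS:
            premature = True
            break
    return PseudogeneEvidence(
        premature,
        FrameshiftEvidence(reference_id, positions, lengths),
        len(nt),
        anchored=True,
    )


# ----------------------------------------------------------------------


def count_tm_domains(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    merge_gap: int = 5,
    min_helix: int = 15,
) -> TMTopology:
    """Predict TM helix intervals by sliding-window Kyte-Doolittle hydropathy.

    Residues whose centred ``window``-average hydropathy reaches
    ``threshold`` mark helix cores; runs separated by fewer than
    ``merge_gap`` residues are merged and runs shorter than ``min_helix``
    are discarded. Deterministic by construction.
    """
    protein = protein.upper().strip("*")
    if len(protein) < 100:
        raise ValueError("protein shorter than 100 residues")
    nonstd = sum(1 for ch in protein if ch not in KD_SCALE)
    if nonstd / len(protein) > 0.10:
        raise ValueError("more than 10% non-standard residues")
    vals = np.array([KD_SCALE.get(ch, 0.0) for ch in protein])
    kernel = np.ones(window) / window
    means = np.convolve(vals, kernel, mode="valid")   # centre offset window//2
    marked = means >= threshold
    half = window // 2

    runs: list[tuple[int, int]] = []
    start = None
    for i, m in enumerate(marked):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(marked)))

    merged: list[tuple[int, int]] = []
    for r in runs:
        if merged and r[0] - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(r)

    helices = [
        (s + half, e + half)  # centre coordinates -> residue coordinates
        for s, e in merged
        if (e - s) >= min_helix
    ]
    return TMTopology(helices)


# ----------------------------------------------------------------------


def classify_status(
    candidate_id: str,
    nt_sequence: str,
    evidence: PseudogeneEvidence,
    family_id: str | None = None,
    tm_counter: Callable[[str], TMTopology] = count_tm_domains,
    min_length_nt: int = MIN_FUNCTIONAL_NT,
) -> ORRecord:
    """Apply the classification rules to one candidate.

    pseudogene  iff premature stop, frameshift, or length < ``min_length_nt``
    sub7TM      iff disruption-free but predicted TM count != 7
    functional  iff disruption-free and exactly 7 predicted TM helices
    """
    nt = nt_sequence.strip().upper()
    if (
        evidence.has_premature_stop
        or evidence.has_frameshift
        or evidence.length_nt < min_length_nt
    ):
        return ORRecord(
            candidate_id, nt, STATUS_PSEUDOGENE, family_id, None, evidence, None
        )
    prot = str(Seq(nt[: len(nt) // 3 * 3]).translate()).rstrip("*")
    topo = tm_counter(prot)
    status = STATUS_FUNCTIONAL if topo.tm_count == 7 else STATUS_SUB7TM
    return ORRecord(candidate_id, nt, status, family_id, prot, evidence, topo.tm_count)


# ----------------------------------------------------------------------


def trim_alignment(
    alignment,
    max_missing_fraction: float = 0.8,
    missing_chars: str = "-.?NnXx",
):
    """Drop alignment columns whose missing-data fraction exceeds the cap.

    Gap characters (``-``, ``.``) and unknowns count as missing; the
    default set targets nucleotide alignments (``N`` unknown) — pass
    ``missing_chars="-.?Xx"`` for protein alignments, where ``N`` is
    asparagine. A column is kept iff its missing fraction is <= the cap
    (the 0.8 boundary itself is kept); row order and count are preserved.
    Accepts and returns a list of equal-length strings (or any object
    with per-row string access via ``str``). Idempotent.
    """
    rows = [str(r) for r in alignment]
    if not rows:
        raise ValueError("empty alignment")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment is not rectangular")
    if ncol == 0:
        raise ValueError("alignment has zero columns")
    missing = set(missing_chars)
    nrow = len(rows)
    keep = [
        c
        for c in range(ncol)
        if sum(1 for r in rows if r[c] in missing) / nrow <= max_missing_fraction
    ]
    return ["".join(r[c] for c in keep) for r in rows]
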