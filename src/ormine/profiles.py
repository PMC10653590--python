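"""Profile construction, genome scanning and redundancy clustering.

The OR mining front end. Per-family position-specific scoring profiles are
built from aligned amino-acid translations of seed coding sequences
(OR genes are short and intronless, so a translated six-frame search is
equivalent to a nucleotide search and makes downstream frameshift evidence
easier to anchor). Genomes are scanned in fixed-width profile blocks so
that loci disrupted by frameshifts or truncations — whose match is split
across reading frames or cut short — are still located; block matches are
then merged into candidate loci. Finally, allelic/assembly redundancy is
collapsed with a greedy longest-first identity clustering at a 98%
nucleotide-identity threshold.
"""
from __future__ import annotations

import json
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from scipy.stats import norm

from .families import FAMILIES

__all__ = [
    "SeedFamilySet",
    "FamilyProfile",
    "GenomeHit",
    "ClusteringResult",
    "build_family_profiles",
    "scan_genome",
    "dedup_cluster",
    "save_profiles",
    "load_profiles",
    "read_fasta",
    "hits_to_bed",
    "global_nt_identity",
]

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
X_IDX = 20      # unknown / ambiguous residue: neutral score
STOP_IDX = 21   # in-frame stop in a translated genome frame
STOP_SCORE = -6.0  # bits; a stop is strong (not absolute) evidence against a match
N_ALPHA = 22
BACKGROUND = 1.0 / 20.0
BLOCK_WIDTH = 50   # profile columns per scanning block
MIN_BLOCK = 20     # a trailing block shorter than this is merged into the previous one
DEFAULT_MERGE_GAP = 60  # nt; block matches closer than this on one strand form one locus

_COMPLEMENT = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn",
                            "TGCAYRMKVHDBNtgcayrmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_protein(protein: str) -> np.ndarray:
    """Map a protein string to integer indices (unknown -> X, '*' -> stop)."""
    out = np.empty(len(protein), dtype=np.int64)
    for i, ch in enumerate(protein.upper()):
        if ch == "*":
            out[i] = STOP_IDX
        else:
            out[i] = AA_INDEX.get(ch, X_IDX)
    return out


# ----------------------------------------------------------------------
# domain types


@dataclass
class SeedFamilySet:
    """Seed coding sequences for one OR family.

    ``sequences`` holds ``(label, coding_nt)`` pairs; labels typically
    combine species and gene identifiers. Sequences must translate without
    internal stops (a single trailing stop codon is allowed and removed).
    """

    family_id: str
    sequences: list[tuple[str, str]]


@dataclass
class GenomeHit:
    """A candidate OR locus on a contig (0-based half-open, stranded)."""

    contig: str
    start: int
    end: int
    strand: str
    family: str
    score: float        # summed block bit score of the best family
    evalue: float       # smallest block E-value supporting the locus
    sequence: str       # strand-corrected nucleotide sequence

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}:{self.strand}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ClusteringResult:
    """Greedy identity clustering of candidate loci."""

    representatives: list[GenomeHit]
    member_map: dict[str, str]      # hit key -> representative key
    identity_threshold: float


# ----------------------------------------------------------------------
# profiles


class FamilyProfile:
    """Ungapped position-specific scoring profile for one OR family.

    Emissions are per-column log-odds scores in bits against a uniform
    amino-acid background. Insertion/deletion tolerance is provided not by
    per-column transition states but by the block chaining model: the
    profile is scored in ``BLOCK_WIDTH``-column blocks and each block may
    shift by up to ``max_shift`` residues relative to the chain
    (``shift_penalty`` bits per block that uses a shifted offset).
    """

    def __init__(
        self,
        family_id: str,
        emissions: np.ndarray,
        consensus: str,
        n_seeds: int,
        alignment_id: str = "",
        max_shift: int = 8,
        shift_penalty: float = 0.0,
    ):
        emissions = np.asarray(emissions, dtype=float)
        if emissions.ndim != 2 or emissions.shape[1] != N_ALPHA:
            raise ValueError("emissions must have shape (model_length, 22)")
        self.family_id = str(family_id)
        self.emissions = emissions
        self.consensus = consensus
        self.n_seeds = int(n_seeds)
        self.alignment_id = alignment_id
        self.max_shift = int(max_shift)
        self.shift_penalty = float(shift_penalty)

    @property
    def model_length(self) -> int:
        return self.emissions.shape[0]

    # -- block decomposition ------------------------------------------
    def block_bounds(self) -> list[tuple[int, int]]:
        L = self.model_length
        starts = list(range(0, L, BLOCK_WIDTH))
        bounds = [(s, min(s + BLOCK_WIDTH, L)) for s in starts]
        if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < MIN_BLOCK:
            last = bounds.pop()
            prev = bounds.pop()
            bounds.append((prev[0], last[1]))
        return bounds

    def block_background_stats(self) -> list[tuple[float, float]]:
        """(mean, sd) of each block score under the uniform background."""
        stats = []
        E = self.emissions[:, :20]
        col_mean = E.mean(axis=1)
        col_var = (E ** 2).mean(axis=1) - col_mean ** 2
        for s, e in self.block_bounds():
            mu = float(col_mean[s:e].sum())
            sd = float(math.sqrt(max(col_var[s:e].sum(), 1e-12)))
            stats.append((mu, sd))
        return stats

    # -- scoring -------------------------------------------------------
    def _diag_scores(self, block: tuple[int, int], idx: np.ndarray) -> np.ndarray:
        """Ungapped score of block vs. every start offset in the protein."""
        s, e = block
        w = e - s
        n = len(idx) - w + 1
        if n <= 0:
            return np.empty(0)
        E = self.emissions
        out = np.zeros(n)
        for c in range(w):
            out += E[s + c, idx[c : c + n]]
        return out

    def score_protein(self, protein: str) -> float:
        """Chained block score (bits) of a protein against the profile.

        Blocks are anchored to a common model-to-protein offset; each block
        may jitter by up to ``max_shift`` residues (small-indel tolerance)
        and contributes ``max(score, 0)`` so missing or diverged blocks do
        not cancel genuine matches elsewhere.
        """
        idx = encode_protein(protein)
        if len(idx) == 0:
            return 0.0
        bounds = self.block_bounds()
        L = len(idx)
        g_lo, g_hi = -self.model_length, L  # candidate gene-start offsets
        width = g_hi - g_lo + 1
        total = np.zeros(width)
        for (s, e) in bounds:
            diag = self._diag_scores((s, e), idx)
            if diag.size == 0:
                continue
            # T[g] = block score when the model starts at protein offset g
            T = np.full(width, -np.inf)
            starts = np.arange(diag.size) - s - g_lo  # index into T
            valid = (starts >= 0) & (starts < width)
            T[starts[valid]] = diag[valid]
            # allow +-max_shift jitter
            best = np.full(width, -np.inf)
            for sh in range(-self.max_shift, self.max_shift + 1):
                shifted = np.full(width, -np.inf)
                if sh >= 0:
                    shifted[: width - sh] = T[sh:]
                else:
                    shifted[-sh:] = T[:width + sh]
                np.maximum(best, shifted, out=best)
            contrib = np.where(np.isfinite(best), best, 0.0)
            total += np.maximum(contrib - (self.shift_penalty if self.shift_penalty else 0.0), 0.0)
        return float(total.max())

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "emissions": self.emissions.tolist(),
            "consensus": self.consensus,
            "n_seeds": self.n_seeds,
            "alignment_id": self.alignment_id,
            "max_shift": self.max_shift,
            "shift_penalty": self.shift_penalty,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FamilyProfile":
        return cls(
            d["family_id"],
            np.array(d["emissions"], dtype=float),
            d["consensus"],
            d["n_seeds"],
            d.get("alignment_id", ""),
            d.get("max_shift", 8),
            d.get("shift_penalty", 0.0),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FamilyProfile(family={self.family_id!r}, "
            f"model_length={self.model_length}, n_seeds={self.n_seeds})"
        )


def save_profiles(profiles: Sequence[FamilyProfile], path: str | Path) -> None:
    """Serialize profiles to a JSON archive (bit-identical on reload)."""
    payload = {
        "format": "ormine-profiles-1",
        "profiles": [p.to_dict() for p in profiles],
    }
    Path(path).write_text(json.dumps(payload))


def load_profiles(path: str | Path) -> list[FamilyProfile]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "ormine-profiles-1":
        raise ValueError(f"{path}: not an ormine profile archive")
    return [FamilyProfile.from_dict(d) for d in payload["profiles"]]


# ----------------------------------------------------------------------
# profile building


def translate_seed(label: str, nt: str) -> str:
    """Translate a seed CDS; strip one trailing stop; reject internal stops."""
    nt = nt.strip().upper()
    if len(nt) >= 3:
        prot_full = str(Seq(nt[: len(nt) // 3 * 3]).translate())
        if prot_full.endswith("*"):
            nt = nt[: (len(prot_full) - 1) * 3]
    if not nt or len(nt) % 3 != 0:
        raise ValueError(f"seed {label!r}: length not divisible by 3 after stop removal")
    prot = str(Seq(nt).translate())
    if "*" in prot:
        raise ValueError(f"seed {label!r}: internal stop codon in seed sequence")
    return prot


def _align_proteins(labeled: list[tuple[str, str]], aligner: str) -> list[str]:
    """Multiple-align translated seeds.

    Equal-length translations (the common case for curated family seeds
    and all synthetic seeds) are stacked directly. Otherwise the external
    ``mafft`` aligner is invoked; an explicit ``aligner="mafft"`` forces it.
    """
    seqs = [s for _, s in labeled]
    if aligner not in ("auto", "mafft", "stack"):
        raise ValueError(f"unknown aligner {aligner!r}")
    same_len = len({len(s) for s in seqs}) == 1
    if aligner == "stack" or (aligner == "auto" and same_len):
        return list(seqs)
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH and seed lengths differ")
    with tempfile.TemporaryDirectory() as td:
        fin = Path(td) / "in.fa"
        fin.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs)))
        res = subprocess.run(
            ["mafft", "--auto", "--quiet", str(fin)],
            capture_output=True, text=True, check=True,
        )
        rows = {r.id: str(r.seq).upper() for r in SeqIO.parse(io_from(res.stdout), "fasta")}
        return [rows[f"s{i}"] for i in range(len(seqs))]


def io_from(text: str):
    import io

    return io.StringIO(text)


def build_family_profiles(
    seeds: Sequence[SeedFamilySet],
    aligner: str = "auto",
    require_complete: bool = False,
) -> list[FamilyProfile]:
    """Build one scoring profile per family from seed coding sequences.

    Columns with more than 50% gaps in the seed alignment are dropped
    (match-state selection); emissions are log-odds in bits with a 0.5
    pseudocount against a uniform background.
    """
    fam_ids = [f.family_id for f in seeds]
    if len(set(fam_ids)) != len(fam_ids):
        raise ValueError("duplicate family ids in seed sets")
    if require_complete and set(fam_ids) != set(FAMILIES):
        missing = sorted(set(FAMILIES) - set(fam_ids))
        raise ValueError(f"incomplete seed set; missing families: {missing}")
    profiles = []
    for fam in seeds:
        if not fam.sequences:
            raise ValueError(f"family {fam.family_id!r}: no seed sequences")
        labeled = [(lab, translate_seed(lab, nt)) for lab, nt in fam.sequences]
        aligned = _align_proteins(labeled, aligner)
        ncol = len(aligned[0])
        nseq = len(aligned)
        keep_cols = []
        for c in range(ncol):
            gaps = sum(1 for row in aligned if row[c] in "-.")
            if gaps / nseq <= 0.5:
                keep_cols.append(c)
        L = len(keep_cols)
        emissions = np.zeros((L, N_ALPHA))
        consensus = []
        for out_c, c in enumerate(keep_cols):
            counts = np.zeros(20)
            for row in aligned:
                ch = row[c]
                if ch in AA_INDEX:
                    counts[AA_INDEX[ch]] += 1
            total = counts.sum()
            freqs = (counts + 0.5 / 20.0) / (total + 0.5)
            emissions[out_c, :20] = np.log2(freqs / BACKGROUND)
            emissions[out_c, X_IDX] = 0.0
            emissions[out_c, STOP_IDX] = STOP_SCORE
            consensus.append(AA[int(np.argmax(counts))] if total else "X")
        profiles.append(
            FamilyProfile(
                fam.family_id,
                emissions,
                "".join(consensus),
                n_seeds=nseq,
                alignment_id=f"{fam.family_id}:{nseq}seeds",
            )
        )
    return profiles


# ----------------------------------------------------------------------
# genome scanning


def read_fasta(source) -> dict[str, str]:
    """Read a FASTA file/handle/dict into ``{contig: sequence}``.

    A dict passes through unchanged. Malformed input (content before the
    first header) raises ``ValueError`` naming the offending line.
    """
    if isinstance(source, Mapping):
        return {str(k): str(v) for k, v in source.items()}
    path = Path(source)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ValueError(f"{path}: line {lineno}: expected FASTA header '>'")
        break
    out: dict[str, str] = {}
    for rec in SeqIO.parse(io_from(text), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def _frame_translations(seq: str) -> list[tuple[str, int, str]]:
    """Six-frame translations: (strand, frame, protein)."""
    out = []
    rc = reverse_complement(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[: len(sub) // 3 * 3]
            if not sub:
                out.append((strand, frame, ""))
                continue
            out.append((strand, frame, str(Seq(sub).translate())))
    return out


def scan_genome(
    profiles: Sequence[FamilyProfile],
    genome,
    evalue: float = 1e-10,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[GenomeHit]:
    """Scan a genome with all family profiles and merge matches into loci.

    Each profile block is slid along every translated frame; block matches
    with E-value <= ``evalue`` are pooled per (contig, strand) and merged
    whenever they overlap or lie within ``merge_gap`` nt, keeping the
    family with the highest summed bit score. Hit sequences are
    strand-corrected. Output ordering is deterministic.
    """
    contigs = read_fasta(genome)
    if not contigs:
        return []
    n_blocks_total = sum(len(p.block_bounds()) for p in profiles)
    genome_len = sum(len(s) for s in contigs.values())
    n_trials = max(1.0, 2.0 * (genome_len / 3.0) * n_blocks_total)
    # equivalent z-score cutoff; avoids evaluating the normal tail everywhere
    z_crit = float(norm.isf(min(evalue / n_trials, 0.5)))

    # per (contig, strand): (start, end, family, bits, evalue, block_col)
    raw: dict[tuple[str, str], list[tuple]] = {}
    for contig_id, seq in contigs.items():
        L = len(seq)
        frames = _frame_translations(seq)
        encoded = {
            (strand, frame): encode_protein(prot) for strand, frame, prot in frames
        }
        for prof in profiles:
            bounds = prof.block_bounds()
            stats = prof.block_background_stats()
            for (strand, frame), idx in encoded.items():
                if idx.size == 0:
                    continue
                for (s, e), (mu, sd) in zip(bounds, stats):
                    diag = prof._diag_scores((s, e), idx)
                    if diag.size == 0:
                        continue
                    z = (diag - mu) / sd
                    cand = np.nonzero(z >= z_crit)[0]
                    if cand.size == 0:
                        continue
                    # non-maximum suppression: the profile's hydrophobic
                    # TM columns self-match at small shifts, so keep only
                    # locally best offsets per block
                    radius = max((e - s) // 2, 1)
                    order = cand[np.argsort(-diag[cand], kind="stable")]
                    kept: list[int] = []
                    for o in order:
                        if all(abs(int(o) - k) > radius for k in kept):
                            kept.append(int(o))
                    kept.sort()
                    hit_offsets = np.array(kept)
                    ev = norm.sf(z[hit_offsets]) * n_trials
                    for o, e_val in zip(hit_offsets, ev):
                        w = e - s
                        aa_start = int(o)
                        nt_lo = frame + 3 * aa_start
                        nt_hi = nt_lo + 3 * w
                        if strand == "+":
                            g_lo, g_hi = nt_lo, nt_hi
                        else:
                            g_lo, g_hi = L - nt_hi, L - nt_lo
                        raw.setdefault((contig_id, strand), []).append(
                            (g_lo, g_hi, prof.family_id, float(diag[o]),
                             float(e_val), s)
                        )

    hits: list[GenomeHit] = []
    for (contig_id, strand), blocks in raw.items():
        blocks.sort(key=lambda b: (b[0], b[1]))
        seq = contigs[contig_id]
        cur: list[tuple[int, int, str, float, float]] = []
        cur_end = -1

        def flush(group):
            if not group:
                return
            # each profile block has one genuine location in a locus; keep
            # only its best-scoring match so self-similar shifted matches
            # (hydrophobic TM columns) cannot inflate the envelope
            per_block: dict[tuple[str, int], tuple] = {}
            for b in group:
                key = (b[2], b[5])
                if key not in per_block or b[3] > per_block[key][3]:
                    per_block[key] = b
            reduced = list(per_block.values())
            # the locus envelope comes from the best-scoring family only
            fam_scores: dict[str, float] = {}
            for b in reduced:
                fam_scores[b[2]] = fam_scores.get(b[2], 0.0) + b[3]
            best_fam = sorted(fam_scores.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            best_blocks = [b for b in reduced if b[2] == best_fam[0]]
            lo = min(b[0] for b in best_blocks)
            hi = max(b[1] for b in best_blocks)
            best_ev = min(b[4] for b in best_blocks)
            sub = seq[lo:hi]
            if strand == "-":
                sub = reverse_complement(sub)
            hits.append(
                GenomeHit(
                    contig_id, lo, hi, strand, best_fam[0],
                    round(best_fam[1], 6), best_ev, sub,
                )
            )

        for b in blocks:
            if cur and b[0] > cur_end + merge_gap:
                flush(cur)
                cur = []
                cur_end = -1
            cur.append(b)
            cur_end = max(cur_end, b[1])
        flush(cur)

    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def hits_to_bed(hits: Iterable[GenomeHit]) -> str:
    """BED6 representation (name = family, score = integer bit score)."""
    lines = [
        f"{h.contig}\t{h.start}\t{h.end}\t{h.family}\t{int(round(h.score))}\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# ----------------------------------------------------------------------
# redundancy clustering

_NT_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=2,
    mismatch_score=-3,
    open_gap_score=-5,
    extend_gap_score=-2,
)


def global_nt_identity(a: str, b: str) -> float:
    """Identity fraction (matches / alignment length) of a global alignment."""
    if not a or not b:
        return 0.0
    aln = _NT_ALIGNER.align(a.upper(), b.upper())[0]
    counts = aln.counts()
    return counts.identities / aln.length


def dedup_cluster(
    hits: Sequence[GenomeHit], threshold: float = 0.98
) -> ClusteringResult:
    """Greedy longest-first identity clustering of candidate loci.

    A hit joins the first (earliest-founded) representative whose global
    nucleotide identity is at least ``threshold``, otherwise it founds a
    new cluster. Ordering is longest-first with ties broken by
    (contig, start, strand), so the result is deterministic.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(hits, key=lambda h: (-len(h), h.contig, h.start, h.strand))
    reps: list[GenomeHit] = []
    member_map: dict[str, str] = {}
    for h in ordered:
        placed = False
        for rep in reps:
            if global_nt_identity(h.sequence, rep.sequence) >= threshold:
                member_map[h.key] = rep.key
                placed = True
                break
        if not placed:
            reps.append(h)
            member_map[h.key] = h.key
    return ClusteringResult(reps, member_map, threshold)
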