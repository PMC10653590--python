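"""Ground-truthed synthetic inputs for every pipeline stage.

The generator states a small, fully known world:

* a GPCR "ancestor" protein with seven strongly hydrophobic transmembrane
  (TM) blocks, from which 13 OR family templates and 11 non-OR GPCR
  decoys are derived by controlled substitution — so profile search,
  family assignment, the phylogenetic non-OR filter and the hydropathy
  TM counter all have planted truth;
* pseudogenization operators (premature stop, frameshift indel,
  truncation, reverse complementation) applied to planted genes;
* genomes made of iid background nucleotides (no repeats or isochores —
  a stated limitation, sufficient to test specificity) with plants at
  recorded coordinates;
* continuous traits simulated on trees by exact multivariate-normal
  sampling under BM (with Pagel's lambda) or stationary OU covariances.

Everything is deterministic given its seed.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .classify import (
    STATUS_FUNCTIONAL,
    STATUS_PSEUDOGENE,
    STATUS_REMOVED,
    STOP_CODONS,
)
from .families import FAMILIES
from .filtering import ReferencePanel
from .profiles import SeedFamilySet, reverse_complement
from .trees import PhyloTree

__all__ = [
    "PlantSpec",
    "make_genome",
    "apply_operator",
    "mutate_cds",
    "family_template_protein",
    "family_template_cds",
    "decoy_proteins",
    "make_seed_families",
    "make_reference_panel",
    "make_ecology",
    "simulate_traits",
    "planted_helix_protein",
    "standard_plant_set",
]

# -- template architecture --------------------------------------------
# 310 aa = N-loop 16 + 7 x (TM 25) + 6 internal loops of 17 + C-loop 17
TM_LEN = 25
N_LOOP, INNER_LOOP, C_LOOP = 16, 17, 17
N_TM = 7
TM_RESIDUES = "IV"            # strongly hydrophobic (Kyte-Doolittle > 4)
TM_SAFE = "IVLFM"             # allowed substitutions inside TM blocks
LOOP_RESIDUES = "DEKNQRST"    # strongly polar loops
TEMPLATE_SEED = 20230         # fixes the ancestral templates of this world

_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)
for aa in _BACK_TABLE:
    _BACK_TABLE[aa].sort()


def _tm_layout() -> list[tuple[int, int]]:
    """0-based half-open TM block intervals of the template protein."""
    blocks = []
    pos = N_LOOP
    for _ in range(N_TM):
        blocks.append((pos, pos + TM_LEN))
        pos += TM_LEN + INNER_LOOP
    return blocks


def _in_tm(i: int, blocks: list[tuple[int, int]]) -> bool:
    return any(s <= i < e for s, e in blocks)


def _ancestor_protein(rng: np.random.Generator) -> str:
    blocks = _tm_layout()
    length = N_LOOP + N_TM * TM_LEN + (N_TM - 1) * INNER_LOOP + C_LOOP
    out = []
    for i in range(length):
        pool = TM_RESIDUES if _in_tm(i, blocks) else LOOP_RESIDUES
        out.append(pool[rng.integers(len(pool))])
    return "".join(out)


def _mutate_protein(
    protein: str, divergence: float, rng: np.random.Generator
) -> str:
    """Substitute a fraction of residues, TM-safely inside TM blocks."""
    blocks = _tm_layout()
    seq = list(protein)
    k = int(round(divergence * len(seq)))
    if k == 0:
        return protein
    for i in rng.choice(len(seq), size=k, replace=False):
        pool = TM_SAFE if _in_tm(int(i), blocks) else LOOP_RESIDUES
        options = [a for a in pool if a != seq[i]]
        seq[i] = options[rng.integers(len(options))]
    return "".join(seq)


@functools.lru_cache(maxsize=8)
def _templates(template_seed: int = TEMPLATE_SEED) -> dict:
    """The fixed proteins of this synthetic world."""
    rng = np.random.default_rng(template_seed)
    ancestor = _ancestor_protein(rng)
    # OR families and non-OR GPCRs form two sister clades: each side has
    # its own ancestor so the non-OR references are a genuine outgroup
    # clade, not a basal star
    or_ancestor = _mutate_protein(ancestor, 0.10, rng)
    nonor_ancestor = _mutate_protein(ancestor, 0.10, rng)
    fams = {f: _mutate_protein(or_ancestor, 0.10, rng) for f in FAMILIES}
    decoy_names = [
        "MC1R_like", "TAAR2_like", "HTR1A_like", "ADRB2_like", "DRD2_like",
        "CHRM1_like", "HRH1_like", "OPN1_like", "AVPR1_like", "OXTR_like",
        "CNR1_like",
    ]
    decoys = {n: _mutate_protein(nonor_ancestor, 0.10, rng) for n in decoy_names}
    return {"ancestor": ancestor, "families": fams, "decoys": decoys}


def family_template_protein(family: str) -> str:
    fams = _templates()["families"]
    if family not in fams:
        raise KeyError(f"unknown OR family {family!r}")
    return fams[family]


def decoy_proteins() -> dict[str, str]:
    return dict(_templates()["decoys"])


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    out = []
    for aa in protein:
        codons = _BACK_TABLE[aa]
        out.append(codons[rng.integers(len(codons))])
    out.append("TAA")
    return "".join(out)


@functools.lru_cache(maxsize=64)
def family_template_cds(family: str) -> str:
    """The canonical coding sequence (933 nt incl. stop) of one family."""
    rng = np.random.default_rng([TEMPLATE_SEED, FAMILIES.index(family)])
    return _back_translate(family_template_protein(family), rng)


@functools.lru_cache(maxsize=64)
def _decoy_cds(name: str) -> str:
    decoys = _templates()["decoys"]
    rng = np.random.default_rng([TEMPLATE_SEED, 1000 + sorted(decoys).index(name)])
    return _back_translate(decoys[name], rng)


# ----------------------------------------------------------------------
# nucleotide-level mutation and pseudogenization operators


_HYDROPHOBIC_OK = set("AMCFLVI")  # Kyte-Doolittle >= 1.8


def mutate_cds(
    nt: str,
    divergence: float,
    rng: np.random.Generator,
    avoid_stops: bool = True,
    preserve_tm: bool = False,
) -> str:
    """Point-substitute a fraction of positions of a coding sequence.

    With ``avoid_stops`` substitutions never create an in-frame stop and
    never touch the terminal stop codon, so a 'no operator' plant keeps
    its intended functional status at any divergence. With
    ``preserve_tm`` substitutions inside the template's TM blocks must
    keep the encoded residue hydrophobic — the nucleotide-level analogue
    of the hydrophobicity-conserving selection acting on real TM domains,
    and the property that keeps intact plants 7-TM at any divergence.
    """
    seq = list(nt.upper())
    mutable = len(seq) - (3 if avoid_stops and len(seq) >= 3 else 0)
    k = int(round(divergence * mutable))
    if k == 0:
        return nt
    tm_blocks = _tm_layout() if preserve_tm else []
    bases = "ACGT"
    positions = rng.choice(mutable, size=k, replace=False)
    for pos in positions:
        pos = int(pos)
        codon_start = pos - pos % 3
        in_tm = _in_tm(codon_start // 3, tm_blocks) if tm_blocks else False
        options = [b for b in bases if b != seq[pos]]
        order = rng.permutation(len(options))
        old = seq[pos]
        for oi in order:
            seq[pos] = options[int(oi)]
            codon = "".join(seq[codon_start : codon_start + 3])
            if avoid_stops and codon in STOP_CODONS:
                seq[pos] = old
                continue
            if in_tm:
                aa = standard_dna_table.forward_table.get(codon)
                if aa is None or aa not in _HYDROPHOBIC_OK:
                    seq[pos] = old
                    continue
            break
    return "".join(seq)


def apply_operator(
    seq: str, operator: str, seed: int, arg: int | None = None
) -> str:
    """Apply one pseudogenization operator to a coding sequence.

    ``premature_stop`` rewrites a middle-third codon to TGA;
    ``frameshift_indel`` deletes or inserts ``arg`` bases (default 1;
    length must not be divisible by 3 for a true frameshift) at a
    middle-third position; ``truncate`` cuts to ``arg`` nt;
    ``reverse_complement`` returns the reverse complement; ``none``
    returns the input. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    seq = seq.upper()
    n = len(seq)
    if operator == "none":
        return seq
    if operator == "premature_stop":
        n_codons = n // 3
        ci = int(rng.integers(n_codons // 3, 2 * n_codons // 3))
        return seq[: 3 * ci] + "TGA" + seq[3 * ci + 3 :]
    if operator == "frameshift_indel":
        length = 1 if arg is None else int(arg)
        pos = int(rng.integers(n // 3, 2 * n // 3))
        if rng.integers(2) == 0:
            return seq[:pos] + seq[pos + length :]
        ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=length))
        return seq[:pos] + ins + seq[pos:]
    if operator == "truncate":
        if arg is None:
            raise ValueError("truncate needs a target length")
        if arg >= n:
            raise ValueError(f"truncate length {arg} >= sequence length {n}")
        return seq[: int(arg)]
    if operator == "reverse_complement":
        return reverse_complement(seq)
    raise ValueError(f"unknown operator {operator!r}")


# ----------------------------------------------------------------------
# genome assembly with planted genes


@dataclass
class PlantSpec:
    """One planted gene: template family (or a non-OR decoy), nucleotide
    divergence from the template, one pseudogenization operator, an
    optional fixed interval start, and a per-plant rng seed."""

    family: str                   # OR family id, or "nonor:<decoy name>"
    divergence: float = 0.0
    operator: str = "none"
    operator_arg: int | None = None
    start: int | None = None
    seed: int = 0


_INTENDED = {
    "none": STATUS_FUNCTIONAL,
    "reverse_complement": STATUS_FUNCTIONAL,
    "premature_stop": STATUS_PSEUDOGENE,
    "frameshift_indel": STATUS_PSEUDOGENE,
    "truncate": STATUS_PSEUDOGENE,
}


def make_genome(
    plants: Sequence[PlantSpec],
    background_length: int = 200_000,
    gc: float = 0.42,
    seed: int = 1,
    contig_id: str = "chr1",
    min_gap: int = 400,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Assemble a synthetic contig with planted genes and a truth table.

    Background is iid nucleotides at the given GC content. Plants replace
    background at either their fixed ``start`` or a random position at
    least ``min_gap`` nt from every other plant. The truth table records
    0-based half-open coordinates, strand, family, operator, and the
    intended classification of every plant.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = rng.choice(list("ACGT"), size=background_length, p=p)

    built = []
    for i, plant in enumerate(plants):
        prng = np.random.default_rng([seed, i, plant.seed])
        if plant.family.startswith("nonor:"):
            prot = _templates()["decoys"][plant.family.split(":", 1)[1]]
            intended = STATUS_REMOVED
        else:
            prot = family_template_protein(plant.family)
            intended = _INTENDED[plant.operator]
        # each plant is an independent paralog: same protein, its own
        # synonymous codon draw, so distinct plants of one family are not
        # collapsed as alleles by the 98% redundancy merge
        cds = _back_translate(prot, prng)
        seq = mutate_cds(
            cds, plant.divergence, prng,
            preserve_tm=not plant.family.startswith("nonor:"),
        )
        seq = apply_operator(seq, plant.operator, seed=int(prng.integers(2**31)),
                             arg=plant.operator_arg)
        strand = "-" if plant.operator == "reverse_complement" else "+"
        built.append((plant, seq, strand, intended))

    # placement
    intervals: list[tuple[int, int, int]] = []  # (start, end, plant index)
    fixed = [(i, b) for i, b in enumerate(built) if b[0].start is not None]
    free = [(i, b) for i, b in enumerate(built) if b[0].start is None]
    for i, (plant, seq, _, _) in fixed:
        s, e = plant.start, plant.start + len(seq)
        if s < 0 or e > background_length:
            raise ValueError(f"plant {i}: interval [{s},{e}) outside genome")
        for s2, e2, j in intervals:
            if s < e2 and s2 < e:
                raise ValueError(f"plants {j} and {i} overlap at [{s},{e})")
        intervals.append((s, e, i))
    for i, (plant, seq, _, _) in free:
        ok = False
        for _ in range(1000):
            s = int(rng.integers(0, background_length - len(seq)))
            e = s + len(seq)
            if all(e + min_gap <= s2 or s - min_gap >= e2 for s2, e2, _ in intervals):
                intervals.append((s, e, i))
                ok = True
                break
        if not ok:
            raise ValueError(f"could not place plant {i}; genome too crowded")

    rows = []
    for s, e, i in sorted(intervals):
        plant, seq, strand, intended = built[i]
        genome[s:e] = list(seq)
        rows.append(
            {
                "plant_id": f"plant{i}",
                "contig": contig_id,
                "start": s,
                "end": e,
                "strand": strand,
                "family": plant.family,
                "operator": plant.operator,
                "divergence": plant.divergence,
                "intended_status": intended,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "plant_id", "contig", "start", "end", "strand",
            "family", "operator", "divergence", "intended_status",
        ],
    )
    return {contig_id: "".join(genome)}, truth


def standard_plant_set(divergence: float, seed: int = 5) -> list[PlantSpec]:
    """The canonical 20-plant recovery suite: 10 intact (3 of them on the
    reverse strand), 4 stop-disrupted, 3 frameshifted, 2 truncated below
    650 nt, and 1 non-OR GPCR decoy."""
    rng = np.random.default_rng(seed)
    fams = list(FAMILIES)
    plants: list[PlantSpec] = []
    picks = [fams[int(i)] for i in rng.integers(0, len(fams), size=19)]
    for i in range(7):
        plants.append(PlantSpec(picks[i], divergence, "none", seed=i))
    for i in range(7, 10):
        plants.append(PlantSpec(picks[i], divergence, "reverse_complement", seed=i))
    for i in range(10, 14):
        plants.append(PlantSpec(picks[i], divergence, "premature_stop", seed=i))
    for i in range(14, 17):
        plants.append(PlantSpec(picks[i], divergence, "frameshift_indel", 1, seed=i))
    plants.append(PlantSpec(picks[17], divergence, "truncate", 600, seed=17))
    plants.append(PlantSpec(picks[18], divergence, "truncate", 480, seed=18))
    plants.append(PlantSpec("nonor:TAAR2_like", divergence, "none", seed=19))
    return plants


# ----------------------------------------------------------------------
# seed sets, reference panel, ecology


def make_seed_families(
    n_per_family: int = 3, divergence: float = 0.04, seed: int = 101
) -> list[SeedFamilySet]:
    """Seed coding sequences per family: template copies at a small
    nucleotide divergence, emulating orthologs from different species."""
    out = []
    for f_idx, fam in enumerate(FAMILIES):
        base = family_template_cds(fam)
        seqs = []
        for i in range(n_per_family):
            rng = np.random.default_rng([seed, f_idx, i])
            seqs.append((f"{fam}_seed{i}", mutate_cds(base, divergence, rng)))
        out.append(SeedFamilySet(fam, seqs))
    return out


def make_reference_panel(seed: int = 7, divergence: float = 0.03) -> ReferencePanel:
    """26 verified OR proteins (2 per family) + 11 non-OR GPCR proteins."""
    or_refs = {}
    for f_idx, fam in enumerate(FAMILIES):
        base = family_template_cds(fam)
        for j, tag in enumerate("ab"):
            rng = np.random.default_rng([seed, f_idx, j])
            nt = mutate_cds(base, divergence, rng)
            prot = str(Seq(nt[: len(nt) // 3 * 3]).translate()).rstrip("*")
            or_refs[f"OR{fam}_{tag}"] = prot
    nonor = decoy_proteins()
    return ReferencePanel(or_refs=or_refs, nonor_refs=nonor)


DIETS = ("herbivorous", "omnivorous", "animalivorous")
ACTIVITIES = ("diurnal", "nocturnal", "generalist")
LIFESTYLES = ("terrestrial", "desert", "fossorial", "semiaquatic")


def make_ecology(species: Sequence[str], seed: int = 3) -> pd.DataFrame:
    """Random but seeded ecological factor table (diet, activity, lifestyle)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "diet": [DIETS[int(i)] for i in rng.integers(0, len(DIETS), len(species))],
            "activity": [
                ACTIVITIES[int(i)] for i in rng.integers(0, len(ACTIVITIES), len(species))
            ],
            "lifestyle": [
                LIFESTYLES[int(i)] for i in rng.integers(0, len(LIFESTYLES), len(species))
            ],
        },
        index=pd.Index(species, name="species"),
    )


# ----------------------------------------------------------------------
# trait simulation on trees


def simulate_traits(
    tree: PhyloTree,
    model: str = "BM",
    sigma2: float = 1.0,
    lam: float = 1.0,
    alpha: float | None = None,
    optima: Mapping[str, float] | float = 0.0,
    regimes: Mapping[str, str] | None = None,
    root_state: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Exact multivariate-normal trait simulation on a tree.

    ``model="BM"`` draws from N(root_state, sigma2 * C_lambda) where
    ``lam`` scales the off-diagonal covariance (Pagel's lambda);
    ``model="OU"`` draws from the stationary OU law with tip covariance
    ``sigma2/(2 alpha) * exp(-alpha d_ij)`` and tip means given by the
    regime optima. Returns a tips x replicates DataFrame.
    """
    if len(tree.tips) < 2:
        raise ValueError("tree needs at least 2 tips")
    labels, C = tree.vcv()
    n = len(labels)
    if model == "BM":
        V = lam * C
        np.fill_diagonal(V, np.diag(C))
        V = sigma2 * V
        mean = np.full(n, float(root_state))
    elif model == "OU":
        if alpha is None or alpha <= 0:
            raise ValueError("OU simulation needs alpha > 0")
        _, D = tree.patristic_distances(labels)
        V = sigma2 / (2.0 * alpha) * np.exp(-alpha * D)
        if regimes is None:
            mean = np.full(n, float(optima if np.isscalar(optima) else 0.0))
        else:
            mean = np.array(
                [float(optima[regimes[l]]) for l in labels]  # type: ignore[index]
            )
    else:
        raise ValueError(f"unknown model {model!r}")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if sigma2 == 0:
        draws = np.tile(mean[:, None], (1, replicates))
    else:
        try:
            L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"non-PSD trait covariance: {exc}") from exc
        rng = np.random.default_rng(seed)
        draws = mean[:, None] + L @ rng.standard_normal((n, replicates))
    return pd.DataFrame(
        draws, index=pd.Index(labels, name="species"),
        columns=[f"rep{r}" for r in range(replicates)],
    )


# ----------------------------------------------------------------------
# planted-helix proteins for the TM counter


def planted_helix_protein(
    n_tm: int = 7,
    tm_len: int = 21,
    loop_len: int = 10,
    seed: int = 0,
    flank: int = 20,
) -> str:
    """A protein with ``n_tm`` hydrophobic blocks in a polar background.

    TM blocks use strongly hydrophobic residues (I/V) and loops mildly to
    strongly polar ones, so the hydropathy scanner's planted truth is
    unambiguous.
    """
    rng = np.random.default_rng(seed)
    loops_pool = "STND"

    def stretch(pool: str, k: int) -> str:
        return "".join(pool[int(i)] for i in rng.integers(0, len(pool), k))

    parts = [stretch(loops_pool, flank)]
    for b in range(n_tm):
        parts.append(stretch(TM_RESIDUES, tm_len))
        parts.append(stretch(loops_pool, loop_len if b < n_tm - 1 else flank))
    return "".join(parts)
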