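"""Seeded generator of ground-truthed synthetic inputs.

The generator emulates the conditions of an RdRp transcriptome screen:
several divergent virus "families" sharing a conserved motif-C core,
members embedded in contigs as whole ORFs or fragments on either strand
under genetic code tables 1/4/6, non-viral decoy transcripts (including
low-complexity and GC-extreme cases), taxonomy lineages spanning every
host category, and mononegavirus-like genomes whose L ORF is split by
AU-rich GU/AG introns and punctuated by transcription stop-start motifs.

Everything is substitution-only (no indels), so family members stay
trivially aligned and every downstream stage can be scored against the
recorded truth without re-deriving anything.  All randomness flows from
explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .orfs import get_code, revcomp
from .profilehmm import AA_ORDER, ROBINSON_BG
from .seqio import Contig, SeedAlignment

MOTIF_TRIPLETS = ("GDD", "SDD", "GDN", "IDD", "ADN", "ADD")

#: lineage fixtures per host category (semicolon-delimited NCBI-style lines)
LINEAGES = {
    "arthropods": (
        "cellular organisms; Eukaryota; Opisthokonta; Metazoa; Arthropoda; "
        "Insecta; Bemisia tabaci"
    ),
    "plants": (
        "cellular organisms; Eukaryota; Viridiplantae; Streptophyta; "
        "Poaceae; Saccharum hybrid"
    ),
    "fungi": (
        "cellular organisms; Eukaryota; Opisthokonta; Fungi; Ascomycota; "
        "Fusarium graminearum"
    ),
    "vertebrates": (
        "cellular organisms; Eukaryota; Opisthokonta; Metazoa; Chordata; "
        "Vertebrata; Ambystoma mexicanum"
    ),
    "invertebrates": (
        "cellular organisms; Eukaryota; Opisthokonta; Metazoa; Mollusca; "
        "Nucella lapillus"
    ),
    "protists": "cellular organisms; Eukaryota; Sar; Alveolata; Ciliophora; Tetrahymena",
    "metagenomic": "gut metagenome",
}


@dataclass
class FamilySim:
    name: str
    seed_alignment: SeedAlignment  # rows: the first half of the members
    members: list[tuple[str, str]]  # all members, (member_id, core aa)
    anchor_col: int  # 0-based column of the motif-C triplet start
    triplet: str
    seed_member_ids: frozenset[str]
    warning: Optional[str] = None

    @property
    def heldout_members(self) -> list[tuple[str, str]]:
        return [(mid, aa) for mid, aa in self.members if mid not in self.seed_member_ids]


@dataclass
class ContigTruth:
    contig_id: str
    kind: str  # 'viral' or 'decoy'
    family: Optional[str] = None
    member_id: Optional[str] = None
    table_id: Optional[int] = None
    strand: Optional[str] = None
    core_aa: Optional[str] = None  # the embedded (possibly fragmented) core
    is_fragment: bool = False
    frag_window: Optional[tuple[int, int]] = None  # aa window on the full core
    orf_nt_span: Optional[tuple[int, int]] = None  # forward-strand coords of coding
    triplet: Optional[str] = None
    motif_pos_in_fragment: Optional[int] = None  # 0-based, None if motif truncated away
    lineage: Optional[str] = None
    host_category: Optional[str] = None
    dataset_id: Optional[str] = None
    species: Optional[str] = None


@dataclass
class SplicedGenomeTruth:
    contig_id: str
    introns: list[tuple[int, int]]  # (donor, acceptor), 0-based half-open
    stop_start_ends: list[int]  # 1-based end coordinates of planted motifs
    l_protein: str
    unspliced_seq: str
    warning: Optional[str] = None


@dataclass
class SimulationTruth:
    families: dict[str, FamilySim] = field(default_factory=dict)
    contigs: dict[str, ContigTruth] = field(default_factory=dict)
    spliced: dict[str, SplicedGenomeTruth] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class ContigSimParams:
    """Embedding conditions for :func:`simulate_contigs`."""

    fragment_prob: float = 0.3
    fragment_len_range: tuple[int, int] = (60, 200)  # aa
    strand_flip_prob: float = 0.5
    table_mix: tuple[int, ...] = (1, 4, 6)
    n_decoys: int = 200
    decoy_len_range: tuple[int, int] = (400, 1500)  # nt
    utr_len_range: tuple[int, int] = (60, 300)  # nt


def _random_protein(rng: np.random.Generator, length: int) -> str:
    codes = rng.choice(20, size=length, p=ROBINSON_BG)
    return "".join(AA_ORDER[c] for c in codes)


def simulate_family(
    n_members: int,
    core_len_aa: int = 400,
    divergence: float = 0.3,
    triplet: str = "GDD",
    seed: int = 0,
    name: str = "fam",
) -> FamilySim:
    """Evolve a virus family from a random ancestral RdRp core.

    Members differ from the ancestor by i.i.d. per-site substitutions
    (probability ``1 - exp(-divergence)`` per site, uniform replacement);
    the motif-C triplet and two columns on each side are held invariant,
    and the ancestor carries at least two Trp residues so code-table-4
    embeddings can use a TGA codon.  The returned seed alignment covers
    the first half of the members; the rest are held out.
    """
    if core_len_aa < 50:
        raise ValueError("core_len_aa must be >= 50")
    if triplet not in MOTIF_TRIPLETS:
        raise ValueError(f"triplet must be one of {MOTIF_TRIPLETS}")
    rng = np.random.default_rng(seed)
    ancestor = list(_random_protein(rng, core_len_aa))
    motif_pos = int(0.70 * core_len_aa)
    ancestor[motif_pos : motif_pos + 3] = triplet
    invariant = set(range(max(0, motif_pos - 2), min(core_len_aa, motif_pos + 5)))
    # guarantee Trp outside the invariant window
    free = [i for i in range(core_len_aa) if i not in invariant]
    for i in rng.choice(free, size=2, replace=False):
        ancestor[i] = "W"
    ancestor_s = "".join(ancestor)

    p_sub = 1.0 - np.exp(-divergence)
    members = []
    for m in range(n_members):
        seq = list(ancestor_s)
        for i in range(core_len_aa):
            if i in invariant:
                continue
            if rng.random() < p_sub:
                choices = [aa for aa in AA_ORDER if aa != seq[i]]
                seq[i] = choices[rng.integers(len(choices))]
        members.append((f"{name}_m{m:02d}", "".join(seq)))

    n_seed = max(1, n_members // 2)
    seed_rows = members[:n_seed]
    fam = FamilySim(
        name=name,
        seed_alignment=SeedAlignment(name=name, rows=list(seed_rows)),
        members=members,
        anchor_col=motif_pos,
        triplet=triplet,
        seed_member_ids=frozenset(mid for mid, _ in seed_rows),
    )
    if n_members >= 2:
        idents = []
        for a in range(min(n_members, 10)):
            for b in range(a + 1, min(n_members, 10)):
                sa, sb = members[a][1], members[b][1]
                idents.append(sum(x == y for x, y in zip(sa, sb)) / core_len_aa)
        if np.mean(idents) < 0.15:
            fam.warning = (
                f"divergence {divergence} leaves mean pairwise identity "
                f"{np.mean(idents):.2f} < 0.15; members may escape their own profile"
            )
    return fam


def _codon_tables(table_id: int) -> dict[str, list[str]]:
    code = get_code(table_id)
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(code.codon_to_aa.items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa


def reverse_translate(
    aa_seq: str, table_id: int, rng: np.random.Generator, force_reassigned: bool = True
) -> str:
    """Reverse-translate with uniform synonymous codon choice.

    Under table 4 at least one Trp uses TGA (and under table 6 at least
    one Gln uses TAA/TAG) when ``force_reassigned``, so the alternative
    code tables are genuinely exercised.
    """
    by_aa = _codon_tables(table_id)
    codons = []
    for aa in aa_seq:
        opts = by_aa.get(aa)
        if not opts:
            raise ValueError(f"no codon for residue {aa!r} under table {table_id}")
        codons.append(opts[rng.integers(len(opts))])
    if force_reassigned:
        if table_id == 4 and "W" in aa_seq and "TGA" not in codons:
            codons[aa_seq.index("W")] = "TGA"
        if table_id == 6 and "Q" in aa_seq and not ({"TAA", "TAG"} & set(codons)):
            codons[aa_seq.index("Q")] = "TAA"
    return "".join(codons)


def _random_nt(rng: np.random.Generator, length: int, p_at: float = 0.5) -> str:
    p = np.array([p_at / 2, (1 - p_at) / 2, (1 - p_at) / 2, p_at / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=p))


def simulate_contigs(
    families: Sequence[FamilySim],
    params: Optional[ContigSimParams] = None,
    seed: int = 0,
) -> tuple[list[Contig], SimulationTruth]:
    """Embed every family member in a contig and add decoy transcripts.

    Each member is reverse-translated under a code table drawn from
    ``table_mix``, bracketed by in-frame stop codons, wrapped in random
    UTR-like flanks, optionally truncated to a 60-200 aa fragment and
    optionally reverse-complemented.  Decoys are random transcripts with
    low-complexity and GC-extreme cases mixed in.  Lineages cycle through
    all seven host categories.
    """
    if not families:
        raise ValueError("at least one family is required")
    params = params or ContigSimParams()
    rng = np.random.default_rng(seed)
    truth = SimulationTruth()
    for fam in families:
        truth.families[fam.name] = fam

    contigs: list[Contig] = []
    categories = list(LINEAGES)
    ci = 0
    for fam in families:
        for member_id, core in fam.members:
            table_id = int(rng.choice(params.table_mix))
            is_fragment = bool(rng.random() < params.fragment_prob)
            frag_window = None
            aa = core
            if is_fragment:
                lo, hi = params.fragment_len_range
                flen = int(rng.integers(lo, hi + 1))
                flen = min(flen, len(core))
                start = int(rng.integers(0, len(core) - flen + 1))
                frag_window = (start, start + flen)
                aa = core[start : start + flen]
            coding = reverse_translate(aa, table_id, rng)
            stop = "TAA" if table_id in (1, 4) else "TGA"
            ulo, uhi = params.utr_len_range
            left = _random_nt(rng, int(rng.integers(ulo, uhi + 1)))
            right = _random_nt(rng, int(rng.integers(ulo, uhi + 1)))
            fwd = left + stop + coding + stop + right
            span = (len(left) + 3, len(left) + 3 + len(coding))
            strand = "-" if rng.random() < params.strand_flip_prob else "+"
            seq = revcomp(fwd) if strand == "-" else fwd
            if strand == "-":
                span = (len(fwd) - span[1], len(fwd) - span[0])
            cid = f"VC{ci:04d}"
            ci += 1
            category = categories[ci % len(categories)]
            motif_pos = None
            if frag_window is None:
                motif_pos = fam.anchor_col
            else:
                s, e = frag_window
                if s <= fam.anchor_col and fam.anchor_col + 3 <= e:
                    motif_pos = fam.anchor_col - s
            lineage = LINEAGES[category]
            contigs.append(Contig(id=cid, seq=seq, lineage=lineage, dataset_id=f"DS{ci % 37:03d}"))
            truth.contigs[cid] = ContigTruth(
                contig_id=cid,
                kind="viral",
                family=fam.name,
                member_id=member_id,
                table_id=table_id,
                strand=strand,
                core_aa=aa,
                is_fragment=is_fragment,
                frag_window=frag_window,
                orf_nt_span=span,
                triplet=fam.triplet if motif_pos is not None else None,
                motif_pos_in_fragment=motif_pos,
                lineage=lineage,
                host_category=category,
                dataset_id=f"DS{ci % 37:03d}",
                species=lineage.split(";")[-1].strip(),
            )

    for d in range(params.n_decoys):
        lo, hi = params.decoy_len_range
        length = int(rng.integers(lo, hi + 1))
        style = d % 10
        if style == 8:  # low-complexity: noisy dinucleotide repeat
            unit = _random_nt(rng, 2)
            seq = "".join(
                unit[i % 2] if rng.random() > 0.1 else "ACGT"[rng.integers(4)]
                for i in range(length)
            )
        elif style == 9:  # GC-extreme
            seq = "".join(
                "GC"[rng.integers(2)] if rng.random() < 0.8 else "AT"[rng.integers(2)]
                for i in range(length)
            )
        else:
            seq = _random_nt(rng, length)
        cid = f"DC{d:04d}"
        category = categories[d % len(categories)]
        lineage = LINEAGES[category]
        contigs.append(Contig(id=cid, seq=seq, lineage=lineage, dataset_id=f"DS{d % 37:03d}"))
        truth.contigs[cid] = ContigTruth(
            contig_id=cid,
            kind="decoy",
            lineage=lineage,
            host_category=category,
            dataset_id=f"DS{d % 37:03d}",
            species=lineage.split(";")[-1].strip(),
        )
    return contigs, truth


# --- spliced mononegavirus-like genome --------------------------------------

# an instantiated copy of the degenerate stop-start consensus
_TSS_INSTANCE = "ACTTTAAAAAAGTGAAAGGC"
# all-frame stop block inserted mid-intron so an unspliced read-through is
# impossible whatever the intron length modulo 3
_STOP_BLOCK = "TTAATTAATTAA"


def _intron_seq(length: int, au_target: float, rng: np.random.Generator) -> str:
    if length < len("GTAAGT") + len(_STOP_BLOCK) + len("TTTTGCAG"):
        raise ValueError(f"intron length {length} too short")
    n_fill = length - 6 - 8 - len(_STOP_BLOCK)
    fixed_au = 4 + 5 + len(_STOP_BLOCK)  # A/T bases in the fixed parts
    want_au = max(0, min(n_fill, round(au_target * length) - fixed_au))
    fill = ["AT"[rng.integers(2)] for _ in range(want_au)] + [
        "CG"[rng.integers(2)] for _ in range(n_fill - want_au)
    ]
    fill = list(np.array(fill)[rng.permutation(n_fill)]) if n_fill else []
    half = n_fill // 2
    interior = "".join(fill[:half]) + _STOP_BLOCK + "".join(fill[half:])
    return "GTAAGT" + interior + "TTTTGCAG"


def simulate_spliced_genome(
    intron_lens: Sequence[int] = (132, 98, 131),
    au_target: float = 0.68,
    seed: int = 0,
    contig_id: str = "SG0000",
    background_au: float = 0.565,
    l_len_aa: int = 850,
) -> tuple[Contig, SplicedGenomeTruth]:
    """Assemble a mononegavirus-like genome with a split L ORF.

    Layout (positive / mRNA sense): leader, N ORF, then transcription
    stop-start motifs before ORF2, ORF3 and the L gene; the L coding
    region is interrupted by GT..AG introns of the requested lengths and
    AU content, inserted at sites whose exonic context matches the splice
    consensus (AG before the donor, G after the acceptor).  The truth
    records exact intron boundaries, motif end positions and the L
    protein.
    """
    rng = np.random.default_rng(seed)

    def gene(aa_len: int) -> tuple[str, str]:
        protein = "M" + _random_protein(rng, aa_len - 1)
        return protein, reverse_translate(protein, 1, rng, force_reassigned=False) + "TAA"

    _, n_gene = gene(400)
    _, orf2_gene = gene(200)
    _, orf3_gene = gene(300)
    l_protein, l_gene = gene(l_len_aa)

    # choose spaced intron insertion sites with consensus exonic context
    sites = [
        i
        for i in range(60, len(l_gene) - 60)
        if l_gene[i - 2 : i] == "AG" and l_gene[i] == "G"
    ]
    chosen: list[int] = []
    for s in sites:
        if len(chosen) == len(intron_lens):
            break
        if not chosen or s - chosen[-1] >= (len(l_gene) - 120) // (len(intron_lens) + 1):
            chosen.append(s)
    if len(chosen) < len(intron_lens):
        # rare: not enough well-spaced AG|G sites; retry with the next seed
        return simulate_spliced_genome(
            intron_lens, au_target, seed + 104729, contig_id, background_au, l_len_aa
        )

    parts = [
        _random_nt(rng, 60, background_au),  # leader
        n_gene,
        _random_nt(rng, 25, background_au),
    ]
    tss_ends = []
    for g in (orf2_gene, orf3_gene):
        parts.append(_TSS_INSTANCE)
        tss_ends.append(sum(len(p) for p in parts))
        parts.append(_random_nt(rng, 10, background_au))
        parts.append(g)
        parts.append(_random_nt(rng, 25, background_au))
    parts.append(_TSS_INSTANCE)
    tss_ends.append(sum(len(p) for p in parts))
    parts.append(_random_nt(rng, 10, background_au))
    l_start = sum(len(p) for p in parts)

    # interleave L exons and introns
    introns_abs: list[tuple[int, int]] = []
    pos = 0
    l_parts = []
    offset = l_start
    for site, length in zip(chosen, intron_lens):
        l_parts.append(l_gene[pos:site])
        offset += site - pos
        intron = _intron_seq(int(length), au_target, rng)
        introns_abs.append((offset, offset + len(intron)))
        l_parts.append(intron)
        offset += len(intron)
        pos = site
    l_parts.append(l_gene[pos:])
    parts.extend(l_parts)
    parts.append(_random_nt(rng, 60, background_au))

    seq = "".join(parts)
    contig = Contig(id=contig_id, seq=seq)
    truth = SplicedGenomeTruth(
        contig_id=contig_id,
        introns=introns_abs,
        stop_start_ends=tss_ends,
        l_protein=l_protein,
        unspliced_seq=seq,
    )
    if au_target < background_au:
        truth.warning = (
            f"intron AU target {au_target} below background {background_au}; "
            "AU-excess ranking will not separate introns from flanks"
        )
    return contig, truth


# --- default preset ---------------------------------------------------------

DEFAULT_FAMILY_TRIPLETS = ("GDD", "SDD", "GDN", "IDD", "ADN")


def default_preset(
    seed: int = 0,
    n_families: int = 5,
    n_members: int = 20,
    core_len_aa: int = 400,
    divergence: float = 0.3,
    params: Optional[ContigSimParams] = None,
) -> tuple[list[Contig], SimulationTruth]:
    """The standard study conditions: five divergent families of twenty
    members (half in the seed alignments, half held out) plus 200 decoys."""
    rng = np.random.default_rng(seed)
    families = [
        simulate_family(
            n_members=n_members,
            core_len_aa=core_len_aa,
            divergence=divergence,
            triplet=DEFAULT_FAMILY_TRIPLETS[i % len(DEFAULT_FAMILY_TRIPLETS)],
            seed=int(rng.integers(2**31 - 1)),
            name=f"fam{i}",
        )
        for i in range(n_families)
    ]
    contigs, truth = simulate_contigs(families, params, seed=int(rng.integers(2**31 - 1)))
    return contigs, truth
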