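"""Between-stop ORF extraction under genetic code tables 1, 4 and 6.

RNA viruses occur in hosts (and organelles/symbionts) that reassign stop
codons, and assembled transcripts are frequently fragmentary, so ORFs are
called as maximal stop-free codon runs on both strands — no start codon is
required — under three code tables:

* table 1 — standard code, stops TAA/TAG/TGA;
* table 4 — TGA reassigned to Trp (mold/protozoan mitochondrial and
  *Mycoplasma*-like);
* table 6 — TAA/TAG reassigned to Gln (ciliate nuclear).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .seqio import Contig

SUPPORTED_TABLES = (1, 4, 6)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table restricted to the three tables used here."""

    table_id: int
    codon_to_aa: dict[str, str]  # 64 codons -> amino acid or '*'

    @classmethod
    def from_table(cls, table_id: int) -> "GeneticCode":
        if table_id not in SUPPORTED_TABLES:
            raise ValueError(f"genetic code table must be one of {SUPPORTED_TABLES}")
        table = unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        assert len(mapping) == 64
        return cls(table_id=table_id, codon_to_aa=mapping)

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")


@lru_cache(maxsize=None)
def get_code(table_id: int) -> GeneticCode:
    return GeneticCode.from_table(table_id)


@dataclass(frozen=True)
class Orf:
    """A translated between-stop region.

    Coordinates are always on the forward strand of the parent contig,
    0-based half-open; ``strand`` records which strand was read and
    ``frame`` is the reading frame (0/1/2) on that strand.
    """

    contig_id: str
    table_id: int
    strand: str  # '+' or '-'
    frame: int
    nt_start: int
    nt_end: int
    aa_seq: str

    @property
    def id(self) -> str:
        return (
            f"{self.contig_id}|t{self.table_id}|{self.strand}{self.frame}"
            f"|{self.nt_start}-{self.nt_end}"
        )

    @property
    def nt_len(self) -> int:
        return self.nt_end - self.nt_start


def translate(nt: str, code: GeneticCode) -> str:
    """Translate a codon-aligned nucleotide string; codons containing N
    become X and stop codons render as ``*``."""
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} is not divisible by 3")
    mapping = code.codon_to_aa
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        out.append("X" if "N" in codon else mapping[codon])
    return "".join(out)


def _frame_runs(strand_seq: str, frame: int, code: GeneticCode, min_nt: int):
    """Yield (codon_start, codon_end, aa) for maximal stop-free runs in one
    frame of one strand, coordinates on that strand, partial codons dropped."""
    mapping = code.codon_to_aa
    n_codons = (len(strand_seq) - frame) // 3
    run_start = 0  # codon index
    aa_buf: list[str] = []
    for ci in range(n_codons + 1):
        if ci < n_codons:
            codon = strand_seq[frame + 3 * ci : frame + 3 * ci + 3]
            aa = "X" if "N" in codon else mapping[codon]
        else:
            aa = "*"  # sentinel closes the final run
        if aa == "*":
            if aa_buf and 3 * len(aa_buf) >= min_nt:
                yield (
                    frame + 3 * run_start,
                    frame + 3 * ci,
                    "".join(aa_buf),
                )
            run_start = ci + 1
            aa_buf = []
        else:
            aa_buf.append(aa)


def extract_orfs(contig: Contig, code: GeneticCode, min_nt: int = 60) -> list[Orf]:
    """Extract all between-stop ORFs of nucleotide length >= ``min_nt``
    from both strands in all three frames.

    ORFs need not start with Met.  ``min_nt`` applies to the complete-codon
    length (60 nt = 20 aa).  Reverse-strand ORFs carry forward-strand
    coordinates with strand '-'.
    """
    if min_nt < 3 or min_nt % 3 != 0:
        raise ValueError("min_nt must be >= 3 and divisible by 3")
    L = len(contig.seq)
    out: list[Orf] = []
    for strand in ("+", "-"):
        strand_seq = contig.seq if strand == "+" else revcomp(contig.seq)
        for frame in range(3):
            for s, e, aa in _frame_runs(strand_seq, frame, code, min_nt):
                if strand == "+":
                    nt_start, nt_end = s, e
                else:
                    nt_start, nt_end = L - e, L - s
                out.append(
                    Orf(
                        contig_id=contig.id,
                        table_id=code.table_id,
                        strand=strand,
                        frame=frame,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        aa_seq=aa,
                    )
                )
    return out


def extract_orfs_all_tables(
    contig: Contig, tables: Iterable[int] = SUPPORTED_TABLES, min_nt: int = 60
) -> list[Orf]:
    out = []
    for t in tables:
        out.extend(extract_orfs(contig, get_code(t), min_nt))
    return out


def dedup_code_variants(orfs: list[Orf]) -> list[Orf]:
    """Collapse redundant ORFs produced from the same contig by the three
    code tables.

    Within each contig, every ORF pair is globally aligned with free gaps
    (identity = longest common subsequence; X never matches); when
    identities divided by the shorter length equal 1 the shorter ORF is
    dropped.  Length ties are resolved by dropping the higher code table,
    then the lexicographically larger strand/frame/coordinate key.  Output
    order is the input order of the survivors; the operation is idempotent.
    """
    from .cluster import lcs_identity_count

    by_contig: dict[str, list[int]] = {}
    for idx, orf in enumerate(orfs):
        by_contig.setdefault(orf.contig_id, []).append(idx)

    dropped: set[int] = set()
    for indices in by_contig.values():
        # priority: longer first, then lower table, then smaller strand/frame key
        def keep_rank(i: int):
            o = orfs[i]
            return (-len(o.aa_seq), o.table_id, o.strand, o.frame, o.nt_start)

        order = sorted(indices, key=keep_rank)
        kept: list[int] = []
        for i in order:
            oi = orfs[i]
            redundant = False
            for j in kept:
                oj = orfs[j]
                shorter = min(len(oi.aa_seq), len(oj.aa_seq))
                if lcs_identity_count(oi.aa_seq, oj.aa_seq) == shorter:
                    redundant = True
                    break
            if redundant:
                dropped.add(i)
            else:
                kept.append(i)
    return [o for idx, o in enumerate(orfs) if idx not in dropped]
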