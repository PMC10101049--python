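"""Readers and writers: FASTA, seed alignments, taxonomy tables, profile text files.

All nucleotide input is normalised to the DNA alphabet (U becomes T,
everything uppercased); internal work is DNA-only and motifs are rendered
back in RNA only where reports call for it.  Amino-acid sequences use the
20 standard residues plus ``X`` (unknown) and ``*`` (stop).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import AlignIO
from Bio.SeqIO.FastaIO import SimpleFastaParser

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}
AA_ALIGN_ALPHABET = AA_ALPHABET | {"-", "."}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Contig:
    """A nucleotide record: the unit scanned for RdRp-encoding ORFs."""

    id: str
    seq: str
    lineage: Optional[str] = None
    dataset_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("contig id must be non-empty")
        if len(self.seq) < 1:
            raise FormatError(f"contig {self.id!r}: empty sequence")


@dataclass
class SeedAlignment:
    """A family-level multiple alignment of RdRp core amino-acid sequences.

    Single-row seeds are legal: profile construction supports families
    known from one sequence only.
    """

    name: str
    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError(f"seed alignment {self.name!r} has no rows")
        width = len(self.rows[0][1])
        for rid, aligned in self.rows:
            if len(aligned) != width:
                raise FormatError(
                    f"seed alignment {self.name!r}: row {rid!r} has length "
                    f"{len(aligned)}, expected {width}"
                )
            bad = set(aligned) - AA_ALIGN_ALPHABET
            if bad:
                raise FormatError(
                    f"seed alignment {self.name!r}: row {rid!r} has illegal "
                    f"characters {sorted(bad)}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])


def _sanitize_nt(seq: str, record_id: str) -> str:
    out = seq.upper().replace("U", "T")
    for pos, ch in enumerate(out):
        if ch not in NT_ALPHABET:
            raise FormatError(
                f"record {record_id!r}: illegal nucleotide {ch!r} at position {pos + 1}"
            )
    return out


def _sanitize_aa(seq: str, record_id: str) -> str:
    out = seq.upper()
    for pos, ch in enumerate(out):
        if ch not in AA_ALPHABET:
            raise FormatError(
                f"record {record_id!r}: illegal amino acid {ch!r} at position {pos + 1}"
            )
    return out


def read_fasta(path: str | Path, alphabet: str = "nt") -> list[tuple[str, str]]:
    """Read a FASTA file as a list of ``(id, seq)`` in file order.

    Ids are taken verbatim up to the first whitespace.  ``alphabet`` is
    ``"nt"`` (U mapped to T) or ``"aa"``.  Duplicate ids and characters
    outside the alphabet are errors.
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    sanitize = _sanitize_nt if alphabet == "nt" else _sanitize_aa
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            rid = title.split()[0] if title.split() else ""
            if not rid:
                raise FormatError(f"{path}: record with empty id")
            if rid in seen:
                raise FormatError(f"{path}: duplicate record id {rid!r}")
            seen.add(rid)
            if not seq:
                raise FormatError(f"{path}: record {rid!r} has empty sequence")
            records.append((rid, sanitize(seq, rid)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def read_contigs(path: str | Path, taxonomy: Optional[dict] = None) -> list[Contig]:
    """Read nucleotide contigs, attaching lineage/dataset metadata when given.

    ``taxonomy`` maps accession to a dict with keys ``lineage`` and
    optionally ``dataset_id`` (see :func:`read_taxonomy`).
    """
    contigs = []
    for rid, seq in read_fasta(path, alphabet="nt"):
        meta = (taxonomy or {}).get(rid, {})
        contigs.append(
            Contig(
                id=rid,
                seq=seq,
                lineage=meta.get("lineage"),
                dataset_id=meta.get("dataset_id"),
            )
        )
    return contigs


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, wrap: int = 60) -> None:
    """Write ``(id, seq)`` records as wrapped FASTA."""
    with open(path, "w") as handle:
        for rid, seq in records:
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                handle.write(seq[i : i + wrap] + "\n")


def read_seed_alignment(path: str | Path, name: Optional[str] = None) -> SeedAlignment:
    """Read a seed alignment from Stockholm 1.0 or aligned FASTA.

    The format is sniffed from the first line.  ``name`` defaults to the
    file stem.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
    fmt = "stockholm" if first.startswith("# STOCKHOLM") else "fasta"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    rows = [(rec.id, str(rec.seq).upper().replace(".", "-")) for rec in aln]
    return SeedAlignment(name=name or path.stem, rows=rows)


def write_stockholm(seed: SeedAlignment, path: str | Path) -> None:
    """Write a seed alignment in Stockholm 1.0."""
    with open(path, "w") as handle:
        handle.write("# STOCKHOLM 1.0\n")
        width = max(len(rid) for rid, _ in seed.rows) + 2
        for rid, aligned in seed.rows:
            handle.write(f"{rid:<{width}}{aligned}\n")
        handle.write("//\n")


def read_taxonomy(path: str | Path) -> dict[str, dict]:
    """Read a taxonomy table: TSV with header ``accession<TAB>lineage`` and
    optional ``dataset_id`` and ``species`` columns.

    Lineages are semicolon-delimited strings as retrieved from NCBI
    taxonomy lines.  Returns accession -> row dict.
    """
    out: dict[str, dict] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if "accession" not in header or "lineage" not in header:
            raise FormatError(f"{path}: taxonomy table needs 'accession' and 'lineage' columns")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(header):
                fields += [""] * (len(header) - len(fields))
            row = dict(zip(header, fields))
            acc = row.pop("accession")
            if acc in out:
                raise FormatError(f"{path}:{lineno}: duplicate accession {acc!r}")
            out[acc] = row
    return out


# --------------------------------------------------------------------------
# Profile text format
#
# A line-oriented, HMMER3-inspired layout (this package's own format;
# reading genuine HMMER3 files is out of scope):
#
#   RDRPSCOUT-PROFILE 1
#   NAME   <family>
#   LENG   <M>
#   ALPH   amino
#   CROP   <start> <end>            (optional, 0-based half-open seed columns)
#   ANCHOR <col>                    (optional, 1-based motif-C profile column)
#   BG     <20 floats>
#   STATS  GUMBEL <mu> <lambda>     (optional; absent = uncalibrated)
#   INSEM  <20 floats>
#   MODEL
#   <k> MATCH <20 floats>
#   <k> TRANS <mm> <mi> <md> <im> <ii> <dm> <dd>
#   //
#
# Probabilities are serialized as natural-log values with 17 significant
# digits so a round trip reproduces scores to well below 1e-9 bits.

_MAGIC = "RDRPSCOUT-PROFILE 1"


def _fmt_logs(values) -> str:
    import numpy as np

    return " ".join(f"{v:.17e}" for v in np.log(np.asarray(values, dtype=float)))


def write_profile(profile, path: str | Path) -> None:
    """Serialize a :class:`~rdrpscout.profilehmm.ProfileHMM` to text."""
    import numpy as np

    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"NAME   {profile.name}\n")
        fh.write(f"LENG   {profile.M}\n")
        fh.write("ALPH   amino\n")
        if profile.crop is not None:
            fh.write(f"CROP   {profile.crop[0]} {profile.crop[1]}\n")
        if profile.motif_anchor_col is not None:
            fh.write(f"ANCHOR {profile.motif_anchor_col}\n")
        fh.write(f"BG     {_fmt_logs(profile.bg)}\n")
        if profile.gumbel_mu is not None:
            fh.write(f"STATS  GUMBEL {profile.gumbel_mu:.17e} {profile.gumbel_lambda:.17e}\n")
        fh.write(f"INSEM  {_fmt_logs(profile.ins_em)}\n")
        fh.write("MODEL\n")
        for k in range(profile.M):
            fh.write(f"{k + 1} MATCH {_fmt_logs(profile.match_em[k])}\n")
            t = profile.trans
            row = [t[key][k] for key in ("mm", "mi", "md", "im", "ii", "dm", "dd")]
            fh.write(f"{k + 1} TRANS {_fmt_logs(row)}\n")
        fh.write("//\n")


def read_profile(path: str | Path):
    """Parse a profile text file back into a ProfileHMM.

    A missing STATS line yields a profile with calibration marked absent
    (scores work, p-values do not).  Structural problems raise
    :class:`FormatError` with the offending line number.
    """
    import numpy as np

    from .profilehmm import ProfileHMM

    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise FormatError(f"{path}:1: missing magic line {_MAGIC!r}")

    header: dict[str, str] = {}
    model_at = None
    for i, line in enumerate(lines[1:], start=2):
        if line.strip() == "MODEL":
            model_at = i
            break
        m = re.match(r"^(\w+)\s+(.*)$", line.strip())
        if not m:
            raise FormatError(f"{path}:{i}: unparseable header line")
        header[m.group(1)] = m.group(2)
    if model_at is None:
        raise FormatError(f"{path}: truncated file, no MODEL section")
    for key in ("NAME", "LENG", "BG", "INSEM"):
        if key not in header:
            raise FormatError(f"{path}: missing required header {key}")

    M = int(header["LENG"])
    bg = np.exp([float(x) for x in header["BG"].split()])
    ins_em = np.exp([float(x) for x in header["INSEM"].split()])
    crop = None
    if "CROP" in header:
        a, b = header["CROP"].split()
        crop = (int(a), int(b))
    anchor = int(header["ANCHOR"]) if "ANCHOR" in header else None
    gumbel_mu = gumbel_lambda = None
    if "STATS" in header:
        parts = header["STATS"].split()
        if parts[0] != "GUMBEL" or len(parts) != 3:
            raise FormatError(f"{path}: malformed STATS line")
        gumbel_mu, gumbel_lambda = float(parts[1]), float(parts[2])

    match_em = np.zeros((M, 20))
    trans = {key: np.zeros(M) for key in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    seen_match = [False] * M
    seen_trans = [False] * M
    for i, line in enumerate(lines[model_at:], start=model_at + 1):
        stripped = line.strip()
        if stripped == "//":
            break
        if not stripped:
            continue
        parts = stripped.split()
        if len(parts) < 3 or parts[1] not in ("MATCH", "TRANS"):
            raise FormatError(f"{path}:{i}: unparseable model line")
        k = int(parts[0]) - 1
        if not (0 <= k < M):
            raise FormatError(f"{path}:{i}: state index {k + 1} outside stated length {M}")
        values = np.exp([float(x) for x in parts[2:]])
        if parts[1] == "MATCH":
            if len(values) != 20:
                raise FormatError(f"{path}:{i}: expected 20 emission values")
            match_em[k] = values
            seen_match[k] = True
        else:
            if len(values) != 7:
                raise FormatError(f"{path}:{i}: expected 7 transition values")
            for key, v in zip(("mm", "mi", "md", "im", "ii", "dm", "dd"), values):
                trans[key][k] = v
            seen_trans[k] = True
    else:
        raise FormatError(f"{path}: truncated file, no terminating '//'")
    if not (all(seen_match) and all(seen_trans)):
        missing = next(k for k in range(M) if not (seen_match[k] and seen_trans[k]))
        raise FormatError(
            f"{path}: stated length {M} but state {missing + 1} has no model lines"
        )

    return ProfileHMM(
        name=header["NAME"],
        M=M,
        match_em=match_em,
        ins_em=ins_em,
        trans=trans,
        bg=bg,
        gumbel_mu=gumbel_mu,
        gumbel_lambda=gumbel_lambda,
        crop=crop,
        motif_anchor_col=anchor,
    )
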