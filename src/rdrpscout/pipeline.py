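"""End-to-end orchestration: build, calibrate, scan, classify, annotate.

The pipeline mirrors a transcriptome RdRp screen: profiles are built from
per-family seed alignments and decoy-calibrated; ORFs are extracted per
genetic code table and searched separately with a database-size-adjusted
E-value so the p-value threshold is constant across tables; hit-bearing
ORFs are deduplicated across code tables, classified by IDscore, trimmed
to their profile-matched core, clustered at a ladder of identity
thresholds, and annotated (motif C, profile co-occurrence, host
categories).  Re-running with the same seed reproduces every output file
byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import annotate as ann
from . import classify as cls
from . import cluster as clu
from . import orfs as orfmod
from . import profilehmm as phmm
from . import seqio


@dataclass
class RunReport:
    seed: int
    config: dict
    stage_counts: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    per_family: dict = field(default_factory=dict)
    cluster_counts: dict = field(default_factory=dict)
    motif_census: dict = field(default_factory=dict)
    host_counts: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory handles to every stage product, plus the report."""

    report: RunReport
    profiles: dict
    orfs_by_table: dict
    hits: list
    surviving_orfs: list
    records: list
    cores: list
    best_hits: dict
    motifs: list
    cooccurrence: object
    host_tables: tuple


def _load_seeds(seeds) -> dict[str, seqio.SeedAlignment]:
    if isinstance(seeds, dict):
        return seeds
    seeds_dir = Path(seeds)
    out = {}
    for path in sorted(seeds_dir.iterdir()):
        if path.suffix in (".fasta", ".fa", ".faa", ".sto", ".stk"):
            aln = seqio.read_seed_alignment(path)
            out[aln.name] = aln
    if not out:
        raise FileNotFoundError(f"no seed alignments found in {seeds_dir}")
    return out


def run_pipeline(
    contigs: Sequence[seqio.Contig] | str | Path,
    seeds,
    config: Optional[cls.PipelineConfig] = None,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
    anchors: Optional[dict[str, int]] = None,
    profiles: Optional[dict[str, phmm.ProfileHMM]] = None,
) -> PipelineResult:
    """Run every stage and (optionally) write all artifacts under ``out_dir``.

    ``contigs`` is a list of :class:`~rdrpscout.seqio.Contig` or a FASTA
    path; ``seeds`` a mapping of family name to seed alignment or a
    directory of alignment files.  ``anchors`` optionally gives the
    0-based seed-alignment column of motif C per family.  Pre-calibrated
    ``profiles`` may be supplied to skip build+calibration.
    """
    config = config or cls.PipelineConfig()
    report = RunReport(seed=seed, config=asdict(config))
    if isinstance(contigs, (str, Path)):
        contigs = seqio.read_contigs(contigs)
    contigs = list(contigs)
    contig_by_id = {c.id: c for c in contigs}
    report.stage_counts["contigs"] = len(contigs)
    report.log.append(f"input: {len(contigs)} contigs")

    # 1-2. build and calibrate profiles
    if profiles is None:
        seed_alns = _load_seeds(seeds)
        profiles = {}
        rng = np.random.default_rng(seed)
        for name in sorted(seed_alns):
            prof = phmm.build_profile(
                seed_alns[name],
                motif_anchor_seed_col=(anchors or {}).get(name),
            )
            cal_seed = int(rng.integers(2**31 - 1))
            profiles[name] = phmm.calibrate_profile(
                prof,
                n_decoys=config.calibration_decoys,
                decoy_len=config.calibration_decoy_len,
                seed=cal_seed,
            )
    report.stage_counts["profiles"] = len(profiles)
    report.log.append(f"profiles: {len(profiles)} built and calibrated")
    profile_list = [profiles[name] for name in sorted(profiles)]

    # 3-4. per-table ORF extraction and search
    orfs_by_table: dict[int, list[orfmod.Orf]] = {}
    hits: list[phmm.Hit] = []
    for table in config.tables:
        code = orfmod.get_code(table)
        table_orfs: list[orfmod.Orf] = []
        for contig in contigs:
            table_orfs.extend(orfmod.extract_orfs(contig, code, min_nt=config.min_orf_nt))
        orfs_by_table[table] = table_orfs
        report.stage_counts[f"orfs_table{table}"] = len(table_orfs)
        table_hits = phmm.search(
            profile_list,
            table_orfs,
            p_threshold=config.p_threshold,
            database_size=len(table_orfs),
        )
        report.log.append(
            f"table {table}: {len(table_orfs)} ORFs, {len(table_hits)} significant hits"
        )
        hits.extend(table_hits)
    report.stage_counts["significant_hits"] = len(hits)

    # 5. dedup code-table variants among hit-bearing ORFs
    orf_by_id = {o.id: o for table_orfs in orfs_by_table.values() for o in table_orfs}
    hits_by_orf: dict[str, list[phmm.Hit]] = {}
    for h in hits:
        hits_by_orf.setdefault(h.orf_ref, []).append(h)
    candidates = [orf_by_id[oid] for oid in sorted(hits_by_orf)]
    surviving = orfmod.dedup_code_variants(candidates)
    report.stage_counts["orfs_with_hits"] = len(candidates)
    report.stage_counts["orfs_after_dedup"] = len(surviving)
    report.log.append(f"dedup: {len(candidates)} hit ORFs -> {len(surviving)}")

    # 6. classification and core trimming
    records: list[cls.ClassificationRecord] = []
    cores: list[cls.CoreSequence] = []
    best_hits: dict[str, phmm.Hit] = {}
    for orf in surviving:
        record = cls.sort_orf(hits_by_orf[orf.id], config)
        records.append(record)
        ranked = sorted(
            hits_by_orf[orf.id],
            key=lambda h: (-cls.idscore(h), -h.bit_score, h.profile_name),
        )
        best_hits[orf.id] = ranked[0]
        if record.status == cls.CLASSIFIED:
            cores.append(cls.trim_to_core(orf, ranked[0]))
    n = {
        s: sum(1 for r in records if r.status == s)
        for s in (cls.CLASSIFIED, cls.AMBIGUOUS, cls.UNCLASSIFIED)
    }
    total = max(1, len(records))
    report.classification = {
        **{f"{k}_count": v for k, v in n.items()},
        **{f"{k}_fraction": v / total for k, v in n.items()},
    }
    fam_counts: dict[str, int] = {}
    for r in records:
        if r.status == cls.CLASSIFIED:
            fam_counts[r.best_profile] = fam_counts.get(r.best_profile, 0) + 1
    report.per_family = dict(sorted(fam_counts.items()))
    report.log.append(
        "classification: "
        + ", ".join(f"{k}={v}" for k, v in sorted(n.items()))
    )

    # 7. clustering of long cores at the threshold ladder
    long_cores = [
        (c.orf_ref, c.aa_seq) for c in cores if len(c.aa_seq) >= config.core_len_cutoff_aa
    ]
    for thr in config.cluster_thresholds:
        key = f"threshold_{thr:.2f}"
        report.cluster_counts[key] = (
            len(clu.greedy_cluster(long_cores, thr)) if long_cores else 0
        )
    report.stage_counts["cores"] = len(cores)
    report.stage_counts["long_cores"] = len(long_cores)

    # 8. annotation: motif C, co-occurrence, hosts
    motifs: list[ann.MotifC] = []
    for core in cores:
        prof = profiles[core.profile_name]
        motif = ann.locate_motif_c(
            core, family_anchor=prof.motif_anchor_col, hit=best_hits[core.orf_ref]
        )
        if motif is not None:
            motifs.append(motif)
    census, _ = ann.triplet_census(motifs)
    report.motif_census = {str(k): int(v) for k, v in census.items()}
    cooc = ann.cooccurrence_matrix(records)

    host_rows = []
    for core, record in [
        (c, r) for c in cores for r in records if r.orf_ref == c.orf_ref
    ]:
        contig_id = core.orf_ref.split("|")[0]
        contig = contig_by_id.get(contig_id)
        assignment = ann.assign_host(contig_id, contig.lineage if contig else None)
        species = (
            (contig.lineage or "").split(";")[-1].strip() if contig and contig.lineage else None
        )
        host_rows.append(
            {
                "family": record.best_profile,
                "core_seq": core.aa_seq,
                "category": assignment.category if contig and contig.lineage is not None else None,
                "dataset_id": contig.dataset_id if contig else None,
                "species": species,
            }
        )
    per_cat, per_fam = ann.host_summary(host_rows)
    report.host_counts = {
        str(cat): int(per_cat.loc[cat, "rdrp_count"]) for cat in per_cat.index
    }
    report.stage_counts["motifs"] = len(motifs)

    result = PipelineResult(
        report=report,
        profiles=profiles,
        orfs_by_table=orfs_by_table,
        hits=hits,
        surviving_orfs=surviving,
        records=records,
        cores=cores,
        best_hits=best_hits,
        motifs=motifs,
        cooccurrence=cooc,
        host_tables=(per_cat, per_fam),
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report = result.report

    hits_df = pd.DataFrame(
        [
            {
                "orf_id": h.orf_ref,
                "profile": h.profile_name,
                "bits": round(h.bit_score, 6),
                "p": f"{h.p_value:.6e}" if h.p_value is not None else "",
                "e": f"{h.e_value:.6e}" if h.e_value is not None else "",
                "seq_from": h.seq_from,
                "seq_to": h.seq_to,
                "prof_from": h.prof_from,
                "prof_to": h.prof_to,
            }
            for h in sorted(result.hits, key=lambda h: (h.orf_ref, -h.bit_score, h.profile_name))
        ]
    )
    hits_df.to_csv(out_dir / "hits.tsv", sep="\t", index=False)

    rec_df = pd.DataFrame(
        [
            {
                "orf_id": r.orf_ref,
                "status": r.status,
                "best_profile": r.best_profile,
                "best_idscore": round(r.best_idscore, 6),
                "second_profile": r.second_profile or "",
                "second_idscore": (
                    round(r.second_idscore, 6) if r.second_idscore is not None else ""
                ),
            }
            for r in sorted(result.records, key=lambda r: r.orf_ref)
        ]
    )
    rec_df.to_csv(out_dir / "records.tsv", sep="\t", index=False)

    seqio.write_fasta(
        sorted(((c.orf_ref, c.aa_seq) for c in result.cores)),
        out_dir / "cores.faa",
    )

    motif_df = pd.DataFrame(
        [
            {
                "core_id": m.core_ref,
                "position": m.position,
                "triplet": m.triplet,
                "window": m.window,
            }
            for m in sorted(result.motifs, key=lambda m: m.core_ref)
        ]
    )
    motif_df.to_csv(out_dir / "motifs.tsv", sep="\t", index=False)

    result.cooccurrence.to_frame(normalized=True).round(6).to_csv(
        out_dir / "cooccur.tsv", sep="\t"
    )
    per_cat, per_fam = result.host_tables
    per_cat.round(6).to_csv(out_dir / "hosts.tsv", sep="\t")
    per_fam.round(6).to_csv(out_dir / "hosts_by_family.tsv", sep="\t")

    # names are stored relative to the run directory so a report is
    # byte-identical across re-runs in different locations
    report.artifacts = {
        name: name
        for name in (
            "hits.tsv",
            "records.tsv",
            "cores.faa",
            "motifs.tsv",
            "cooccur.tsv",
            "hosts.tsv",
            "hosts_by_family.tsv",
            "report.json",
            "report.txt",
        )
    }
    (out_dir / "report.json").write_text(report.to_json() + "\n")
    lines = [
        "rdrpscout run report",
        f"seed: {report.seed}",
        "",
        "stage counts:",
        *(f"  {k}: {v}" for k, v in report.stage_counts.items()),
        "",
        "classification:",
        *(f"  {k}: {v}" for k, v in sorted(report.classification.items())),
        "",
        "clusters:",
        *(f"  {k}: {v}" for k, v in report.cluster_counts.items()),
        "",
        "log:",
        *(f"  {entry}" for entry in report.log),
        "",
    ]
    (out_dir / "report.txt").write_text("\n".join(lines))
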